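"""Strain-sharing detection from marker-gene phylogenies.

For each sufficiently sampled wild-plant module SGB, single-copy core genes
private to that SGB serve as strain markers; per-SGB marker trees yield a
normalized phylogenetic distance (nGD: leaf-to-leaf path length divided by
total tree branch length) between the strains of two individuals.  A
sharing threshold is calibrated per SGB on labelled related/unrelated pair
distances by maximizing Youden's J, subject to at most 5% of unrelated
pairs falling below the threshold (false-sharing bound); query pairs at
nGD <= threshold are called sharing events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import AbundanceTable, GenePresenceMatrix, PhyloTree, ValidationError

logger = logging.getLogger("wildgut")

__all__ = [
    "MarkerSet",
    "StrainPairDistance",
    "SharingThreshold",
    "select_eligible_wpsgbs",
    "select_markers",
    "ngd",
    "calibrate_threshold",
    "call_sharing",
]


@dataclass
class MarkerSet:
    """Strain markers for one SGB: private core genes passing the validity rule."""

    sgb_id: str
    marker_gene_ids: frozenset[str]
    fraction_mags_mapped: dict[str, float]


@dataclass(frozen=True)
class StrainPairDistance:
    """nGD between two individuals' strains of one SGB."""

    sgb_id: str
    sample_a: str
    sample_b: str
    relation: str  # same_group_pair | unrelated_pair | query_pair
    ngd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ngd <= 1.0:
            raise ValidationError(f"nGD {self.ngd} outside [0, 1]")
        if self.relation not in ("same_group_pair", "unrelated_pair", "query_pair"):
            raise ValidationError(f"unknown relation {self.relation}")


@dataclass
class SharingThreshold:
    """Calibrated per-SGB nGD cut-off with its Youden J and false-sharing rate."""

    sgb_id: str
    threshold: float
    youden_j: float
    false_sharing_rate: float
    constrained: bool = False


def select_eligible_wpsgbs(mags_per_sgb: dict[str, int], table: AbundanceTable,
                           group_a: str, group_b: str, min_mags: int = 5,
                           min_gcpm: float = 5.0) -> frozenset[str]:
    """SGBs eligible for strain analysis.

    Requires >= ``min_mags`` MAGs and abundance > ``min_gcpm`` gcpm in at
    least one sample of *each* of the two designated groups (strict bound).
    """
    cols = table.group_columns()
    for g in (group_a, group_b):
        if g not in cols:
            raise ValidationError(f"group {g} absent from table")
    eligible = []
    for i, sgb in enumerate(table.sgb_ids):
        if mags_per_sgb.get(sgb, 0) < min_mags:
            continue
        row = table.values[i]
        if (row[cols[group_a]] > min_gcpm).any() and (row[cols[group_b]] > min_gcpm).any():
            eligible.append(sgb)
    return frozenset(eligible)


def select_markers(presence: GenePresenceMatrix, sgb: str,
                   mapping_stats: pd.DataFrame, min_frac_mags: float = 0.90,
                   min_cov: float = 0.50) -> MarkerSet:
    """Select valid marker genes for one SGB.

    Candidates are genes present in the SGB and absent from every other SGB
    (private core genes); a candidate is a valid marker iff the fraction of
    the SGB's MAGs covering more than ``min_cov`` of its length is at least
    ``min_frac_mags`` (coverage bound strict, fraction bound inclusive).
    ``mapping_stats`` is a gene x MAG DataFrame of coverage fractions.
    """
    if sgb not in presence.sgb_ids:
        raise ValidationError(f"unknown SGB {sgb}")
    col = presence.sgb_ids.index(sgb)
    mat = presence.presence.astype(bool)
    others = np.ones(len(presence.sgb_ids), dtype=bool)
    others[col] = False
    private_core = [
        g for i, g in enumerate(presence.gene_ids)
        if mat[i, col] and not mat[i, others].any()
    ]
    markers = []
    fracs = {}
    for g in private_core:
        if g not in mapping_stats.index:
            continue
        cov = mapping_stats.loc[g].to_numpy(float)
        frac = float((cov > min_cov).mean())
        fracs[g] = frac
        if frac >= min_frac_mags:
            markers.append(g)
    return MarkerSet(sgb, frozenset(markers), fracs)


def ngd(tree: PhyloTree, leaf_a: str, leaf_b: str) -> float:
    """Normalized phylogenetic distance between two leaves.

    Leaf-to-leaf path length divided by the total branch length of the tree.
    """
    total = tree.total_branch_length()
    if total <= 0:
        raise ValidationError("total tree branch length must be > 0")
    return tree.leaf_distance(leaf_a, leaf_b) / total


def calibrate_threshold(related, unrelated, fdr_bound: float = 0.05,
                        sgb_id: str = "") -> SharingThreshold:
    """Choose the nGD sharing threshold from labelled pair distances.

    Candidate thresholds are midpoints of consecutive distinct pooled
    values (plus one candidate below the pooled minimum).  For each
    candidate ``t``: sensitivity = fraction of related pairs with nGD <= t,
    specificity = fraction of unrelated pairs with nGD > t,
    ``J = sensitivity + specificity - 1``.  The chosen ``t`` maximizes J
    subject to the false-sharing bound (fraction of unrelated pairs <= t
    at most ``fdr_bound``); ties break toward smaller t.  If no candidate
    maximizing J satisfies the bound, the largest admissible t is returned
    with ``constrained=True``.
    """
    related = np.asarray(sorted(related), float)
    unrelated = np.asarray(sorted(unrelated), float)
    if related.size == 0 or unrelated.size == 0:
        raise ValidationError("both related and unrelated pair lists must be non-empty")
    pooled = np.unique(np.concatenate([related, unrelated]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if pooled.size > 1 else np.empty(0)
    below = pooled[0] - min(1e-9, pooled[0] / 2 if pooled[0] > 0 else 1e-9)
    candidates = np.concatenate([[below], mids])

    def stats_at(t):
        sens = float((related <= t).mean())
        false_rate = float((unrelated <= t).mean())
        return sens, 1.0 - false_rate, false_rate

    best = None  # (J, t, false_rate)
    for t in candidates:
        sens, spec, fr = stats_at(t)
        if fr > fdr_bound:
            continue
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, fr)
    constrained = False
    # did the bound exclude a strictly better unconstrained candidate?
    j_unc = max(sum(stats_at(t)[:2]) - 1.0 for t in candidates)
    if best is None:
        # every candidate violates the bound: fall back to the largest t kept
        admissible = [t for t in candidates if stats_at(t)[2] <= fdr_bound]
        t = max(admissible) if admissible else float(candidates[0])
        sens, spec, fr = stats_at(t)
        best = (sens + spec - 1.0, t, fr)
        constrained = True
    elif best[0] < j_unc - 1e-12:
        constrained = True
    j, t, fr = best
    return SharingThreshold(sgb_id, float(t), float(j), float(fr), constrained)


def call_sharing(query_pairs: list[StrainPairDistance],
                 thresholds: dict[str, SharingThreshold]):
    """Call strain-sharing events: nGD <= the SGB's threshold (inclusive).

    Returns ``(events, counts)``: the sharing pairs and per-SGB event counts
    (zero rows included for SGBs with calibrated thresholds but no events).
    """
    missing = {p.sgb_id for p in query_pairs} - set(thresholds)
    if missing:
        raise ValidationError(f"no calibrated threshold for SGBs: {sorted(missing)[:5]}")
    events = [
        p for p in query_pairs if p.ngd <= thresholds[p.sgb_id].threshold
    ]
    counts = {sgb: 0 for sgb in thresholds}
    for e in events:
        counts[e.sgb_id] += 1
    return events, pd.Series(counts, name="n_events").sort_index()
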