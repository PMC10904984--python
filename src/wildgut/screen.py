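"""Exclusive-feature screening and RPKM prevalence across metagenome panels.

Genes present only in wild-plant module SGBs (wpSGBs) and annotated in
degradation-relevant categories are screened for prevalence across external
metagenome panels, after RPKM normalisation of aligned-read counts
(reads per kilobase of reference per million mapped reads).  Biosynthetic
gene clusters (BGCs) go through the same prevalence computation, with
results additionally grouped by product class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenePresenceMatrix, MappingCounts, ValidationError

__all__ = [
    "ExclusiveFeature",
    "PrevalenceResult",
    "DEFAULT_SCREEN_CATEGORIES",
    "exclusive_genes",
    "rpkm",
    "prevalence",
    "bgc_prevalence",
]

# the annotation categories of interest for plant-substrate degradation
DEFAULT_SCREEN_CATEGORIES = frozenset({"CAZy-like", "xenobiotic-like"})


@dataclass(frozen=True)
class ExclusiveFeature:
    """A gene carried only by module SGBs, in a screened annotation category."""

    feature_id: str
    owner_sgb_ids: frozenset[str]
    category: str
    length_bp: int


@dataclass
class PrevalenceResult:
    """RPKM, binary presence and per-population prevalence fractions."""

    rpkm: pd.DataFrame            # feature x metagenome
    presence: pd.DataFrame        # binary, same shape
    fractions: pd.DataFrame       # feature x population prevalence in [0, 1]


def exclusive_genes(presence: GenePresenceMatrix, module,
                    categories=DEFAULT_SCREEN_CATEGORIES) -> list[ExclusiveFeature]:
    """Genes present in >= 1 module SGB, absent from every non-module SGB,
    and annotated in one of ``categories``."""
    module = set(module)
    unknown = module - set(presence.sgb_ids)
    if unknown:
        raise ValidationError(f"module SGBs absent from presence matrix: {sorted(unknown)[:5]}")
    in_module = np.array([s in module for s in presence.sgb_ids])
    mat = presence.presence.astype(bool)
    has_module = mat[:, in_module].any(axis=1)
    outside = mat[:, ~in_module].any(axis=1) if (~in_module).any() else np.zeros(
        len(presence.gene_ids), dtype=bool
    )
    out = []
    for i, gene in enumerate(presence.gene_ids):
        if has_module[i] and not outside[i] and presence.annotation_category[i] in categories:
            owners = frozenset(
                s for s, inc, present in zip(presence.sgb_ids, in_module, mat[i])
                if inc and present
            )
            out.append(
                ExclusiveFeature(gene, owners, presence.annotation_category[i],
                                 int(presence.gene_length_bp[i]))
            )
    return out


def rpkm(counts: MappingCounts) -> pd.DataFrame:
    """Reads per kilobase of reference per million mapped reads.

    ``rpkm[f, s] = counts[f, s] / ((length_bp[f] / 1000) * (total_mapped_reads[s] / 1e6))``
    """
    kb = counts.feature_length_bp[:, None] / 1000.0
    per_million = counts.total_mapped_reads[None, :] / 1e6
    vals = counts.counts / (kb * per_million)
    return pd.DataFrame(vals, index=counts.feature_ids, columns=counts.metagenome_ids)


def prevalence(rpkm_matrix: pd.DataFrame, population_labels: dict[str, str],
               presence_threshold: float = 0.0) -> PrevalenceResult:
    """Binary presence (rpkm > threshold) and per-population prevalence.

    ``population_labels`` maps every metagenome id to a population label
    (e.g. rural vs industrialized panels); prevalence is the mean presence
    per population, a fraction in [0, 1].
    """
    missing = [m for m in rpkm_matrix.columns if m not in population_labels]
    if missing:
        raise ValidationError(f"metagenomes without population label: {missing[:5]}")
    pres = (rpkm_matrix > presence_threshold).astype(int)
    pops = pd.Series({m: population_labels[m] for m in rpkm_matrix.columns})
    fractions = pres.T.groupby(pops).mean().T
    return PrevalenceResult(rpkm_matrix, pres, fractions)


def bgc_prevalence(bgc_table: MappingCounts, population_labels: dict[str, str],
                   presence_threshold: float = 0.0):
    """Prevalence of biosynthetic gene clusters, grouped by product class.

    Identical computation to gene prevalence; additionally returns
    per-(product class, population) mean prevalence.  BGC features must
    carry product-class labels (e.g. arylpolyene, terpene, NRPS, T1PKS,
    RiPP-like).
    """
    if bgc_table.feature_class is None:
        raise ValidationError("BGC table must carry product-class labels")
    res = prevalence(rpkm(bgc_table), population_labels, presence_threshold)
    classes = pd.Series(bgc_table.feature_class, index=bgc_table.feature_ids)
    by_class = res.fractions.groupby(classes).mean()
    return res, by_class
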