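"""MAG quality filtering and species-level dereplication.

MAGs passing CheckM-style quality gates (completeness above 50%,
contamination below 5%, both strict) are clustered into species-level
genome bins (SGBs) by single-linkage at 5% genome distance, i.e. the
connected components of the thresholded distance graph.  Within each
cluster the representative is the MAG maximising the dRep-style score
``Q = completeness - 5 x contamination``, with ties broken by larger
genome size, then lexicographic MAG id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .types import DistanceMatrix, MagRecord, ValidationError

__all__ = ["SgbCluster", "qc_filter", "sketch_distance", "dereplicate"]

DEFAULT_DEREP_THRESHOLD = 0.05  # 5% genetic diversity


@dataclass(frozen=True)
class SgbCluster:
    """One species-level genome bin: member MAGs plus a representative."""

    sgb_id: str
    member_mag_ids: frozenset[str]
    representative_mag_id: str

    def __post_init__(self) -> None:
        if not self.member_mag_ids:
            raise ValidationError(f"{self.sgb_id}: empty cluster")
        if self.representative_mag_id not in self.member_mag_ids:
            raise ValidationError(
                f"{self.sgb_id}: representative not among members"
            )


def qc_filter(mags: list[MagRecord], min_completeness: float = 50.0,
              max_contamination: float = 5.0) -> list[MagRecord]:
    """Keep MAGs with completeness > ``min_completeness`` and
    contamination < ``max_contamination`` (both bounds strict)."""
    return [
        m
        for m in mags
        if m.completeness > min_completeness and m.contamination < max_contamination
    ]


def sketch_distance(genome_a: set, genome_b: set, k: int = 21) -> float:
    """Mash-style distance between two k-mer sets.

    ``d = -(1/k) * ln(2j / (1 + j))`` with ``j`` the Jaccard index; 0 for
    identical sets, capped at 1 for disjoint sets.
    """
    if not genome_a or not genome_b:
        raise ValidationError("k-mer sets must be non-empty")
    if k <= 0:
        raise ValidationError("k must be positive")
    inter = len(genome_a & genome_b)
    union = len(genome_a | genome_b)
    j = inter / union
    if j == 0.0:
        return 1.0
    if j == 1.0:
        return 0.0
    d = -(1.0 / k) * math.log(2.0 * j / (1.0 + j))
    return min(d, 1.0)


def _representative(members: list[MagRecord]) -> str:
    # highest Q, then largest genome, then lexicographically smallest id
    best = min(members, key=lambda m: (-m.quality_score, -m.genome_size, m.mag_id))
    return best.mag_id


def dereplicate(mags: list[MagRecord], dist: DistanceMatrix,
                threshold: float = DEFAULT_DEREP_THRESHOLD) -> list[SgbCluster]:
    """Single-linkage dereplication of MAGs into SGBs at ``threshold``.

    Clusters are the connected components of the graph joining MAG pairs at
    distance <= ``threshold``.  Output order is deterministic: clusters
    sorted by their lexicographically smallest member and labelled
    ``SGB_0001`` onwards.
    """
    by_id = {m.mag_id: m for m in mags}
    if len(by_id) != len(mags):
        raise ValidationError("duplicated mag_id in input")
    missing = [m.mag_id for m in mags if m.mag_id not in dist]
    if missing:
        raise ValidationError(f"MAGs absent from distance matrix: {missing[:5]}")

    # union-find over the <= threshold graph
    parent = {m.mag_id: m.mag_id for m in mags}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ids = [m.mag_id for m in mags]
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if dist.get(a, b) <= threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb

    groups: dict[str, list[MagRecord]] = {}
    for m in mags:
        groups.setdefault(find(m.mag_id), []).append(m)

    clusters = sorted(groups.values(), key=lambda ms: min(m.mag_id for m in ms))
    return [
        SgbCluster(
            sgb_id=f"SGB_{i + 1:04d}",
            member_mag_ids=frozenset(m.mag_id for m in members),
            representative_mag_id=_representative(members),
        )
        for i, members in enumerate(clusters)
    ]
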