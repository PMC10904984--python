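"""Shared domain types for the analysis pipeline.

All containers validate their invariants at construction time and raise
:class:`ValidationError` on bad input, so downstream stages can assume
well-formed data.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger("wildgut")

__all__ = [
    "ValidationError",
    "SampleMeta",
    "AbundanceTable",
    "MagRecord",
    "DistanceMatrix",
    "PhyloTree",
    "GenePresenceMatrix",
    "MetabolicNetwork",
    "Reaction",
    "SubstrateProfile",
    "MappingCounts",
]


class ValidationError(ValueError):
    """An input violates a domain-type invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one metagenome sample.

    ``group`` is the cohort label (e.g. ``baka_forest``, ``baka_settled``,
    ``nzime_village``); ``total_reads`` is the sequencing depth used for
    per-million normalisation.
    """

    sample_id: str
    group: str
    total_reads: int

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if not self.group:
            raise ValidationError(f"sample {self.sample_id}: empty group label")
        if self.total_reads <= 0:
            raise ValidationError(
                f"sample {self.sample_id}: total_reads must be > 0, "
                f"got {self.total_reads}"
            )


class AbundanceTable:
    """SGB x sample abundance matrix in genome copies per million reads (gcpm).

    Parameters
    ----------
    sgb_ids
        Row labels; must be unique.
    samples
        One :class:`SampleMeta` per column, order matching ``values``.
    values
        Non-negative matrix of shape ``(len(sgb_ids), len(samples))``.
    """

    def __init__(self, sgb_ids, samples, values) -> None:
        sgb_ids = list(sgb_ids)
        samples = list(samples)
        values = np.asarray(values, dtype=float)
        if len(set(sgb_ids)) != len(sgb_ids):
            raise ValidationError("duplicated sgb_ids in abundance table")
        if len({s.sample_id for s in samples}) != len(samples):
            raise ValidationError("duplicated sample_ids in abundance table")
        if values.shape != (len(sgb_ids), len(samples)):
            raise ValidationError(
                f"value matrix shape {values.shape} inconsistent with "
                f"{len(sgb_ids)} SGBs x {len(samples)} samples"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("abundance values must be finite")
        if np.any(values < 0):
            raise ValidationError("abundance values must be non-negative")
        self.sgb_ids = sgb_ids
        self.samples = samples
        self.values = values

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sgb_ids, columns=self.sample_ids)

    def subset_sgbs(self, keep) -> "AbundanceTable":
        """Return a new table restricted to ``keep`` (order preserved)."""
        keep = set(keep)
        idx = [i for i, s in enumerate(self.sgb_ids) if s in keep]
        return AbundanceTable(
            [self.sgb_ids[i] for i in idx], self.samples, self.values[idx, :]
        )

    def group_columns(self) -> dict[str, np.ndarray]:
        """Column indices per group label."""
        out: dict[str, list[int]] = {}
        for j, s in enumerate(self.samples):
            out.setdefault(s.group, []).append(j)
        return {g: np.asarray(js) for g, js in out.items()}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AbundanceTable)
            and self.sgb_ids == other.sgb_ids
            and self.samples == other.samples
            and np.allclose(self.values, other.values)
        )

    def __repr__(self) -> str:
        return (
            f"AbundanceTable({len(self.sgb_ids)} SGBs x "
            f"{len(self.samples)} samples)"
        )


@dataclass(frozen=True)
class MagRecord:
    """CheckM-style quality record for one metagenome-assembled genome."""

    mag_id: str
    completeness: float
    contamination: float
    genome_size: int = 0
    n_contigs: int = 0
    n50: int = 0
    source_sample: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValidationError(
                f"{self.mag_id}: completeness {self.completeness} outside [0, 100]"
            )
        if self.contamination < 0:
            raise ValidationError(
                f"{self.mag_id}: contamination {self.contamination} < 0"
            )

    @property
    def quality_score(self) -> float:
        """dRep-style score: completeness - 5 x contamination."""
        return self.completeness - 5.0 * self.contamination


class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal.

    Houses pairwise genome distances (dereplication) and UniFrac distances
    between samples.
    """

    _SYM_TOL = 1e-9

    def __init__(self, ids, d) -> None:
        ids = list(ids)
        d = np.asarray(d, dtype=float)
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicated ids in distance matrix")
        if d.shape != (len(ids), len(ids)):
            raise ValidationError("distance matrix shape inconsistent with ids")
        if np.any(d < 0):
            raise ValidationError("distances must be non-negative")
        if np.any(np.abs(np.diag(d)) > self._SYM_TOL):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(np.abs(d - d.T) > self._SYM_TOL):
            raise ValidationError("distance matrix must be symmetric")
        self.ids = ids
        # enforce exact symmetry / zero diagonal after tolerance check
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        self.d = d
        self._index = {g: i for i, g in enumerate(ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def __contains__(self, item: str) -> bool:
        return item in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


class PhyloTree:
    """Rooted phylogeny with branch lengths, wrapping a scikit-bio TreeNode.

    Leaf labels must be unique; missing branch lengths default to zero with a
    logged warning.  Internal node labels are ignored.
    """

    def __init__(self, tree: skbio.TreeNode) -> None:
        n_missing = 0
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
                n_missing += 1
            elif node.length < 0:
                raise ValidationError("negative branch length in tree")
        if tree.length is None:
            tree.length = 0.0
        if n_missing:
            logger.warning(
                "%d branch lengths missing from tree; defaulting to 0", n_missing
            )
        labels = [t.name for t in tree.tips()]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise ValidationError("tree has unnamed leaves")
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicated leaf labels in tree")
        self.tree = tree
        self.leaf_labels = labels

    @classmethod
    def from_newick(cls, source: str) -> "PhyloTree":
        """Parse a Newick string (see :func:`wildgut.io.read_newick` for files)."""
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tree = skbio.TreeNode.read(io.StringIO(source), convert_underscores=False)
        except Exception as exc:  # skbio raises NewickFormatError
            raise ValidationError(f"cannot parse Newick: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue()

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def total_branch_length(self) -> float:
        return float(
            sum(n.length for n in self.tree.traverse(include_self=False))
            + (self.tree.length or 0.0)
        )

    def leaf_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between leaves ``a`` and ``b``."""
        if a == b:
            if a not in self.leaf_labels:
                raise KeyError(a)
            return 0.0
        return float(self.tree.find(a).distance(self.tree.find(b)))


class GenePresenceMatrix:
    """Pangenome gene x SGB presence/absence with per-gene annotation.

    ``annotation_category`` is one of ``{"CAZy-like", "xenobiotic-like",
    "other", "none"}`` — the first two stand for the carbohydrate-active and
    xenobiotic-degradation annotation databases used in the exclusivity
    screen.
    """

    CATEGORIES = ("CAZy-like", "xenobiotic-like", "other", "none")

    def __init__(self, gene_ids, sgb_ids, presence, gene_length_bp, annotation_category) -> None:
        gene_ids = list(gene_ids)
        sgb_ids = list(sgb_ids)
        presence = np.asarray(presence)
        gene_length_bp = np.asarray(gene_length_bp, dtype=int)
        annotation_category = list(annotation_category)
        if len(set(gene_ids)) != len(gene_ids):
            raise ValidationError("duplicated gene_ids")
        if len(set(sgb_ids)) != len(sgb_ids):
            raise ValidationError("duplicated sgb_ids")
        if presence.shape != (len(gene_ids), len(sgb_ids)):
            raise ValidationError("presence matrix shape inconsistent")
        if not np.isin(presence, (0, 1)).all():
            raise ValidationError("presence values must be 0 or 1")
        if gene_length_bp.shape != (len(gene_ids),) or np.any(gene_length_bp <= 0):
            raise ValidationError("gene_length_bp must be positive, one per gene")
        bad = set(annotation_category) - set(self.CATEGORIES)
        if bad:
            raise ValidationError(f"unknown annotation categories: {sorted(bad)}")
        self.gene_ids = gene_ids
        self.sgb_ids = sgb_ids
        self.presence = presence.astype(np.int8)
        self.gene_length_bp = gene_length_bp
        self.annotation_category = annotation_category


@dataclass(frozen=True)
class Reaction:
    """One boolean-logic reaction: fires when all substrates are reachable."""

    substrates: frozenset[str]
    products: frozenset[str]

    def __post_init__(self) -> None:
        if not self.substrates:
            raise ValidationError("reaction with empty substrate set")
        if not self.products:
            raise ValidationError("reaction with empty product set")
        if any(not m for m in self.substrates | self.products):
            raise ValidationError("empty metabolite id in reaction")

    @staticmethod
    def make(substrates, products) -> "Reaction":
        return Reaction(frozenset(substrates), frozenset(products))


@dataclass
class MetabolicNetwork:
    """Per-species reaction set in the boolean network-expansion formalism.

    Reversible reactions are encoded as two explicit directed reactions.
    """

    species_id: str
    reactions: set[Reaction] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValidationError("empty species_id")
        self.reactions = set(self.reactions)

    def __len__(self) -> int:
        return len(self.reactions)


@dataclass
class SubstrateProfile:
    """Seed and target metabolites of one wild-plant substrate.

    Seeds are the metabolites the plant food supplies; targets are the
    degradation products whose community-level producibility defines
    substrate usage.
    """

    plant_name: str
    seed_metabolites: frozenset[str]
    target_metabolites: frozenset[str]

    def __post_init__(self) -> None:
        self.seed_metabolites = frozenset(self.seed_metabolites)
        self.target_metabolites = frozenset(self.target_metabolites)
        if not self.seed_metabolites or not self.target_metabolites:
            raise ValidationError(
                f"{self.plant_name}: seeds and targets must both be non-empty"
            )
        if self.seed_metabolites & self.target_metabolites:
            raise ValidationError(
                f"{self.plant_name}: seeds and targets must be disjoint"
            )


class MappingCounts:
    """Aligned-read counts of features (genes or BGCs) across metagenomes.

    Used for RPKM prevalence screening; ``total_mapped_reads`` is the
    per-metagenome library size of mapped reads.
    """

    def __init__(self, feature_ids, feature_length_bp, metagenome_ids, counts,
                 total_mapped_reads, feature_class=None) -> None:
        feature_ids = list(feature_ids)
        metagenome_ids = list(metagenome_ids)
        feature_length_bp = np.asarray(feature_length_bp, dtype=int)
        counts = np.asarray(counts)
        total_mapped_reads = np.asarray(total_mapped_reads, dtype=np.int64)
        if len(set(feature_ids)) != len(feature_ids):
            raise ValidationError("duplicated feature_ids")
        if len(set(metagenome_ids)) != len(metagenome_ids):
            raise ValidationError("duplicated metagenome_ids")
        if counts.shape != (len(feature_ids), len(metagenome_ids)):
            raise ValidationError("counts shape inconsistent")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.number):
            raise ValidationError("counts must be non-negative")
        if np.any(counts != np.round(counts)):
            raise ValidationError("counts must be integers")
        if np.any(feature_length_bp <= 0):
            raise ValidationError("feature lengths must be > 0")
        if np.any(total_mapped_reads <= 0):
            raise ValidationError("total_mapped_reads must be > 0")
        if feature_class is not None:
            feature_class = list(feature_class)
            if len(feature_class) != len(feature_ids):
                raise ValidationError("feature_class length mismatch")
        self.feature_ids = feature_ids
        self.feature_length_bp = feature_length_bp
        self.metagenome_ids = metagenome_ids
        self.counts = counts.astype(np.int64)
        self.total_mapped_reads = total_mapped_reads
        self.feature_class = feature_class
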