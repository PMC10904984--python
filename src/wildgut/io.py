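"""Readers and writers for the pipeline's on-disk formats.

Conventions: TSV is tab-separated with a header row, UTF-8, ``.`` decimal
separator.  Trees are single-tree Newick.  Metabolic networks and substrate
profiles are JSON.  Every reader validates against the domain-type
invariants and raises :class:`~wildgut.types.ValidationError` on violation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    AbundanceTable,
    GenePresenceMatrix,
    MagRecord,
    MappingCounts,
    MetabolicNetwork,
    PhyloTree,
    Reaction,
    SampleMeta,
    SubstrateProfile,
    ValidationError,
)

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_sample_metadata",
    "read_newick",
    "write_newick",
    "read_metabolic_networks",
    "write_metabolic_networks",
    "read_substrate_profiles",
    "write_substrate_profiles",
    "read_mag_records",
    "write_mag_records",
    "read_gene_presence",
    "write_gene_presence",
    "read_mapping_counts",
    "write_mapping_counts",
    "read_distance_matrix",
    "write_distance_matrix",
]

# stable float formatting so repeated runs are byte-identical
FLOAT_FMT = "%.10g"


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_metadata(meta_path) -> dict[str, SampleMeta]:
    """Read a sample metadata TSV with columns sample_id, group, total_reads."""
    df = pd.read_csv(meta_path, sep="\t")
    required = {"sample_id", "group", "total_reads"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"metadata must have columns {sorted(required)}, got {list(df.columns)}"
        )
    metas = {}
    for row in df.itertuples(index=False):
        if row.sample_id in metas:
            raise ValidationError(f"duplicated sample_id {row.sample_id} in metadata")
        metas[str(row.sample_id)] = SampleMeta(
            str(row.sample_id), str(row.group), int(row.total_reads)
        )
    return metas


def read_abundance_table(path, meta_path) -> AbundanceTable:
    """Read an SGB x sample gcpm TSV plus its sample metadata TSV.

    Samples missing from the metadata are rejected; metadata rows without a
    matching column are ignored.
    """
    df = _read_tsv(path)
    metas = read_sample_metadata(meta_path)
    missing = [c for c in df.columns if c not in metas]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")
    samples = [metas[c] for c in df.columns]
    return AbundanceTable(df.index.astype(str).tolist(), samples, df.to_numpy(float))


def write_abundance_table(table: AbundanceTable, path, meta_path) -> None:
    table.to_frame().to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="sgb_id")
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in table.samples],
            "group": [s.group for s in table.samples],
            "total_reads": [s.total_reads for s in table.samples],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def read_newick(path) -> PhyloTree:
    """Read a single rooted Newick tree with branch lengths."""
    text = Path(path).read_text().strip()
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.to_newick())


def read_metabolic_networks(path) -> list[MetabolicNetwork]:
    """Read per-species metabolic networks from JSON.

    Layout: ``{"species_id": [{"substrates": [...], "products": [...]}, ...]}``.
    """
    data = json.loads(Path(path).read_text())
    nets = []
    for species_id, reactions in data.items():
        rset = {
            Reaction.make(r["substrates"], r["products"]) for r in reactions
        }
        nets.append(MetabolicNetwork(species_id, rset))
    return nets


def write_metabolic_networks(networks, path) -> None:
    data = {
        net.species_id: [
            {"substrates": sorted(r.substrates), "products": sorted(r.products)}
            for r in sorted(
                net.reactions, key=lambda r: (sorted(r.substrates), sorted(r.products))
            )
        ]
        for net in sorted(networks, key=lambda n: n.species_id)
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")


def read_substrate_profiles(path) -> list[SubstrateProfile]:
    """Read plant substrate profiles from JSON: {plant: {seeds: [...], targets: [...]}}."""
    data = json.loads(Path(path).read_text())
    return [
        SubstrateProfile(plant, frozenset(spec["seeds"]), frozenset(spec["targets"]))
        for plant, spec in data.items()
    ]


def write_substrate_profiles(profiles, path) -> None:
    data = {
        p.plant_name: {
            "seeds": sorted(p.seed_metabolites),
            "targets": sorted(p.target_metabolites),
        }
        for p in sorted(profiles, key=lambda p: p.plant_name)
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")


_MAG_COLUMNS = [
    "completeness",
    "contamination",
    "genome_size",
    "n_contigs",
    "n50",
    "source_sample",
]


def read_mag_records(path) -> list[MagRecord]:
    """Read a per-MAG QC TSV (CheckM-style columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"mag_id": str})
    if "mag_id" not in df.columns:
        raise ValidationError("QC table must have a mag_id column")
    if df["mag_id"].duplicated().any():
        raise ValidationError("duplicated mag_id in QC table")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MagRecord(
                mag_id=row.mag_id,
                completeness=float(row.completeness),
                contamination=float(row.contamination),
                genome_size=int(getattr(row, "genome_size", 0) or 0),
                n_contigs=int(getattr(row, "n_contigs", 0) or 0),
                n50=int(getattr(row, "n50", 0) or 0),
                source_sample=str(getattr(row, "source_sample", "") or ""),
            )
        )
    return records


def write_mag_records(records, path) -> None:
    df = pd.DataFrame(
        [
            {
                "mag_id": r.mag_id,
                **{c: getattr(r, c) for c in _MAG_COLUMNS},
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_gene_presence(path, annot_path) -> GenePresenceMatrix:
    """Read a gene x SGB presence TSV plus an annotation TSV.

    The annotation TSV has columns gene_id, length_bp, category.
    """
    pres = _read_tsv(path)
    annot = pd.read_csv(annot_path, sep="\t", index_col="gene_id")
    missing = pres.index.difference(annot.index)
    if len(missing):
        raise ValidationError(f"genes missing annotation: {list(missing)[:5]}")
    annot = annot.loc[pres.index]
    return GenePresenceMatrix(
        pres.index.astype(str).tolist(),
        pres.columns.astype(str).tolist(),
        pres.to_numpy(),
        annot["length_bp"].to_numpy(int),
        annot["category"].astype(str).tolist(),
    )


def write_gene_presence(gpm: GenePresenceMatrix, path, annot_path) -> None:
    pd.DataFrame(gpm.presence, index=gpm.gene_ids, columns=gpm.sgb_ids).to_csv(
        path, sep="\t", index_label="gene_id"
    )
    pd.DataFrame(
        {
            "gene_id": gpm.gene_ids,
            "length_bp": gpm.gene_length_bp,
            "category": gpm.annotation_category,
        }
    ).to_csv(annot_path, sep="\t", index=False)


def read_mapping_counts(path, feature_path, totals_path) -> MappingCounts:
    """Read feature x metagenome counts, feature lengths/classes, library sizes."""
    counts = _read_tsv(path)
    feats = pd.read_csv(feature_path, sep="\t", index_col="feature_id")
    totals = pd.read_csv(totals_path, sep="\t", index_col="metagenome_id")
    missing = counts.index.difference(feats.index)
    if len(missing):
        raise ValidationError(f"features missing length info: {list(missing)[:5]}")
    missing = counts.columns.difference(totals.index)
    if len(missing):
        raise ValidationError(f"metagenomes missing totals: {list(missing)[:5]}")
    feats = feats.loc[counts.index]
    classes = (
        feats["feature_class"].astype(str).tolist()
        if "feature_class" in feats.columns
        else None
    )
    return MappingCounts(
        counts.index.astype(str).tolist(),
        feats["length_bp"].to_numpy(int),
        counts.columns.astype(str).tolist(),
        counts.to_numpy(),
        totals.loc[counts.columns, "total_mapped_reads"].to_numpy(np.int64),
        feature_class=classes,
    )


def write_mapping_counts(mc: MappingCounts, path, feature_path, totals_path) -> None:
    pd.DataFrame(mc.counts, index=mc.feature_ids, columns=mc.metagenome_ids).to_csv(
        path, sep="\t", index_label="feature_id"
    )
    feats = pd.DataFrame({"feature_id": mc.feature_ids, "length_bp": mc.feature_length_bp})
    if mc.feature_class is not None:
        feats["feature_class"] = mc.feature_class
    feats.to_csv(feature_path, sep="\t", index=False)
    pd.DataFrame(
        {"metagenome_id": mc.metagenome_ids, "total_mapped_reads": mc.total_mapped_reads}
    ).to_csv(totals_path, sep="\t", index=False)


def read_distance_matrix(path):
    from .types import DistanceMatrix

    df = _read_tsv(path)
    if list(df.index) != list(df.columns):
        raise ValidationError("distance matrix rows and columns must match")
    return DistanceMatrix(df.index.astype(str).tolist(), df.to_numpy(float))


def write_distance_matrix(dm, path) -> None:
    dm.to_frame().to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="id")
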