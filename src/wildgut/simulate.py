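"""Synthetic cohorts with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes —
a three-group cohort with a compositional gradient and a planted
high-abundance module, pangenomes with planted module-exclusive annotated
genes, metabolic networks with planted substrate-degrader guilds, and
marker trees realizing prescribed related/unrelated strain-distance
distributions — so the whole pipeline runs end-to-end with no downloads
and every downstream call can be scored against planted truth.

Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .types import (
    AbundanceTable,
    GenePresenceMatrix,
    MetabolicNetwork,
    PhyloTree,
    Reaction,
    SampleMeta,
    SubstrateProfile,
    ValidationError,
)
from .metabolism import scope

__all__ = [
    "GROUPS",
    "CohortSpec",
    "NetworkSpec",
    "StrainSpec",
    "GeneratedPair",
    "gen_cohort",
    "gen_pangenome",
    "gen_networks",
    "gen_strain_pairs",
    "gen_mapping_counts",
]

# cohort groups, ordered along the lifestyle gradient
GROUPS = ("baka_forest", "baka_settled", "nzime_village")

# the five wild-plant substrates, with their dietary-recall intake frequencies
PLANTS = (
    ("Gnetum_africanum", 40.7),
    ("Irvingia_spp", 8.4),
    ("Baillonella_toxisperma", 5.9),
    ("Afrostyrax_lepidophyllus", 1.5),
    ("Panda_oleosa", 1.3),
)


@dataclass
class CohortSpec:
    """Three-group cohort with a compositional gradient and a planted module.

    Defaults mirror a field-scale cohort: 161 SGBs across 16 forest, 10 settled
    and 18 village samples; a 26-SGB module elevated along the
    village-to-forest gradient; log-normal noise.  ``gradient_effect`` and
    ``module_effect`` are log2-fold changes per group step.
    """

    n_sgbs: int = 161
    n_samples_per_group: tuple[int, int, int] = (16, 10, 18)
    n_gradient_sgbs: int = 12
    gradient_effect: float = 2.0
    n_module_sgbs: int = 26
    module_effect: float = 1.0
    noise_sigma: float = 1.0
    detection_limit_gcpm: float = 5.0
    total_gcpm: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma <= 0:
            raise ValidationError("noise_sigma must be > 0")
        if self.n_gradient_sgbs + self.n_module_sgbs > self.n_sgbs // 2:
            raise ValidationError(
                "planted sets exceed the detectable half of the SGB universe"
            )


def _random_tree(ids: list[str], rng: np.random.Generator) -> PhyloTree:
    """Random coalescent-style rooted binary tree with exponential branch lengths."""
    nodes = [TreeNode(name=i, length=float(rng.exponential(0.1))) for i in ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.1)), children=[a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return PhyloTree(root)


def gen_cohort(spec: CohortSpec):
    """Generate ``(AbundanceTable, PhyloTree, ground_truth)``.

    Abundances are log-normal with multiplicative group effects on the
    planted gradient and module SGBs, closed so every sample sums to
    ``spec.total_gcpm`` (per-million compositional normalisation); values
    below the detection limit are zeroed, reproducing the abundance-coupled
    zero pattern of real gcpm tables, and columns are re-closed.  Half of
    the gradient SGBs increase toward the village group, half decrease.
    """
    rng = np.random.default_rng(spec.seed)
    sgb_ids = [f"SGB_{i + 1:04d}" for i in range(spec.n_sgbs)]
    # per-SGB baseline spans several orders of magnitude, as real gcpm
    # profiles do; sd 3 in natural log is ~1.3 decades
    base_mu = rng.normal(0.0, 3.0, size=spec.n_sgbs)
    # plant effects on well-detected taxa (above-median baseline): the
    # trends being emulated concern abundant, reliably assembled species
    detectable = np.flatnonzero(base_mu >= np.median(base_mu))
    chosen = rng.choice(detectable, size=spec.n_gradient_sgbs + spec.n_module_sgbs,
                        replace=False)
    gradient_idx = chosen[: spec.n_gradient_sgbs]
    module_idx = chosen[spec.n_gradient_sgbs:]
    directions = np.where(np.arange(spec.n_gradient_sgbs) % 2 == 0, 1.0, -1.0)

    samples = []
    for g, (group, n) in enumerate(zip(GROUPS, spec.n_samples_per_group)):
        for k in range(n):
            # sequencing depth around a typical 8.1M +/- 1.9M shotgun library
            depth = max(int(rng.normal(8.1e6, 1.9e6)), 1_000_000)
            samples.append(SampleMeta(f"{group}_{k + 1:02d}", group, depth))

    values = np.empty((spec.n_sgbs, len(samples)))
    col = 0
    for g, n in enumerate(spec.n_samples_per_group):
        mu = base_mu.copy()
        mu[gradient_idx] += math.log(2) * spec.gradient_effect * directions * g
        # module SGBs are most abundant in the forest group (step 2 - g)
        mu[module_idx] += math.log(2) * spec.module_effect * (2 - g)
        for _ in range(n):
            values[:, col] = np.exp(mu + rng.normal(0.0, spec.noise_sigma,
                                                    size=spec.n_sgbs))
            col += 1

    def close(v):
        totals = v.sum(axis=0, keepdims=True)
        totals[totals == 0] = 1.0
        return v * (spec.total_gcpm / totals)

    values = close(values)
    values[values < spec.detection_limit_gcpm] = 0.0
    values = close(values)

    table = AbundanceTable(sgb_ids, samples, values)
    tree = _random_tree(sgb_ids, rng)
    truth = {
        "gradient_sgbs": [sgb_ids[i] for i in gradient_idx],
        "gradient_directions": {
            sgb_ids[i]: int(d) for i, d in zip(gradient_idx, directions)
        },
        "module_sgbs": [sgb_ids[i] for i in module_idx],
        "groups": list(GROUPS),
    }
    return table, tree, truth


def gen_pangenome(n_genes: int, sgb_ids: list[str], module, n_exclusive: int,
                  categories=("CAZy-like", "xenobiotic-like"), seed: int = 0,
                  background_presence: float = 0.3):
    """Generate a pangenome presence matrix with planted exclusive genes.

    ``n_exclusive`` annotated genes are planted only in module SGBs; the
    remaining background genes are scattered freely, except that annotated
    background genes are forced to appear in at least one non-module SGB so
    the planted set is exactly the module-exclusive annotated set.
    """
    rng = np.random.default_rng(seed)
    module = sorted(set(module))
    non_module = [s for s in sgb_ids if s not in set(module)]
    if n_exclusive > 0 and not module:
        raise ValidationError("cannot plant exclusive genes without a module")
    if n_exclusive > n_genes:
        raise ValidationError("n_exclusive exceeds n_genes")
    categories = list(categories)
    sgb_index = {s: j for j, s in enumerate(sgb_ids)}
    presence = np.zeros((n_genes, len(sgb_ids)), dtype=np.int8)
    cats = []
    gene_ids = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    all_cats = ["CAZy-like", "xenobiotic-like", "other", "none"]
    for i in range(n_genes):
        if i < n_exclusive:
            owners = rng.choice(module, size=rng.integers(1, min(3, len(module)) + 1),
                                replace=False)
            for s in owners:
                presence[i, sgb_index[s]] = 1
            cats.append(categories[int(rng.integers(len(categories)))])
        else:
            row = rng.random(len(sgb_ids)) < background_presence
            cat = all_cats[int(rng.integers(len(all_cats)))]
            if cat in categories and non_module:
                # keep annotated background genes non-exclusive by construction
                row[sgb_index[non_module[int(rng.integers(len(non_module)))]]] = True
            if not row.any():
                row[int(rng.integers(len(sgb_ids)))] = True
            presence[i, row] = 1
            cats.append(cat)
    lengths = rng.integers(300, 3001, size=n_genes)
    gpm = GenePresenceMatrix(gene_ids, list(sgb_ids), presence, lengths, cats)
    truth = {"exclusive_genes": gene_ids[:n_exclusive], "module": module}
    return gpm, truth


@dataclass
class NetworkSpec:
    """Metabolic networks with planted substrate-degrader guilds.

    One obligate cross-feeding guild per plant profile: the chain
    seed -> intermediates -> targets is split across the guild members, so
    every member is essential for that substrate.  Defaults mirror the
    cohort scale: 161 species, five plant profiles, guilds summing to a
    26-species module.  Distractor reactions consume seeds or distractor
    metabolites and produce only distractor metabolites, so they can never
    complete a chain (audited at generation time).
    """

    n_species: int = 161
    guild_sizes: tuple[int, ...] = (6, 6, 5, 5, 4)
    distractor_reactions_per_species: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.guild_sizes) > self.n_species:
            raise ValidationError("guilds exceed the species universe")
        if len(self.guild_sizes) > len(PLANTS):
            raise ValidationError(f"at most {len(PLANTS)} plant profiles supported")


def gen_networks(spec: NetworkSpec):
    """Generate ``(networks, profiles, ground_truth)`` with planted guilds."""
    rng = np.random.default_rng(spec.seed)
    species = [f"SGB_{i + 1:04d}" for i in range(spec.n_species)]
    order = rng.permutation(spec.n_species)
    nets = {s: MetabolicNetwork(s, set()) for s in species}
    profiles = []
    truth_guilds = {}
    pos = 0
    for (plant, _freq), size in zip(PLANTS, spec.guild_sizes):
        guild = [species[i] for i in order[pos: pos + size]]
        pos += size
        seeds = frozenset({f"{plant}:seed1", f"{plant}:seed2"})
        chain = [f"{plant}:int{j}" for j in range(1, size)]
        targets = frozenset({f"{plant}:target"})
        stages = [frozenset(seeds)] + [frozenset({c}) for c in chain] + [targets]
        for k, member in enumerate(guild):
            nets[member].reactions.add(Reaction(stages[k], stages[k + 1]))
        profiles.append(SubstrateProfile(plant, seeds, targets))
        truth_guilds[plant] = sorted(guild)

    # distractor reactions: inputs from seeds/distractor pool, outputs only
    # distractor metabolites, so no chain can be completed without its guild
    distractor_pool = [f"junk{j}" for j in range(3 * spec.n_species)]
    seed_pool = sorted({m for p in profiles for m in p.seed_metabolites})
    for s in species:
        for _ in range(spec.distractor_reactions_per_species):
            n_sub = int(rng.integers(1, 3))
            subs = set(
                rng.choice(seed_pool + distractor_pool, size=n_sub, replace=False)
            )
            prods = set(
                rng.choice(distractor_pool, size=int(rng.integers(1, 3)),
                           replace=False)
            ) - subs
            if prods:
                nets[s].reactions.add(Reaction(frozenset(subs), frozenset(prods)))

    networks = [nets[s] for s in species]
    # generation-time audit: without its guild, no profile's target is reachable
    for profile in profiles:
        guild = set(truth_guilds[profile.plant_name])
        rest = [n for n in networks if n.species_id not in guild]
        reach = scope(rest, frozenset(n.species_id for n in rest),
                      profile.seed_metabolites).reachable_metabolites
        if profile.target_metabolites & reach:
            raise AssertionError(
                f"{profile.plant_name}: distractors completed the chain"
            )
    truth = {
        "guilds": truth_guilds,
        "module": sorted({s for g in truth_guilds.values() for s in g}),
    }
    return networks, profiles, truth


@dataclass
class StrainSpec:
    """Related/unrelated strain-pair nGD distributions to realize in trees.

    Defaults place related pairs (same-group strain retention) at nGD
    around 0.01 and unrelated pairs around 0.5, i.e. well separated; the
    draws are truncated into (0, 0.94] so each value is realizable in a
    three-leaf tree of unit total length.
    """

    n_related_pairs: int = 30
    n_unrelated_pairs: int = 30
    related_mean: float = 0.01
    related_sd: float = 0.005
    unrelated_mean: float = 0.5
    unrelated_sd: float = 0.05
    seed: int = 0


@dataclass(frozen=True)
class GeneratedPair:
    tree_index: int
    leaf_a: str
    leaf_b: str
    relation: str  # same_group_pair | unrelated_pair
    ngd_target: float


def _pair_tree(g: float, idx: int) -> tuple[PhyloTree, str, str]:
    """A 3-leaf tree of unit total length whose cherry pair has nGD ``g``."""
    b = g / 2.0
    c = min(0.02, (1.0 - g) / 4.0)
    out = 1.0 - 2.0 * b - c
    a_name, b_name = f"P{idx}_a", f"P{idx}_b"
    newick = f"(({a_name}:{b:.12g},{b_name}:{b:.12g}):{c:.12g},OUT{idx}:{out:.12g});"
    return PhyloTree.from_newick(newick), a_name, b_name


def gen_strain_pairs(spec: StrainSpec):
    """Generate ``(trees, pairs, ground_truth)``.

    Each pair lives on its own three-leaf tree (a cherry plus an outgroup
    branch tuning the total length), so the requested nGD is realized
    exactly and pairs are independent.
    """
    rng = np.random.default_rng(spec.seed)

    def draw(mean, sd, n):
        return np.clip(rng.normal(mean, sd, size=n), 1e-4, 0.94)

    related = draw(spec.related_mean, spec.related_sd, spec.n_related_pairs)
    unrelated = draw(spec.unrelated_mean, spec.unrelated_sd, spec.n_unrelated_pairs)
    trees: list[PhyloTree] = []
    pairs: list[GeneratedPair] = []
    for relation, values in (("same_group_pair", related),
                             ("unrelated_pair", unrelated)):
        for g in values:
            idx = len(trees)
            tree, a, b = _pair_tree(float(g), idx)
            trees.append(tree)
            pairs.append(GeneratedPair(idx, a, b, relation, float(g)))
    truth = {
        "related_ngd": related.tolist(),
        "unrelated_ngd": unrelated.tolist(),
    }
    return trees, pairs, truth


def gen_mapping_counts(feature_ids, feature_length_bp, n_rural: int = 10,
                       n_industrial: int = 10, rural_only_features=(),
                       mean_depth: float = 5e6, seed: int = 0,
                       feature_class=None):
    """Synthetic aligned-read counts across a rural/industrialized panel.

    Features in ``rural_only_features`` receive positive counts only in
    rural metagenomes (planted truth: prevalence 1.0 rural, 0.0
    industrial); all other features are detected everywhere.  Returns
    ``(MappingCounts, population_labels, ground_truth)``.
    """
    from .types import MappingCounts

    rng = np.random.default_rng(seed)
    feature_ids = list(feature_ids)
    rural_only = set(rural_only_features)
    unknown = rural_only - set(feature_ids)
    if unknown:
        raise ValidationError(f"unknown rural-only features: {sorted(unknown)[:5]}")
    metas = [f"rural_{i + 1:02d}" for i in range(n_rural)] + [
        f"industrial_{i + 1:02d}" for i in range(n_industrial)
    ]
    labels = {m: ("rural" if m.startswith("rural") else "industrial") for m in metas}
    totals = np.maximum(rng.normal(mean_depth, mean_depth / 5, size=len(metas)),
                        1e5).astype(np.int64)
    lengths = np.asarray(feature_length_bp, dtype=int)
    counts = np.zeros((len(feature_ids), len(metas)), dtype=np.int64)
    for i, f in enumerate(feature_ids):
        for j, m in enumerate(metas):
            if f in rural_only and labels[m] == "industrial":
                continue
            # expected coverage scales with feature length and library size
            lam = 20.0 * lengths[i] / 1000.0 * totals[j] / mean_depth
            counts[i, j] = 1 + rng.poisson(lam)
    mc = MappingCounts(feature_ids, lengths, metas, counts, totals,
                       feature_class=feature_class)
    truth = {"rural_only": sorted(rural_only)}
    return mc, labels, truth
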