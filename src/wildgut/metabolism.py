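"""Metabolic key-species identification by boolean network expansion.

Per-species genome-scale reaction networks are combined into a community
network; reachability from a substrate profile's seed metabolites is
computed by network expansion (a reaction fires when all of its substrates
are reachable, adding its products, iterated to fixpoint).  Key species for
a substrate are derived from the inclusion-minimal communities whose
combined scope produces all community-producible targets: species in every
minimal community are *essential*, species in some but not all are
*alternative*.  The union over substrate profiles of essential and
alternative species is the wild-plant module (wpSGBs).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import two_group_test
from .types import AbundanceTable, MetabolicNetwork, SubstrateProfile, ValidationError

logger = logging.getLogger("wildgut")

__all__ = [
    "ScopeResult",
    "KeySpeciesResult",
    "scope",
    "producible_targets",
    "minimal_communities",
    "wp_module",
    "module_abundance_test",
]

EXHAUSTIVE_CUTOFF = 20  # species count above which enumeration degrades to greedy


@dataclass
class ScopeResult:
    """Fixpoint of network expansion: reachable metabolites of a community."""

    species_set: frozenset[str]
    reachable_metabolites: frozenset[str]


@dataclass
class KeySpeciesResult:
    """Key-species classification for one substrate profile."""

    plant_name: str
    producible_targets: frozenset[str]
    essential_species: frozenset[str]
    alternative_species: frozenset[str]
    minimal_communities: list[frozenset[str]] = field(default_factory=list)
    exhaustive: bool = True


def _reaction_pool(networks: list[MetabolicNetwork], species_subset) -> list:
    by_species = {n.species_id: n for n in networks}
    if len(by_species) != len(networks):
        raise ValidationError("duplicated species_id among networks")
    unknown = set(species_subset) - set(by_species)
    if unknown:
        raise ValidationError(f"unknown species ids: {sorted(unknown)[:5]}")
    pool = []
    for sp in species_subset:
        pool.extend(by_species[sp].reactions)
    return pool


def _expand(reactions, seeds: frozenset[str]) -> frozenset[str]:
    """Iterate reaction firing to fixpoint; monotone and bounded, so it halts."""
    reachable = set(seeds)
    pending = list(reactions)
    changed = True
    while changed:
        changed = False
        rest = []
        for r in pending:
            if r.substrates <= reachable:
                if not r.products <= reachable:
                    reachable |= r.products
                    changed = True
            else:
                rest.append(r)
        pending = rest
    return frozenset(reachable)


def scope(networks: list[MetabolicNetwork], species_subset, seeds) -> ScopeResult:
    """Community-level network expansion from ``seeds``.

    A reaction of any species in ``species_subset`` fires when all its
    substrates are in the current reachable set; products are added; the
    result is the fixpoint.
    """
    species_subset = frozenset(species_subset)
    pool = _reaction_pool(networks, species_subset)
    return ScopeResult(species_subset, _expand(pool, frozenset(seeds)))


def producible_targets(networks, species_subset, profile: SubstrateProfile) -> frozenset[str]:
    """Targets of ``profile`` reachable by the community from its seeds."""
    res = scope(networks, species_subset, profile.seed_metabolites)
    return frozenset(profile.target_metabolites & res.reachable_metabolites)


def _covers(networks_by_sp, subset, seeds, targets) -> bool:
    pool = []
    for sp in subset:
        pool.extend(networks_by_sp[sp].reactions)
    return targets <= _expand(pool, seeds)


def minimal_communities(networks: list[MetabolicNetwork], profile: SubstrateProfile,
                        max_size: int = 8,
                        exhaustive_cutoff: int = EXHAUSTIVE_CUTOFF) -> KeySpeciesResult:
    """Enumerate inclusion-minimal communities covering all producible targets.

    Targets producible by the full community are determined first; minimal
    communities are all inclusion-minimal species subsets of size
    <= ``max_size`` whose scope covers them.  With more than
    ``exhaustive_cutoff`` candidate species the search degrades to greedy
    set-cover seeding with minimality pruning (essentiality stays exact via
    leave-one-out on the full community; alternative species come from
    greedy covers forced to include each remaining candidate) and
    ``exhaustive`` is False.
    """
    by_sp = {n.species_id: n for n in networks}
    all_species = frozenset(by_sp)
    seeds = profile.seed_metabolites
    targets = producible_targets(networks, all_species, profile)
    if not targets:
        return KeySpeciesResult(profile.plant_name, frozenset(), frozenset(),
                                frozenset(), [], True)

    # a minimal-community member fires at least one reaction inside the
    # community scope, which is contained in the full scope (monotonicity),
    # so species inert under the full scope can be dropped up front
    full_reach = scope(networks, all_species, seeds).reachable_metabolites
    candidates = sorted(
        sp for sp in all_species
        if any(r.substrates <= full_reach for r in by_sp[sp].reactions)
    )

    if len(candidates) <= exhaustive_cutoff:
        minimal: list[frozenset[str]] = []
        for size in range(1, min(max_size, len(candidates)) + 1):
            for combo in itertools.combinations(candidates, size):
                cset = frozenset(combo)
                if any(m <= cset for m in minimal):
                    continue
                if _covers(by_sp, cset, seeds, targets):
                    minimal.append(cset)
        exhaustive = True
    else:
        logger.warning(
            "%s: %d candidate species exceeds the exhaustive cutoff; "
            "using greedy set-cover seeding (results may miss minimal communities)",
            profile.plant_name, len(candidates),
        )
        return _greedy_key_species(networks, by_sp, profile, candidates,
                                   seeds, targets)

    if not minimal:
        logger.warning(
            "%s: no community of size <= %d covers the producible targets",
            profile.plant_name, max_size,
        )
        return KeySpeciesResult(profile.plant_name, targets, frozenset(),
                                frozenset(), [], exhaustive)
    essential = frozenset.intersection(*minimal)
    alternative = frozenset.union(*minimal) - essential
    return KeySpeciesResult(profile.plant_name, targets, essential, alternative,
                            minimal, exhaustive)


def _greedy_prune(by_sp, community: set[str], seeds, targets,
                  keep: set[str]) -> set[str]:
    """Drop removable members (never touching ``keep``) until inclusion-minimal."""
    for sp in sorted(community - keep):
        trial = community - {sp}
        if trial and _covers(by_sp, trial, seeds, targets):
            community = trial
    # members of ``keep`` are last to go, so forced species survive if possible
    for sp in sorted(community & keep):
        trial = community - {sp}
        if trial and _covers(by_sp, trial, seeds, targets):
            community = trial
    return community


def _greedy_cover(networks, candidates, seeds, targets,
                  start: set[str]) -> set[str] | None:
    community = set(start)
    covered = frozenset(
        targets & scope(networks, community, seeds).reachable_metabolites
    ) if community else frozenset()
    while not targets <= covered:
        best, best_gain = None, -1
        for sp in candidates:
            if sp in community:
                continue
            reach = scope(networks, community | {sp}, seeds).reachable_metabolites
            gain = len(targets & reach)
            if gain > best_gain:
                best, best_gain = sp, gain
        if best is None:
            return None
        community.add(best)
        covered = frozenset(
            targets & scope(networks, community, seeds).reachable_metabolites
        )
    return community


def _greedy_key_species(networks, by_sp, profile, candidates, seeds,
                        targets) -> KeySpeciesResult:
    """Heuristic key-species classification for large communities.

    Essentiality is exact (leave-one-out on the full community).  If the
    essential set alone covers the targets it is the unique minimal
    community; otherwise each non-essential candidate is tested by a greedy
    cover forced to include it, so interchangeable degraders are still
    labelled alternative (pathological instances may be missed).
    """
    all_species = frozenset(by_sp)
    essential = frozenset(
        sp for sp in candidates
        if not _covers(by_sp, all_species - {sp}, seeds, targets)
    )
    if essential and _covers(by_sp, essential, seeds, targets):
        return KeySpeciesResult(profile.plant_name, targets, essential,
                                frozenset(), [essential], False)
    minimal: list[frozenset[str]] = []
    alternative: set[str] = set()
    for sp in candidates:
        if sp in essential:
            continue
        community = _greedy_cover(networks, candidates, seeds, targets,
                                  start=set(essential) | {sp})
        if community is None:
            continue
        community = frozenset(
            _greedy_prune(by_sp, community, seeds, targets, keep={sp})
        )
        if sp in community:
            alternative.add(sp)
            if community not in minimal:
                minimal.append(community)
    if not minimal:
        base = _greedy_cover(networks, candidates, seeds, targets, start=set(essential))
        if base is not None:
            minimal = [frozenset(_greedy_prune(by_sp, base, seeds, targets, keep=set()))]
    return KeySpeciesResult(profile.plant_name, targets, essential,
                            frozenset(alternative) - essential, minimal, False)


def wp_module(results: list[KeySpeciesResult], essential_only: bool = False) -> frozenset[str]:
    """Union over substrate profiles of the species involved in degradation.

    By default both essential and alternative species count as involved;
    ``essential_only`` restricts to species essential for some profile.
    """
    module: frozenset[str] = frozenset()
    for r in results:
        module |= r.essential_species
        if not essential_only:
            module |= r.alternative_species
    return module


def module_abundance_test(table: AbundanceTable, module):
    """Cumulative per-sample abundance of the module plus pairwise group tests.

    Module members missing from the table are logged and skipped.  Returns
    ``(sums, tests)``: a per-sample Series of summed gcpm and a DataFrame of
    pairwise two-group rank-test p-values.
    """
    module = set(module)
    if not module:
        raise ValidationError("empty module")
    present = [s for s in table.sgb_ids if s in module]
    missing = module - set(present)
    if missing:
        logger.warning("%d module members absent from table; skipped", len(missing))
    if not present:
        raise ValidationError("no module member present in the abundance table")
    idx = [table.sgb_ids.index(s) for s in present]
    sums = pd.Series(table.values[idx].sum(axis=0), index=table.sample_ids,
                     name="module_gcpm")
    group_cols = table.group_columns()
    names = sorted(group_cols)
    vals = sums.to_numpy(float)
    rows = []
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            rows.append(
                {
                    "group_a": g1,
                    "group_b": g2,
                    "p_value": two_group_test(vals[group_cols[g1]], vals[group_cols[g2]]),
                    "median_a": float(np.median(vals[group_cols[g1]])),
                    "median_b": float(np.median(vals[group_cols[g2]])),
                }
            )
    return sums, pd.DataFrame(rows)
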