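"""Synthetic trees, taxonomies and scored-tip sets with known dispersion
regimes, so the whole audit is testable without any external data.

The generator emulates the inputs the audit consumes in the real analysis:
a clock-like reference phylogeny (Yule stand-in for a dated supertree), a
nested species/genus/family/order taxonomy partitioning the tips, and a set
of "scored" tips drawn under one of three regimes — random (uniform
subset), clustered (a seed tip plus its nearest neighbours), or
overdispersed (greedy maximin spread).  Clustered sets should recover
positive NTI/NRI, overdispersed sets negative, random sets near zero.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

from .coverage import TaxonomyTable
from .tree_io import DistanceMatrix, patristic_matrix, tip_labels

__all__ = [
    "simulate_yule",
    "sample_random",
    "sample_clustered",
    "sample_overdispersed",
    "make_taxonomy",
    "Scenario",
    "generate_scenario",
    "write_scenario",
]

REGIMES = ("random", "clustered", "overdispersed")


def _rng(seed: np.random.Generator | int | None) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_yule(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: np.random.Generator | int | None = None,
) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with ``n_tips`` leaves.

    Waiting times between speciation events are exponential with rate
    (birth_rate x number of extant lineages); the splitting lineage is
    chosen uniformly.  After the last split all pendant edges are extended
    by one more exponential waiting time so no tip edge has zero length.
    Tips are labeled ``sp0001``... in traversal order.  Deterministic for a
    fixed seed.
    """
    if n_tips < 3:
        raise ValueError(f"n_tips must be >= 3, got {n_tips}")
    if not (birth_rate > 0 and np.isfinite(birth_rate)):
        raise ValueError(f"birth_rate must be a positive finite number, got {birth_rate}")
    rng = _rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    root._birth = 0.0
    active = [root]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        if node is not root:
            node.edge.length = t - node._birth
        for _ in range(2):
            child = node.new_child()
            child._birth = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for node in active:
        node.edge.length = t - node._birth
    root.edge.length = None
    for k, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tns.require_taxon(f"sp{k:04d}")
    return tree


def sample_random(tips: Iterable[str], n: int,
                  seed: np.random.Generator | int | None = None) -> set[str]:
    """Uniform subset of ``n`` distinct tips."""
    tips = sorted(set(tips))
    if not 2 <= n <= len(tips):
        raise ValueError(f"n={n} out of range [2, {len(tips)}]")
    rng = _rng(seed)
    return {str(t) for t in rng.choice(tips, size=n, replace=False)}


def _as_dm(tree_or_dm) -> DistanceMatrix:
    if isinstance(tree_or_dm, DistanceMatrix):
        return tree_or_dm
    return patristic_matrix(tree_or_dm)


def sample_clustered(tree_or_dm, n: int,
                     seed: np.random.Generator | int | None = None,
                     start_tip: str | None = None) -> set[str]:
    """A phylogenetically clustered tip set: one uniformly-chosen seed tip
    plus its ``n - 1`` nearest tips by patristic distance (distance ties
    broken by label).  ``start_tip`` pins the seed tip, for tests."""
    dm = _as_dm(tree_or_dm)
    T = len(dm)
    if not 2 <= n < T:
        raise ValueError(f"n={n} out of range [2, {T})")
    rng = _rng(seed)
    if start_tip is None:
        start_tip = dm.labels[int(rng.integers(T))]
    elif start_tip not in dm.labels:
        raise ValueError(f"start tip {start_tip!r} not in tree")
    others = [lab for lab in dm.labels if lab != start_tip]
    others.sort(key=lambda lab: (dm.distance(start_tip, lab), lab))
    return {start_tip, *others[: n - 1]}


def sample_overdispersed(tree_or_dm, n: int,
                         seed: np.random.Generator | int | None = None) -> set[str]:
    """A maximally spread tip set by greedy maximin.

    Starts from the most distant tip pair, then repeatedly adds the tip
    whose minimum distance to the chosen set is largest (ties broken by
    label).  Deterministic; the seed argument is accepted for interface
    symmetry with the other samplers but unused.
    """
    dm = _as_dm(tree_or_dm)
    T = len(dm)
    if not 2 <= n < T:
        raise ValueError(f"n={n} out of range [2, {T})")
    vals = dm.values
    # labels sorted so argmax tie-breaks lexicographically
    order = np.argsort(np.array(dm.labels))
    best = (-np.inf, None)
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1:]:
            if vals[i, j] > best[0]:
                best = (vals[i, j], (int(i), int(j)))
    chosen = list(best[1])
    remaining = [int(i) for i in order if i not in chosen]
    while len(chosen) < n:
        dists = [(min(vals[i, j] for j in chosen), i) for i in remaining]
        gap = max(d for d, _ in dists)
        pick = next(i for d, i in dists if d == gap)  # remaining is label-sorted
        chosen.append(pick)
        remaining.remove(pick)
    return {dm.labels[i] for i in chosen}


def make_taxonomy(
    tree: dendropy.Tree,
    genus_size_mean: float = 3.0,
    family_size_mean: float = 3.0,
    seed: np.random.Generator | int | None = None,
    order_name: str = "Simuliformes",
) -> TaxonomyTable:
    """Nest the tree's tips into genera, families and one order.

    Tips are taken in tree (leaf-traversal) order and chunked into
    contiguous runs: genus sizes are 1 + Poisson(genus_size_mean - 1)
    species, family sizes 1 + Poisson(family_size_mean - 1) genera, so
    every genus/family is a contiguous block of the tree's tip ordering and
    the table partitions the tips exactly.
    """
    if genus_size_mean < 1 or family_size_mean < 1:
        raise ValueError("mean sizes must be >= 1")
    rng = _rng(seed)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]

    def chunk(items: list, mean: float) -> list[list]:
        out, i = [], 0
        while i < len(items):
            size = 1 + int(rng.poisson(mean - 1))
            out.append(items[i : i + size])
            i += size
        return out

    genera = chunk(tips, genus_size_mean)
    families = chunk(list(range(len(genera))), family_size_mean)
    fam_of_genus = {g: fi for fi, fam in enumerate(families) for g in fam}
    rows = []
    for gi, members in enumerate(genera):
        for sp in members:
            rows.append({
                "species": sp,
                "genus": f"Genus{gi + 1:03d}",
                "family": f"Fam{fam_of_genus[gi] + 1:03d}",
                "order": order_name,
            })
    return TaxonomyTable(pd.DataFrame(rows))


@dataclass
class Scenario:
    """One synthetic study condition: tree + taxonomy + scored tips."""

    tree: dendropy.Tree
    taxonomy: TaxonomyTable
    scored: set[str]
    params: dict = field(default_factory=dict)


def generate_scenario(
    n_tips: int = 64,
    coverage: float = 0.25,
    regime: str = "random",
    seed: int = 0,
    birth_rate: float = 1.0,
    genus_size_mean: float = 3.0,
    family_size_mean: float = 3.0,
    order_name: str = "Simuliformes",
) -> Scenario:
    """Tree, taxonomy and a scored-tip set drawn under one regime.

    The scored-set size is round(coverage x n_tips), floored at 2.
    Sub-seeds for the tree, taxonomy and sampler are spawned from ``seed``
    so the same tree is produced for every regime at a given seed.
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}, got {regime!r}")
    if not 0 < coverage < 1:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    streams = np.random.SeedSequence(seed).spawn(3)
    tree = simulate_yule(n_tips, birth_rate, np.random.default_rng(streams[0]))
    taxonomy = make_taxonomy(tree, genus_size_mean, family_size_mean,
                             np.random.default_rng(streams[1]), order_name)
    n_scored = max(2, round(coverage * n_tips))
    sampler_rng = np.random.default_rng(streams[2])
    if regime == "random":
        scored = sample_random(tip_labels(tree), n_scored, sampler_rng)
    elif regime == "clustered":
        scored = sample_clustered(tree, n_scored, sampler_rng)
    else:
        scored = sample_overdispersed(tree, n_scored, sampler_rng)
    params = {
        "n_tips": n_tips, "coverage": coverage, "regime": regime,
        "seed": seed, "birth_rate": birth_rate,
        "genus_size_mean": genus_size_mean, "family_size_mean": family_size_mean,
        "order_name": order_name, "n_scored": n_scored,
    }
    return Scenario(tree, taxonomy, scored, params)


def write_scenario(scenario: Scenario, outdir: str) -> dict[str, str]:
    """Write a scenario as the file bundle the pipeline consumes.

    ``tree.nwk`` (Newick), ``taxonomy.csv``, ``scored_species.txt`` (one
    name per line) and ``params.json``; returns the paths.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "tree": os.path.join(outdir, "tree.nwk"),
        "taxonomy": os.path.join(outdir, "taxonomy.csv"),
        "scored": os.path.join(outdir, "scored_species.txt"),
        "params": os.path.join(outdir, "params.json"),
    }
    scenario.tree.write(path=paths["tree"], schema="newick",
                        suppress_rooting=True, unquoted_underscores=True)
    scenario.taxonomy.to_csv(paths["taxonomy"])
    with open(paths["scored"], "w") as fh:
        fh.write("\n".join(sorted(scenario.scored)) + "\n")
    with open(paths["params"], "w") as fh:
        json.dump(scenario.params, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
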