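"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure its downstream stage
assumes, with planted ground truth returned alongside the data so recovery
can be measured:

* :func:`gen_interactome` — a background interactome built around a known
  seed/partner split, so one-hop seed expansion has a known node count.
* :func:`gen_planted_partition` — a two-parameter stochastic block model
  (within-module edge probability p_in, between-module p_out) with known
  module labels, the standard benchmark for community recovery.
* :func:`gen_annotations` — gene-set annotations where chosen (module, term)
  pairs are enriched: module members carry the term with probability
  ``enrich_frac`` against an independent Bernoulli ``background_rate``,
  matching the hypergeometric null up to conditioning.
* :func:`gen_dige_tables` — paired-design DIGE gels with planted signed folds,
  multiplicative lognormal ratio noise (additive Gaussian on log2), and dye
  swaps on a chosen subset of gels.
* :func:`gen_cohort` — clinical cohort tables shaped like the study's
  printed patient details.

All randomness flows from one explicit integer seed per call; identical
parameters and seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .io_formats import (COMPLETE_CY3, COMPLETE_CY5, AnnotationSet, CohortTable,
                         DigeExperiment, GelRecord, Interactome)


@dataclass(frozen=True)
class PlantedGraphTruth:
    partition_labels: dict[Hashable, int]
    p_in: float
    p_out: float
    rng_seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise InvalidParameterError(
                f"need 0 <= p_out < p_in <= 1, got p_in={self.p_in}, "
                f"p_out={self.p_out}")


@dataclass(frozen=True)
class PlantedEnrichmentTruth:
    enriched_pairs: frozenset[tuple[int, str]]
    enrich_frac: float
    background_rate: float
    universe_size: int


@dataclass(frozen=True)
class PlantedDigeTruth:
    """Ground truth for a DIGE simulation.

    ``differential_spots`` maps spot id to its true signed fold (|fold| >= 1);
    spots not listed have true fold 1 (no change). ``dye_swap_gels`` are
    emitted reverse-labelled.
    """

    differential_spots: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.15
    dye_swap_gels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")
        for spot, fold in self.differential_spots.items():
            if abs(fold) < 1:
                raise InvalidParameterError(
                    f"spot {spot}: |signed fold| must be >= 1, got {fold}")


def gen_interactome(n_seeds: int, n_partners: int, extra_edges: int,
                    rng_seed: int) -> tuple[Interactome, list[str]]:
    """Background interactome with a known seed/partner structure.

    Every partner is attached to at least one seed and every seed has at
    least one interaction, so one-hop expansion from the seed list recovers
    exactly ``n_seeds + n_partners`` nodes. ``extra_edges`` additional
    distinct edges are scattered over the whole node set (seed-seed,
    seed-partner or partner-partner).
    """
    if n_seeds < 1:
        raise InvalidParameterError("n_seeds must be >= 1")
    if n_partners < 0 or extra_edges < 0:
        raise InvalidParameterError("n_partners and extra_edges must be >= 0")
    if n_partners == 0 and n_seeds < 2:
        raise InvalidParameterError(
            "a single seed with no partners would be isolated")
    rng = np.random.default_rng(rng_seed)
    seeds = [f"SEED{i:04d}" for i in range(1, n_seeds + 1)]
    partners = [f"PRT{i:05d}" for i in range(1, n_partners + 1)]
    edges: set[tuple[str, str]] = set()

    def add(a: str, b: str) -> None:
        if a != b:
            edges.add((a, b) if a <= b else (b, a))

    for p in partners:
        add(str(rng.choice(seeds)), p)
    if partners:
        linked = {s for a, b in edges for s in (a, b)}
        for s in seeds:
            if s not in linked:
                add(s, str(rng.choice(partners)))
    else:
        order = list(rng.permutation(seeds))
        for a, b in zip(order, order[1:] + order[:1]):
            add(a, b)

    nodes = seeds + partners
    budget = extra_edges
    max_tries = 20 * extra_edges + 100
    while budget > 0 and max_tries > 0:
        a, b = rng.choice(nodes, size=2, replace=False)
        key = (a, b) if a <= b else (b, a)
        if key not in edges:
            edges.add(key)
            budget -= 1
        max_tries -= 1
    return Interactome.from_edges(edges, source_meta="synthetic"), seeds


def gen_planted_partition(module_sizes: Sequence[int], p_in: float, p_out: float,
                          rng_seed: int) -> tuple[Interactome, PlantedGraphTruth]:
    """Stochastic block model with planted module labels.

    Each within-module node pair is an edge with probability ``p_in``, each
    between-module pair with ``p_out``; recoverable structure needs
    p_in > p_out.
    """
    if any(s < 2 for s in module_sizes):
        raise InvalidParameterError("every module size must be >= 2")
    if not 0 <= p_out < p_in <= 1:
        raise InvalidParameterError(
            f"need 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    sizes = list(module_sizes)
    probs = [[p_in if i == j else p_out for j in range(len(sizes))]
             for i in range(len(sizes))]
    g = nx.stochastic_block_model(sizes, probs, seed=int(rng_seed))
    n_total = sum(sizes)
    width = len(str(n_total))
    names = {i: f"G{i + 1:0{width}d}" for i in range(n_total)}
    labels: dict[str, int] = {}
    idx = 0
    for module, size in enumerate(sizes):
        for _ in range(size):
            labels[names[idx]] = module
            idx += 1
    edges = [(names[u], names[v]) for u, v in g.edges]
    truth = PlantedGraphTruth(partition_labels=labels, p_in=p_in, p_out=p_out,
                              rng_seed=rng_seed)
    return Interactome.from_edges(edges, source_meta="synthetic SBM"), truth


def gen_annotations(truth_partition: Mapping[Hashable, int], n_terms: int,
                    enrich_frac: float, background_rate: float,
                    universe_size: int, rng_seed: int,
                    ) -> tuple[AnnotationSet, PlantedEnrichmentTruth]:
    """Gene-set annotations with planted module-term enrichments.

    Term j is planted in the j-th module (in sorted module-id order) while
    both exist: members of that module carry the term with probability
    ``enrich_frac``; every other universe gene carries it with
    ``background_rate``. The universe is the partition's genes padded with
    filler symbols up to ``universe_size``.
    """
    if not 0 <= background_rate < enrich_frac <= 1:
        raise InvalidParameterError(
            "need 0 <= background_rate < enrich_frac <= 1")
    if n_terms < 1:
        raise InvalidParameterError("n_terms must be >= 1")
    genes = sorted(truth_partition, key=str)
    if universe_size < len(genes):
        raise InvalidParameterError(
            f"universe_size {universe_size} smaller than the {len(genes)} "
            "partitioned genes")
    rng = np.random.default_rng(rng_seed)
    filler = [f"U{i:06d}" for i in range(1, universe_size - len(genes) + 1)]
    universe = genes + filler
    module_ids = sorted(set(truth_partition.values()))
    term_to_genes: dict[str, frozenset[str]] = {}
    term_names: dict[str, str] = {}
    planted: set[tuple[int, str]] = set()
    for j in range(n_terms):
        term = f"TERM{j + 1:03d}"
        target = module_ids[j] if j < len(module_ids) else None
        members: set[str] = set()
        for g in universe:
            rate = (enrich_frac
                    if target is not None and truth_partition.get(g) == target
                    else background_rate)
            if rng.random() < rate:
                members.add(g)
        if not members:  # AnnotationSet forbids empty sets
            members.add(filler[j % len(filler)] if filler else genes[0])
        term_to_genes[term] = frozenset(members)
        if target is not None:
            term_names[term] = f"planted in module {target}"
            planted.add((target, term))
        else:
            term_names[term] = "background term"
    annotations = AnnotationSet(term_to_genes=term_to_genes,
                                term_names=term_names,
                                universe_size=universe_size)
    truth = PlantedEnrichmentTruth(enriched_pairs=frozenset(planted),
                                   enrich_frac=enrich_frac,
                                   background_rate=background_rate,
                                   universe_size=universe_size)
    return annotations, truth


def gen_dige_tables(n_spots: int, n_gels: int, truth: PlantedDigeTruth,
                    rng_seed: int) -> DigeExperiment:
    """Simulated paired DIGE gels with planted folds and lognormal noise.

    Per gel and spot the oriented (complete/incomplete) ratio is the true
    ratio times 2**N(0, noise_sd); gels in ``truth.dye_swap_gels`` report the
    reciprocal Cy5/Cy3 value under the reverse dye orientation. The spot map
    identifies each spot with itself, so planted screens resolve symbols
    trivially.
    """
    if n_gels < 2:
        raise InvalidParameterError("n_gels must be >= 2")
    if n_spots < 1:
        raise InvalidParameterError("n_spots must be >= 1")
    spots = [f"S{i:04d}" for i in range(1, n_spots + 1)]
    unknown = set(truth.differential_spots) - set(spots)
    if unknown:
        raise InvalidParameterError(
            f"differential spot id(s) {sorted(unknown)} outside the spot set")
    gel_ids = [f"GEL{i}" for i in range(1, n_gels + 1)]
    bad_swaps = set(truth.dye_swap_gels) - set(gel_ids)
    if bad_swaps:
        raise InvalidParameterError(
            f"dye_swap_gels {sorted(bad_swaps)} outside the gel set")
    rng = np.random.default_rng(rng_seed)
    gels = []
    for gel_id in gel_ids:
        ratios: dict[str, float] = {}
        swapped = gel_id in truth.dye_swap_gels
        for spot in spots:
            fold = truth.differential_spots.get(spot, 1.0)
            true_ratio = fold if fold >= 1 else -1.0 / fold
            log2_obs = np.log2(true_ratio) + rng.normal(0.0, truth.noise_sd)
            oriented = float(2.0 ** log2_obs)
            ratios[spot] = 1.0 / oriented if swapped else oriented
        gels.append(GelRecord(
            gel_id=gel_id,
            dye_orientation=COMPLETE_CY3 if swapped else COMPLETE_CY5,
            spot_ratios=ratios))
    spot_map = {s: [(s, s)] for s in spots}
    return DigeExperiment(gels=gels, spot_map=spot_map)


def gen_cohort(n: int, age_range: tuple[int, int], dpi_range: tuple[int, int],
               grades: Sequence[str], rng_seed: int) -> CohortTable:
    """Cohort table with n rows, ages/DPI uniform in the given closed ranges."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if not grades:
        raise InvalidParameterError("grade list must be non-empty")
    if age_range[1] < age_range[0] or dpi_range[1] < dpi_range[0]:
        raise InvalidParameterError("ranges must be non-empty")
    rng = np.random.default_rng(rng_seed)
    sensory = ["none", "T6", "T7", "T8", "T9", "T11", "T12", "L1", "L2", "L4"]
    rows = [{
        "age": int(rng.integers(age_range[0], age_range[1] + 1)),
        "sensory_level": str(rng.choice(sensory)),
        "motor_level": "L2",
        "days_post_injury": int(rng.integers(dpi_range[0], dpi_range[1] + 1)),
        "dige_pair": f"DIGE {i // 2 + 1}",
        "ais_grade": str(rng.choice(list(grades))),
        "cause": str(rng.choice(["fall", "crush"])),
    } for i in range(n)]
    return CohortTable(pd.DataFrame(rows))
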