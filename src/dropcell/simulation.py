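"""Simulated droplet datasets with known truth labels, and call scoring.

Two designs are provided.  In the first (IA), an input dataset is split
at the inflection point of its barcode-rank curve; below-inflection
barcodes define an ambient profile from which one synthetic background
barcode is drawn per input barcode (matching its total), while real
cells are sampled from the above-inflection barcodes: a large group G1
(untouched), a medium group G1.5 (50% binomially thinned) and a small
group G2 (90% thinned).  The second design (IB) additionally shuffles
10% of the genes within every real cell, pushing cells further from the
background.  A fully synthetic input generator removes any dependence on
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .background import find_thresholds, good_turing_proportions
from .matrix_io import CountMatrix, barcode_totals

__all__ = [
    "SimConfig",
    "SimDataset",
    "EvalMetrics",
    "generate_synthetic_input",
    "downsample_counts",
    "shuffle_gene_fraction",
    "simulate_sim_ia",
    "simulate_sim_ib",
    "evaluate_calls",
]

BACKGROUND = "background"
GROUPS = ("G1", "G1.5", "G2")


@dataclass
class SimConfig:
    n_per_group: int = 2000
    downsample_g2: float = 0.90
    downsample_g15: float = 0.50
    shuffle_fraction: float = 0.10  # IB only
    seed: int = 0

    def __post_init__(self):
        for rate in (self.downsample_g2, self.downsample_g15, self.shuffle_fraction):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


@dataclass
class SimDataset:
    matrix: CountMatrix
    truth: np.ndarray  # per-barcode label: background / G1 / G1.5 / G2
    seed: int
    config: SimConfig
    source_indices: dict = field(default_factory=dict)  # group -> input column indices
    source_totals: dict = field(default_factory=dict)  # group -> input totals

    def truth_by_id(self) -> dict:
        return dict(zip(self.matrix.barcode_ids, self.truth.tolist()))


@dataclass
class EvalMetrics:
    power_g1: float
    power_g15: float
    power_g2: float
    empirical_fdr: float
    n_called: int


def _sparse_from_dense_rows(chunks) -> sp.csc_matrix:
    """Stack dense (barcodes x genes) chunks into a genes x barcodes CSC."""
    parts = [sp.csr_matrix(chunk) for chunk in chunks]
    return sp.vstack(parts).T.tocsc()


def generate_synthetic_input(
    n_genes: int = 3000,
    n_cell_types: int = 3,
    n_cells: int = 2500,
    n_ambient: int = 20000,
    seed: int = 0,
) -> CountMatrix:
    """Emulate a droplet experiment: correlated cell types over an ambient sea.

    Cell barcodes draw from per-type multinomial profiles (the types share
    an ambient-derived base but carry disjoint boosted marker blocks) with
    totals lognormal around 5000; ambient barcodes draw from the ambient
    profile with totals lognormal around 50 so most land at or below 100.
    The resulting barcode-rank curve has a high plateau, a cliff, and a
    long tail, so knee/inflection detection succeeds.
    """
    if min(n_genes, n_cell_types, n_cells, n_ambient) < 1:
        raise ValueError("all sizes must be >= 1")
    rng = np.random.default_rng(seed)
    ambient_p = rng.dirichlet(np.full(n_genes, 0.3))

    block = max(1, n_genes // 50)
    type_ps = []
    for t in range(n_cell_types):
        w = ambient_p * rng.lognormal(0.0, 0.8, size=n_genes)
        lo = (t * block) % max(1, n_genes - block + 1)
        w[lo : lo + block] *= 30.0
        type_ps.append(w / w.sum())

    cell_types = rng.integers(0, n_cell_types, size=n_cells)
    cell_totals = np.maximum(1, np.round(rng.lognormal(np.log(5000.0), 0.35, n_cells))).astype(
        np.int64
    )
    ambient_totals = np.maximum(1, np.round(rng.lognormal(np.log(45.0), 0.45, n_ambient))).astype(
        np.int64
    )

    cell_chunks = []
    for t in range(n_cell_types):
        idx = np.flatnonzero(cell_types == t)
        if idx.size:
            cell_chunks.append((idx, rng.multinomial(cell_totals[idx], type_ps[t])))
    cell_block = np.empty((n_cells, n_genes), dtype=np.int64)
    for idx, draws in cell_chunks:
        cell_block[idx] = draws

    chunks = [cell_block]
    for start in range(0, n_ambient, 2000):
        chunks.append(rng.multinomial(ambient_totals[start : start + 2000], ambient_p))
    counts = _sparse_from_dense_rows(chunks)

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    barcode_ids = [f"BC{i:06d}" for i in range(n_cells + n_ambient)]
    return CountMatrix(gene_ids, barcode_ids, counts, gene_symbols=list(gene_ids))


def downsample_counts(x, remove_rate: float, seed=0) -> np.ndarray:
    """Binomial thinning: keep each count unit with probability 1 - remove_rate."""
    if not 0 <= remove_rate <= 1:
        raise ValueError("remove_rate must lie in [0, 1]")
    x = np.asarray(x)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(x.astype(np.int64), 1.0 - remove_rate)


def shuffle_gene_fraction(x, fraction: float, seed=0) -> np.ndarray:
    """Permute the counts of a random ``round(fraction * n_genes)`` gene subset.

    The multiset of counts (and hence the total) is preserved; ties in
    ``round`` follow round-half-to-even.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    x = np.asarray(x).copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = int(round(fraction * x.size))
    if k < 2:
        return x
    pos = rng.choice(x.size, size=k, replace=False)
    x[pos] = x[pos[rng.permutation(k)]]
    return x


def _split_by_inflection(input_m: CountMatrix):
    totals = barcode_totals(input_m)
    inflection = find_thresholds(totals, mode="inflection")
    below = np.flatnonzero((totals > 0) & (totals <= inflection))
    above = np.flatnonzero(totals > inflection)
    return totals, inflection, below, above


def simulate_sim_ia(input_m: CountMatrix, config: SimConfig) -> SimDataset:
    """Build a truth-labelled dataset from an input matrix (design IA)."""
    rng = np.random.default_rng(config.seed)
    totals, inflection, below, above = _split_by_inflection(input_m)
    if above.size < config.n_per_group:
        raise ValueError(
            f"only {above.size} high-count barcodes; need >= {config.n_per_group}"
        )
    if below.size == 0:
        raise ValueError("no below-inflection barcodes to model background from")

    pooled = np.asarray(input_m.counts[:, below].sum(axis=1)).ravel()
    bg_p = good_turing_proportions(pooled)
    bg_totals = totals[below]
    chunks = []
    for start in range(0, below.size, 2000):
        chunks.append(rng.multinomial(bg_totals[start : start + 2000], bg_p))
    bg_block = _sparse_from_dense_rows(chunks)

    # three independently sampled sets (no replacement within a set)
    picks = {g: np.sort(rng.choice(above, size=config.n_per_group, replace=False)) for g in GROUPS}
    cell_blocks = {}
    cell_blocks["G1"] = input_m.counts[:, picks["G1"]].tocsc()
    for g, rate in (("G1.5", config.downsample_g15), ("G2", config.downsample_g2)):
        sub = input_m.counts[:, picks[g]].tocsc().copy()
        sub.data = rng.binomial(sub.data, 1.0 - rate)
        sub.eliminate_zeros()
        cell_blocks[g] = sub

    counts = sp.hstack([bg_block, cell_blocks["G1"], cell_blocks["G1.5"], cell_blocks["G2"]]).tocsc()
    labels = np.concatenate(
        [
            np.repeat(BACKGROUND, below.size),
            np.repeat("G1", config.n_per_group),
            np.repeat("G1.5", config.n_per_group),
            np.repeat("G2", config.n_per_group),
        ]
    )
    barcode_ids = (
        [f"BG-{i:06d}" for i in range(below.size)]
        + [f"G1-{i:05d}" for i in range(config.n_per_group)]
        + [f"G1.5-{i:05d}" for i in range(config.n_per_group)]
        + [f"G2-{i:05d}" for i in range(config.n_per_group)]
    )
    matrix = CountMatrix(
        list(input_m.gene_ids), barcode_ids, counts, gene_symbols=input_m.gene_symbols
    )
    return SimDataset(
        matrix=matrix,
        truth=labels,
        seed=config.seed,
        config=config,
        source_indices={g: picks[g] for g in GROUPS},
        source_totals={g: totals[picks[g]] for g in GROUPS},
    )


def simulate_sim_ib(input_m: CountMatrix, config: SimConfig) -> SimDataset:
    """Design IB: IA plus a 10% gene shuffle within every real cell."""
    sim = simulate_sim_ia(input_m, config)
    mat = sim.matrix.counts.tocsc()
    real = np.flatnonzero(sim.truth != BACKGROUND)
    ss = np.random.SeedSequence([int(config.seed), 0x5B])
    child_rngs = [np.random.default_rng(s) for s in ss.spawn(real.size)]
    cols = []
    for rng, i in zip(child_rngs, real):
        x = np.asarray(mat[:, [i]].todense()).ravel()
        cols.append(shuffle_gene_fraction(x, config.shuffle_fraction, seed=rng))
    shuffled = _sparse_from_dense_rows(np.vstack(cols))
    out = sp.hstack([mat[:, : real[0]], shuffled]).tocsc() if real.size else mat
    matrix = CountMatrix(
        list(sim.matrix.gene_ids),
        list(sim.matrix.barcode_ids),
        out,
        gene_symbols=sim.matrix.gene_symbols,
    )
    return SimDataset(
        matrix=matrix,
        truth=sim.truth,
        seed=config.seed,
        config=config,
        source_indices=sim.source_indices,
        source_totals=sim.source_totals,
    )


def evaluate_calls(retained_ids, sim: SimDataset) -> EvalMetrics:
    """Per-group recall and empirical FDR of a set of retained barcode ids.

    ``retained_ids`` may be a CellCalls (its retained ids are used) or any
    iterable of barcode id strings; every id must exist in the simulation.
    """
    if hasattr(retained_ids, "retained_ids"):
        retained_ids = retained_ids.retained_ids
    retained = set(retained_ids)
    known = set(sim.matrix.barcode_ids)
    unknown = retained - known
    if unknown:
        raise ValueError(f"{len(unknown)} retained barcodes not present in the simulation")
    truth = sim.truth_by_id()
    n_called = len(retained)
    false_calls = sum(1 for b in retained if truth[b] == BACKGROUND)
    powers = {}
    for g in GROUPS:
        members = [b for b, lab in truth.items() if lab == g]
        powers[g] = (
            sum(1 for b in members if b in retained) / len(members) if members else 0.0
        )
    return EvalMetrics(
        power_g1=powers["G1"],
        power_g15=powers["G1.5"],
        power_g2=powers["G2"],
        empirical_fdr=false_calls / n_called if n_called else 0.0,
        n_called=n_called,
    )
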