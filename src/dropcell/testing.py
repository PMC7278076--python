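"""Monte-Carlo tests against the ambient background and pipeline orchestration.

Two tests are provided.  Tight clusters are tested via the median of the
Pearson correlations between each member and the smoothed background
profile; the null is simulated with multinomial draws at the size of the
barcode that contributes the median.  Individual barcodes are tested via
their Dirichlet-multinomial log-likelihood under the background profile,
with DM null draws at the barcode's size (multinomial when the fitted
concentration is infinite).  Both p-values use the add-one Monte-Carlo
formula ``(#{null <= observed} + 1) / (M + 1)`` and are corrected with
Benjamini-Hochberg, separately for the cluster and individual passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .background import (
    BackgroundProfile,
    BarcodePartition,
    estimate_background_profile,
    estimate_concentration,
    partition_barcodes,
)
from .clustering import (
    TightnessTable,
    calibrate_thresholds,
    extract_tight_clusters,
    group_by_size,
)
from .matrix_io import CountMatrix, barcode_totals, drop_empty

__all__ = [
    "ClusterTestResult",
    "BarcodeTestResult",
    "CellCalls",
    "mc_pvalue",
    "dm_loglik",
    "cluster_mc_test",
    "ed_barcode_test",
    "bh_adjust",
    "call_cells",
    "filter_mito",
]


@dataclass
class ClusterTestResult:
    cluster: np.ndarray
    t_c: float
    n_ref: int
    m_iter: int
    p_value: float
    q_value: float | None = None


@dataclass
class BarcodeTestResult:
    barcode: int
    log_lik: float
    p_value: float
    q_value: float | None = None


@dataclass
class CellCalls:
    """Retained barcodes with per-barcode provenance and run diagnostics."""

    retained: np.ndarray
    provenance: dict
    fdr_target: float
    barcode_ids: list
    matrix: CountMatrix
    partition: BarcodePartition
    profile: BackgroundProfile | None = None
    tightness: TightnessTable | None = None
    cluster_results: list = field(default_factory=list)
    barcode_results: list = field(default_factory=list)
    seed: int | None = None

    @property
    def retained_ids(self) -> list:
        return [self.barcode_ids[i] for i in self.retained]


def mc_pvalue(null_stats, observed: float) -> float:
    """Add-one Monte-Carlo p-value, lower tail: (#{null <= obs} + 1) / (M + 1)."""
    null_stats = np.asarray(null_stats, dtype=float)
    m = null_stats.size
    if m < 1:
        raise ValueError("need at least one Monte-Carlo draw")
    return float((np.count_nonzero(null_stats <= observed) + 1) / (m + 1))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _corr_cols_with_profile(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of ``x`` (genes x n) with ``p``."""
    xc = x - x.mean(axis=0, keepdims=True)
    pc = p - p.mean()
    denom = np.sqrt((xc**2).sum(axis=0)) * np.sqrt((pc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        out = xc.T @ pc / denom
    return np.nan_to_num(out, nan=0.0)


def dm_loglik(x, p: np.ndarray, concentration: float = np.inf) -> float:
    """Dirichlet-multinomial log-likelihood of one count vector under ``p``.

    ``concentration=inf`` gives the multinomial limit.  Includes the
    multinomial coefficient, matching the vectorized null computation.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.sum()
    nz = x > 0
    v = x[nz]
    pv = p[nz]
    base = gammaln(n + 1) - gammaln(v + 1).sum()
    if np.isinf(concentration):
        return float(base + (v * np.log(pv)).sum())
    a = concentration
    ap = a * pv
    return float(base + gammaln(a) - gammaln(n + a) + (gammaln(v + ap) - gammaln(ap)).sum())


def _loglik_rows(draws: np.ndarray, p: np.ndarray, concentration: float) -> np.ndarray:
    """DM (or multinomial) log-likelihood of each row of a dense draw matrix."""
    m = draws.shape[0]
    n = draws.sum(axis=1).astype(float)
    rows, cols = np.nonzero(draws)
    v = draws[rows, cols].astype(float)
    if np.isinf(concentration):
        per = v * np.log(p[cols]) - gammaln(v + 1)
    else:
        ap = concentration * p[cols]
        per = gammaln(v + ap) - gammaln(ap) - gammaln(v + 1)
    out = gammaln(n + 1) + np.bincount(rows, weights=per, minlength=m)
    if not np.isinf(concentration):
        out += gammaln(concentration) - gammaln(n + concentration)
    return out


def _multinomial_rows(
    rng: np.random.Generator, n_umi: int, p: np.ndarray, m_iter: int
) -> np.ndarray:
    """M multinomial(n, p) rows; categorical sampling when n << n_genes.

    For small draws it is much cheaper to place n categorical samples by
    inverse-CDF than to run the G-step binomial cascade; both routes are
    exact multinomial samplers.
    """
    n_genes = p.size
    if n_umi >= n_genes // 4:  # crossover point; both routes are exact
        return rng.multinomial(n_umi, p, size=m_iter)
    cdf = np.cumsum(p)
    cdf[-1] = 1.0
    genes = np.searchsorted(cdf, rng.random((m_iter, n_umi)), side="right")
    flat = (np.arange(m_iter)[:, None] * n_genes + genes).ravel()
    return np.bincount(flat, minlength=m_iter * n_genes).reshape(m_iter, n_genes)


def _sample_null_counts(
    rng: np.random.Generator, n_umi: int, p: np.ndarray, concentration: float, m_iter: int
) -> np.ndarray:
    if np.isinf(concentration):
        return _multinomial_rows(rng, n_umi, p, m_iter)
    shape = np.broadcast_to(concentration * p, (m_iter, p.size))
    g = rng.gamma(shape)
    g_sum = np.maximum(g.sum(axis=1, keepdims=True), np.finfo(float).tiny)
    return rng.multinomial(n_umi, g / g_sum)


def cluster_mc_test(
    m: CountMatrix,
    cluster,
    profile: BackgroundProfile,
    m_iter: int = 1000,
    seed=0,
    null_cache: dict | None = None,
) -> ClusterTestResult:
    """Monte-Carlo test of a tight cluster against the background profile.

    The statistic T_C is the median of the members' Pearson correlations
    with the smoothed background profile; the null correlations come from
    M multinomial draws at the size N of the barcode giving T_C, and
    ``p = (#{null corr <= T_C} + 1) / (M + 1)``.
    """
    if m_iter < 1:
        raise ValueError("m_iter must be >= 1")
    cluster = np.asarray(cluster, dtype=np.int64)
    if cluster.size < 2:
        raise ValueError("cluster must have at least 2 members")
    rng = _as_rng(seed)
    dense = np.asarray(m.counts[:, cluster].todense(), dtype=float)
    totals = dense.sum(axis=0)
    corrs = _corr_cols_with_profile(dense, profile.p_b0)
    t_c = float(np.median(corrs))
    order = np.argsort(corrs, kind="stable")
    k = cluster.size
    # even cluster: the median is a midpoint; use the lower-correlation
    # barcode of the middle pair (conservative: typically larger N variance)
    ref_pos = order[k // 2] if k % 2 else order[k // 2 - 1]
    n_ref = int(totals[ref_pos])
    key = n_ref
    if null_cache is not None and key in null_cache:
        null_corrs = null_cache[key]
    else:
        draws = _multinomial_rows(rng, n_ref, profile.p_b0, m_iter).astype(float)
        null_corrs = _corr_cols_with_profile(draws.T, profile.p_b0)
        if null_cache is not None:
            null_cache[key] = null_corrs
    return ClusterTestResult(
        cluster=cluster,
        t_c=t_c,
        n_ref=n_ref,
        m_iter=m_iter,
        p_value=mc_pvalue(null_corrs, t_c),
    )


def ed_barcode_test(
    m: CountMatrix,
    barcode: int,
    profile: BackgroundProfile,
    m_iter: int = 1000,
    seed=0,
    null_cache: dict | None = None,
) -> BarcodeTestResult:
    """Individual-barcode Monte-Carlo test: DM log-likelihood under p_b0.

    Null barcodes of the same size are simulated from the
    Dirichlet-multinomial (multinomial if the concentration is infinite);
    lower log-likelihood is more extreme.
    """
    if m_iter < 1:
        raise ValueError("m_iter must be >= 1")
    rng = _as_rng(seed)
    x = np.asarray(m.counts[:, [barcode]].todense(), dtype=float).ravel()
    n_umi = int(x.sum())
    if n_umi <= 0:
        raise ValueError("barcode has zero total count")
    stat = dm_loglik(x, profile.p_b0, profile.concentration)
    if null_cache is not None and n_umi in null_cache:
        null_lls = null_cache[n_umi]
    else:
        draws = _sample_null_counts(rng, n_umi, profile.p_b0, profile.concentration, m_iter)
        null_lls = _loglik_rows(draws, profile.p_b0, profile.concentration)
        if null_cache is not None:
            null_cache[n_umi] = null_lls
    return BarcodeTestResult(barcode=int(barcode), log_lik=stat, p_value=mc_pvalue(null_lls, stat))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_cells(
    m: CountMatrix,
    lower: int = 100,
    upper="auto",
    fdr: float = 0.01,
    s: int = 1000,
    m_iter: int = 1000,
    seed: int = 0,
) -> CellCalls:
    """Run the full cluster-aware cell-calling pipeline.

    Order: drop empty rows/columns, partition by total count, estimate the
    smoothed background profile and DM concentration, group the mid-range
    barcodes by size, calibrate tightness thresholds, extract tight
    clusters, test clusters (BH at ``fdr``), then test every remaining
    mid-range barcode individually (second BH at ``fdr``).  High-count
    barcodes are retained without testing.  Deterministic given ``seed``.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    m = drop_empty(m)
    part = partition_barcodes(m, lower=lower, upper=upper)
    profile = estimate_background_profile(m, part)
    if part.b0.size >= 2:
        profile = replace(profile, concentration=estimate_concentration(m, part, profile))
    totals = barcode_totals(m)

    retained = list(part.b2)
    provenance = {int(i): "high_count" for i in part.b2}
    cluster_results: list[ClusterTestResult] = []
    barcode_results: list[BarcodeTestResult] = []
    tightness = None

    ss = np.random.SeedSequence(seed)
    seed_cal, seed_clu, seed_ind = ss.spawn(3)

    if part.b1.size:
        tightness = calibrate_thresholds(profile, n_samples=100, seed=seed_cal, group_size=s)
        groups = group_by_size(totals[part.b1], s=s, indices=part.b1)
        tight, individual = [], []
        for group in groups.groups:
            cs = extract_tight_clusters(m, group, tightness)
            tight.extend(cs.tight_clusters)
            individual.extend(cs.unclustered.tolist())

        if tight:
            rng_clu = np.random.default_rng(seed_clu)
            cache: dict = {}
            for tc in tight:
                cluster_results.append(
                    cluster_mc_test(
                        m, tc.indices, profile, m_iter=m_iter, seed=rng_clu, null_cache=cache
                    )
                )
            q = bh_adjust([r.p_value for r in cluster_results])
            for r, qv in zip(cluster_results, q):
                r.q_value = float(qv)
                if qv <= fdr:
                    for i in r.cluster:
                        retained.append(int(i))
                        provenance[int(i)] = "cluster_test"
                else:
                    individual.extend(int(i) for i in r.cluster)

        if individual:
            rng_ind = np.random.default_rng(seed_ind)
            cache = {}
            cand = sorted(set(individual), key=lambda i: (totals[i], i))
            for i in cand:
                barcode_results.append(
                    ed_barcode_test(m, i, profile, m_iter=m_iter, seed=rng_ind, null_cache=cache)
                )
            q = bh_adjust([r.p_value for r in barcode_results])
            for r, qv in zip(barcode_results, q):
                r.q_value = float(qv)
                if qv <= fdr:
                    retained.append(r.barcode)
                    provenance[r.barcode] = "individual_test"

    return CellCalls(
        retained=np.array(sorted(set(retained)), dtype=np.int64),
        provenance=provenance,
        fdr_target=fdr,
        barcode_ids=m.barcode_ids,
        matrix=m,
        partition=part,
        profile=profile,
        tightness=tightness,
        cluster_results=cluster_results,
        barcode_results=barcode_results,
        seed=seed,
    )


def filter_mito(
    m: CountMatrix, calls: CellCalls, mito_prefix="MT-", threshold: float = 0.40
) -> CellCalls:
    """Drop retained barcodes whose mitochondrial fraction is >= ``threshold``.

    Gene symbols (falling back to gene ids) are matched case-insensitively
    against one or more prefixes.  If no gene matches, the calls are
    returned unchanged.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    prefixes = [mito_prefix] if isinstance(mito_prefix, str) else list(mito_prefix)
    prefixes = [p.upper() for p in prefixes]
    names = m.gene_symbols if m.gene_symbols is not None else m.gene_ids
    mito = np.array([any(str(g).upper().startswith(p) for p in prefixes) for g in names])
    if not mito.any():
        return calls
    totals = barcode_totals(m)
    mito_counts = np.asarray(m.counts[mito, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    keep = np.array([i for i in calls.retained if frac[i] < threshold], dtype=np.int64)
    prov = {int(i): calls.provenance[int(i)] for i in keep}
    return replace(calls, retained=keep, provenance=prov)
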