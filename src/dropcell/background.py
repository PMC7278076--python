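"""Barcode-rank thresholds, barcode partitioning, and the ambient background model.

Barcodes are split by total UMI count into a background set ``b0``
(total <= lower threshold), a high-count set ``b2`` (total > upper
threshold, by default the knee of the barcode-rank curve), and the
remainder ``b1`` which is what actually gets tested.  The ambient
expression profile is estimated from pooled ``b0`` counts with Simple
Good-Turing smoothing so every gene has strictly positive probability,
and a Dirichlet-multinomial concentration is fitted to the ``b0``
barcodes by maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .matrix_io import CountMatrix, barcode_totals

__all__ = [
    "BarcodePartition",
    "BackgroundProfile",
    "good_turing_proportions",
    "find_thresholds",
    "partition_barcodes",
    "estimate_background_profile",
    "estimate_concentration",
    "shannon_entropy",
]

#: concentrations above this are treated as the multinomial limit
CONCENTRATION_UPPER = 1e6


@dataclass
class BarcodePartition:
    """Index sets b0 (background), b1 (to test), b2 (kept as cells)."""

    lower_threshold: int
    upper_threshold: int
    b0: np.ndarray
    b1: np.ndarray
    b2: np.ndarray

    def __post_init__(self):
        self.b0 = np.asarray(self.b0, dtype=np.int64)
        self.b1 = np.asarray(self.b1, dtype=np.int64)
        self.b2 = np.asarray(self.b2, dtype=np.int64)
        if self.lower_threshold >= self.upper_threshold:
            raise ValueError("lower threshold must be < upper threshold")


@dataclass
class BackgroundProfile:
    """Smoothed ambient profile, high-count profile and DM concentration.

    ``concentration`` may be ``numpy.inf``, meaning the multinomial limit
    (no detectable overdispersion in the background barcodes).
    """

    p_b0: np.ndarray
    p_b2: np.ndarray | None = None
    concentration: float = np.inf

    def __post_init__(self):
        self.p_b0 = np.asarray(self.p_b0, dtype=float)
        if abs(self.p_b0.sum() - 1.0) > 1e-8:
            raise ValueError("p_b0 must sum to 1")
        if (self.p_b0 <= 0).any():
            raise ValueError("p_b0 must be strictly positive")
        if self.p_b2 is not None:
            self.p_b2 = np.asarray(self.p_b2, dtype=float)
            if abs(self.p_b2.sum() - 1.0) > 1e-8:
                raise ValueError("p_b2 must sum to 1")
        if not self.concentration > 0:
            raise ValueError("concentration must be positive")


def good_turing_proportions(counts) -> np.ndarray:
    """Simple Good-Turing (Gale-Sampson) proportions for pooled gene counts.

    Every gene, including unseen (zero-count) genes, receives strictly
    positive probability: the Turing estimate of the unseen mass
    ``N1 / N`` is split evenly among zero-count genes.  If there are no
    singletons but unseen genes exist, a minimal mass ``1 / (N + 1)`` is
    reserved instead so the positivity guarantee still holds.
    """
    c = np.asarray(counts)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-d vector")
    if np.issubdtype(c.dtype, np.floating):
        if not np.allclose(c, np.round(c)):
            raise ValueError("counts must be integer-valued")
        c = np.round(c).astype(np.int64)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    n_total = int(c.sum())
    if n_total == 0:
        raise ValueError("counts sum to zero")

    observed = c > 0
    n0 = int((~observed).sum())
    rs, nr = np.unique(c[observed], return_counts=True)  # ascending r
    n1 = int(nr[0]) if rs[0] == 1 else 0

    if n0 > 0:
        p0 = n1 / n_total if n1 > 0 else 1.0 / (n_total + 1)
    else:
        p0 = 0.0

    if len(rs) < 2:
        r_star = rs.astype(float)
    else:
        rsf = rs.astype(float)
        q = np.concatenate(([0.0], rsf[:-1]))
        t = np.concatenate((rsf[1:], [2.0 * rsf[-1] - rsf[-2]]))
        z = nr / (0.5 * (t - q))
        slope, intercept = np.polyfit(np.log(rsf), np.log(z), 1)
        lgt = (rsf + 1.0) * ((rsf + 1.0) / rsf) ** slope

        next_nr = np.zeros(len(rs))
        lookup = dict(zip(rs.tolist(), nr.tolist()))
        for j, r in enumerate(rs.tolist()):
            next_nr[j] = lookup.get(r + 1, 0)
        turing = np.where(next_nr > 0, (rsf + 1.0) * next_nr / nr, 0.0)

        r_star = np.empty(len(rs))
        switched = False
        for j in range(len(rs)):
            if not switched:
                if next_nr[j] == 0:
                    switched = True
                else:
                    sd = np.sqrt(
                        (rsf[j] + 1.0) ** 2
                        * (next_nr[j] / nr[j] ** 2)
                        * (1.0 + next_nr[j] / nr[j])
                    )
                    if abs(turing[j] - lgt[j]) <= 1.65 * sd:
                        switched = True
            r_star[j] = lgt[j] if switched else turing[j]

    n_prime = float((nr * r_star).sum())
    star_of = dict(zip(rs.tolist(), r_star.tolist()))
    p = np.zeros(len(c), dtype=float)
    obs_idx = np.flatnonzero(observed)
    p[obs_idx] = [(1.0 - p0) * star_of[int(r)] / n_prime for r in c[obs_idx]]
    if n0 > 0:
        p[~observed] = p0 / n0
    return p


def _rank_curve(totals):
    """Unique totals (descending), their cumulative ranks, and log10 coords."""
    t = np.asarray(totals, dtype=np.int64)
    t = t[t > 0]
    if t.size < 3:
        raise ValueError("need at least 3 positive totals")
    u, counts = np.unique(t, return_counts=True)
    u = u[::-1]
    counts = counts[::-1]
    if u.size < 2:
        raise ValueError("totals are constant; no transition detectable")
    ranks = np.cumsum(counts)  # rank of the last barcode at each total
    return u, np.log10(ranks), np.log10(u.astype(float))


def find_thresholds(totals, mode: str = "knee", lower: int = 100) -> int:
    """Locate the knee or inflection of the barcode-rank curve.

    The curve is ``log10(total)`` against ``log10(rank)`` over unique
    totals, lightly smoothed with a width-5 running median.  The
    inflection is the midpoint (geometric mean of totals) of the
    steepest-descent interval; the knee is the curve point of minimum
    signed curvature.  The search is restricted to totals above
    ``lower`` so the low-count tail cannot attract the threshold.
    """
    if mode not in ("knee", "inflection"):
        raise ValueError(f"unknown mode {mode!r}")
    u, x, y = _rank_curve(totals)
    n = len(u)
    if n >= 5:
        y_s = scipy.ndimage.median_filter(y, size=5, mode="nearest")
    else:
        y_s = y

    # steepest interval between consecutive unique totals
    slopes = np.diff(y_s) / np.diff(x)
    gm = np.sqrt(u[:-1].astype(float) * u[1:].astype(float))
    valid = gm > lower
    if not valid.any():
        raise ValueError("no transition above the lower threshold")
    infl_i = np.flatnonzero(valid)[np.argmin(slopes[valid])]
    infl_threshold = int(round(gm[infl_i]))

    if mode == "inflection":
        return infl_threshold

    interior = np.zeros(n, dtype=bool)
    interior[1:-1] = True
    cand = interior & (u > lower)
    if n < 3 or not cand.any():
        return infl_threshold  # curvature undefined; fall back
    d1 = np.gradient(y_s, x)
    d2 = np.gradient(d1, x)
    curv = d2 / (1.0 + d1**2) ** 1.5
    knee_j = np.flatnonzero(cand)[np.argmin(curv[cand])]
    return int(u[knee_j])


def partition_barcodes(m: CountMatrix, lower: int = 100, upper="auto") -> BarcodePartition:
    """Split barcodes into b0 / b1 / b2 by total count.

    Boundary semantics: ``total <= lower`` goes to b0, ``total > upper``
    goes to b2, everything in between to b1.  ``upper='auto'`` locates
    the knee of the rank curve.
    """
    totals = barcode_totals(m)
    if upper == "auto":
        upper = find_thresholds(totals, mode="knee", lower=lower)
    upper = int(upper)
    lower = int(lower)
    if upper <= lower:
        raise ValueError(f"upper threshold ({upper}) must exceed lower ({lower})")
    b0 = np.flatnonzero(totals <= lower)
    b2 = np.flatnonzero(totals > upper)
    b1 = np.flatnonzero((totals > lower) & (totals <= upper))
    if b0.size == 0:
        raise ValueError("no background barcodes at or below the lower threshold")
    return BarcodePartition(lower, upper, b0, b1, b2)


def estimate_background_profile(m: CountMatrix, part: BarcodePartition) -> BackgroundProfile:
    """Good-Turing-smoothed ambient profile from pooled b0 counts.

    The high-count profile ``p_b2`` is computed the same way from pooled
    b2 counts when b2 is non-empty (it is needed to calibrate cluster
    tightness thresholds); otherwise it is ``None``.
    """
    pooled0 = np.asarray(m.counts[:, part.b0].sum(axis=1)).ravel()
    if pooled0.sum() == 0:
        raise ValueError("background barcodes have zero total mass")
    p_b0 = good_turing_proportions(pooled0)
    p_b2 = None
    if part.b2.size:
        pooled2 = np.asarray(m.counts[:, part.b2].sum(axis=1)).ravel()
        if pooled2.sum() > 0:
            p_b2 = good_turing_proportions(pooled2)
    return BackgroundProfile(p_b0=p_b0, p_b2=p_b2)


def _dm_loglik_terms(m: CountMatrix, cols: np.ndarray, p: np.ndarray):
    sub = m.counts[:, cols].tocsc()
    return sub.data.astype(float), p[sub.indices], np.asarray(sub.sum(axis=0)).ravel().astype(float)


def estimate_concentration(
    m: CountMatrix, part: BarcodePartition, profile: BackgroundProfile
) -> float:
    """MLE of the Dirichlet-multinomial concentration from b0 barcodes.

    Maximizes the DM log-likelihood over ``log(alpha)`` on
    ``[1e-2, 1e6]`` with the mean profile fixed at ``p_b0``.  Returns
    ``numpy.inf`` when the likelihood keeps increasing up to the search
    bound, or when the estimate exceeds 100x the largest background
    barcode total — at that point the DM dispersion factor is below 1.01
    and the model is practically the multinomial limit.
    """
    if part.b0.size < 2:
        raise ValueError("need at least 2 background barcodes")
    x, p_nz, n_b = _dm_loglik_terms(m, part.b0, profile.p_b0)
    n_barcodes = part.b0.size

    def loglik(log_alpha: float) -> float:
        a = np.exp(log_alpha)
        ap = a * p_nz
        return float(
            n_barcodes * gammaln(a)
            - gammaln(n_b + a).sum()
            + (gammaln(x + ap) - gammaln(ap)).sum()
        )

    grid = np.linspace(np.log(1e-2), np.log(CONCENTRATION_UPPER), 25)
    vals = np.array([loglik(g) for g in grid])
    if np.allclose(vals, vals[0]):
        return np.inf  # likelihood flat in alpha (degenerate profile)
    i = int(np.argmax(vals))
    if i == len(grid) - 1:
        if np.all(np.diff(vals[-5:]) >= -1e-9):
            return np.inf
        raise RuntimeError(
            "concentration likelihood has no interior maximum and is not "
            f"monotone near the upper bound (grid values tail: {vals[-5:]})"
        )
    if i == 0:
        lo, hi = grid[0], grid[1]
    else:
        lo, hi = grid[i - 1], grid[i + 1]
    res = minimize_scalar(lambda la: -loglik(la), bounds=(lo, hi), method="bounded")
    if not res.success:
        raise RuntimeError(f"concentration optimization failed: {res.message}")
    alpha = float(np.exp(res.x))
    if alpha >= CONCENTRATION_UPPER * 0.99:
        return np.inf
    # boundary likelihood-ratio check: keep the multinomial limit unless a
    # finite alpha fits significantly better (chi-bar-square, 5% level)
    ll_inf = float((x * np.log(p_nz)).sum())
    if 2.0 * (loglik(np.log(alpha)) - ll_inf) < 2.71:
        return np.inf
    return alpha


def shannon_entropy(p) -> float:
    """Shannon entropy in nats, with the 0*log(0) = 0 convention."""
    p = np.asarray(p, dtype=float)
    if (p < -1e-12).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    pos = p[p > 0]
    return float(-(pos * np.log(pos)).sum())
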