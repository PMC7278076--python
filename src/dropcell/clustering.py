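"""Size grouping, tightness calibration and tight-cluster extraction.

Barcodes to be tested are sorted by total count and chunked into groups
of ``s`` (an undersized final group is merged into its neighbour when it
holds fewer than ``s/2`` barcodes).  Within each group, hierarchical
clustering with average linkage on 1 - Pearson correlation yields a
dendrogram; a subtree is accepted as a *tight cluster* when the average
pairwise correlation of its leaves exceeds a calibrated threshold kappa.
Kappa is calibrated per barcode size by simulating clusters of
multinomial draws from whichever of the smoothed background or
high-count profile has larger Shannon entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .background import BackgroundProfile, shannon_entropy
from .matrix_io import CountMatrix, barcode_totals

__all__ = [
    "SizeGroups",
    "TightnessTable",
    "TightCluster",
    "ClusterSet",
    "group_by_size",
    "calibrate_thresholds",
    "extract_tight_clusters",
]

CALIBRATION_SIZES = np.arange(100, 1001, 100)


@dataclass
class SizeGroups:
    group_size_s: int
    groups: list  # list of np.ndarray of barcode indices, ordered by total

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class TightnessTable:
    """Per-size tightness thresholds from simulated multinomial clusters.

    ``kappa`` is the average pairwise Pearson correlation of the simulated
    cluster.  ``kappa_sel`` is a selection-corrected floor: the extreme
    pairwise correlation expected among pure-noise pairs when the node
    search scans a whole size group (see ``_selection_floor``).  Candidate
    clusters must beat both, otherwise the search would accept noise
    subsets that merely exceed the unconditional mean.
    """

    sizes: np.ndarray
    kappa: np.ndarray
    kappa_sel: np.ndarray | None = None

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.kappa_sel is None:
            self.kappa_sel = self.kappa.copy()
        self.kappa_sel = np.asarray(self.kappa_sel, dtype=float)
        if not len(self.sizes) == len(self.kappa) == len(self.kappa_sel):
            raise ValueError("sizes/kappa length mismatch")
        if ((self.kappa < -1) | (self.kappa > 1)).any():
            raise ValueError("kappa values must lie in [-1, 1]")

    def _nearest(self, size: float) -> int:
        s = min(max(float(size), self.sizes.min()), self.sizes.max())
        return int(np.argmin(np.abs(self.sizes - s)))

    def kappa_for(self, size: float) -> float:
        """Calibrated kappa for the table entry nearest ``size`` (clamped)."""
        return float(self.kappa[self._nearest(size)])

    def threshold_for(self, size: float) -> float:
        """Effective acceptance threshold: max(kappa, selection floor)."""
        j = self._nearest(size)
        return float(max(self.kappa[j], self.kappa_sel[j]))


@dataclass
class TightCluster:
    indices: np.ndarray  # matrix-level barcode indices
    avg_correlation: float
    kappa: float


@dataclass
class ClusterSet:
    tight_clusters: list
    unclustered: np.ndarray


def group_by_size(b1_totals, s: int = 1000, indices=None) -> SizeGroups:
    """Chunk barcodes (sorted by ascending total) into groups of size ``s``.

    ``indices`` maps positions in ``b1_totals`` to matrix-level barcode
    indices; ties in total are broken by index for determinism.  If the
    final group has fewer than ``s/2`` members it is merged into the
    previous one, so the last group holds between ``s/2`` and ``2s - 1``.
    """
    totals = np.asarray(b1_totals, dtype=np.int64)
    if totals.size == 0:
        raise ValueError("no barcodes to group")
    if s < 2:
        raise ValueError("group size must be >= 2")
    if indices is None:
        indices = np.arange(totals.size)
    indices = np.asarray(indices, dtype=np.int64)
    order = np.lexsort((indices, totals))
    ordered = indices[order]
    n = ordered.size
    k = int(np.ceil(n / s))
    groups = [ordered[j * s : (j + 1) * s] for j in range(k)]
    if len(groups) >= 2 and groups[-1].size < s / 2:
        groups[-2] = np.concatenate([groups[-2], groups[-1]])
        groups.pop()
    return SizeGroups(group_size_s=s, groups=groups)


def _mean_offdiag(corr: np.ndarray) -> float:
    n = corr.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(corr[iu].mean())


def _correlation_dendrogram(corr: np.ndarray):
    """Average-linkage tree on distance 1 - correlation; returns the root."""
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return to_tree(z)


def _selection_floor(corr: np.ndarray, group_size: int) -> float:
    """Expected extreme pairwise correlation among a noise group's pairs.

    The node search examines every subtree of a ``group_size`` group, so
    pure-noise pairs are selected from ~group_size^2/2 candidates.  Using
    the simulated cluster's pair-correlation sample (mean mu, sd sigma),
    the expected maximum of K near-Gaussian draws is approximately
    mu + sqrt(2 ln K) * sigma.
    """
    n = corr.shape[0]
    iu = np.triu_indices(n, k=1)
    pairs = corr[iu]
    k = max(group_size * (group_size - 1) / 2.0, 2.0)
    return float(min(pairs.mean() + np.sqrt(2.0 * np.log(k)) * pairs.std(), 1.0))


def calibrate_thresholds(
    profile: BackgroundProfile, n_samples: int = 100, seed: int = 0, group_size: int = 1000
) -> TightnessTable:
    """Simulate tight clusters of sizes 100..1000 and record their tightness.

    For each size N a cluster of ``n_samples`` multinomial(N, p*) draws is
    generated, where p* is the background or high-count profile with the
    larger Shannon entropy; kappa is the average pairwise Pearson
    correlation of the simulated cluster.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples per simulated cluster")
    p_star = profile.p_b0
    if profile.p_b2 is not None and shannon_entropy(profile.p_b2) > shannon_entropy(
        profile.p_b0
    ):
        p_star = profile.p_b2
    if len(p_star) < 2:
        raise ValueError("correlation is undefined for a single-gene profile")
    rng = np.random.default_rng(seed)
    kappas = np.empty(len(CALIBRATION_SIZES))
    kappa_sel = np.empty(len(CALIBRATION_SIZES))
    for j, n_umi in enumerate(CALIBRATION_SIZES):
        draws = rng.multinomial(int(n_umi), p_star, size=n_samples).astype(float)
        corr = np.corrcoef(draws)
        np.nan_to_num(corr, copy=False, nan=0.0)
        kappas[j] = _mean_offdiag(corr)
        kappa_sel[j] = _selection_floor(corr, group_size)
    return TightnessTable(sizes=CALIBRATION_SIZES.copy(), kappa=kappas, kappa_sel=kappa_sel)


def extract_tight_clusters(
    m: CountMatrix, group: np.ndarray, table: TightnessTable
) -> ClusterSet:
    """Pull maximal tight clusters out of one size group's dendrogram.

    Average-linkage hierarchical clustering on 1 - Pearson correlation;
    a node is accepted (and not descended into) when the average pairwise
    correlation of its leaves exceeds the kappa matched to the cluster's
    median total UMI count.  Leaves never covered by an accepted node are
    returned as ``unclustered`` and go to individual testing.
    """
    group = np.asarray(group, dtype=np.int64)
    if group.size < 2:
        return ClusterSet(tight_clusters=[], unclustered=group.copy())
    dense = np.asarray(m.counts[:, group].todense(), dtype=float)
    totals = dense.sum(axis=0)
    corr = np.corrcoef(dense, rowvar=False)
    np.nan_to_num(corr, copy=False, nan=0.0)
    root = _correlation_dendrogram(corr)

    tight = []
    unclustered = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            unclustered.append(node.id)
            continue
        leaves = node.pre_order(lambda leaf: leaf.id)
        sub = corr[np.ix_(leaves, leaves)]
        avg = _mean_offdiag(sub)
        kap = table.threshold_for(np.median(totals[leaves]))
        if avg > kap:
            tight.append(
                TightCluster(
                    indices=group[np.sort(leaves)], avg_correlation=avg, kappa=kap
                )
            )
        else:
            stack.append(node.left)
            stack.append(node.right)
    return ClusterSet(
        tight_clusters=tight,
        unclustered=group[np.sort(np.asarray(unclustered, dtype=np.int64))]
        if unclustered
        else np.empty(0, dtype=np.int64),
    )
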