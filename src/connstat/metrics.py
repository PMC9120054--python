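"""Proportional thresholding and weighted nodal centrality features.

All three centralities operate on weighted matrices.  Betweenness maps
edge weights to lengths l = 1/w (stronger connection = shorter path) and
counts shortest paths with fractional credit for ties; clustering uses the
geometric-mean triangle-intensity formula with global max-normalization.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from connstat.io import ConnectivityMatrix, Cohort
from connstat.regions import RegionTable

logger = logging.getLogger(__name__)

METRIC_NAMES = ("strength", "betweenness", "clustering")


@dataclass
class SparsityGrid:
    """Strictly increasing sparsity fractions in (0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) == 0:
            raise ValueError("grid must be a nonempty 1-d sequence")
        if np.any(v <= 0) or np.any(v > 1):
            raise ValueError("sparsity values must lie in (0, 1]")
        if np.any(np.diff(v) <= 0):
            raise ValueError("sparsity values must be strictly increasing")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def default(cls) -> "SparsityGrid":
        """0.10 to 0.30 inclusive in steps of 0.01 (21 points)."""
        return cls(np.round(np.arange(10, 31) / 100.0, 10))

    @classmethod
    def from_spec(cls, spec: str) -> "SparsityGrid":
        """Parse 'lo:hi:step', e.g. '0.10:0.30:0.01' (inclusive endpoints)."""
        try:
            lo, hi, step = (float(x) for x in spec.split(":"))
        except ValueError as e:
            raise ValueError(f"bad grid spec {spec!r}, expected 'lo:hi:step'") from e
        n = int(round((hi - lo) / step)) + 1
        return cls(np.round(lo + step * np.arange(n), 10))


@dataclass
class MetricCurve:
    """Per-region centrality values across a sparsity grid (N x |grid|)."""

    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        if self.metric_name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.metric_name!r}")
        self.values = np.asarray(self.values, dtype=float)


def threshold_proportional(W: ConnectivityMatrix, S: float) -> ConnectivityMatrix:
    """Retain the floor(S * N(N-1)/2) strongest edges, weights preserved.

    Ties at the cutoff are broken by ascending (row, column) index of the
    upper-triangle entry.  If the matrix has fewer nonzero edges than
    requested, all nonzero edges are retained and a warning is logged.
    """
    if not (0 < S <= 1):
        raise ValueError(f"sparsity S must be in (0, 1], got {S}")
    A = W.weights
    N = A.shape[0]
    rows, cols = np.triu_indices(N, k=1)
    w = A[rows, cols]
    k = int(np.floor(S * N * (N - 1) / 2))
    nz = w > 0
    n_nonzero = int(nz.sum())
    if n_nonzero < k:
        logger.warning(
            "matrix density below requested sparsity: %d nonzero edges < k=%d; retaining all",
            n_nonzero,
            k,
        )
        k = n_nonzero
    # primary: descending weight; ties: ascending (row, col)
    order = np.lexsort((cols, rows, -w))
    keep = order[:k]
    keep = keep[w[keep] > 0]
    out = np.zeros_like(A)
    out[rows[keep], cols[keep]] = w[keep]
    out += out.T
    return ConnectivityMatrix(out, W.region_table)


def node_strength(W: ConnectivityMatrix) -> np.ndarray:
    """Sum of edge weights incident to each node."""
    return W.weights.sum(axis=1)


def _betweenness_array(A: np.ndarray) -> np.ndarray:
    """Brandes betweenness on lengths 1/w; unordered pairs counted once."""
    N = A.shape[0]
    # adjacency lists of (neighbor, length)
    nbrs: list[np.ndarray] = []
    lens: list[np.ndarray] = []
    for i in range(N):
        j = np.flatnonzero(A[i])
        nbrs.append(j)
        lens.append(1.0 / A[i, j])
    bc = np.zeros(N)
    for s in range(N):
        dist = np.full(N, np.inf)
        sigma = np.zeros(N)
        preds: list[list[int]] = [[] for _ in range(N)]
        dist[s] = 0.0
        sigma[s] = 1.0
        done = np.zeros(N, dtype=bool)
        order: list[int] = []
        heap = [(0.0, s)]
        while heap:
            d, v = heapq.heappop(heap)
            if done[v]:
                continue
            done[v] = True
            order.append(v)
            for u, l in zip(nbrs[v], lens[v]):
                if done[u]:
                    continue
                nd = d + l
                if nd < dist[u]:
                    dist[u] = nd
                    sigma[u] = sigma[v]
                    preds[u] = [v]
                    heapq.heappush(heap, (nd, u))
                elif nd == dist[u]:
                    sigma[u] += sigma[v]
                    preds[u].append(v)
        delta = np.zeros(N)
        for w_ in reversed(order):
            coeff = (1.0 + delta[w_]) / sigma[w_]
            for v in preds[w_]:
                delta[v] += sigma[v] * coeff
            if w_ != s:
                bc[w_] += delta[w_]
    return bc / 2.0  # each unordered pair was counted from both endpoints


def betweenness(W: ConnectivityMatrix) -> np.ndarray:
    """Weighted betweenness centrality (unnormalized path counts).

    Each unordered source-target pair contributes once, with fractional
    credit split across equal-length shortest paths; disconnected pairs
    contribute zero.
    """
    A = W.weights
    if not (A > 0).any():
        raise ValueError("betweenness undefined on an all-zero matrix")
    return _betweenness_array(A)


def clustering_coefficient(W: ConnectivityMatrix) -> np.ndarray:
    """Weighted clustering via geometric-mean triangle intensity.

    With w_hat = W / max(W):  C_i = sum_{j,h} (w_hat_ij w_hat_ih w_hat_jh)^(1/3)
    / (k_i (k_i - 1)), where k_i counts nonzero neighbors; C_i = 0 for k_i < 2.
    Reduces to the binary triangle fraction on 0/1 matrices.
    """
    A = W.weights
    mx = A.max()
    if mx == 0:
        return np.zeros(A.shape[0])
    Ahat = np.cbrt(A / mx)
    cyc3 = np.einsum("ij,jk,ki->i", Ahat, Ahat, Ahat)
    k = (A > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(denom > 0, cyc3 / denom, 0.0)
    return C


_METRIC_FUNCS = {
    "strength": node_strength,
    "betweenness": betweenness,
    "clustering": clustering_coefficient,
}


def metric_curves(
    W: ConnectivityMatrix,
    grid: SparsityGrid,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> dict[str, MetricCurve]:
    """Centrality-vs-sparsity curves: threshold at each S, then each metric."""
    for m in metrics:
        if m not in _METRIC_FUNCS:
            raise ValueError(f"unknown metric {m!r}")
    N = W.n_regions
    out = {m: np.empty((N, len(grid))) for m in metrics}
    for j, S in enumerate(grid.values):
        Wt = threshold_proportional(W, S)
        for m in metrics:
            out[m][:, j] = _METRIC_FUNCS[m](Wt)
    return {m: MetricCurve(v, m) for m, v in out.items()}


def auc_over_thresholds(curve: MetricCurve, grid: SparsityGrid) -> np.ndarray:
    """Trapezoidal integral of each region's curve over the sparsity grid."""
    if len(grid) < 2:
        raise ValueError("AUC requires a grid of at least 2 points")
    if curve.values.shape[1] != len(grid):
        raise ValueError("curve column count does not match grid length")
    return np.trapezoid(curve.values, grid.values, axis=1)


@dataclass
class NodalFeatureTable:
    """AUC-summarized centrality features: metric -> (n_subjects x N) array."""

    data: dict[str, np.ndarray]
    subject_ids: list[str]
    region_table: RegionTable = field(repr=False)

    def __post_init__(self) -> None:
        n, N = len(self.subject_ids), len(self.region_table)
        for m, arr in self.data.items():
            if arr.shape != (n, N):
                raise ValueError(f"feature array for {m!r} has shape {arr.shape}, expected {(n, N)}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite feature values for {m!r}")

    @property
    def metrics(self) -> list[str]:
        return list(self.data)

    def to_frame(self) -> pd.DataFrame:
        names = self.region_table.names
        rows = []
        for m, arr in self.data.items():
            for i, sid in enumerate(self.subject_ids):
                for r in range(arr.shape[1]):
                    rows.append((sid, r, names[r], m, arr[i, r]))
        return pd.DataFrame(rows, columns=["subject_id", "region_index", "region", "metric", "auc_value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, region_table: RegionTable) -> "NodalFeatureTable":
        subject_ids = list(dict.fromkeys(df["subject_id"].astype(str)))
        sid_pos = {s: i for i, s in enumerate(subject_ids)}
        N = len(region_table)
        data = {}
        for m, sub in df.groupby("metric", sort=False):
            arr = np.full((len(subject_ids), N), np.nan)
            arr[[sid_pos[str(s)] for s in sub["subject_id"]], sub["region_index"].to_numpy()] = sub[
                "auc_value"
            ].to_numpy()
            data[m] = arr
        return cls(data, subject_ids, region_table)


def compute_nodal_features(
    cohort: Cohort,
    grid: SparsityGrid | None = None,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> NodalFeatureTable:
    """Per-subject AUC-over-thresholds features for every region and metric."""
    if grid is None:
        grid = SparsityGrid.default()
    n, N = len(cohort), len(cohort.region_table)
    data = {m: np.empty((n, N)) for m in metrics}
    for i, W in enumerate(cohort.matrices):
        curves = metric_curves(W, grid, metrics)
        for m in metrics:
            data[m][i] = auc_over_thresholds(curves[m], grid)
    return NodalFeatureTable(data, [s.subject_id for s in cohort.subjects], cohort.region_table)
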