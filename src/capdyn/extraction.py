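"""Brain-state extraction by frame clustering.

Frames are intensity-thresholded (rank cutoff on the top 10% / bottom 5%
of voxels), concatenated over the whole cohort exactly once, and
clustered with K-means++ under correlation distance d = 1 - Pearson's r.
The partition objective is D = sum_k sum_{j in k} d^2(z_j, c_k).
Explained variance over a K range drives elbow selection; cluster-mean
maps of the *unthresholded* z-scored frames form the CAPs, which are then
arranged into anti-correlated pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FramePartition",
    "VarianceCurve",
    "CapMapSet",
    "threshold_frame",
    "threshold_frames",
    "correlation_distance",
    "cluster_frames",
    "explained_variance",
    "variance_curve",
    "select_k_elbow",
    "compute_cap_maps",
    "pair_and_order_caps",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# thresholding

def _threshold_counts(m: int, top_pct: float, bottom_pct: float) -> tuple[int, int]:
    n_top = int(np.ceil(top_pct / 100.0 * m))
    n_bot = int(np.ceil(bottom_pct / 100.0 * m))
    return n_top, n_bot


def threshold_frame(
    frame: np.ndarray, top_pct: float = 10.0, bottom_pct: float = 5.0
) -> np.ndarray:
    """Keep the top/bottom rank fractions of voxels, zero the rest.

    Rank-cutoff convention: the ceil(top_pct% * m) largest and
    ceil(bottom_pct% * m) smallest values are retained; ties are broken by
    voxel index (stable sort).  A constant frame is degenerate — nothing
    survives and the event is logged.
    """
    frame = np.asarray(frame, dtype=float)
    m = frame.size
    if m < 20:
        raise ValueError("frame too short to threshold meaningfully")
    if np.ptp(frame) == 0:
        log.warning("constant frame encountered during thresholding; zeroed out")
        return np.zeros_like(frame)
    n_top, n_bot = _threshold_counts(m, top_pct, bottom_pct)
    order = np.argsort(frame, kind="stable")
    keep = np.zeros(m, dtype=bool)
    keep[order[:n_bot]] = True
    keep[order[m - n_top:]] = True
    out = np.where(keep, frame, 0.0)
    return out


def threshold_frames(
    frames: np.ndarray, top_pct: float = 10.0, bottom_pct: float = 5.0
) -> np.ndarray:
    """Vectorised :func:`threshold_frame` over an (N, m) frame stack."""
    frames = np.asarray(frames, dtype=float)
    N, m = frames.shape
    n_top, n_bot = _threshold_counts(m, top_pct, bottom_pct)
    order = np.argsort(frames, axis=1, kind="stable")
    keep = np.zeros_like(frames, dtype=bool)
    rows = np.arange(N)[:, None]
    keep[rows, order[:, :n_bot]] = True
    keep[rows, order[:, m - n_top:]] = True
    constant = np.ptp(frames, axis=1) == 0
    if constant.any():
        log.warning("%d constant frames zeroed during thresholding", constant.sum())
        keep[constant] = False
    return np.where(keep, frames, 0.0)


# ---------------------------------------------------------------------------
# correlation-distance K-means

def _normalize_rows(X: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm, so corr = dot product."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return Xc / norms


def correlation_distance(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Pairwise d = 1 - Pearson r between rows of X (N, m) and C (K, m)."""
    return 1.0 - _normalize_rows(np.atleast_2d(X)) @ _normalize_rows(
        np.atleast_2d(C)
    ).T


@dataclass
class FramePartition:
    """One K-clustering of the concatenated frame stack."""

    K: int
    labels: np.ndarray            # 1-based cluster id per frame
    centroids: np.ndarray         # (K, m), row-centered unit-norm directions
    D: float                      # sum of within-cluster squared corr distances
    N: int
    m: int
    seed: int
    n_restarts: int
    provenance: pd.DataFrame | None = None  # subject_id, frame per row

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels - 1, minlength=self.K)


def _kmeanspp_init(Xn: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Seeding that favours mutually distant centroids (d^2 weighting)."""
    N = Xn.shape[0]
    centers = np.empty(K, dtype=int)
    centers[0] = rng.integers(N)
    d2 = (1.0 - Xn @ Xn[centers[0]]) ** 2
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:
            centers[k] = rng.integers(N)
        else:
            centers[k] = np.searchsorted(np.cumsum(d2), rng.random() * total)
            centers[k] = min(centers[k], N - 1)
        d2 = np.minimum(d2, (1.0 - Xn @ Xn[centers[k]]) ** 2)
    return Xn[centers].copy()


def _lloyd(
    Xn: np.ndarray, C: np.ndarray, max_iter: int = 100, tol: float = 0.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations under correlation distance; returns labels0, C, D."""
    N = Xn.shape[0]
    K = C.shape[0]
    labels = np.full(N, -1)
    for _ in range(max_iter):
        dist = 1.0 - Xn @ _normalize_rows(C).T  # (N, K)
        new_labels = np.argmin(dist, axis=1)
        # deterministic empty-cluster repair: re-seed at worst-fit frame
        counts = np.bincount(new_labels, minlength=K)
        if (counts == 0).any():
            worst = np.argsort(-dist[np.arange(N), new_labels])
            wi = 0
            for k in np.flatnonzero(counts == 0):
                while counts[new_labels[worst[wi]]] <= 1:
                    wi += 1
                counts[new_labels[worst[wi]]] -= 1
                new_labels[worst[wi]] = k
                counts[k] = 1
                wi += 1
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        C = np.vstack([Xn[labels == k].mean(axis=0) for k in range(K)])
    Cn = _normalize_rows(C)
    dist = 1.0 - Xn @ Cn.T
    D = float((dist[np.arange(N), labels] ** 2).sum())
    return labels, Cn, D


def cluster_frames(
    frames: np.ndarray,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
    provenance: pd.DataFrame | None = None,
) -> FramePartition:
    """Best-of-restarts K-means++ clustering under correlation distance.

    Zero-variance frames are excluded (with a log entry) before
    clustering; ``K >= N`` is an error.
    """
    X = np.atleast_2d(np.asarray(frames, dtype=float))
    N, m = X.shape
    variances = X.var(axis=1)
    keep = variances > 0
    if not keep.all():
        log.warning("excluding %d zero-variance frames from clustering",
                    (~keep).sum())
        X = X[keep]
        if provenance is not None:
            provenance = provenance.loc[np.asarray(keep)].reset_index(drop=True)
        N = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= N and K > 1:
        raise ValueError(f"K={K} must be smaller than the frame count N={N}")

    Xn = _normalize_rows(X)
    if K == 1:
        labels = np.zeros(N, dtype=int)
        C = _normalize_rows(Xn.mean(axis=0, keepdims=True))
        D = float(((1.0 - Xn @ C.T) ** 2).sum())
        return FramePartition(1, labels + 1, C, D, N, m, seed, 1, provenance)

    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        C0 = _kmeanspp_init(Xn, K, rng)
        labels, C, D = _lloyd(Xn, C0)
        if best is None or D < best[2]:
            best = (labels, C, D)
    labels, C, D = best
    return FramePartition(K, labels + 1, C, D, N, m, seed, n_restarts, provenance)


# ---------------------------------------------------------------------------
# explained variance and elbow selection

def explained_variance(partition: FramePartition) -> tuple[float, float, float]:
    """Return (V_w, V_B, EV) for a partition.

    V_w = D / N; V_B = (1/N) sum_k n_k d^2(c_k, c) with the global
    centroid c the frame-count-weighted mean of the cluster centroids;
    EV = V_B / (V_w + V_B).
    """
    if partition.N == 0:
        raise ValueError("empty partition")
    n_k = partition.cluster_sizes
    V_w = partition.D / partition.N
    c = (n_k[:, None] * partition.centroids).sum(axis=0) / partition.N
    d = correlation_distance(partition.centroids, c[None, :])[:, 0]
    V_B = float((n_k * d**2).sum() / partition.N)
    denom = V_w + V_B
    EV = V_B / denom if denom > 0 else 0.0
    return V_w, V_B, EV


@dataclass
class VarianceCurve:
    """Explained-variance bookkeeping over a K range."""

    ks: np.ndarray
    V_w: np.ndarray
    V_B: np.ndarray
    EV: np.ndarray
    elbow_K: int | None = None
    partitions: dict[int, FramePartition] = field(default_factory=dict)

    @property
    def fractional_gain(self) -> np.ndarray:
        """Gain of EV at K relative to K-1 (NaN for the first K)."""
        g = np.full(self.ks.size, np.nan)
        g[1:] = np.diff(self.EV) / self.EV[:-1]
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"K": self.ks, "V_w": self.V_w, "V_B": self.V_B,
             "EV": self.EV, "fractional_gain": self.fractional_gain}
        )


def select_k_elbow(
    ks: np.ndarray,
    ev: np.ndarray,
    gain_threshold: float = 0.005,
    mode: str = "all_subsequent",
) -> int:
    """Smallest K at which the EV curve saturates.

    ``mode="all_subsequent"`` (default): smallest K whose fractional gains
    for every larger K in the range stay below ``gain_threshold``.
    ``mode="first"``: first K whose own gain vs K-1 is below threshold.
    Falls back to the largest K with a warning when no K qualifies.
    """
    ks = np.asarray(ks)
    ev = np.asarray(ev, dtype=float)
    if np.any(np.diff(ks) != 1):
        raise ValueError("K range must be contiguous")
    gains = np.full(ks.size, np.inf)
    gains[1:] = np.diff(ev) / ev[:-1]
    if mode == "first":
        ok = np.flatnonzero(gains < gain_threshold)
        if ok.size:
            return int(ks[ok[0]])
    elif mode == "all_subsequent":
        below = gains < gain_threshold
        for i in range(ks.size):
            if below[i + 1:].all() and (i + 1 < ks.size):
                return int(ks[i])
    else:
        raise ValueError(f"unknown elbow mode {mode!r}")
    log.warning("no elbow found below gain threshold %.4f; returning max K",
                gain_threshold)
    return int(ks[-1])


def variance_curve(
    frames: np.ndarray,
    k_range: tuple[int, int] = (2, 30),
    seed: int = 0,
    n_restarts: int = 10,
    gain_threshold: float = 0.005,
    elbow_mode: str = "all_subsequent",
    provenance: pd.DataFrame | None = None,
    keep_partitions: bool = True,
) -> VarianceCurve:
    """Cluster over a contiguous K range and locate the elbow."""
    ks = np.arange(k_range[0], k_range[1] + 1)
    vws, vbs, evs = [], [], []
    parts: dict[int, FramePartition] = {}
    for K in ks:
        part = cluster_frames(frames, int(K), seed=seed, n_restarts=n_restarts,
                              provenance=provenance)
        V_w, V_B, EV = explained_variance(part)
        vws.append(V_w)
        vbs.append(V_B)
        evs.append(EV)
        if keep_partitions:
            parts[int(K)] = part
    curve = VarianceCurve(
        ks=ks, V_w=np.array(vws), V_B=np.array(vbs), EV=np.array(evs),
        partitions=parts,
    )
    curve.elbow_K = select_k_elbow(ks, curve.EV, gain_threshold, elbow_mode)
    return curve


# ---------------------------------------------------------------------------
# CAP maps

@dataclass
class CapMapSet:
    """Voxel-wise mean-activation maps per CAP at cohort and cell level."""

    cohort_maps: np.ndarray                  # (K, m)
    cell_maps: dict[str, np.ndarray]         # cell -> (K, m), NaN when empty
    cell_counts: dict[str, np.ndarray]       # cell -> frames per CAP
    occurrence_pct: np.ndarray               # cohort-level % frames per CAP
    order: np.ndarray | None = None          # display order of CAP ids (1-based)
    pairs: list[tuple[int, int]] = field(default_factory=list)
    pair_corrs: list[float] = field(default_factory=list)
    unpaired: list[int] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.cohort_maps.shape[0]


def compute_cap_maps(
    partition: FramePartition,
    frames: np.ndarray,
    manifest: pd.DataFrame | None = None,
) -> CapMapSet:
    """Average the *unthresholded* z-scored frames within each cluster.

    ``frames`` must align row-for-row with the partition labels.  When a
    manifest is supplied (and the partition has provenance), per
    genotype-age cell maps are computed from that cell's frames only;
    empty cell-CAP combinations are recorded as NaN maps.
    """
    X = np.asarray(frames, dtype=float)
    if X.shape[0] != partition.labels.size:
        raise ValueError("frames and partition labels are misaligned")
    K = partition.K
    cohort = np.vstack(
        [X[partition.labels == k + 1].mean(axis=0) for k in range(K)]
    )
    counts = partition.cluster_sizes
    occurrence = 100.0 * counts / partition.N

    cell_maps: dict[str, np.ndarray] = {}
    cell_counts: dict[str, np.ndarray] = {}
    if manifest is not None and partition.provenance is not None:
        meta = partition.provenance.merge(
            manifest[["subject_id", "genotype", "age"]], on="subject_id", how="left"
        )
        cells = meta.genotype + "-" + meta.age
        for cell in sorted(cells.unique()):
            in_cell = (cells == cell).to_numpy()
            maps = np.full((K, X.shape[1]), np.nan)
            n = np.zeros(K, dtype=int)
            for k in range(K):
                sel = in_cell & (partition.labels == k + 1)
                n[k] = sel.sum()
                if n[k]:
                    maps[k] = X[sel].mean(axis=0)
                else:
                    log.warning("cell %s has no frames for CAP %d", cell, k + 1)
            cell_maps[cell] = maps
            cell_counts[cell] = n
    return CapMapSet(
        cohort_maps=cohort,
        cell_maps=cell_maps,
        cell_counts=cell_counts,
        occurrence_pct=occurrence,
    )


def pair_and_order_caps(maps: CapMapSet) -> CapMapSet:
    """Arrange CAPs into anti-correlated pairs.

    Greedy pairing on the most negative pairwise Pearson correlation of
    the cohort maps; pairs sorted from strongest to weakest
    anti-correlation; within a pair the more frequent CAP comes first.
    Odd K leaves one CAP unpaired (flagged).
    """
    K = maps.K
    corr = np.corrcoef(maps.cohort_maps)
    available = set(range(K))
    pairs: list[tuple[int, int]] = []
    pair_corrs: list[float] = []
    while len(available) >= 2:
        best = None
        for i in sorted(available):
            for j in sorted(available):
                if j <= i:
                    continue
                if best is None or corr[i, j] < best[0]:
                    best = (corr[i, j], i, j)
        r, i, j = best
        if r >= 0:
            log.warning("pair (%d, %d) formed with non-negative correlation %.3f",
                        i + 1, j + 1, r)
        pairs.append((i, j))
        pair_corrs.append(float(r))
        available -= {i, j}
    unpaired = sorted(available)
    if unpaired:
        log.warning("odd number of CAPs: CAP %s left unpaired",
                    [u + 1 for u in unpaired])

    # strongest anti-correlation first; occurrence decides within-pair order
    sort_idx = np.argsort(pair_corrs)
    order: list[int] = []
    sorted_pairs: list[tuple[int, int]] = []
    sorted_corrs: list[float] = []
    for si in sort_idx:
        i, j = pairs[si]
        if maps.occurrence_pct[j] > maps.occurrence_pct[i]:
            i, j = j, i
        sorted_pairs.append((i + 1, j + 1))
        sorted_corrs.append(pair_corrs[si])
        order.extend([i + 1, j + 1])
    order.extend(u + 1 for u in unpaired)

    maps.pairs = sorted_pairs
    maps.pair_corrs = sorted_corrs
    maps.unpaired = [u + 1 for u in unpaired]
    maps.order = np.array(order)
    return maps
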