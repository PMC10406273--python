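"""Static and dynamic functional network connectivity (FNC) over a
subject's K spatiotemporal network maps, connectivity states, occupancy
ratios and group contrasts.

Static FNC (sFNC) is the Pearson correlation between two 4D maps
flattened over (masked voxels x all timepoints); dynamic FNC applies the
same correlation over rectangular sliding windows.  All windows of all
subjects are clustered with k-means (on vectorized upper triangles) into
recurring connectivity states; the elbow criterion (largest second
difference of the inertia curve) picks the state count, and each
subject's occupancy ratio is the fraction of their windows assigned to
each state.  Group contrasts are elementwise Welch t-tests with
Benjamini-Hochberg false-discovery-rate control over the distinct pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FncMatrix", "WindowSpec", "StateModel",
    "sfnc_pair", "sfnc_matrix", "dfnc_windows", "n_windows",
    "fit_states", "assign_states", "occupancy_ratio", "fnc_group_test",
    "matrix_to_features", "features_to_matrix",
]


@dataclass
class FncMatrix:
    """K x K symmetric Pearson-correlation matrix between network maps
    (unit diagonal; NaN marks undefined pairs).  ``labels`` order the
    networks grouped by domain (e.g. SM1, SM2, DMN1, ...)."""

    data: np.ndarray
    labels: list[str] | None = None
    subject_id: str | None = None
    window_id: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        k = self.data.shape[0]
        if self.data.shape != (k, k):
            raise ValueError("FNC matrix must be square")


@dataclass
class WindowSpec:
    """Sliding-window layout: length in timepoints and the number of
    timepoints consecutive windows share (overlap 10 with length 30 means
    stride 20)."""

    window_length: int = 30
    overlap: int = 10

    def __post_init__(self):
        if not 1 <= self.overlap < self.window_length:
            raise ValueError(
                f"need 1 <= overlap < window_length, got overlap="
                f"{self.overlap}, length={self.window_length}")

    @property
    def stride(self) -> int:
        return self.window_length - self.overlap


@dataclass
class StateModel:
    """k-means connectivity states over vectorized FNC windows."""

    k: int
    centroids: np.ndarray               # (k, n_features)
    inertia_curve: dict[int, float]
    n_networks: int
    seed: int
    labels_: np.ndarray | None = field(default=None, repr=False)

    def centroid_matrices(self) -> list[np.ndarray]:
        return [features_to_matrix(c, self.n_networks)
                for c in self.centroids]


# ---------------------------------------------------------------------------
# correlations

def _flatten(omega: np.ndarray, mask: np.ndarray | None,
             t_slice: slice) -> np.ndarray:
    omega = np.asarray(omega)
    sub = omega[..., t_slice]
    if mask is None:
        return sub.reshape(-1)
    return sub[mask].reshape(-1)


def sfnc_pair(omega_p: np.ndarray, omega_q: np.ndarray,
              mask: np.ndarray | None = None,
              t_slice: slice = slice(None)) -> float:
    """Pearson correlation of two 4D maps over (masked voxels x
    timepoints).  Returns NaN when either flattened vector has zero
    variance (undefined correlation)."""
    if omega_p.shape != omega_q.shape:
        raise ValueError("maps must share grid and timepoints")
    if mask is not None and not np.asarray(mask).any():
        raise ValueError("empty mask")
    a = _flatten(omega_p, mask, t_slice)
    b = _flatten(omega_q, mask, t_slice)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a.astype(np.float64), b.astype(np.float64))[0, 1])


def sfnc_matrix(maps: list[np.ndarray], mask: np.ndarray | None = None,
                labels: list[str] | None = None,
                t_slice: slice = slice(None),
                subject_id: str | None = None,
                window_id: int | None = None) -> FncMatrix:
    """All-pairs static FNC: symmetric, unit diagonal, NaN where a pair is
    undefined."""
    k = len(maps)
    if k < 2:
        raise ValueError("need at least 2 network maps")
    x = np.stack([_flatten(m, mask, t_slice).astype(np.float64)
                  for m in maps])
    sd = x.std(axis=1)
    r = np.full((k, k), np.nan)
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(x[ok])
        r[np.ix_(ok, ok)] = sub
    np.fill_diagonal(r, 1.0)
    return FncMatrix(r, labels=labels, subject_id=subject_id,
                     window_id=window_id)


def n_windows(t_total: int, spec: WindowSpec) -> int:
    """Number of full sliding windows: floor((T - L) / stride) + 1."""
    if t_total < spec.window_length:
        raise ValueError(
            f"scan of {t_total} timepoints shorter than window "
            f"{spec.window_length}")
    return (t_total - spec.window_length) // spec.stride + 1


def dfnc_windows(maps: list[np.ndarray], spec: WindowSpec,
                 mask: np.ndarray | None = None,
                 labels: list[str] | None = None,
                 subject_id: str | None = None) -> list[FncMatrix]:
    """Dynamic FNC: one correlation matrix per sliding window (windows
    start at 0, stride = length - overlap, trailing partial window
    dropped)."""
    t_total = maps[0].shape[-1]
    count = n_windows(t_total, spec)
    out = []
    for w in range(count):
        start = w * spec.stride
        out.append(sfnc_matrix(maps, mask=mask, labels=labels,
                               t_slice=slice(start, start + spec.window_length),
                               subject_id=subject_id, window_id=w))
    return out


# ---------------------------------------------------------------------------
# states

def matrix_to_features(m: np.ndarray) -> np.ndarray:
    """Vectorized strict upper triangle (the clustering feature space)."""
    k = m.shape[0]
    iu = np.triu_indices(k, 1)
    return np.asarray(m)[iu]


def features_to_matrix(v: np.ndarray, k: int) -> np.ndarray:
    out = np.eye(k)
    iu = np.triu_indices(k, 1)
    out[iu] = v
    out[(iu[1], iu[0])] = v
    return out


def _feature_stack(windows: list[FncMatrix]) -> np.ndarray:
    return np.stack([matrix_to_features(w.data) for w in windows])


def fit_states(windows: list[FncMatrix], k_candidates=range(2, 7),
               seed: int = 0, n_init: int = 10) -> StateModel:
    """Cluster all subjects' FNC windows into connectivity states.

    k-means (k-means++ init, Euclidean distance, ``n_init`` restarts,
    seeded) is fitted for every candidate k; the state count is chosen by
    the elbow criterion, here the candidate maximizing the second
    difference of the inertia curve (endpoints can only win when no
    interior candidate exists).
    """
    x = _feature_stack(windows)
    k_candidates = sorted(k_candidates)
    if len(x) < max(k_candidates):
        raise ValueError(
            f"only {len(x)} windows for up to {max(k_candidates)} clusters")
    fits, inertia = {}, {}
    for k in k_candidates:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        km.fit(x)
        fits[k] = km
        inertia[k] = float(km.inertia_)
    if len(k_candidates) >= 3:
        second_diff = {
            k: inertia[lo] - 2 * inertia[k] + inertia[hi]
            for lo, k, hi in zip(k_candidates, k_candidates[1:],
                                 k_candidates[2:])}
        chosen = max(second_diff, key=lambda k: (second_diff[k], -k))
    else:
        chosen = k_candidates[0]
    model = StateModel(k=chosen,
                       centroids=fits[chosen].cluster_centers_.copy(),
                       inertia_curve=inertia,
                       n_networks=windows[0].data.shape[0],
                       seed=seed)
    model.labels_ = assign_states(windows, model)
    return model


def assign_states(windows: list[FncMatrix], model: StateModel) -> np.ndarray:
    """Nearest-centroid state labels (0-based); ties go to the lowest
    state index."""
    x = _feature_stack(windows)
    if x.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match centroids "
            f"{model.centroids.shape[1]}")
    d = cdist(x, model.centroids)
    return np.argmin(d, axis=1)


def occupancy_ratio(labels: np.ndarray, k: int) -> np.ndarray:
    """Fraction of a subject's windows spent in each state; sums to 1."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels outside 0..{k - 1}")
    return np.bincount(labels, minlength=k) / labels.size


# ---------------------------------------------------------------------------
# group contrast

def fnc_group_test(group_c: list[FncMatrix], group_s: list[FncMatrix],
                   q: float = 0.05):
    """Elementwise Welch t (control minus patient) over the upper
    triangle with Benjamini-Hochberg FDR control at level ``q``.

    Returns (t_matrix, significance_mask, p_adjusted_matrix), each K x K
    and symmetric.
    """
    if len(group_c) < 2 or len(group_s) < 2:
        raise ValueError("need >=2 subjects per group")
    xc = _feature_stack(group_c)
    xs = _feature_stack(group_s)
    t, p = stats.ttest_ind(xc, xs, axis=0, equal_var=False)
    finite = np.isfinite(p)
    reject = np.zeros_like(p, dtype=bool)
    p_adj = np.full_like(p, np.nan)
    if finite.any():
        rej, adj, _, _ = multipletests(p[finite], alpha=q, method="fdr_bh")
        reject[finite] = rej
        p_adj[finite] = adj
    k = group_c[0].data.shape[0]
    t_mat = features_to_matrix(np.where(np.isfinite(t), t, 0.0), k)
    np.fill_diagonal(t_mat, 0.0)
    sig = features_to_matrix(reject.astype(float), k).astype(bool)
    np.fill_diagonal(sig, False)
    adj_mat = features_to_matrix(p_adj, k)
    np.fill_diagonal(adj_mat, np.nan)
    return t_mat, sig, adj_mat
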