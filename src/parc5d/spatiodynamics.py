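"""Voxel-wise spatial and spatiotemporal summaries and group inference.

A subject's 4D network score map omega (X, Y, Z, T) is reduced to 3D maps:
the voxel-wise time mean (static amplitude) and the temporal deviation --
the sum of absolute differences between consecutive timepoints, which is
zero exactly where the voxel series is constant and grows with voxel-level
spatial dynamics.  Subject maps are averaged into group maps, contrasted
with voxel-wise Welch two-sample t statistics, and probed further via the
peak voxels of the group difference map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Map3D", "TStatResult", "PeakSelection",
    "time_mean", "temporal_deviation", "subject_mean",
    "voxelwise_ttest", "difference_map", "select_peaks",
    "collect_peak_values", "threshold_mask",
]

_KINDS = {"time_mean", "temporal_deviation", "group_mean",
          "group_deviation", "difference", "tstat"}
_GROUP_KIND = {"time_mean": "group_mean",
               "temporal_deviation": "group_deviation"}


@dataclass
class Map3D:
    """A voxel-wise 3D summary on the analysis grid."""

    data: np.ndarray
    kind: str
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Map3D needs a 3D array, got {self.data.ndim}D")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if self.mask is not None and self.mask.shape != self.data.shape:
            raise ValueError("mask shape differs from data shape")


@dataclass
class TStatResult:
    """Voxel-wise Welch two-sample t statistics with per-group moments."""

    tmap: Map3D
    mean_c: np.ndarray
    mean_s: np.ndarray
    var_c: np.ndarray
    var_s: np.ndarray
    n_c: int
    n_s: int
    pmap: np.ndarray | None = None
    valid: np.ndarray | None = None     # False where both variances are 0


@dataclass
class PeakSelection:
    """Positive/negative peak voxels of a difference map plus, once
    filled, the per-subject values observed at those voxels."""

    positive: tuple[int, int, int] | None
    negative: tuple[int, int, int] | None
    values: dict = field(default_factory=dict)   # sign -> (labels, values)


def _check_time_axis(omega: np.ndarray, min_t: int) -> np.ndarray:
    omega = np.asarray(omega)
    if omega.ndim != 4:
        raise ValueError(f"expected a 4D (X,Y,Z,T) map, got {omega.ndim}D")
    if omega.shape[-1] < min_t:
        raise ValueError(
            f"need at least {min_t} timepoints, got {omega.shape[-1]}")
    return omega


def time_mean(omega: np.ndarray) -> Map3D:
    """Voxel-wise average over time of a 4D score map."""
    omega = _check_time_axis(omega, 1)
    return Map3D(omega.mean(axis=-1), "time_mean")


def temporal_deviation(omega: np.ndarray) -> Map3D:
    """Voxel-wise sum of absolute consecutive-timepoint differences.

    Zero iff the voxel series is constant in time; undefined for T < 2.
    """
    omega = _check_time_axis(omega, 2)
    dev = np.abs(np.diff(omega, axis=-1)).sum(axis=-1)
    return Map3D(dev, "temporal_deviation")


def subject_mean(maps: list[Map3D]) -> Map3D:
    """Voxel-wise mean over subjects; promotes the kind to its group
    counterpart."""
    if not maps:
        raise ValueError("need at least one subject map")
    kinds = {m.kind for m in maps}
    if len(kinds) != 1:
        raise ValueError(f"cannot average maps of mixed kinds {kinds}")
    shapes = {m.data.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"cannot average maps on different grids {shapes}")
    kind = maps[0].kind
    out_kind = _GROUP_KIND.get(kind, kind)
    data = np.mean([m.data for m in maps], axis=0)
    return Map3D(data, out_kind, mask=maps[0].mask)


def voxelwise_ttest(group_c: list[Map3D], group_s: list[Map3D],
                    compute_p: bool = True) -> TStatResult:
    """Welch two-sample t per voxel, control minus patient.

    Sample variances use denominator n-1; voxels where both groups have
    zero variance are flagged invalid and their t set to 0.  Two-sided
    p-values use the t distribution with Welch-Satterthwaite degrees of
    freedom.
    """
    n_c, n_s = len(group_c), len(group_s)
    if n_c < 2 or n_s < 2:
        raise ValueError(f"need >=2 subjects per group, got {n_c} and {n_s}")
    xc = np.stack([m.data for m in group_c])
    xs = np.stack([m.data for m in group_s])
    mean_c, mean_s = xc.mean(0), xs.mean(0)
    var_c = xc.var(0, ddof=1)
    var_s = xs.var(0, ddof=1)
    se2 = var_c / n_c + var_s / n_s
    valid = se2 > 0
    t = np.zeros_like(mean_c)
    np.divide(mean_c - mean_s, np.sqrt(se2, where=valid, out=np.ones_like(se2)),
              out=t, where=valid)
    pmap = None
    if compute_p:
        df = np.ones_like(t)
        num = se2 ** 2
        den = (var_c / n_c) ** 2 / (n_c - 1) + (var_s / n_s) ** 2 / (n_s - 1)
        np.divide(num, den, out=df, where=den > 0)
        pmap = np.where(valid,
                        2.0 * stats.t.sf(np.abs(t), df), np.nan)
    return TStatResult(tmap=Map3D(t, "tstat", mask=valid),
                       mean_c=mean_c, mean_s=mean_s,
                       var_c=var_c, var_s=var_s, n_c=n_c, n_s=n_s,
                       pmap=pmap, valid=valid)


def difference_map(group_c_mean: Map3D, group_s_mean: Map3D) -> Map3D:
    """Voxel-wise control-minus-patient difference of group maps."""
    if group_c_mean.data.shape != group_s_mean.data.shape:
        raise ValueError("group maps live on different grids")
    return Map3D(group_c_mean.data - group_s_mean.data, "difference",
                 mask=group_c_mean.mask)


def select_peaks(diff: Map3D, mask: np.ndarray) -> PeakSelection:
    """Locate the extreme voxels of the positive and negative segments of
    a difference map within a mask (ties broken by lexicographic voxel
    order, the order numpy's argmax scans).  A missing segment yields
    ``None`` for that peak."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != diff.data.shape:
        raise ValueError("mask shape differs from map shape")
    if not mask.any():
        raise ValueError("empty mask")
    d = np.where(mask, diff.data, 0.0)
    pos = np.unravel_index(np.argmax(d), d.shape) if (d > 0).any() else None
    neg = np.unravel_index(np.argmin(d), d.shape) if (d < 0).any() else None
    return PeakSelection(
        positive=tuple(int(i) for i in pos) if pos else None,
        negative=tuple(int(i) for i in neg) if neg else None)


def collect_peak_values(selection: PeakSelection, subject_maps: list[Map3D],
                        labels: list[str]) -> PeakSelection:
    """Fill a peak selection with each subject's map value at the peak
    voxels, keeping the group label alongside."""
    if len(subject_maps) != len(labels):
        raise ValueError("one label per subject map required")
    for sign, voxel in (("positive", selection.positive),
                        ("negative", selection.negative)):
        if voxel is None:
            continue
        vals = np.array([m.data[voxel] for m in subject_maps])
        selection.values[sign] = (list(labels), vals)
    return selection


def threshold_mask(map3d: Map3D, cutoff: float | None = None,
                   quantile: float | None = None) -> np.ndarray:
    """Boolean mask of voxels with |value| >= cutoff, or above an
    upper quantile of |value|; stricter rules give subset masks."""
    if (cutoff is None) == (quantile is None):
        raise ValueError("give exactly one of cutoff or quantile")
    a = np.abs(map3d.data)
    if quantile is not None:
        if not 0.0 < quantile < 1.0:
            raise ValueError(f"quantile {quantile} outside (0, 1)")
        cutoff = np.quantile(a, quantile)
        return a > cutoff
    return a >= cutoff
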