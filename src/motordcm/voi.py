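"""Volume-of-interest peak search and timeseries extraction.

Individual-run coordinates are found by searching for a local maximum of
the statistic map near a group-level peak: the candidate must lie within
a per-region distance bound (15 mm for cortical/cerebellar regions, 9 mm
for the thalamus) and pass the most stringent achievable threshold of a
p = 0.05 -> 0.25 ladder; when no candidate passes even the most liberal
rung, the group coordinate itself is used.  Timeseries are summarised
over a 4 mm-radius sphere, by default as the first principal temporal
component (eigenvariate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .glm import StatMap, _volumes_to_array

__all__ = ["PeakSearchPolicy", "find_voi_peak", "extract_voi"]

DEFAULT_DISTANCE_BOUNDS = {"M1": 15.0, "SMA": 15.0, "CB": 15.0, "THA": 9.0}


@dataclass
class PeakSearchPolicy:
    """Distance bounds and the threshold ladder for individual peaks."""

    max_distance: dict = field(
        default_factory=lambda: dict(DEFAULT_DISTANCE_BOUNDS))
    ladder: tuple = (0.05, 0.10, 0.15, 0.20, 0.25)
    voi_radius: float = 4.0

    def __post_init__(self):
        if any(d <= 0 for d in self.max_distance.values()):
            raise ValueError("distance bounds must be positive")
        if not all(a < b for a, b in zip(self.ladder, self.ladder[1:])):
            raise ValueError("threshold ladder must be strictly increasing")

    def bound(self, region: str) -> float:
        try:
            return self.max_distance[region]
        except KeyError:
            raise KeyError(f"no distance bound configured for region "
                           f"{region!r}") from None


def find_voi_peak(stat_map: StatMap, roi_mask, group_coord, region: str,
                  policy: PeakSearchPolicy = None) -> dict:
    """Locate the individual peak for one region.

    Returns a dict with keys ``coord`` (mm), ``threshold_used`` (the p
    rung that produced the peak, or None on fallback), ``fallback`` and
    ``distance`` (mm from the group coordinate).
    """
    if policy is None:
        policy = PeakSearchPolicy()
    mask = np.asarray(roi_mask, bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    F = np.asarray(stat_map.data, float)
    aff = stat_map.affine
    group_coord = np.asarray(group_coord, float)
    # all voxel centres in mm
    idx = np.argwhere(mask)
    mm = (aff @ np.column_stack([idx, np.ones(len(idx))]).T).T[:, :3]
    dist = np.linalg.norm(mm - group_coord, axis=1)
    bound = policy.bound(region)
    # local maxima of the statistic (26-neighbourhood)
    local_max = (F == ndimage.maximum_filter(F, size=3)) & mask
    for p in policy.ladder:
        thr = stat_map.p_to_threshold(p)
        ok = local_max[tuple(idx.T)] & (F[tuple(idx.T)] >= thr) & (dist <= bound)
        if ok.any():
            best = np.flatnonzero(ok)[np.argmin(dist[np.flatnonzero(ok)])]
            return {"coord": tuple(float(v) for v in mm[best]),
                    "threshold_used": p, "fallback": False,
                    "distance": float(dist[best])}
    return {"coord": tuple(float(v) for v in group_coord),
            "threshold_used": None, "fallback": True, "distance": 0.0}


def extract_voi(volumes, centre, radius: float = 4.0, affine=None,
                method: str = "eigenvariate") -> np.ndarray:
    """Summary timeseries of a spherical volume of interest.

    ``method='eigenvariate'`` returns the first principal temporal
    component of the in-sphere voxels, sign-aligned to correlate
    positively with the sphere mean and scaled to the mean's variance;
    ``method='mean'`` returns the plain sphere mean.  A sphere containing
    a single voxel falls back to that voxel's series with a warning.
    """
    data, img_affine = _volumes_to_array(volumes)
    if affine is None:
        affine = img_affine
    shape3 = data.shape[:-1]
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape3], indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel(),
                           np.ones(ii.size)])
    mm = (np.asarray(affine) @ vox.T).T[:, :3]
    dist = np.linalg.norm(mm - np.asarray(centre, float), axis=1)
    inside = dist <= radius
    if not inside.any():
        raise ValueError("sphere does not intersect the grid")
    Y = data.reshape(-1, data.shape[-1])[inside].T    # (T, v)
    if Y.shape[1] < 2:
        warnings.warn("sphere contains fewer than 2 voxels; returning the "
                      "single voxel series", UserWarning)
        return Y[:, 0].copy()
    mean_series = Y.mean(axis=1)
    if method == "mean":
        return mean_series
    if method != "eigenvariate":
        raise ValueError(f"unknown method {method!r}")
    Yc = Y - Y.mean(axis=0)
    U, s, _Vt = np.linalg.svd(Yc, full_matrices=False)
    pc = U[:, 0] * s[0]
    mc = mean_series - mean_series.mean()
    if pc @ mc < 0:
        pc = -pc
    sd = pc.std()
    if sd > 0 and mc.std() > 0:
        pc = pc / sd * mc.std()
    return pc + mean_series.mean()
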