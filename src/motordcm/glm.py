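"""First-level GLM and group factorial interaction testing.

The first level models each volume as move-block activation (boxcar
convolved with a canonical double-gamma HRF) plus drift (discrete-cosine
high-pass, 80 s cutoff), optional motion nuisance columns, and a
constant; contrasts give per-session effect maps.  The group level tests
the polarity-by-time interaction voxelwise with subject treated as a
repeated measure, restricted to regions of interest, discarding
single-voxel clusters as spurious.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .dcm.invert import confound_basis

__all__ = ["GLMDesign", "StatMap", "canonical_hrf", "build_design",
           "fit_glm", "factorial_interaction"]


def canonical_hrf(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                  ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Double-gamma hemodynamic response function (unit peak ~6 s)."""
    t = np.asarray(t, float)
    h = stats.gamma.pdf(t, peak, scale=1.0) \
        - ratio * stats.gamma.pdf(t, undershoot, scale=1.0)
    return h / h.max()


@dataclass
class GLMDesign:
    """First-level design matrix with named columns."""

    matrix: pd.DataFrame
    TR: float
    n_volumes: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.matrix.to_numpy())):
            raise ValueError("design matrix must be finite")
        if len(self.matrix) != self.n_volumes:
            raise ValueError("design rows must equal n_volumes")

    @property
    def columns(self):
        return list(self.matrix.columns)

    def array(self) -> np.ndarray:
        return self.matrix.to_numpy(float)

    def contrast_vector(self, column: str = "task") -> np.ndarray:
        c = np.zeros(len(self.matrix.columns))
        c[self.matrix.columns.get_loc(column)] = 1.0
        return c


def build_design(schedule, TR: float, n_volumes: int, motion=None,
                 highpass_cutoff: float = 80.0,
                 microtime_dt: float = 0.1) -> GLMDesign:
    """Build the first-level design for one run.

    The move-block boxcar is convolved with the canonical HRF on a fine
    grid and sampled at volume times; drift columns are the cosine set
    with period > ``highpass_cutoff``; ``motion`` supplies the 6 nuisance
    columns (None -> omitted with a warning).
    """
    if n_volumes * TR < schedule.total_duration:
        raise ValueError("n_volumes x TR does not cover the schedule")
    duration = n_volumes * TR
    n_fine = int(round(duration / microtime_dt))
    t_fine = np.arange(n_fine) * microtime_dt
    boxcar = np.zeros(n_fine)
    for onset in schedule.move_onsets:
        boxcar[(t_fine >= onset) & (t_fine < onset + schedule.block_duration)] = 1.0
    hrf = canonical_hrf(np.arange(0, 32.0, microtime_dt))
    conv = np.convolve(boxcar, hrf)[:n_fine] * microtime_dt
    vol_idx = np.round(np.arange(n_volumes) * TR / microtime_dt).astype(int)
    task = conv[vol_idx]

    basis = confound_basis(n_volumes, TR, highpass_cutoff)  # constant first
    cols = {"task": task}
    for k in range(1, basis.shape[1]):
        cols[f"drift_{k}"] = basis[:, k]
    if motion is None:
        warnings.warn("no motion nuisance columns supplied; design built "
                      "without them", UserWarning)
    else:
        motion = np.asarray(motion, float)
        if motion.shape[0] != n_volumes:
            raise ValueError("motion regressors must have one row per volume")
        for k in range(motion.shape[1]):
            cols[f"motion_{k + 1}"] = motion[:, k]
    cols["constant"] = np.ones(n_volumes)
    return GLMDesign(matrix=pd.DataFrame(cols), TR=TR, n_volumes=n_volumes)


@dataclass
class StatMap:
    """Voxelwise statistic map with its degrees of freedom and affine."""

    data: np.ndarray
    dof: tuple          # (1, df_error) for t; (df_num, df_den) for F
    affine: np.ndarray
    kind: str = "t"     # 't' or 'F'

    def __post_init__(self):
        if min(self.dof) <= 0:
            raise ValueError("degrees of freedom must be positive")

    def p_to_threshold(self, p: float) -> float:
        if self.kind == "t":
            return float(stats.t.isf(p, self.dof[1]))
        return float(stats.f.isf(p, *self.dof))


def _volumes_to_array(volumes):
    import nibabel as nib
    if isinstance(volumes, nib.Nifti1Image):
        return np.asarray(volumes.dataobj, float), volumes.affine
    return np.asarray(volumes, float), np.eye(4)


def fit_glm(volumes, design: GLMDesign, contrast=None):
    """Voxelwise OLS fit; returns (t StatMap, effect map).

    ``contrast`` is a weight vector over design columns (default: the
    task column).  Raises on a rank-deficient design, naming the
    collinear columns.
    """
    data, affine = _volumes_to_array(volumes)
    X = design.array()
    T = X.shape[0]
    if data.shape[-1] != T:
        raise ValueError("volume count does not match design rows")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [design.columns[i] for i in range(X.shape[1])
               if abs(R[i, i]) < 1e-8 * abs(R).max()]
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear columns: {bad}")
    if contrast is None:
        contrast = design.contrast_vector("task")
    c = np.asarray(contrast, float)

    shape3 = data.shape[:-1]
    Y = data.reshape(-1, T).T            # (T, V)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = T - rank
    sigma2 = (resid ** 2).sum(axis=0) / dof
    XtXinv = np.linalg.inv(X.T @ X)
    var_c = float(c @ XtXinv @ c)
    effect = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = effect / np.sqrt(np.maximum(sigma2 * var_c, 1e-300))
    tval[sigma2 == 0] = 0.0
    tmap = StatMap(data=tval.reshape(shape3), dof=(1, dof), affine=affine,
                   kind="t")
    return tmap, effect.reshape(shape3)


def factorial_interaction(effect_maps, polarity, time, subject,
                          roi_mask=None, p_threshold: float = 1e-4,
                          min_cluster: int = 2):
    """Voxelwise polarity-by-time interaction across sessions.

    ``effect_maps`` is a sequence of 3-D session effect maps with aligned
    ``polarity`` / ``time`` / ``subject`` labels; every subject must
    contribute every polarity-by-time cell.  The interaction F statistic
    uses the subject-by-interaction term as error (repeated measures,
    pooled over voxels' own error terms).  Suprathreshold voxels at
    ``p_threshold`` (uncorrected) are restricted to ``roi_mask`` and
    clusters smaller than ``min_cluster`` voxels are discarded as
    spurious.

    Returns (F StatMap, suprathreshold boolean mask, cluster table).
    """
    maps = np.asarray([np.asarray(m, float) for m in effect_maps])
    polarity = np.asarray(polarity)
    time = np.asarray(time)
    subject = np.asarray(subject)
    pols = sorted(set(polarity))
    times = sorted(set(time))
    subs = sorted(set(subject))
    P, Tn, S = len(pols), len(times), len(subs)
    cell = np.full((S, P, Tn), -1, int)
    for idx in range(len(maps)):
        s = subs.index(subject[idx])
        p = pols.index(polarity[idx])
        t = times.index(time[idx])
        cell[s, p, t] = idx
    missing = np.argwhere(cell < 0)
    if len(missing):
        s, p, t = missing[0]
        raise ValueError(f"subject {subs[s]!r} is missing cell "
                         f"({pols[p]}, {times[t]})")
    shape3 = maps.shape[1:]
    Y = maps.reshape(len(maps), -1)[cell]          # (S, P, T, V)

    m = Y.mean(axis=(0, 1, 2))
    m_s = Y.mean(axis=(1, 2))
    m_p = Y.mean(axis=(0, 2))
    m_t = Y.mean(axis=(0, 1))
    m_pt = Y.mean(axis=0)
    m_sp = Y.mean(axis=2)
    m_st = Y.mean(axis=1)

    ss_int = S * ((m_pt - m_p[:, None] - m_t[None, :] + m) ** 2).sum(axis=(0, 1))
    resid = (Y - m_sp[:, :, None] - m_st[:, None, :] - m_pt[None]
             + m_s[:, None, None] + m_p[None, :, None] + m_t[None, None, :]
             - m)
    ss_err = (resid ** 2).sum(axis=(0, 1, 2))
    df_int = (P - 1) * (Tn - 1)
    df_err = (S - 1) * df_int
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_int / df_int) / np.maximum(ss_err / df_err, 1e-300)
    F = np.where(ss_err == 0, 0.0, F).reshape(shape3)
    fmap = StatMap(data=F, dof=(df_int, df_err), affine=np.eye(4), kind="F")

    thr = fmap.p_to_threshold(p_threshold)
    supra = F > thr
    if roi_mask is not None:
        supra &= np.asarray(roi_mask, bool)
    labels, n_clust = ndimage.label(supra)
    rows = []
    for lab in range(1, n_clust + 1):
        vox = labels == lab
        size = int(vox.sum())
        if size < min_cluster:      # single significant voxel -> spurious
            supra[vox] = False
            continue
        peak_idx = np.unravel_index(np.argmax(np.where(vox, F, -np.inf)),
                                    F.shape)
        rows.append({"cluster": lab, "size": size,
                     "peak_i": peak_idx[0], "peak_j": peak_idx[1],
                     "peak_k": peak_idx[2],
                     "peak_F": float(F[peak_idx])})
    clusters = pd.DataFrame(rows, columns=["cluster", "size", "peak_i",
                                           "peak_j", "peak_k", "peak_F"])
    return fmap, supra, clusters
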