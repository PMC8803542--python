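"""Synthetic inputs for the whole pipeline.

Everything the analysis consumes can be generated here with seeded
reproducibility: crossover cohorts with ground-truth polarity-by-time
connectivity effects, 4-node BOLD runs from the bilinear DCM, small
volumetric grids embedding the node signals at the group coordinates,
1200 Hz joystick traces with cue-locked minimum-jerk thumb movements,
and paired blinding-judgement tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import nibabel as nib
from scipy.ndimage import gaussian_filter

from .schedule import TaskSchedule, generate_schedule
from .dcm.model import (ConnectivityModel, DCMStructure, HemodynamicConstants,
                        REGIONS, build_inputs, region_index)
from .dcm.forward import forward_predict

logger = logging.getLogger(__name__)

POLARITIES = ("anodal", "cathodal", "sham")
TIMES = ("pre", "post")

#: group-level peak coordinates (mm) used as embedding centres, one set per
#: experiment (left M1, left SMA, left thalamus, right cerebellum)
GROUP_COORDINATES = {
    "exp1": {"M1": (-33.0, -13.0, 62.0), "SMA": (0.0, -7.0, 65.0),
             "THA": (-12.0, -22.0, 5.0), "CB": (15.0, -55.0, -22.0)},
    "exp2": {"M1": (-24.0, -19.0, 74.0), "SMA": (-3.0, -4.0, 65.0),
             "THA": (-18.0, -16.0, 14.0), "CB": (12.0, -55.0, -25.0)},
}

#: acquisition models: (TR in s, volumes per run)
ACQUISITION = {"exp1": (2.0, 160), "exp2": (2.7, 119)}


def default_baseline() -> ConnectivityModel:
    """Plausible stable group-mean connectivity for the motor network."""
    return ConnectivityModel(
        a_off=[[0.00, 0.20, 0.30, -0.10],   # to M1  from (M1,SMA,THA,CB)
               [0.15, 0.00, 0.20, 0.00],    # to SMA
               [0.10, 0.10, 0.00, 0.20],    # to THA
               [0.10, 0.00, 0.10, 0.00]],   # to CB
        a_self=[0.0, 0.0, 0.0, 0.0],
        b_self=[0.3, 0.3, 0.2, 0.1],
        c=[0.3, 0.3, 0.0, 0.0])


#: polarity-specific coupling shifts applied in post sessions, following the
#: direction of the reported polarity-by-time effects for each montage
DEFAULT_SHIFTS = {
    "exp1": {
        "anodal": {"A:THA(self)": -0.2, "A:CB->M1": -0.2},
        "cathodal": {"A:THA->SMA": +0.2, "B:M1(self)": +0.2},
    },
    "exp2": {
        "cathodal": {"A:THA->M1": +0.2, "A:M1(self)": +0.2,
                     "A:M1->SMA": -0.2},
        "anodal": {"A:M1(self)": +0.2, "A:THA(self)": +0.2,
                   "A:SMA(self)": -0.2, "A:M1->SMA": +0.2},
    },
}

#: default between-subject standard deviations per parameter block
DEFAULT_BETWEEN_SD = {"a_off": 0.05, "a_self": 0.1, "b_self": 0.1, "c": 0.1,
                      "ln_kappa": 0.0, "ln_tau": 0.0}


@dataclass
class CohortSpec:
    """Crossover cohort: every subject completes all 6 polarity-by-time cells."""

    n_subjects: int = 21
    polarities: tuple = POLARITIES
    times: tuple = TIMES
    seed: int = 0

    def draw_covariates(self) -> pd.DataFrame:
        """Subject covariates: age (years), sex (1=male), handedness score."""
        rng = np.random.default_rng(self.seed + 1_000_003)
        return pd.DataFrame({
            "subject": [f"sub-{i + 1:02d}" for i in range(self.n_subjects)],
            "age": np.round(np.clip(rng.normal(25, 4, self.n_subjects), 18, 45)),
            "sex": (rng.random(self.n_subjects) < 0.38).astype(int),
            "handedness": np.round(np.clip(
                rng.normal(80, 15, self.n_subjects), 40, 100)),
        }).set_index("subject")


def _apply_shift(model: ConnectivityModel, name: str, value: float) -> None:
    """Add ``value`` to the named connection (labels as DCMStructure.labels)."""
    try:
        kind, rest = name.split(":", 1)
        if "->" in rest:
            src, dst = rest.split("->")
            i, j = region_index(dst), region_index(src)
            if kind != "A":
                raise ValueError
            model.a_off[i, j] += value
        elif rest.endswith("(self)"):
            r = region_index(rest.removesuffix("(self)"))
            {"A": model.a_self, "B": model.b_self}[kind][r] += value
        else:
            if kind != "C":
                raise ValueError
            model.c[region_index(rest)] += value
    except (ValueError, KeyError):
        raise KeyError(f"unknown connection name {name!r}; use e.g. "
                       "'A:THA->M1', 'A:M1(self)', 'B:SMA(self)' or 'C:M1'") \
            from None


@dataclass
class GroundTruthEffects:
    """Baseline connectivity, between-subject spread, and interaction shifts.

    ``shifts`` maps polarity -> {connection name -> additive change}; the
    change is applied in post sessions of that polarity only.  Sham must
    carry no shift.
    """

    baseline: ConnectivityModel = field(default_factory=default_baseline)
    between_sd: dict = field(default_factory=lambda: dict(DEFAULT_BETWEEN_SD))
    shifts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.shifts.get("sham"):
            raise ValueError("sham sessions must carry a zero shift")
        # validate connection names eagerly
        for pol, table in self.shifts.items():
            if pol not in POLARITIES:
                raise KeyError(f"unknown polarity {pol!r}")
            probe = self.baseline.copy()
            for name, value in table.items():
                _apply_shift(probe, name, value)

    @classmethod
    def default(cls, experiment: str = "exp2") -> "GroundTruthEffects":
        return cls(shifts={p: dict(t) for p, t in
                           DEFAULT_SHIFTS[experiment].items()})


def generate_cohort(spec: CohortSpec, effects: GroundTruthEffects,
                    max_redraws: int = 50) -> dict:
    """Draw per-session ground-truth connectivity for a crossover cohort.

    Each subject's baseline is drawn once (Gaussian around the group
    means) and shared across that subject's sessions; post sessions add
    the polarity's interaction shift.  Unstable draws (non-negative real
    eigenvalue of the rest Jacobian, for any session) are rejected and
    redrawn, with a log entry.

    Returns a manifest dict: ``subjects`` -> list of per-subject records
    with covariates and 6 session parameter sets, plus the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    cov = spec.draw_covariates()
    subjects = []
    n_redraws = 0
    for sid in cov.index:
        for attempt in range(max_redraws):
            base = effects.baseline.copy()
            n = base.n_regions
            jitter = rng.normal(0.0, effects.between_sd["a_off"], (n, n))
            np.fill_diagonal(jitter, 0.0)
            base.a_off += jitter
            base.a_self += rng.normal(0, effects.between_sd["a_self"], n)
            base.b_self += rng.normal(0, effects.between_sd["b_self"], n)
            base.c += np.where(base.c != 0,
                               rng.normal(0, effects.between_sd["c"], n), 0.0)
            sessions = {}
            ok = True
            for pol in spec.polarities:
                for t in spec.times:
                    m = base.copy()
                    if t == "post":
                        for name, value in effects.shifts.get(pol, {}).items():
                            _apply_shift(m, name, value)
                    if not m.is_stable(0.0):
                        ok = False
                        break
                    sessions[(pol, t)] = m
                if not ok:
                    break
            if ok:
                break
            n_redraws += 1
            logger.info("unstable parameter draw for %s (attempt %d); redrawing",
                        sid, attempt + 1)
        else:
            raise RuntimeError(f"could not draw a stable model for {sid}")
        subjects.append({
            "subject": sid,
            "covariates": cov.loc[sid].to_dict(),
            "sessions": {f"{pol}_{t}": m.to_dict()
                         for (pol, t), m in sessions.items()},
        })
    return {
        "seed": spec.seed,
        "n_subjects": spec.n_subjects,
        "n_sessions": spec.n_subjects * len(spec.polarities) * len(spec.times),
        "n_redraws": n_redraws,
        "ground_truth": {
            "baseline": effects.baseline.to_dict(),
            "between_sd": effects.between_sd,
            "shifts": effects.shifts,
        },
        "subjects": subjects,
    }


def cohort_covariates(manifest: dict) -> pd.DataFrame:
    rows = {s["subject"]: s["covariates"] for s in manifest["subjects"]}
    return pd.DataFrame.from_dict(rows, orient="index")


def session_model(manifest: dict, subject, polarity: str,
                  time: str) -> ConnectivityModel:
    if isinstance(subject, int):
        rec = manifest["subjects"][subject]
    else:
        rec = next(s for s in manifest["subjects"] if s["subject"] == subject)
    return ConnectivityModel.from_dict(rec["sessions"][f"{polarity}_{time}"])


def emulate_session_posteriors(manifest: dict, structure, obs_sd: float = 0.05,
                               seed: int = 0) -> dict:
    """Emulate first-level posteriors directly from ground-truth parameters.

    For experiments that exercise the group-level machinery at scale
    (many cohorts), running the full variational inversion for every
    session is unnecessary: each session's posterior is emulated as a
    Gaussian centred on the true session parameters plus observation
    noise of sd ``obs_sd``, with covariance ``obs_sd**2 * I`` — the
    typical sharpness of a converged single-run inversion.

    Returns {(subject_index, polarity, time): PosteriorEstimate}.
    """
    from .dcm.invert import PosteriorEstimate

    rng = np.random.default_rng(seed)
    out = {}
    labels = structure.labels()
    k = structure.n_free
    for s, rec in enumerate(manifest["subjects"]):
        for key, params in rec["sessions"].items():
            pol, t = key.rsplit("_", 1)
            model = ConnectivityModel.from_dict(params)
            mean = structure.pack(model) + rng.normal(0.0, obs_sd, k)
            out[(s, pol, t)] = PosteriorEstimate(
                mean=mean, cov=np.eye(k) * obs_sd ** 2,
                log_precisions=np.array([]), free_energy=0.0, labels=labels)
    return out


# ---------------------------------------------------------------------------
# BOLD simulation

@dataclass
class SyntheticRun:
    """One simulated session: noisy node BOLD plus the noiseless truth."""

    node_timeseries: np.ndarray   # (n_volumes, n_regions)
    ground_truth: np.ndarray      # noiseless forward prediction
    TR: float
    n_volumes: int
    noise_sd: np.ndarray
    drift_amplitude: float = 0.0
    regions: tuple = REGIONS

    def __post_init__(self):
        if self.node_timeseries.shape[0] != self.n_volumes:
            raise ValueError("timeseries length must equal n_volumes")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.node_timeseries, columns=list(self.regions))
        df.insert(0, "time", np.arange(self.n_volumes) * self.TR)
        return df


def volumes_for(schedule: TaskSchedule, TR: float) -> int:
    """ceil(total_duration / TR) — 160 volumes at TR 2.0, 119 at TR 2.7."""
    return int(math.ceil(schedule.total_duration / TR))


def simulate_session_bold(model: ConnectivityModel, schedule: TaskSchedule,
                          TR: float, n_volumes: int = None,
                          noise_sd=0.0, seed: int = 0,
                          drift_amplitude: float = 0.0,
                          constants: HemodynamicConstants = None,
                          relative_noise: bool = False) -> SyntheticRun:
    """Forward-simulate one session's 4-node BOLD run.

    ``noise_sd`` is i.i.d. Gaussian observation noise in signal units
    (scalar or per region); with ``relative_noise=True`` it is interpreted
    as a fraction of each region's noiseless signal standard deviation.
    ``drift_amplitude`` adds a random sum of slow cosines (period > 80 s),
    emulating scanner drift the GLM high-pass must remove.
    """
    if model.n_regions != len(REGIONS):
        raise ValueError("expected a 4-region model")
    if n_volumes is None:
        n_volumes = volumes_for(schedule, TR)
    if n_volumes * TR < schedule.total_duration:
        raise ValueError("n_volumes x TR must cover the schedule")
    if constants is None:
        constants = HemodynamicConstants()
    if not model.is_stable(0.0):
        raise ValueError("unstable parameter set (positive real-part "
                         "eigenvalue at rest); redraw before simulating")
    rng = np.random.default_rng(seed)
    duration = max(schedule.total_duration, n_volumes * TR)
    inputs = build_inputs(schedule, dt=TR / 16.0, duration=duration)
    g = forward_predict(model, constants, inputs, TR, n_volumes)
    sd = np.asarray(noise_sd, float) * (g.std(axis=0) if relative_noise else 1.0)
    y = g + rng.normal(0.0, 1.0, g.shape) * sd
    if drift_amplitude > 0:
        t = np.arange(n_volumes) * TR
        n_drift = max(int(np.floor(2 * duration / 80.0)) - 1, 1)
        for k in range(1, n_drift + 1):
            coef = rng.normal(0, drift_amplitude, len(REGIONS))
            y = y + np.cos(np.pi * k * (t[:, None] + TR / 2) / duration) * coef
    return SyntheticRun(node_timeseries=y, ground_truth=g, TR=TR,
                        n_volumes=n_volumes,
                        noise_sd=np.broadcast_to(sd, (len(REGIONS),)).copy(),
                        drift_amplitude=drift_amplitude)


# ---------------------------------------------------------------------------
# volumetric embedding

DEFAULT_GRID_SHAPE = (32, 32, 38)
DEFAULT_VOXEL_SIZE = 3.0
DEFAULT_ORIGIN = (-57.0, -79.0, -34.0)


def grid_affine(voxel_size: float = DEFAULT_VOXEL_SIZE,
                origin=DEFAULT_ORIGIN) -> np.ndarray:
    aff = np.diag([voxel_size] * 3 + [1.0])
    aff[:3, 3] = origin
    return aff


def embed_volumes(run: SyntheticRun, region_coords: dict,
                  grid_shape=DEFAULT_GRID_SHAPE,
                  affine: np.ndarray = None,
                  smooth_noise_sd: float = 0.0,
                  smooth_fwhm_vox: float = 2.0,
                  cluster_radius_mm: float = 4.0,
                  seed: int = 0) -> nib.Nifti1Image:
    """Embed node timeseries into a small 4-D grid at given mm coordinates.

    Each region's series is added to the compact cluster of voxels within
    ``cluster_radius_mm`` of its coordinate; spatially smooth Gaussian
    noise (sd ``smooth_noise_sd`` after smoothing) fills the rest.
    """
    if affine is None:
        affine = grid_affine()
    inv = np.linalg.inv(affine)
    rng = np.random.default_rng(seed)
    shape4 = tuple(grid_shape) + (run.n_volumes,)
    if smooth_noise_sd > 0:
        sigma = smooth_fwhm_vox / 2.3548
        noise = rng.standard_normal(shape4)
        for t in range(run.n_volumes):
            noise[..., t] = gaussian_filter(noise[..., t], sigma)
        noise *= smooth_noise_sd / noise.std()
        data = noise
    else:
        data = np.zeros(shape4)

    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    mm = vox @ affine.T

    for r, (region, coord) in enumerate(region_coords.items()):
        ijk = (inv @ np.append(np.asarray(coord, float), 1.0))[:3]
        if np.any(ijk < -0.5) or np.any(ijk > np.asarray(grid_shape) - 0.5):
            raise ValueError(f"coordinate {tuple(coord)} for region "
                             f"{region!r} falls outside the grid")
        dist = np.linalg.norm(mm[..., :3] - np.asarray(coord), axis=-1)
        cluster = dist <= cluster_radius_mm
        col = list(run.regions).index(region) if region in run.regions else r
        data[cluster, :] += run.node_timeseries[:, col]
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms((DEFAULT_VOXEL_SIZE,) * 3 + (run.TR,))
    return img


# ---------------------------------------------------------------------------
# joystick traces

JOYSTICK_RATE = 1200.0  # Hz


@dataclass
class JoystickTrace:
    """x-y joystick displacement sampled uniformly at 1200 Hz."""

    sample_times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rate: float = JOYSTICK_RATE

    def __post_init__(self):
        dt = np.diff(self.sample_times)
        if len(dt) and not np.allclose(dt, 1.0 / self.rate, atol=1e-9):
            raise ValueError("joystick trace must be uniformly sampled")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.sample_times, "x": self.x,
                             "y": self.y})


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(tau), s(0)=0, s(1)=1."""
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def _bump(tau: np.ndarray) -> np.ndarray:
    """Out-and-back thumb displacement: minimum-jerk rise then return."""
    out = np.where(tau <= 0.5, _minimum_jerk(2 * tau),
                   _minimum_jerk(2 * (1 - tau)))
    return np.clip(out, 0.0, None)


def simulate_joystick(schedule: TaskSchedule, latency_mean: float = 0.30,
                      latency_sd: float = 0.04,
                      movement_duration: float = 0.20,
                      amplitude: float = 1.0, noise_sd: float = 0.01,
                      miss_rate: float = 0.0, seed: int = 0,
                      rate: float = JOYSTICK_RATE):
    """Simulate a run's joystick trace with cue-locked movements.

    Each non-missed cue is followed, after a Gaussian latency, by a
    minimum-jerk out-and-back displacement bump of the given duration and
    amplitude on the x axis.  Returns (JoystickTrace, ground-truth trial
    table) where the table records the generator's onsets and the mean
    absolute velocity / peak absolute acceleration of the noiseless bump.
    """
    if latency_mean <= 0:
        raise ValueError("latency_mean must be positive")
    if not 0 <= miss_rate < 1:
        raise ValueError("miss_rate must lie in [0, 1)")
    from .schedule import CUE_ISI_RANGE
    if movement_duration > CUE_ISI_RANGE[0]:
        raise ValueError("movement_duration exceeds the minimum inter-cue "
                         "interval; movements would overlap")
    rng = np.random.default_rng(seed)
    n = int(round(schedule.total_duration * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)
    records = []
    for cue in np.sort(schedule.cue_onsets):
        if rng.random() < miss_rate:
            continue
        latency = max(rng.normal(latency_mean, latency_sd), 0.05)
        onset = cue + latency
        offset = onset + movement_duration
        sel = (t >= onset) & (t < offset)
        tau = (t[sel] - onset) / movement_duration
        bump = amplitude * _bump(tau)
        x[sel] += bump
        vel = np.gradient(bump, 1.0 / rate) if len(bump) > 2 else np.zeros(1)
        acc = np.gradient(vel, 1.0 / rate) if len(bump) > 2 else np.zeros(1)
        records.append({
            "cue_time": cue, "onset": onset, "offset": offset,
            "reaction_time": latency,
            "mean_velocity": float(np.mean(np.abs(vel))),
            "peak_acceleration": float(np.max(np.abs(acc))),
        })
    x_noisy = x + rng.normal(0, noise_sd, n)
    y_noisy = rng.normal(0, noise_sd, n)
    trace = JoystickTrace(sample_times=t, x=x_noisy, y=y_noisy, rate=rate)
    return trace, pd.DataFrame(records, columns=[
        "cue_time", "onset", "offset", "reaction_time", "mean_velocity",
        "peak_acceleration"])


# ---------------------------------------------------------------------------
# blinding

def simulate_blinding(n_subjects: int, p_correct_active: float,
                      p_correct_sham: float, seed: int = 0):
    """Paired correct/incorrect stimulation judgements per subject.

    Returns (per-subject DataFrame, 2x2 concordance table) where the
    table rows index the active-session judgement (correct, incorrect)
    and columns the sham-session judgement.
    """
    for p in (p_correct_active, p_correct_sham):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    active = rng.random(n_subjects) < p_correct_active
    sham = rng.random(n_subjects) < p_correct_sham
    df = pd.DataFrame({"subject": [f"sub-{i + 1:02d}" for i in range(n_subjects)],
                       "correct_active": active, "correct_sham": sham})
    table = np.array([
        [int(np.sum(active & sham)), int(np.sum(active & ~sham))],
        [int(np.sum(~active & sham)), int(np.sum(~active & ~sham))],
    ])
    return df, table
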