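"""Joystick kinematics and behavioural statistics.

The processing chain mirrors standard motion-tracking practice for
cue-locked discrete movements: Euclidean displacement, zero-phase 15 Hz
low-pass, change-point segmentation of each trial window under a
mean-shift model, per-trial reaction time / mean velocity / peak
acceleration, run-level averages, a 2 (time) x 3 (polarity)
repeated-measures ANOVA, and McNemar's exact test for blinding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = ["preprocess_trace", "detect_changepoints", "detect_movement",
           "trial_metrics", "extract_trials", "summarize_run", "rm_anova",
           "mcnemar", "MovementTrial", "RunSummary", "BlindingTable"]

LOWPASS_HZ = 15.0
FILTER_ORDER = 4


@dataclass
class MovementTrial:
    """Kinematics of one cued movement (times in seconds)."""

    cue_time: float
    onset: float = np.nan
    offset: float = np.nan
    reaction_time: float = np.nan
    mean_velocity: float = np.nan
    peak_acceleration: float = np.nan
    valid: bool = False

    def __post_init__(self):
        if self.valid:
            if not self.onset < self.offset:
                raise ValueError("valid trial requires onset < offset")
            if self.reaction_time < 0:
                raise ValueError("valid trial requires non-negative RT")


@dataclass
class RunSummary:
    """Run-level averages of the valid trials of one session."""

    subject: str
    polarity: str
    time: str
    reaction_time: float
    mean_velocity: float
    peak_acceleration: float
    n_valid: int
    n_excluded: int


@dataclass
class BlindingTable:
    """Paired 2x2 counts of correct/incorrect judgements (active vs sham).

    ``counts[0, 0]`` = both correct, ``counts[0, 1]`` = active correct /
    sham incorrect, ``counts[1, 0]`` the reverse, ``counts[1, 1]`` = both
    incorrect.
    """

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (2, 2):
            raise ValueError("blinding table must be 2x2")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype,
                                                        np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_subjects(self) -> int:
        return int(self.counts.sum())

    @property
    def discordant(self) -> tuple:
        return int(self.counts[0, 1]), int(self.counts[1, 0])


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_trace(trace, cutoff_hz: float = LOWPASS_HZ,
                     rest_position=(0.0, 0.0)) -> np.ndarray:
    """Scalar displacement: Euclidean distance from rest, low-passed.

    The joystick is calibrated before each run, so the rest position
    defaults to the origin; pass ``rest_position='auto'`` to estimate it
    as the per-axis median instead.  The filter is a 4th-order zero-phase
    Butterworth at ``cutoff_hz``.
    """
    x = np.asarray(trace.x, float)
    y = np.asarray(trace.y, float)
    rate = trace.rate
    dt = np.diff(np.asarray(trace.sample_times, float))
    if len(dt) and not np.allclose(dt, dt[0], atol=1e-9):
        raise ValueError("trace must be uniformly sampled")
    if isinstance(rest_position, str) and rest_position == "auto":
        rest_position = (np.median(x), np.median(y))
    d = np.hypot(x - rest_position[0], y - rest_position[1])
    b, a = sps.butter(FILTER_ORDER, cutoff_hz, fs=rate)
    return sps.filtfilt(b, a, d)


# ---------------------------------------------------------------------------
# change-point detection (mean-shift model, penalized optimal partitioning)

def estimate_noise_sd(x: np.ndarray) -> float:
    """Robust scale of the signal about its median (MAD-based).

    The low-passed displacement noise is strongly autocorrelated, so a
    first-difference estimator would badly understate the wander the
    change-point penalty must resist; the plain robust scale (movement
    occupies a minority of each trial window) is the better reference.
    """
    x = np.asarray(x, float)
    if len(x) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def default_penalty(x: np.ndarray, factor: float = 200.0) -> float:
    """BIC-style penalty per change-point: factor * sigma^2 * log n.

    The factor absorbs the autocorrelation of the 15 Hz low-passed noise
    (roughly the effective-sample-size correction at 1200 Hz sampling).
    """
    n = len(x)
    s2 = estimate_noise_sd(x) ** 2
    return max(factor * s2 * np.log(max(n, 2)), 1e-12)


def detect_changepoints(x: np.ndarray, penalty: float = None,
                        min_size: int = 1) -> list:
    """All change-points minimising SSE + penalty * (#change-points).

    Dynamic-programming optimal partitioning of the signal into
    constant-mean segments; returns the sorted change-point indices
    (segment start indices, excluding 0), possibly empty.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 2 * min_size:
        return []
    if penalty is None:
        penalty = default_penalty(x)
    S1 = np.concatenate([[0.0], np.cumsum(x)])
    S2 = np.concatenate([[0.0], np.cumsum(x * x)])
    F = np.empty(n + 1)
    F[0] = -penalty
    prev = np.zeros(n + 1, int)
    for j in range(min_size, n + 1):
        i = np.arange(0, j - min_size + 1)
        length = j - i
        seg = (S2[j] - S2[i]) - (S1[j] - S1[i]) ** 2 / length
        tot = F[i] + penalty + seg
        best = int(np.argmin(tot))
        F[j] = tot[best]
        prev[j] = i[best]
    cps = []
    j = n
    while prev[j] > 0:
        cps.append(int(prev[j]))
        j = prev[j]
    return sorted(cps)


def detect_movement(signal_window: np.ndarray, window: int = None,
                    penalty: float = None, refine: bool = True,
                    baseline_k: float = 2.0):
    """Movement onset/offset in a trial window, or None if nothing changed.

    Fits the mean-shift change-point model to the (filtered) displacement
    samples; the first detected change marks the onset and the last the
    offset.  With ``refine=True`` the boundaries are then walked outward
    to where the displacement re-enters the pre-movement baseline band
    (median + ``baseline_k`` * MAD of the samples preceding the first
    change), correcting the systematic lag a mean-shift model shows on
    smooth displacement profiles.  ``window`` optionally truncates the
    search; it must cover at least 3 samples.
    """
    x = np.asarray(signal_window, float)
    if window is not None:
        if window < 3:
            raise ValueError("window must span at least 3 samples")
        x = x[:window]
    cps = detect_changepoints(x, penalty=penalty)
    if not cps:
        return None
    onset, offset = int(cps[0]), int(cps[-1])
    if refine:
        base = x[:onset] if onset >= 10 else x
        med = np.median(base)
        mad = 1.4826 * np.median(np.abs(base - med))
        thr = med + baseline_k * max(mad, 1e-12)
        while onset > 0 and x[onset - 1] > thr:
            onset -= 1
        while offset < len(x) - 1 and x[offset + 1] > thr:
            offset += 1
    return onset, offset


# ---------------------------------------------------------------------------
# trial metrics

def trial_metrics(signal: np.ndarray, onset: int, offset: int,
                  cue_time: float, sampling_rate: float,
                  t0: float = 0.0) -> MovementTrial:
    """Kinematic metrics of one segmented movement.

    ``onset``/``offset`` are sample indices into ``signal`` whose first
    sample corresponds to time ``t0``.  Velocity is the first difference
    of the filtered displacement times the rate; acceleration the second
    difference times rate^2; means/maxima are taken as absolute values
    over [onset, offset].
    """
    if offset <= onset:
        return MovementTrial(cue_time=cue_time, valid=False)
    x = np.asarray(signal, float)
    onset_t = t0 + onset / sampling_rate
    offset_t = t0 + offset / sampling_rate
    rt = onset_t - cue_time
    if rt < 0:
        return MovementTrial(cue_time=cue_time, valid=False)
    seg = x[onset:offset + 1]
    v = np.diff(seg) * sampling_rate
    a = np.diff(seg, 2) * sampling_rate ** 2
    return MovementTrial(
        cue_time=cue_time, onset=onset_t, offset=offset_t,
        reaction_time=rt,
        mean_velocity=float(np.mean(np.abs(v))) if len(v) else np.nan,
        peak_acceleration=float(np.max(np.abs(a))) if len(a) else np.nan,
        valid=True)


def extract_trials(filtered: np.ndarray, schedule, rate: float,
                   penalty: float = None, decimate: int = 8) -> pd.DataFrame:
    """Segment every cued trial of a run and compute its metrics.

    The search window for each cue extends to the next cue or to the end
    of its movement block, whichever comes first.  The change-point
    search runs on every ``decimate``-th sample (the 15 Hz low-passed
    signal is heavily oversampled at 1200 Hz); the onset/offset
    refinement then operates at the full rate, so trial metrics keep
    full temporal resolution.  Trials with no detected change (no
    movement, or a dead joystick) are excluded but counted.
    """
    cues = np.sort(np.asarray(schedule.cue_onsets, float))
    rows = []
    for idx, cue in enumerate(cues):
        nxt = cues[idx + 1] if idx + 1 < len(cues) else np.inf
        block_end = next(o + schedule.block_duration
                         for o in schedule.move_onsets
                         if o <= cue < o + schedule.block_duration)
        end = min(nxt, block_end)
        i0 = int(round(cue * rate))
        i1 = min(int(round(end * rate)), len(filtered))
        win = filtered[i0:i1]
        xd = win[::decimate]
        pen = penalty
        if pen is None:
            # the autocorrelation correction in the default factor scales
            # with the sampling rate
            pen = default_penalty(xd, factor=200.0 / decimate)
        cps = detect_changepoints(xd, penalty=pen)
        if not cps:
            rows.append(MovementTrial(cue_time=cue, valid=False).__dict__)
            continue
        onset, offset = cps[0] * decimate, cps[-1] * decimate
        base = win[:onset] if onset >= 10 else win
        med = np.median(base)
        mad = 1.4826 * np.median(np.abs(base - med))
        thr = med + 2.0 * max(mad, 1e-12)
        while onset > 0 and win[onset - 1] > thr:
            onset -= 1
        while offset < len(win) - 1 and win[offset + 1] > thr:
            offset += 1
        trial = trial_metrics(win, onset, offset, cue_time=cue,
                              sampling_rate=rate, t0=cue)
        rows.append(trial.__dict__)
    return pd.DataFrame(rows)


def summarize_run(trials: pd.DataFrame, subject: str, polarity: str,
                  time: str) -> RunSummary:
    valid = trials[trials.valid.astype(bool)]
    return RunSummary(
        subject=subject, polarity=polarity, time=time,
        reaction_time=float(valid.reaction_time.mean()),
        mean_velocity=float(valid.mean_velocity.mean()),
        peak_acceleration=float(valid.peak_acceleration.mean()),
        n_valid=int(len(valid)), n_excluded=int(len(trials) - len(valid)))


# ---------------------------------------------------------------------------
# group statistics

def rm_anova(summaries, metrics=("reaction_time", "mean_velocity",
                                 "peak_acceleration")) -> dict:
    """2 (time) x 3 (polarity) repeated-measures ANOVA per metric.

    ``summaries`` is a DataFrame (or list of RunSummary) with columns
    subject, polarity, time and the metric columns.  Returns, per metric,
    F / p / partial eta squared for the time and polarity main effects
    and their interaction.
    """
    import pingouin as pg

    if not isinstance(summaries, pd.DataFrame):
        summaries = pd.DataFrame([s.__dict__ for s in summaries])
    cells = summaries.groupby(["subject", "polarity", "time"]).size()
    expected = summaries.polarity.nunique() * summaries.time.nunique()
    per_subject = cells.groupby("subject").size()
    bad = per_subject[per_subject != expected]
    if len(bad):
        sub = bad.index[0]
        have = set(cells.loc[sub].index)
        alln = {(p, t) for p in summaries.polarity.unique()
                for t in summaries.time.unique()}
        missing = sorted(alln - have)
        raise ValueError(f"subject {sub!r} is missing cell(s) {missing}")
    out = {}
    for metric in metrics:
        aov = pg.rm_anova(data=summaries, dv=metric,
                          within=["time", "polarity"], subject="subject",
                          detailed=True, effsize="np2")
        res = {}
        for _, row in aov.iterrows():
            name = {"time": "time", "polarity": "polarity",
                    "time * polarity": "interaction"}.get(row["Source"])
            if name is None:
                continue
            F = float(row["F"])
            p = float(row["p_unc"])
            np2 = float(row["np2"])
            if not np.isfinite(F) and abs(float(row["SS"])) < 1e-12:
                # no within-subject variance for this effect
                F, p, np2 = 0.0, 1.0, 0.0
            res[name] = {"F": F, "p": p, "partial_eta_sq": np2}
        out[metric] = res
    return out


def mcnemar(table) -> dict:
    """Exact (binomial) two-sided McNemar test on the discordant pairs."""
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    if isinstance(table, BlindingTable):
        counts = table.counts
    else:
        counts = np.asarray(table)
        BlindingTable(counts)  # validation
    b, c = int(counts[0, 1]), int(counts[1, 0])
    if b + c == 0:
        return {"p": 1.0, "b": b, "c": c,
                "note": "no discordant pairs; test undefined, p set to 1"}
    res = sm_mcnemar(counts, exact=True)
    return {"p": float(res.pvalue), "b": b, "c": c, "note": ""}
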