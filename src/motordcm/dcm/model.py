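"""Containers for the bilinear one-state DCM of the 4-node motor network.

The network comprises left primary motor cortex (M1), left supplementary
motor area (SMA), left thalamus (THA) and right cerebellum (CB).  Neural
dynamics follow the bilinear form

    dx/dt = J(u) x + C u_drive,

with off-diagonal couplings J_ij = A_ij (Hz) and self-connections
parameterised as log-scalings of a -0.5 Hz reference,

    J_ii = -0.5 * exp(a_self_i + u_mod * b_self_i),

so that self-connections are inhibitory for every finite parameter value.
The task enters twice: a modulatory boxcar over move blocks (mean-centred)
acting on the self-connections, and a brief driving "ping" at each move
block onset with per-region gains C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGIONS = ("M1", "SMA", "THA", "CB")
N_REGIONS = len(REGIONS)

SELF_SCALE = -0.5  # Hz; reference self-coupling scaled by exp(a_self)


def region_index(name: str) -> int:
    try:
        return REGIONS.index(name)
    except ValueError:
        raise KeyError(f"unknown region {name!r}; expected one of {REGIONS}") from None


@dataclass(frozen=True)
class HemodynamicConstants:
    """Balloon-model and BOLD observation constants (canonical values)."""

    kappa: float = 0.64   # 1/s, vasodilatory signal decay
    gamma: float = 0.32   # 1/s, flow feedback
    tau: float = 2.0      # s, mean transit time
    alpha: float = 0.32   # Grubb stiffness exponent
    E0: float = 0.4       # resting oxygen extraction fraction
    V0: float = 0.04      # resting venous blood volume fraction
    k1: float = field(default=None)
    k2: float = 2.0
    k3: float = field(default=None)

    def __post_init__(self):
        # classic observation coefficients tied to E0
        if self.k1 is None:
            object.__setattr__(self, "k1", 7.0 * self.E0)
        if self.k3 is None:
            object.__setattr__(self, "k3", 2.0 * self.E0 - 0.2)
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("kappa", "gamma", "tau", "E0", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ConnectivityModel:
    """A/B/C parameters plus per-region hemodynamic log-scalings.

    ``a_off`` is the 4x4 between-region coupling in Hz (diagonal ignored,
    kept zero); ``a_self``/``b_self`` are unitless log-scalings of the
    -0.5 Hz self-connection (``b_self`` is the task-modulatory effect);
    ``c`` holds driving-input gains per region; ``ln_kappa``/``ln_tau``
    are log-scalings of the hemodynamic decay and transit constants.
    """

    a_off: np.ndarray
    a_self: np.ndarray
    b_self: np.ndarray
    c: np.ndarray
    ln_kappa: np.ndarray = None
    ln_tau: np.ndarray = None

    def __post_init__(self):
        self.a_off = np.array(self.a_off, float)
        np.fill_diagonal(self.a_off, 0.0)
        self.a_self = np.array(self.a_self, float)
        self.b_self = np.array(self.b_self, float)
        self.c = np.array(self.c, float)
        n = self.a_off.shape[0]
        if self.a_off.shape != (n, n):
            raise ValueError("a_off must be square")
        for v in (self.a_self, self.b_self, self.c):
            if v.shape != (n,):
                raise ValueError("parameter vectors must have one entry per region")
        if self.ln_kappa is None:
            self.ln_kappa = np.zeros(n)
        if self.ln_tau is None:
            self.ln_tau = np.zeros(n)
        self.ln_kappa = np.array(self.ln_kappa, float)
        self.ln_tau = np.array(self.ln_tau, float)
        arrs = (self.a_off, self.a_self, self.b_self, self.c,
                self.ln_kappa, self.ln_tau)
        if not all(np.all(np.isfinite(a)) for a in arrs):
            raise ValueError("non-finite connectivity parameter")

    @property
    def n_regions(self) -> int:
        return self.a_off.shape[0]

    def jacobian(self, u_mod: float = 0.0) -> np.ndarray:
        """Effective neural Jacobian J(u) at modulatory input ``u_mod``."""
        J = self.a_off.copy()
        np.fill_diagonal(J, SELF_SCALE * np.exp(self.a_self + u_mod * self.b_self))
        return J

    def is_stable(self, u_mod: float = 0.0) -> bool:
        return bool(np.all(np.linalg.eigvals(self.jacobian(u_mod)).real < 0))

    def copy(self) -> "ConnectivityModel":
        return ConnectivityModel(self.a_off.copy(), self.a_self.copy(),
                                 self.b_self.copy(), self.c.copy(),
                                 self.ln_kappa.copy(), self.ln_tau.copy())

    @classmethod
    def zeros(cls, n: int = N_REGIONS) -> "ConnectivityModel":
        return cls(np.zeros((n, n)), np.zeros(n), np.zeros(n), np.zeros(n))

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "a_off": self.a_off.tolist(),
            "a_self": self.a_self.tolist(),
            "b_self": self.b_self.tolist(),
            "c": self.c.tolist(),
            "ln_kappa": self.ln_kappa.tolist(),
            "ln_tau": self.ln_tau.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConnectivityModel":
        return cls(**{k: np.asarray(v, float) for k, v in d.items()})


# ---------------------------------------------------------------------------
# free-parameter structure and priors


@dataclass
class DCMStructure:
    """Boolean masks marking which DCM parameters are free to vary.

    The default ("full") structure frees every between-region connection,
    every self log-scaling, every modulatory self effect, driving gains to
    M1 and SMA, and the per-region hemodynamic log-scalings.
    """

    a_off: np.ndarray
    a_self: np.ndarray
    b_self: np.ndarray
    c: np.ndarray
    ln_kappa: np.ndarray
    ln_tau: np.ndarray

    _BLOCKS = ("a_off", "a_self", "b_self", "c", "ln_kappa", "ln_tau")

    def __post_init__(self):
        for name in self._BLOCKS:
            setattr(self, name, np.asarray(getattr(self, name), bool))
        np.fill_diagonal(self.a_off, False)

    @classmethod
    def full(cls, n: int = N_REGIONS, driving_regions=("M1", "SMA"),
             free_hemo: bool = True) -> "DCMStructure":
        a_off = ~np.eye(n, dtype=bool)
        c = np.zeros(n, bool)
        for r in driving_regions:
            c[region_index(r) if isinstance(r, str) else r] = True
        hemo = np.full(n, free_hemo)
        return cls(a_off, np.ones(n, bool), np.ones(n, bool), c,
                   hemo.copy(), hemo.copy())

    @property
    def n_free(self) -> int:
        return int(sum(getattr(self, b).sum() for b in self._BLOCKS))

    def labels(self) -> list:
        """Human-readable name per free parameter, in pack order."""
        out = []
        n = self.a_off.shape[0]
        for i in range(n):
            for j in range(n):
                if self.a_off[i, j]:
                    out.append(f"A:{REGIONS[j]}->{REGIONS[i]}")
        for name, tag in (("a_self", "A"), ("b_self", "B"), ("c", "C"),
                          ("ln_kappa", "H:kappa"), ("ln_tau", "H:tau")):
            mask = getattr(self, name)
            for i in range(n):
                if mask[i]:
                    suffix = "(self)" if name in ("a_self", "b_self") else ""
                    out.append(f"{tag}:{REGIONS[i]}{suffix}")
        return out

    def pack(self, model: ConnectivityModel) -> np.ndarray:
        """Extract the free-parameter vector from ``model``."""
        return np.concatenate([
            model.a_off[self.a_off],
            model.a_self[self.a_self],
            model.b_self[self.b_self],
            model.c[self.c],
            model.ln_kappa[self.ln_kappa],
            model.ln_tau[self.ln_tau],
        ])

    def unpack(self, theta: np.ndarray,
               template: ConnectivityModel) -> ConnectivityModel:
        """Insert free parameters into a copy of ``template``."""
        theta = np.asarray(theta, float)
        if theta.shape != (self.n_free,):
            raise ValueError(f"theta must have length {self.n_free}")
        m = template.copy()
        i = 0
        for name in self._BLOCKS:
            mask = getattr(self, name)
            k = int(mask.sum())
            getattr(m, name)[mask] = theta[i:i + k]
            i += k
        return m

    def block_slices(self) -> dict:
        out, i = {}, 0
        for name in self._BLOCKS:
            k = int(getattr(self, name).sum())
            out[name] = slice(i, i + k)
            i += k
        return out


#: default prior variances per parameter block (package defaults,
#: configurable through PriorSpec)
DEFAULT_PRIOR_VARIANCES = {
    "a_off": 1.0 / 16.0,
    "a_self": 1.0 / 4.0,
    "b_self": 1.0 / 4.0,
    "c": 1.0,
    "ln_kappa": 1.0 / 256.0,
    "ln_tau": 1.0 / 256.0,
}


@dataclass
class PriorSpec:
    """Diagonal Gaussian prior over the free-parameter vector."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.variance = np.asarray(self.variance, float)
        if self.mean.shape != self.variance.shape:
            raise ValueError("prior mean/variance shape mismatch")
        if np.any(self.variance < 0):
            raise ValueError("prior variances must be non-negative")

    @property
    def covariance(self) -> np.ndarray:
        return np.diag(self.variance)

    @classmethod
    def default(cls, structure: DCMStructure,
                variances: dict = None) -> "PriorSpec":
        variances = {**DEFAULT_PRIOR_VARIANCES, **(variances or {})}
        var = np.concatenate([
            np.full(int(getattr(structure, b).sum()), variances[b])
            for b in structure._BLOCKS
        ])
        return cls(np.zeros_like(var), var)


@dataclass
class InputSet:
    """Driving and modulatory input functions on a fine time grid."""

    t: np.ndarray         # fine-grid times, s
    driving: np.ndarray   # unit pings at move-block onsets
    modulatory: np.ndarray  # mean-centred move-block boxcar
    dt: float

    @property
    def duration(self) -> float:
        return float(self.t[-1] + self.dt)


def build_inputs(schedule, dt: float, duration: float = None,
                 ping_duration: float = 0.5,
                 mean_centre: bool = True) -> InputSet:
    """Construct the DCM input functions from a task schedule.

    The driving input is a unit-height pulse of ``ping_duration`` seconds
    at each move-block onset; the modulatory input is the move-block
    boxcar, mean-centred over the run so its bilinear effect is expressed
    relative to the session average.
    """
    if duration is None:
        duration = schedule.total_duration
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    driving = np.zeros(n)
    boxcar = np.zeros(n)
    for onset in schedule.move_onsets:
        driving[(t >= onset) & (t < onset + ping_duration)] = 1.0
        boxcar[(t >= onset) & (t < onset + schedule.block_duration)] = 1.0
    modulatory = boxcar - boxcar.mean() if mean_centre else boxcar
    return InputSet(t=t, driving=driving, modulatory=modulatory, dt=dt)
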