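"""Forward model: bilinear neural dynamics, balloon hemodynamics, BOLD.

The generative path is x (neural) -> s, f (vasodilatory signal, inflow)
-> v, q (venous volume, deoxyhemoglobin) -> y (BOLD).  Integration uses a
fixed-step 4th-order Runge-Kutta scheme on a fine grid (default TR/16)
with inputs held piecewise-constant over each fine step; BOLD is sampled
at volume acquisition times k*TR.  A numba-compiled batched integrator is
the fast path (used for numerical Jacobians during inversion); a plain
NumPy implementation of the same scheme serves as the reference.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model import (ConnectivityModel, HemodynamicConstants, InputSet,
                    SELF_SCALE)

__all__ = ["neural_derivative", "hemodynamic_step", "bold_signal",
           "forward_predict", "predict_batch"]


def neural_derivative(x, u_driving, u_mod, model: ConnectivityModel):
    """dx/dt of the bilinear neural state equation.

    ``u_driving`` may be scalar (shared driving input, gains in model.c).
    """
    x = np.asarray(x, float)
    J = model.jacobian(u_mod)
    return J @ x + model.c * u_driving


def hemodynamic_step(state: dict, x, constants: HemodynamicConstants) -> dict:
    """Balloon-model state derivatives for states s, f, v, q.

    ``state`` maps names to per-region arrays; returns the same structure
    of time derivatives.  Raises if flow, volume or deoxyhemoglobin are
    non-positive (a sign the integration step is too large).
    """
    s = np.asarray(state["s"], float)
    f = np.asarray(state["f"], float)
    v = np.asarray(state["v"], float)
    q = np.asarray(state["q"], float)
    if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
        raise FloatingPointError(
            "non-positive hemodynamic state (f, v or q); reduce the step size")
    c = constants
    E = 1.0 - (1.0 - c.E0) ** (1.0 / f)  # oxygen extraction at flow f
    fout = v ** (1.0 / c.alpha)
    return {
        "s": np.asarray(x, float) - c.kappa * s - c.gamma * (f - 1.0),
        "f": s,
        "v": (f - fout) / c.tau,
        "q": (f * E / c.E0 - fout * q / v) / c.tau,
    }


def bold_signal(v, q, constants: HemodynamicConstants):
    """BOLD observation equation y = V0 (k1(1-q) + k2(1-q/v) + k3(1-v))."""
    v = np.asarray(v, float)
    q = np.asarray(q, float)
    if np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("v and q must be positive")
    c = constants
    return c.V0 * (c.k1 * (1.0 - q) + c.k2 * (1.0 - q / v) + c.k3 * (1.0 - v))


# ---------------------------------------------------------------------------
# batched fixed-step RK4 integrator (numba fast path)

@njit(cache=True)
def _rk4_batch(A, a_self, b_self, C, kappa, tau,
               gamma, alpha, E0, V0, k1, k2, k3,
               ud, um, dt, sample_idx, out):
    B, R = a_self.shape
    T = ud.shape[0]
    x = np.zeros((B, R))
    s = np.zeros((B, R))
    f = np.ones((B, R))
    v = np.ones((B, R))
    q = np.ones((B, R))
    dxk = np.empty((4, B, R))
    dsk = np.empty((4, B, R))
    dfk = np.empty((4, B, R))
    dvk = np.empty((4, B, R))
    dqk = np.empty((4, B, R))
    n_samp = sample_idx.shape[0]
    samp = 0
    status = 0
    for it in range(T):
        while samp < n_samp and sample_idx[samp] == it:
            for b in range(B):
                for r in range(R):
                    out[b, samp, r] = V0 * (k1 * (1.0 - q[b, r])
                                            + k2 * (1.0 - q[b, r] / v[b, r])
                                            + k3 * (1.0 - v[b, r]))
            samp += 1
        u_d = ud[it]
        u_m = um[it]
        # RK4 substeps with inputs frozen over the fine step
        for k in range(4):
            if k == 0:
                w = 0.0
            elif k == 3:
                w = 1.0
            else:
                w = 0.5
            for b in range(B):
                for r in range(R):
                    xb = x[b, r] + w * dt * dxk[k - 1, b, r] if k > 0 else x[b, r]
                    sb = s[b, r] + w * dt * dsk[k - 1, b, r] if k > 0 else s[b, r]
                    fb = f[b, r] + w * dt * dfk[k - 1, b, r] if k > 0 else f[b, r]
                    vb = v[b, r] + w * dt * dvk[k - 1, b, r] if k > 0 else v[b, r]
                    qb = q[b, r] + w * dt * dqk[k - 1, b, r] if k > 0 else q[b, r]
                    if fb <= 1e-6 or vb <= 1e-6 or qb <= 1e-6:
                        status = 1
                        fb = max(fb, 1e-6)
                        vb = max(vb, 1e-6)
                        qb = max(qb, 1e-6)
                    # neural derivative
                    acc = 0.0
                    for j in range(R):
                        if j != r:
                            xj = x[b, j] + w * dt * dxk[k - 1, b, j] if k > 0 else x[b, j]
                            acc += A[b, r, j] * xj
                    acc += SELF_SCALE * np.exp(a_self[b, r] + u_m * b_self[b, r]) * xb
                    acc += C[b, r] * u_d
                    dxk[k, b, r] = acc
                    # hemodynamics
                    E = 1.0 - (1.0 - E0) ** (1.0 / fb)
                    fout = vb ** (1.0 / alpha)
                    dsk[k, b, r] = xb - kappa[b, r] * sb - gamma * (fb - 1.0)
                    dfk[k, b, r] = sb
                    dvk[k, b, r] = (fb - fout) / tau[b, r]
                    dqk[k, b, r] = (fb * E / E0 - fout * qb / vb) / tau[b, r]
        for b in range(B):
            for r in range(R):
                x[b, r] += dt / 6.0 * (dxk[0, b, r] + 2 * dxk[1, b, r]
                                       + 2 * dxk[2, b, r] + dxk[3, b, r])
                s[b, r] += dt / 6.0 * (dsk[0, b, r] + 2 * dsk[1, b, r]
                                       + 2 * dsk[2, b, r] + dsk[3, b, r])
                f[b, r] += dt / 6.0 * (dfk[0, b, r] + 2 * dfk[1, b, r]
                                       + 2 * dfk[2, b, r] + dfk[3, b, r])
                v[b, r] += dt / 6.0 * (dvk[0, b, r] + 2 * dvk[1, b, r]
                                       + 2 * dvk[2, b, r] + dvk[3, b, r])
                q[b, r] += dt / 6.0 * (dqk[0, b, r] + 2 * dqk[1, b, r]
                                       + 2 * dqk[2, b, r] + dqk[3, b, r])
    # samples falling exactly at the end of the grid
    while samp < n_samp:
        for b in range(B):
            for r in range(R):
                out[b, samp, r] = V0 * (k1 * (1.0 - q[b, r])
                                        + k2 * (1.0 - q[b, r] / v[b, r])
                                        + k3 * (1.0 - v[b, r]))
        samp += 1
    return status


def predict_batch(models, constants: HemodynamicConstants, inputs: InputSet,
                  TR: float, n_volumes: int) -> np.ndarray:
    """Fast path: predicted BOLD for a batch of models, shape (B, T, R)."""
    B = len(models)
    R = models[0].n_regions
    A = np.stack([m.a_off for m in models])
    a_self = np.stack([m.a_self for m in models])
    b_self = np.stack([m.b_self for m in models])
    C = np.stack([m.c for m in models])
    kappa = constants.kappa * np.exp(np.stack([m.ln_kappa for m in models]))
    tau = constants.tau * np.exp(np.stack([m.ln_tau for m in models]))
    sample_idx = _sample_indices(inputs, TR, n_volumes)
    out = np.zeros((B, n_volumes, R))
    status = _rk4_batch(A, a_self, b_self, C, kappa, tau,
                        constants.gamma, constants.alpha, constants.E0,
                        constants.V0, constants.k1, constants.k2, constants.k3,
                        inputs.driving, inputs.modulatory, inputs.dt,
                        sample_idx, out)
    if status != 0 or not np.all(np.isfinite(out)):
        raise FloatingPointError(
            "hemodynamic integration left the positive domain; the neural "
            "parameters are likely unstable")
    return out


def _sample_indices(inputs: InputSet, TR: float, n_volumes: int) -> np.ndarray:
    idx = np.round(np.arange(n_volumes) * TR / inputs.dt).astype(np.int64)
    if idx[-1] > len(inputs.t):
        raise ValueError("inputs do not span the acquisition window")
    return idx


def _reference_predict(model: ConnectivityModel,
                       constants: HemodynamicConstants, inputs: InputSet,
                       TR: float, n_volumes: int) -> np.ndarray:
    """Pure-NumPy RK4 of the identical system (dense oracle for tests)."""
    R = model.n_regions
    kappa = constants.kappa * np.exp(model.ln_kappa)
    tau = constants.tau * np.exp(model.ln_tau)
    local = HemodynamicConstants(kappa=1.0, gamma=constants.gamma, tau=1.0,
                                 alpha=constants.alpha, E0=constants.E0,
                                 V0=constants.V0, k1=constants.k1,
                                 k2=constants.k2, k3=constants.k3)

    def deriv(state, u_d, u_m):
        x, s, f, v, q = state
        dx = neural_derivative(x, u_d, u_m, model)
        hd = hemodynamic_step({"s": s, "f": f, "v": v, "q": q}, x, local)
        # per-region kappa/tau applied outside the shared-constant helper
        ds = x - kappa * s - constants.gamma * (f - 1.0)
        dv = hd["v"] / tau
        dq = hd["q"] / tau
        return np.array([dx, ds, hd["f"], dv, dq])

    state = np.zeros((5, R))
    state[2:] = 1.0  # f, v, q rest at 1
    dt = inputs.dt
    sample_idx = _sample_indices(inputs, TR, n_volumes)
    y = np.zeros((n_volumes, R))
    samp = 0
    for it in range(len(inputs.t) + 1):
        while samp < n_volumes and sample_idx[samp] == it:
            y[samp] = bold_signal(state[3], state[4], constants)
            samp += 1
        if it == len(inputs.t):
            break
        u_d, u_m = inputs.driving[it], inputs.modulatory[it]
        k1 = deriv(state, u_d, u_m)
        k2 = deriv(state + 0.5 * dt * k1, u_d, u_m)
        k3 = deriv(state + 0.5 * dt * k2, u_d, u_m)
        k4 = deriv(state + dt * k3, u_d, u_m)
        state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


def forward_predict(model: ConnectivityModel, constants: HemodynamicConstants,
                    inputs: InputSet, TR: float, n_volumes: int,
                    engine: str = "fast") -> np.ndarray:
    """Predicted BOLD timeseries, shape (n_volumes, n_regions).

    ``engine='fast'`` uses the compiled batched integrator;
    ``engine='reference'`` runs the plain-NumPy implementation of the same
    fixed-step scheme (slow; intended for validation).
    """
    if not model.is_stable(0.0):
        raise ValueError("unstable model: effective Jacobian at rest has a "
                         "non-negative real eigenvalue")
    if engine == "fast":
        return predict_batch([model], constants, inputs, TR, n_volumes)[0]
    if engine == "reference":
        return _reference_predict(model, constants, inputs, TR, n_volumes)
    raise ValueError(f"unknown engine {engine!r}")
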