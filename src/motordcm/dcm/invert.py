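"""Variational-Laplace inversion of the bilinear DCM.

The scheme ascends the Gaussian variational free energy

    F = E_q[log p(y|theta)] - KL(q(theta) || p(theta)),

with a fixed-form Gaussian posterior q = N(mu, Sigma), region-wise noise
log-precisions updated by exact M-steps, and Gauss-Newton updates of mu
with Levenberg-style trust-region damping.  A step is accepted only if it
increases F, so F is non-decreasing over accepted iterations by
construction.  Nuisance drifts (constant plus discrete-cosine high-pass
set) are projected out of both data and predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import (ConnectivityModel, DCMStructure, HemodynamicConstants,
                    InputSet, PriorSpec)
from .forward import predict_batch

__all__ = ["PosteriorEstimate", "free_energy", "invert", "confound_basis"]

LOG2PI = np.log(2.0 * np.pi)


def confound_basis(n_volumes: int, TR: float, cutoff: float = 80.0) -> np.ndarray:
    """Constant plus discrete-cosine drift regressors (period > ``cutoff``).

    Column k (k >= 1) is cos(pi k (t + 1/2) / N) with period 2 N TR / k;
    the number of drift columns is floor(2 N TR / cutoff) - 1, matching
    the standard high-pass parameterisation.
    """
    n_drift = max(int(np.floor(2.0 * n_volumes * TR / cutoff)) - 1, 0)
    t = (np.arange(n_volumes) + 0.5) / n_volumes
    cols = [np.ones(n_volumes)]
    for k in range(1, n_drift + 1):
        cols.append(np.sqrt(2.0) * np.cos(np.pi * k * t))
    return np.column_stack(cols)


def _residual_projector(X0: np.ndarray) -> tuple:
    """Residual-forming matrix of the confound space and its rank."""
    if X0 is None or X0.size == 0:
        return None, 0
    Q, _ = np.linalg.qr(X0)
    rank = np.linalg.matrix_rank(X0)
    return Q[:, :rank], rank


def _project(R0_Q, Y):
    if R0_Q is None:
        return Y
    return Y - R0_Q @ (R0_Q.T @ Y)


@dataclass
class PosteriorEstimate:
    """Gaussian posterior over the free DCM parameters.

    ``mean``/``cov`` are over the packed free-parameter vector (ordering
    given by ``labels``); ``log_precisions`` hold the per-region noise
    log-precision point estimates; ``free_energy`` is the final bound in
    nats and ``f_trace`` the accepted-iteration history.
    """

    mean: np.ndarray
    cov: np.ndarray
    log_precisions: np.ndarray
    free_energy: float
    f_trace: list = field(default_factory=list)
    converged: bool = True
    labels: list = None

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.cov = np.asarray(self.cov, float)
        if not np.isfinite(self.free_energy):
            raise ValueError("free energy must be finite")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("posterior covariance must be symmetric")
        eig = np.linalg.eigvalsh(self.cov)
        if eig.min() < -1e-8 * max(eig.max(), 1.0):
            raise ValueError("posterior covariance must be positive semi-definite")

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        from scipy import stats
        z = stats.norm.ppf(0.5 + level / 2.0)
        sd = np.sqrt(np.diag(self.cov))
        return np.column_stack([self.mean - z * sd, self.mean + z * sd])

    def to_dict(self) -> dict:
        tri = self.cov[np.tril_indices(len(self.mean))]
        return {
            "mean": self.mean.tolist(),
            "cov_lower_triangle": tri.tolist(),
            "log_precisions": np.asarray(self.log_precisions).tolist(),
            "free_energy": float(self.free_energy),
            "converged": bool(self.converged),
            "labels": list(self.labels) if self.labels else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PosteriorEstimate":
        mean = np.asarray(d["mean"], float)
        k = len(mean)
        cov = np.zeros((k, k))
        cov[np.tril_indices(k)] = d["cov_lower_triangle"]
        cov = cov + np.tril(cov, -1).T
        return cls(mean=mean, cov=cov,
                   log_precisions=np.asarray(d["log_precisions"], float),
                   free_energy=d["free_energy"], converged=d["converged"],
                   labels=d.get("labels"))


def free_energy(data: np.ndarray, prediction: np.ndarray,
                mu: np.ndarray, Sigma: np.ndarray, priors: PriorSpec,
                log_precisions: np.ndarray, jacobian: np.ndarray = None,
                confounds: np.ndarray = None) -> float:
    """Gaussian variational free energy of a posterior candidate, in nats.

    Parameters
    ----------
    data, prediction : (T, R) observed and predicted region timeseries.
    mu, Sigma : posterior mean and covariance over free parameters.
    priors : diagonal Gaussian prior.
    log_precisions : (R,) noise log-precision per region.
    jacobian : optional (R, T, k) prediction derivatives; contributes the
        expected-curvature term tr(J Sigma J').  Omitted -> treated as 0.
    confounds : optional (T, K) nuisance basis projected from both sides.
    """
    data = np.atleast_2d(np.asarray(data, float))
    prediction = np.atleast_2d(np.asarray(prediction, float))
    T, R = data.shape
    Q, rank0 = _residual_projector(confounds)
    n_eff = T - rank0
    e = _project(Q, data - prediction)
    lam = np.exp(np.asarray(log_precisions, float))

    acc = 0.0
    for r in range(R):
        sse = float(e[:, r] @ e[:, r])
        if jacobian is not None:
            Jr = jacobian[r]
            sse += float(np.trace(Jr @ Sigma @ Jr.T))
        acc += -0.5 * lam[r] * sse + 0.5 * n_eff * (log_precisions[r] - LOG2PI)

    pC = priors.variance
    if np.any(pC <= 0):
        raise np.linalg.LinAlgError("singular prior covariance")
    d = np.asarray(mu, float) - priors.mean
    sign, logdet_S = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular posterior covariance")
    k = len(d)
    kl = 0.5 * (np.sum(np.diag(Sigma) / pC) + np.sum(d * d / pC) - k
                + np.sum(np.log(pC)) - logdet_S)
    return float(acc - kl)


def invert(data: np.ndarray, structure: DCMStructure, priors: PriorSpec,
           inputs: InputSet, TR: float,
           constants: HemodynamicConstants = None,
           template: ConnectivityModel = None,
           confounds="auto", highpass_cutoff: float = 80.0,
           max_iter: int = 64, tol: float = 1e-2,
           fd_step_scale: float = 1e-3) -> PosteriorEstimate:
    """Invert the DCM on a (T, R) timeseries by variational Laplace.

    ``confounds='auto'`` builds the constant + cosine high-pass basis
    (80 s cutoff by default); pass an explicit (T, K) array or None.
    Convergence: |dF| < ``tol`` nats on 3 consecutive accepted steps.
    Non-convergence raises no error: the best estimate is returned with
    ``converged=False`` and a warning.
    """
    Y = np.asarray(data, float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("data must be finite")
    T, R = Y.shape
    if R < 2:
        raise ValueError("at least 2 regions are required")
    if constants is None:
        constants = HemodynamicConstants()
    if template is None:
        template = ConnectivityModel.zeros(R)
    if isinstance(confounds, str) and confounds == "auto":
        confounds = confound_basis(T, TR, highpass_cutoff)
    Q0, rank0 = _residual_projector(confounds)
    n_eff = T - rank0
    Yp = _project(Q0, Y)

    k = structure.n_free
    pE, pC = priors.mean.copy(), priors.variance.copy()
    if pE.shape != (k,):
        raise ValueError("prior size does not match the number of free parameters")
    if np.any(pC <= 0):
        raise ValueError("free parameters require positive prior variance")
    Pi0 = np.diag(1.0 / pC)

    mu = pE.copy()
    h = np.log(np.full(R, 1.0) / np.maximum(Yp.var(axis=0), 1e-12))
    delta = fd_step_scale * np.sqrt(pC)

    def predict_and_jacobian(theta):
        models = [structure.unpack(theta, template)]
        for j in range(k):
            tp = theta.copy()
            tp[j] += delta[j]
            models.append(structure.unpack(tp, template))
        preds = predict_batch(models, constants, inputs, TR, len(Y))
        g = preds[0]
        J = np.empty((R, T, k))
        for j in range(k):
            J[:, :, j] = ((preds[j + 1] - g) / delta[j]).T
        return _project(Q0, g), np.stack([_project(Q0, J[r]) for r in range(R)])

    def posterior_cov(J, lam):
        H = Pi0.copy()
        for r in range(R):
            H += lam[r] * (J[r].T @ J[r])
        H = 0.5 * (H + H.T)
        return np.linalg.inv(H), H

    # floor on the residual power keeps the precisions finite on (near-)
    # noiseless data, bounding lambda at ~1e8 x the inverse signal power
    sse_floor = n_eff * max(float(Yp.var()), 1e-12) * 1e-8

    def update_h(e, J, lam):
        # exact M-step for the noise precisions, iterated with Sigma
        for _ in range(4):
            Sigma, _H = posterior_cov(J, lam)
            for r in range(R):
                sse = e[:, r] @ e[:, r] + np.trace(J[r] @ Sigma @ J[r].T)
                lam[r] = n_eff / max(sse, sse_floor)
        return lam, Sigma

    g, J = predict_and_jacobian(mu)
    e = Yp - g
    lam = np.exp(h)
    lam, Sigma = update_h(e, J, lam)
    h = np.log(lam)
    F = _fe(e, J, Sigma, mu, pE, pC, h, n_eff)
    f_trace = [F]

    nu = 1.0 / 128.0
    stall = 0
    for _ in range(max_iter):
        grad = -Pi0 @ (mu - pE)
        H = Pi0.copy()
        for r in range(R):
            grad += lam[r] * (J[r].T @ e[:, r])
            H += lam[r] * (J[r].T @ J[r])
        scale = np.mean(np.diag(H))
        accepted = False
        for _retry in range(8):
            try:
                step = np.linalg.solve(H + nu * scale * np.eye(k), grad)
            except np.linalg.LinAlgError:
                nu *= 8.0
                continue
            mu_new = mu + step
            try:
                g_new, J_new = predict_and_jacobian(mu_new)
            except (FloatingPointError, ValueError):
                nu *= 8.0
                continue
            e_new = Yp - g_new
            lam_new = lam.copy()
            lam_new, Sigma_new = update_h(e_new, J_new, lam_new)
            h_new = np.log(lam_new)
            F_new = _fe(e_new, J_new, Sigma_new, mu_new, pE, pC, h_new, n_eff)
            if np.isfinite(F_new) and F_new > F:
                accepted = True
                break
            nu *= 8.0
        if not accepted:
            break
        dF = F_new - F
        mu, g, J, e, lam, h, Sigma, F = (mu_new, g_new, J_new, e_new,
                                         lam_new, h_new, Sigma_new, F_new)
        f_trace.append(F)
        nu = max(nu / 2.0, 1.0 / 128.0)
        stall = stall + 1 if abs(dF) < tol else 0
        if stall >= 3:
            break
    else:
        warnings.warn("DCM inversion did not converge within max_iter; "
                      "returning the best estimate so far", RuntimeWarning)
        return PosteriorEstimate(mu, Sigma, h, F, f_trace, converged=False,
                                 labels=structure.labels())

    return PosteriorEstimate(mu, Sigma, h, F, f_trace, converged=True,
                             labels=structure.labels())


def _fe(e, J, Sigma, mu, pE, pC, h, n_eff) -> float:
    """Free energy from projected residuals (internal fast form)."""
    R = e.shape[1]
    lam = np.exp(h)
    acc = 0.0
    for r in range(R):
        sse = e[:, r] @ e[:, r] + np.trace(J[r] @ Sigma @ J[r].T)
        acc += -0.5 * lam[r] * sse + 0.5 * n_eff * (h[r] - LOG2PI)
    d = mu - pE
    sign, logdet_S = np.linalg.slogdet(Sigma)
    k = len(d)
    kl = 0.5 * (np.sum(np.diag(Sigma) / pC) + np.sum(d * d / pC) - k
                + np.sum(np.log(pC)) - logdet_S)
    return float(acc - kl)
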