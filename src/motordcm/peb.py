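"""Hierarchical empirical-Bayes modelling of DCM parameters.

Subject- (or session-) level posteriors are treated as noisy observations
of a group-level linear model,

    theta_i = X_i beta + eps_i,      eps_i ~ N(0, Sigma_b),

with a single between-level random-effects component Sigma_b =
exp(-gamma) * Q and a Gaussian hyperprior on the log-precision scale
gamma.  Because every level is linear-Gaussian, the group posterior over
beta and the model evidence are available in closed form given gamma;
gamma itself is optimised by maximising the evidence (empirical Bayes).

Bayesian model reduction (BMR) computes the evidence change of switching
parameters off (near-zero-variance null priors) analytically from the
full posterior, and Bayesian model averaging (BMA) averages parameters
over the candidate model set weighted by evidence.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .dcm.invert import PosteriorEstimate

__all__ = [
    "build_interaction_design", "build_group_design", "validate_design",
    "PEBModel", "BMAResult", "fit_peb", "reduce_model", "search_and_average",
    "bayesian_model_reduction",
]

CONTRASTS = {
    "anodal_vs_sham": ("anodal", "sham"),
    "anodal_vs_cathodal": ("anodal", "cathodal"),
    "cathodal_vs_sham": ("cathodal", "sham"),
}

#: ratio of between-level variance to the parameter prior variance at gamma=0
DEFAULT_BETWEEN_RATIO = 1.0 / 16.0
GAMMA_HYPERPRIOR_VAR = 1.0 / 16.0
NULL_VARIANCE_RATIO = 1e-8


# ---------------------------------------------------------------------------
# design matrices

def build_interaction_design(sessions, contrast_name: str) -> pd.DataFrame:
    """Within-subject 2x2 polarity-by-time interaction design.

    ``sessions`` is a sequence of (polarity, time) labels, one per
    observation, covering exactly the four cells of the two polarities
    named by ``contrast_name`` crossed with {pre, post}.  Columns are
    [mean, interaction]; the interaction column is the (post - pre)
    difference of the first-named polarity minus that of the second,
    coded with +-1/2 weights.
    """
    if contrast_name not in CONTRASTS:
        raise KeyError(f"unknown contrast {contrast_name!r}; "
                       f"expected one of {sorted(CONTRASTS)}")
    p1, p2 = CONTRASTS[contrast_name]
    sessions = [(str(p), str(t)) for p, t in sessions]
    needed = {(p, t) for p in (p1, p2) for t in ("pre", "post")}
    if set(sessions) != needed or len(sessions) != 4:
        missing = sorted(needed - set(sessions))
        raise ValueError(f"interaction design needs exactly the 4 cells "
                         f"{sorted(needed)}; missing or extra: {missing or sorted(set(sessions) - needed)}")
    rows = []
    for pol, t in sessions:
        sign_p = 1.0 if pol == p1 else -1.0
        sign_t = 0.5 if t == "post" else -0.5
        rows.append([1.0, sign_p * sign_t])
    X = pd.DataFrame(rows, columns=["mean", "interaction"],
                     index=[f"{p}-{t}" for p, t in sessions])
    return X


def build_group_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Group design [mean, sex, age, handedness] with mean-centred covariates."""
    required = ("sex", "age", "handedness")
    for c in required:
        if c not in covariates.columns:
            raise ValueError(f"missing covariate {c!r}")
        if covariates[c].isna().any():
            raise ValueError(f"missing covariate values in {c!r}")
    X = pd.DataFrame({"mean": np.ones(len(covariates))},
                     index=covariates.index)
    for c in required:
        col = covariates[c].to_numpy(float)
        centred = col - col.mean()
        if np.allclose(centred, 0):
            warnings.warn(f"covariate {c!r} is constant; centred column is "
                          "all zeros (degenerate regressor)", UserWarning)
        X[c] = centred
    return X


def validate_design(X: pd.DataFrame, require_full_rank: bool = True) -> None:
    A = X.to_numpy(float)
    if not np.allclose(A[:, 0], 1.0):
        raise ValueError("first design column must be the constant (mean)")
    for c in X.columns[1:]:
        if c != "interaction" and abs(X[c].sum()) > 1e-10:
            raise ValueError(f"covariate column {c!r} is not mean-centred")
    if require_full_rank and np.linalg.matrix_rank(A) < min(A.shape):
        raise np.linalg.LinAlgError("rank-deficient design matrix")


# ---------------------------------------------------------------------------
# model containers

@dataclass
class PEBModel:
    """Group-level posterior over regression effects on DCM parameters.

    ``mean`` is stacked column-major over design regressors: entries
    [c*p : (c+1)*p] hold the effects of regressor c on the p parameters.
    """

    mean: np.ndarray
    cov: np.ndarray
    columns: list
    param_labels: list
    prior_variance: np.ndarray
    gamma: float
    free_energy: float
    n_observations: int

    @property
    def n_params(self) -> int:
        return len(self.param_labels)

    def _block(self, column: str) -> slice:
        c = list(self.columns).index(column)
        p = self.n_params
        return slice(c * p, (c + 1) * p)

    def marginal(self, column: str = "mean") -> PosteriorEstimate:
        """Marginal posterior over one regressor's parameter effects."""
        s = self._block(column)
        return PosteriorEstimate(
            mean=self.mean[s], cov=self.cov[s, s], log_precisions=np.array([]),
            free_energy=self.free_energy, labels=list(self.param_labels))

    def entry_labels(self) -> list:
        return [f"{c}:{l}" for c in self.columns for l in self.param_labels]


@dataclass
class BMAResult:
    """Model-averaged effects with per-parameter posterior probabilities."""

    table: pd.DataFrame          # parameter, effect, sd, pp, flagged
    model_space: pd.DataFrame    # candidate models and their evidence weights
    threshold: float = 0.95

    def __post_init__(self):
        pp = self.table["pp"].to_numpy(float)
        if np.any(pp < -1e-9) or np.any(pp > 1 + 1e-9):
            raise ValueError("posterior probabilities must lie in [0, 1]")

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table.flagged]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fitting

def _as_mean_cov(obj, field_mask=None):
    if isinstance(obj, PosteriorEstimate):
        m, S = obj.mean, obj.cov
    else:
        m, S = obj
    m = np.asarray(m, float)
    S = np.asarray(S, float)
    if field_mask is not None:
        idx = np.flatnonzero(field_mask) if np.asarray(field_mask).dtype == bool \
            else np.asarray(field_mask, int)
        m = m[idx]
        S = S[np.ix_(idx, idx)]
    return m, S


def fit_peb(first_level, X, field_mask=None, param_prior_var=1.0 / 16.0,
            between_ratio: float = DEFAULT_BETWEEN_RATIO,
            between_var=None, gamma_bounds=(-5.0, 5.0),
            param_labels=None) -> PEBModel:
    """Empirical-Bayes group model over first-level posteriors.

    Parameters
    ----------
    first_level : sequence of PosteriorEstimate or (mean, cov) pairs.
    X : design matrix (DataFrame or array), one row per observation.
    field_mask : optional boolean mask or index array restricting the
        parameter space shared by all posteriors.
    param_prior_var : scalar or (p,) prior variance of the group effects,
        applied to every regressor column.
    between_ratio : ratio of the between-level variance component Q to the
        parameter prior variance at gamma = 0; 0 fixes Sigma_b = 0.
    between_var : scalar or (p,) absolute between-level variance at
        gamma = 0; overrides ``between_ratio`` (useful when the beta
        prior is deliberately vague and must not inflate Q).
    """
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        Xa = X.to_numpy(float)
    else:
        Xa = np.asarray(X, float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        columns = [f"x{c}" for c in range(Xa.shape[1])]
    n, ncol = Xa.shape
    if len(first_level) != n:
        raise ValueError("one design row per first-level posterior required")
    if np.linalg.matrix_rank(Xa) < ncol:
        raise np.linalg.LinAlgError("rank-deficient design matrix")

    pairs = [_as_mean_cov(o, field_mask) for o in first_level]
    p = len(pairs[0][0])
    if any(len(m) != p for m, _ in pairs):
        raise ValueError("first-level posteriors do not share a parameter space")
    if param_labels is None:
        obj = first_level[0]
        if isinstance(obj, PosteriorEstimate) and obj.labels is not None:
            labels = np.asarray(obj.labels, object)
            if field_mask is not None:
                idx = np.flatnonzero(field_mask) if np.asarray(field_mask).dtype == bool \
                    else np.asarray(field_mask, int)
                labels = labels[idx]
            param_labels = list(labels)
        else:
            param_labels = [f"p{i}" for i in range(p)]

    prior_var_param = np.broadcast_to(np.asarray(param_prior_var, float), (p,)).copy()
    prior_var = np.tile(prior_var_param, ncol)
    if between_var is not None:
        Q = np.broadcast_to(np.asarray(between_var, float), (p,)).copy()
        if np.all(Q == 0):
            between_ratio = 0.0
    else:
        Q = between_ratio * prior_var_param

    m_stack = np.concatenate([m for m, _ in pairs])
    X_full = np.kron(Xa, np.eye(p))

    def _posterior_and_evidence(gamma):
        Vi = [S + np.diag(np.exp(-gamma) * Q) for _, S in pairs]
        # marginal covariance of the stacked observations
        C = np.zeros((n * p, n * p))
        for i, V in enumerate(Vi):
            C[i * p:(i + 1) * p, i * p:(i + 1) * p] = V
        C += X_full @ (prior_var[:, None] * X_full.T)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return None, None, -np.inf
        alpha = np.linalg.solve(L, m_stack)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        F = (-0.5 * alpha @ alpha - 0.5 * logdet - 0.5 * n * p * np.log(2 * np.pi))
        if between_ratio > 0:
            F += -0.5 * gamma ** 2 / GAMMA_HYPERPRIOR_VAR \
                - 0.5 * np.log(2 * np.pi * GAMMA_HYPERPRIOR_VAR)
        # posterior over beta
        Vinv_blocks = [np.linalg.inv(V) for V in Vi]
        Pi = np.diag(1.0 / prior_var).astype(float)
        rhs = np.zeros(ncol * p)
        for i, Vinv in enumerate(Vinv_blocks):
            Xi = X_full[i * p:(i + 1) * p]
            Pi += Xi.T @ Vinv @ Xi
            rhs += Xi.T @ (Vinv @ pairs[i][0])
        Sigma_b = np.linalg.inv(Pi)
        Sigma_b = 0.5 * (Sigma_b + Sigma_b.T)
        return Sigma_b @ rhs, Sigma_b, float(F)

    if between_ratio > 0:
        res = minimize_scalar(lambda g: -_posterior_and_evidence(g)[2],
                              bounds=gamma_bounds, method="bounded",
                              options={"xatol": 1e-3})
        gamma = float(res.x)
    else:
        gamma = 0.0
    mean, cov, F = _posterior_and_evidence(gamma)
    if mean is None:
        raise np.linalg.LinAlgError("singular observation covariance in PEB")
    return PEBModel(mean=mean, cov=cov, columns=columns,
                    param_labels=param_labels, prior_variance=prior_var,
                    gamma=gamma, free_energy=F, n_observations=n)


# ---------------------------------------------------------------------------
# Bayesian model reduction

def bayesian_model_reduction(mu, Sigma, pE, pC, pE_r, pC_r):
    """Evidence change and posterior under a reduced prior (analytic).

    Given a posterior N(mu, Sigma) obtained under prior N(pE, pC), returns
    (dF, mu_r, Sigma_r) for the model whose prior is N(pE_r, pC_r),
    without refitting: dF = log of the Gaussian integral of
    q(theta) p_r(theta) / p(theta).
    """
    mu, pE, pE_r = (np.asarray(a, float) for a in (mu, pE, pE_r))
    Sigma, pC, pC_r = (np.atleast_2d(np.asarray(a, float))
                       for a in (Sigma, pC, pC_r))
    Pi = np.linalg.inv(Sigma)
    Pi0 = np.linalg.inv(pC)
    Pi0r = np.linalg.inv(pC_r)
    Pir = Pi + Pi0r - Pi0
    sign, _ = np.linalg.slogdet(Pir)
    if sign <= 0:
        raise np.linalg.LinAlgError("reduced posterior precision not positive "
                                    "definite")
    Sigma_r = np.linalg.inv(Pir)
    Sigma_r = 0.5 * (Sigma_r + Sigma_r.T)
    mu_r = Sigma_r @ (Pi @ mu + Pi0r @ pE_r - Pi0 @ pE)
    logdets = (np.linalg.slogdet(Pi)[1] + np.linalg.slogdet(Pi0r)[1]
               - np.linalg.slogdet(Pi0)[1] - np.linalg.slogdet(Pir)[1])
    quad = (mu @ Pi @ mu + pE_r @ Pi0r @ pE_r - pE @ Pi0 @ pE
            - mu_r @ Pir @ mu_r)
    dF = 0.5 * logdets - 0.5 * quad
    return float(dF), mu_r, Sigma_r


def _prior_of(model, priors):
    if isinstance(model, PEBModel):
        return np.zeros_like(model.mean), np.diag(model.prior_variance)
    if priors is None:
        raise ValueError("priors are required when reducing a raw posterior")
    return priors.mean, priors.covariance


def reduce_model(model, off_mask, priors=None,
                 null_variance_ratio: float = NULL_VARIANCE_RATIO):
    """Switch a subset of parameters off and return (dF, reduced posterior).

    ``off_mask`` is boolean (or index) over the model's free parameters;
    switched-off parameters receive a zero-mean prior whose variance is
    ``null_variance_ratio`` times the original (a numerically stable
    surrogate for zero).  dF > 0 favours the reduced model.
    """
    if isinstance(model, PEBModel):
        mu, Sigma = model.mean, model.cov
    else:
        mu, Sigma = _as_mean_cov(model)
    pE, pC = _prior_of(model, priors)
    k = len(mu)
    off_arr = np.asarray(off_mask)
    if off_arr.dtype == bool:
        if off_arr.shape != (k,):
            raise ValueError("boolean off_mask must match the parameter count")
        off = off_arr.copy()
    else:
        off = np.zeros(k, bool)
        off[off_arr.astype(int)] = True
    if not off.any():
        post = PosteriorEstimate(mean=np.asarray(mu, float),
                                 cov=np.atleast_2d(np.asarray(Sigma, float)),
                                 log_precisions=np.array([]), free_energy=0.0)
        return 0.0, post
    pE_r = np.asarray(pE, float).copy()
    pC_r = np.atleast_2d(np.asarray(pC, float)).copy()
    pE_r[off] = 0.0
    d = np.diag(pC_r).copy()
    d[off] = d[off] * null_variance_ratio
    # zero cross-covariances of switched-off entries in the reduced prior
    pC_r[off, :] = 0.0
    pC_r[:, off] = 0.0
    pC_r[np.diag_indices(k)] = d
    dF, mu_r, Sigma_r = bayesian_model_reduction(mu, Sigma, pE, pC, pE_r, pC_r)
    reduced = PosteriorEstimate(mean=mu_r, cov=Sigma_r,
                                log_precisions=np.array([]), free_energy=dF)
    return dF, reduced


# ---------------------------------------------------------------------------
# greedy search and model averaging

def search_and_average(model: PEBModel, search_columns=None,
                       threshold: float = 0.95,
                       max_exhaustive: int = 8,
                       model_cap: int = 256) -> BMAResult:
    """Prune parameters not contributing to evidence, then average.

    Parameters whose regressor column is listed in ``search_columns``
    (default: all columns) are candidates for removal.  When more than
    ``max_exhaustive`` candidates survive an initial greedy elimination,
    the weakest are fixed off until an exhaustive search over the
    remainder fits within ``model_cap`` models.  Evidence weights over
    the final candidate set give the Bayesian model average and the
    per-parameter posterior probability of being switched on.
    """
    labels = model.entry_labels()
    k = len(model.mean)
    if search_columns is None:
        search_idx = np.arange(k)
    else:
        p = model.n_params
        search_idx = np.concatenate([
            np.arange(model._block(c).start, model._block(c).stop)
            for c in search_columns])

    def dF_of(off_set):
        off = np.zeros(k, bool)
        off[list(off_set)] = True
        if not off.any():
            return 0.0, model.mean
        dF, red = reduce_model(model, off)
        return dF, red.mean

    # greedy elimination until the exhaustive stage is affordable
    off_fixed = set()
    candidates = list(search_idx)
    while len(candidates) > max_exhaustive:
        base_dF, _ = dF_of(off_fixed)
        gains = {i: dF_of(off_fixed | {i})[0] - base_dF for i in candidates}
        best_i = max(gains, key=gains.get)
        if gains[best_i] > 0:
            off_fixed.add(best_i)
            candidates.remove(best_i)
        else:
            # no single removal improves evidence: keep the best-supported
            # parameters fixed on and only examine the weakest few
            # exhaustively
            candidates = sorted(candidates, key=lambda i: -gains[i])[:max_exhaustive]

    # exhaustive on/off over the surviving candidates
    rows = []
    dFs, means, ons = [], [], []
    for subset in itertools.product([False, True], repeat=len(candidates)):
        off = set(off_fixed) | {i for i, o in zip(candidates, subset) if o}
        dF, mu_r = dF_of(off)
        on = np.ones(k, bool)
        on[list(off)] = False
        dFs.append(dF)
        means.append(mu_r)
        ons.append(on)
        if len(dFs) >= model_cap:
            break
    dFs = np.asarray(dFs)
    w = np.exp(dFs - dFs.max())
    w /= w.sum()
    ons = np.asarray(ons)
    means = np.asarray(means)

    bma_mean = w @ means
    pp = np.ones(k)
    in_scope = np.zeros(k, bool)
    in_scope[search_idx] = True
    pp[in_scope] = (w[:, None] * ons[:, in_scope]).sum(axis=0)
    sd_full = np.sqrt(np.diag(model.cov))

    table = pd.DataFrame({
        "parameter": labels,
        "effect": bma_mean,
        "sd": sd_full,
        "pp": pp,
        "flagged": (pp > threshold) & in_scope,
        "searched": in_scope,
    })
    space = pd.DataFrame({
        "dF": dFs,
        "weight": w,
        "on": ["".join("1" if o else "0" for o in row[search_idx])
               for row in ons],
    })
    return BMAResult(table=table, model_space=space, threshold=threshold)
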