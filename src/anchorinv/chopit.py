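"""Compound hierarchical ordered probit (CHOPIT) estimation.

Joint maximum-likelihood model of one indicator's self-reports and the
vignette ratings of that indicator:

* self component: the latent self-assessment is N(mu_i, 1) with
  mu_i = X_i beta + eta_i, eta_i ~ N(0, omega^2) a respondent random
  effect; no intercept in X beta (location is absorbed by the threshold
  intercept, and the latent scale is fixed by the unit residual SD);
* vignette component: the latent evaluation of vignette level j is
  N(theta_j, sigma_j^2), with no respondent effect;
* both components are discretised by the same respondent-specific
  thresholds tau_i^1 = gamma^1 V_i, tau_i^k = tau_i^{k-1} + exp(gamma^k V_i)
  (response consistency), which is what identifies the threshold model.

The random-effect integral of the self component is evaluated by
Gauss-Hermite quadrature.  One model is fitted per indicator; the fitted
threshold coefficients then predict respondent-specific thresholds for
the whole sample (the covariates the downstream covariate MGCFA uses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

from .dataset import (
    INDICATORS,
    N_CATEGORIES,
    SurveyDataset,
    design_matrix,
    self_col,
    vignette_col,
)
from .synthetic import thresholds_from_gamma

__all__ = [
    "ChopitParams",
    "ChopitFit",
    "chopit_loglik",
    "loglik_arrays",
    "self_category_probs",
    "fit_chopit",
    "predict_thresholds",
    "screen_threshold_covariates",
    "simulate_chopit",
    "DEFAULT_COVARIATES",
]

#: covariates of the study's threshold/location model: language (group),
#: gender, age and insurance card; education is excluded by default because
#: its missingness would shrink the estimation sample.
DEFAULT_COVARIATES: tuple[str, ...] = ("group", "gender", "age_band", "insurance")

_MIN_P = 1e-300


@dataclass
class ChopitParams:
    """Parameters of one indicator's CHOPIT model."""

    beta: np.ndarray  # (nx,) covariate effects on the self latent mean
    omega: float  # SD of the respondent random effect
    gamma: np.ndarray  # (K-1, nv) threshold coefficients, col 0 = intercept row order
    theta: np.ndarray  # (J,) vignette latent locations
    sigma: np.ndarray  # (J,) vignette latent SDs
    levels: tuple[int, ...] = ()  # vignette levels the theta/sigma refer to
    x_names: tuple[str, ...] = ()
    v_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, float))
        self.gamma = np.atleast_2d(np.asarray(self.gamma, float))
        self.theta = np.atleast_1d(np.asarray(self.theta, float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, float))
        if self.omega < 0:
            raise ValueError("omega must be non-negative")
        if np.any(self.sigma <= 0):
            raise ValueError("vignette SDs must be strictly positive")
        if not self.levels:
            self.levels = tuple(range(1, len(self.theta) + 1))

    def validate_finite(self) -> None:
        for name, arr in (
            ("beta", self.beta),
            ("gamma", self.gamma),
            ("theta", self.theta),
            ("sigma", self.sigma),
            ("omega", np.array([self.omega])),
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite value in parameter {name!r}")


@dataclass
class ChopitFit:
    params: ChopitParams
    loglik: float
    vcov: np.ndarray | None
    se: dict | None
    converged: bool
    n_self: int
    n_vignette: int
    indicator: str
    thresholds: np.ndarray  # (n_fit, K-1) for the estimation sample
    resp_id: np.ndarray
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------
def _category_bounds(ratings: np.ndarray, tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper latent thresholds for each observed category (1..K)."""
    n, Km1 = tau.shape
    padded = np.column_stack([np.full(n, -np.inf), tau, np.full(n, np.inf)])
    k = ratings.astype(int)
    rows = np.arange(n)
    return padded[rows, k - 1], padded[rows, k]


def loglik_arrays(
    params: ChopitParams,
    X: np.ndarray,
    V: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    quadrature_nodes: int = 15,
) -> float:
    """Log-likelihood from raw arrays.

    X: (n, nx) mean covariates; V: (n, nv) threshold covariates (intercept
    first); y: (n,) self ratings with NaN allowed; Z: (n, J) vignette
    ratings with NaN for unrated levels.
    """
    params.validate_finite()
    if quadrature_nodes < 5:
        raise ValueError("quadrature_nodes must be >= 5")
    n = len(V)
    if n == 0:
        raise ValueError("empty data")
    tau = thresholds_from_gamma(params.gamma, V)
    total = 0.0

    obs = ~np.isnan(y)
    if obs.any():
        probs = _self_likelihood(params, X[obs], tau[obs], y[obs], quadrature_nodes)
        total += float(np.sum(np.log(np.maximum(probs, _MIN_P))))

    if Z is not None:
        for j in range(Z.shape[1]):
            zc = Z[:, j]
            m = ~np.isnan(zc)
            if not m.any():
                continue
            lo, hi = _category_bounds(zc[m], tau[m])
            pj = ndtr((hi - params.theta[j]) / params.sigma[j]) - ndtr(
                (lo - params.theta[j]) / params.sigma[j]
            )
            total += float(np.sum(np.log(np.maximum(pj, _MIN_P))))
    return total


def _self_likelihood(
    params: ChopitParams,
    X: np.ndarray,
    tau: np.ndarray,
    y: np.ndarray,
    nodes: int,
) -> np.ndarray:
    mu = X @ params.beta if X.shape[1] else np.zeros(len(X))
    lo, hi = _category_bounds(y, tau)
    if params.omega == 0.0:
        return ndtr(hi - mu) - ndtr(lo - mu)
    t, w = np.polynomial.hermite.hermgauss(nodes)
    eta = np.sqrt(2.0) * params.omega * t  # (Q,)
    up = hi[:, None] - mu[:, None] - eta[None, :]
    dn = lo[:, None] - mu[:, None] - eta[None, :]
    P = ndtr(up) - ndtr(dn)  # (n, Q)
    return P @ (w / np.sqrt(np.pi))


def self_category_probs(
    params: ChopitParams,
    X: np.ndarray,
    V: np.ndarray,
    quadrature_nodes: int = 15,
) -> np.ndarray:
    """Marginal P(y = k) for every row and category; rows sum to one."""
    n = len(V)
    tau = thresholds_from_gamma(params.gamma, V)
    out = np.empty((n, N_CATEGORIES))
    for k in range(1, N_CATEGORIES + 1):
        out[:, k - 1] = _self_likelihood(
            params, X, tau, np.full(n, k), quadrature_nodes
        )
    return out


# ---------------------------------------------------------------------------
# data assembly
# ---------------------------------------------------------------------------
def _assemble(
    data: SurveyDataset,
    indicator: str,
    covariates: Sequence[str],
    include_sets: Sequence[int] | None,
):
    if indicator not in INDICATORS:
        raise ValueError(f"unknown indicator {indicator!r}")
    df = data.df
    if include_sets is not None and "vignette_set" in df.columns:
        df = df[df["vignette_set"].isin(list(include_sets))]
    X, x_names = design_matrix(df, covariates, intercept=False)
    V = np.column_stack([np.ones(len(df)), X])
    v_names = ["const"] + x_names
    keep = ~np.isnan(X).any(axis=1)
    df = df.loc[keep]
    X, V = X[keep], V[keep]
    y = df[self_col(indicator)].to_numpy(float)
    levels = [
        lev
        for lev in range(1, N_CATEGORIES + 1)
        if vignette_col(indicator, lev) in df.columns
        and df[vignette_col(indicator, lev)].notna().any()
    ]
    Z = (
        np.column_stack(
            [df[vignette_col(indicator, lev)].to_numpy(float) for lev in levels]
        )
        if levels
        else np.empty((len(df), 0))
    )
    # keep rows contributing at least one observation
    contrib = ~np.isnan(y)
    if Z.shape[1]:
        contrib |= ~np.isnan(Z).all(axis=1)
    return (
        X[contrib],
        V[contrib],
        y[contrib],
        Z[contrib],
        tuple(levels),
        tuple(x_names),
        tuple(v_names),
        df.loc[contrib, "resp_id"].to_numpy(),
    )


def chopit_loglik(
    params: ChopitParams,
    data: SurveyDataset,
    indicator: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    quadrature_nodes: int = 15,
    include_sets: Sequence[int] | None = None,
) -> float:
    """Log-likelihood of ``params`` for one indicator's survey data."""
    X, V, y, Z, levels, _, _, _ = _assemble(data, indicator, covariates, include_sets)
    if levels and len(params.theta) != len(levels):
        raise ValueError(
            f"params carry {len(params.theta)} vignette levels, data has "
            f"{len(levels)}"
        )
    return loglik_arrays(params, X, V, y, Z, quadrature_nodes)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------
def _pack(params: ChopitParams, fix_omega: bool) -> np.ndarray:
    parts = [params.beta]
    if not fix_omega:
        parts.append([np.log(max(params.omega, 1e-4))])
    parts.append(params.gamma.ravel())
    parts.append(params.theta)
    parts.append(np.log(params.sigma))
    return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])


def _unpack(
    x: np.ndarray,
    nx: int,
    nv: int,
    J: int,
    levels: tuple[int, ...],
    fix_omega: bool,
    x_names,
    v_names,
) -> ChopitParams:
    pos = 0
    beta = x[pos : pos + nx]
    pos += nx
    if fix_omega:
        omega = 0.0
    else:
        omega = float(np.exp(x[pos]))
        pos += 1
    Km1 = N_CATEGORIES - 1
    gamma = x[pos : pos + Km1 * nv].reshape(Km1, nv)
    pos += Km1 * nv
    theta = x[pos : pos + J]
    pos += J
    sigma = np.exp(x[pos : pos + J])
    return ChopitParams(
        beta=beta,
        omega=omega,
        gamma=gamma,
        theta=theta,
        sigma=sigma,
        levels=levels,
        x_names=x_names,
        v_names=v_names,
    )


def _ordered_probit_start(y: np.ndarray, nv: int) -> np.ndarray:
    """Marginal ordered-probit cutpoints -> gamma intercept column."""
    obs = y[~np.isnan(y)].astype(int)
    cum = np.array(
        [np.mean(obs <= k) for k in range(1, N_CATEGORIES)]
    )
    cum = np.clip(cum, 1e-3, 1 - 1e-3)
    cuts = stats.norm.ppf(cum)
    cuts = np.maximum.accumulate(cuts + 1e-6 * np.arange(len(cuts)))
    gamma = np.zeros((N_CATEGORIES - 1, nv))
    gamma[0, 0] = cuts[0]
    for k in range(1, N_CATEGORIES - 1):
        gamma[k, 0] = np.log(max(cuts[k] - cuts[k - 1], 1e-3))
    return gamma


def fit_chopit(
    data: SurveyDataset,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    indicator: str = "attention",
    quadrature_nodes: int = 15,
    tol: float = 1e-6,
    seed: int = 0,
    include_sets: Sequence[int] | None = None,
    fix_omega: bool = False,
    compute_se: bool = True,
    multistart: int = 0,
) -> ChopitFit:
    """Maximum-likelihood CHOPIT fit for one indicator.

    Starts from a deterministic point (marginal ordered-probit cutpoints,
    zero covariate effects); ``multistart`` adds seeded random restarts for
    rough likelihoods.  Listwise-complete rows (on the covariates) only.
    """
    X, V, y, Z, levels, x_names, v_names, resp_id = _assemble(
        data, indicator, covariates, include_sets
    )
    return fit_chopit_arrays(
        X,
        V,
        y,
        Z,
        levels=levels,
        x_names=x_names,
        v_names=v_names,
        resp_id=resp_id,
        indicator=indicator,
        quadrature_nodes=quadrature_nodes,
        tol=tol,
        seed=seed,
        fix_omega=fix_omega,
        compute_se=compute_se,
        multistart=multistart,
    )


def fit_chopit_arrays(
    X: np.ndarray,
    V: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray,
    levels: tuple[int, ...] = (),
    x_names: tuple[str, ...] = (),
    v_names: tuple[str, ...] = (),
    resp_id: np.ndarray | None = None,
    indicator: str = "",
    quadrature_nodes: int = 15,
    tol: float = 1e-6,
    seed: int = 0,
    fix_omega: bool = False,
    compute_se: bool = True,
    multistart: int = 0,
) -> ChopitFit:
    """Array-level CHOPIT fit (see :func:`fit_chopit`)."""
    if not levels:
        levels = tuple(range(1, Z.shape[1] + 1))
    if not x_names:
        x_names = tuple(f"x{i}" for i in range(X.shape[1]))
    if not v_names:
        v_names = ("const",) + tuple(f"x{i}" for i in range(V.shape[1] - 1))
    if resp_id is None:
        resp_id = np.arange(len(y))
    n_self = int((~np.isnan(y)).sum())
    n_vig = int((~np.isnan(Z)).sum()) if Z.size else 0
    if len(np.unique(y[~np.isnan(y)])) < 2:
        raise ValueError(f"fewer than 2 observed categories for {indicator!r}")
    nx, nv, J = X.shape[1], V.shape[1], len(levels)
    aug = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(aug) < nx + 1:
        raise ValueError("covariate matrix is rank deficient after expansion")
    n_par = nx + (0 if fix_omega else 1) + (N_CATEGORIES - 1) * nv + 2 * J
    if len(y) < n_par:
        raise ValueError(
            f"{len(y)} respondents for {n_par} parameters; model too rich"
        )

    gamma0 = _ordered_probit_start(y, nv)
    cuts = thresholds_from_gamma(gamma0, np.eye(nv)[:1])[0]
    theta0 = np.empty(J)
    for jj, lev in enumerate(levels):
        col = Z[:, jj]
        mcat = float(np.nanmean(col)) if np.any(~np.isnan(col)) else lev
        centres = np.concatenate(
            [[cuts[0] - 1.0], (cuts[:-1] + cuts[1:]) / 2, [cuts[-1] + 1.0]]
        )
        theta0[jj] = np.interp(mcat, np.arange(1, N_CATEGORIES + 1), centres)
    start = ChopitParams(
        beta=np.zeros(nx),
        omega=0.0 if fix_omega else 0.5,
        gamma=gamma0,
        theta=theta0,
        sigma=np.ones(J),
        levels=levels,
        x_names=x_names,
        v_names=v_names,
    )
    x0 = _pack(start, fix_omega)

    def nll(xv: np.ndarray) -> float:
        p = _unpack(xv, nx, nv, J, levels, fix_omega, x_names, v_names)
        try:
            return -loglik_arrays(p, X, V, y, Z, quadrature_nodes)
        except (ValueError, FloatingPointError):
            return 1e12

    best = optimize.minimize(
        nll, x0, method="L-BFGS-B", options={"maxiter": 1000, "ftol": tol * 1e-3}
    )
    if multistart:
        rng = np.random.default_rng(seed)
        for _ in range(multistart):
            res = optimize.minimize(
                nll,
                x0 + 0.3 * rng.standard_normal(len(x0)),
                method="L-BFGS-B",
                options={"maxiter": 1000, "ftol": tol * 1e-3},
            )
            if res.fun < best.fun:
                best = res

    params = _unpack(best.x, nx, nv, J, levels, fix_omega, x_names, v_names)
    vcov = se = None
    if compute_se:
        vcov, se = _observed_information(
            best.x, nll, nx, nv, J, levels, fix_omega, x_names, v_names
        )
    tau_fit = thresholds_from_gamma(params.gamma, V)
    assert np.all(np.diff(tau_fit, axis=1) > 0), "threshold monotonicity violated"
    return ChopitFit(
        params=params,
        loglik=-float(best.fun),
        vcov=vcov,
        se=se,
        converged=bool(best.success),
        n_self=n_self,
        n_vignette=n_vig,
        indicator=indicator,
        thresholds=tau_fit,
        resp_id=resp_id,
        diagnostics={"message": str(best.message), "n_iter": int(best.nit)},
    )


def _observed_information(xhat, nll, nx, nv, J, levels, fix_omega, x_names, v_names):
    """Delta-method SEs on the natural scale from the numerically
    differentiated observed information of the internal parameterization."""
    n = len(xhat)
    eps = 1e-4
    H = np.zeros((n, n))
    f0 = nll(xhat)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        xp = xhat.copy()
        xp[i] += eps
        fp[i] = nll(xp)
        xm = xhat.copy()
        xm[i] -= eps
        fm[i] = nll(xm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / eps**2
    for i in range(n):
        for j in range(i + 1, n):
            xpp = xhat.copy()
            xpp[[i, j]] += eps
            xmm = xhat.copy()
            xmm[[i, j]] -= eps
            H[i, j] = H[j, i] = (
                nll(xpp) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + nll(xmm)
            ) / (2 * eps**2)
    try:
        vcov_int = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        return None, None
    # jacobian of natural wrt internal parameters (log reparameterizations)
    jac = np.ones(n)
    pos = nx
    if not fix_omega:
        jac[pos] = np.exp(xhat[pos])  # omega
        pos += 1
    pos += (N_CATEGORIES - 1) * nv + J
    jac[pos : pos + J] = np.exp(xhat[pos : pos + J])  # sigmas
    vcov_nat = vcov_int * np.outer(jac, jac)
    se_vec = np.sqrt(np.maximum(np.diag(vcov_nat), 0.0))
    names: list[str] = [f"beta[{nm}]" for nm in x_names]
    if not fix_omega:
        names.append("omega")
    for k in range(1, N_CATEGORIES):
        names += [f"gamma{k}[{nm}]" for nm in v_names]
    names += [f"theta[L{lev}]" for lev in levels]
    names += [f"sigma[L{lev}]" for lev in levels]
    return vcov_nat, dict(zip(names, se_vec))


# ---------------------------------------------------------------------------
# threshold prediction and screening
# ---------------------------------------------------------------------------
def predict_thresholds(fit: ChopitFit, V: np.ndarray) -> np.ndarray:
    """Respondent-specific thresholds tau^1..tau^{K-1} from fitted gamma."""
    V = np.asarray(V, float)
    if V.shape[1] != fit.params.gamma.shape[1]:
        raise ValueError(
            f"V has {V.shape[1]} columns, fit expects {fit.params.gamma.shape[1]}"
        )
    return thresholds_from_gamma(fit.params.gamma, V)


def predict_thresholds_table(
    fits: dict[str, ChopitFit],
    data: SurveyDataset,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Predicted thresholds for every respondent, wide format:
    one column ``thr_<indicator>_k<k>`` per indicator and boundary."""
    X, _ = design_matrix(data.df, covariates, intercept=False)
    V = np.column_stack([np.ones(len(data.df)), X])
    ok = ~np.isnan(V).any(axis=1)
    out = pd.DataFrame({"resp_id": data.df["resp_id"].to_numpy()})
    for ind, fit in fits.items():
        tau = np.full((len(data.df), N_CATEGORIES - 1), np.nan)
        tau[ok] = predict_thresholds(fit, V[ok])
        for k in range(N_CATEGORIES - 1):
            out[f"thr_{ind}_k{k + 1}"] = tau[:, k]
    return out.set_index("resp_id")


def screen_threshold_covariates(
    thresholds: pd.DataFrame,
    data: SurveyDataset,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Keep predicted-threshold variables with a significant simple linear
    path to at least one indicator's self-report (tested per group).

    Returns the kept column names and the table of qualifying paths.
    """
    self_block = data.self_reports()
    groups = data.df.set_index("resp_id")["group"]
    recs = []
    for col in thresholds.columns:
        tvals = thresholds[col]
        for ind in INDICATORS:
            for g in data.groups:
                idx = groups[groups == g].index
                pair = pd.DataFrame(
                    {"t": tvals.reindex(idx), "y": self_block[ind].reindex(idx)}
                ).dropna()
                if len(pair) < 4 or pair["t"].std() == 0:
                    continue
                reg = stats.linregress(pair["t"], pair["y"])
                recs.append(
                    {
                        "threshold": col,
                        "indicator": ind,
                        "group": g,
                        "slope": reg.slope,
                        "pvalue": reg.pvalue,
                    }
                )
    paths = pd.DataFrame(recs)
    if paths.empty:
        raise ValueError("no complete rows for threshold screening")
    sig = paths[paths["pvalue"] < alpha]
    kept = [c for c in thresholds.columns if c in set(sig["threshold"])]
    return kept, sig.reset_index(drop=True)


# ---------------------------------------------------------------------------
# simulation (parameter-recovery studies)
# ---------------------------------------------------------------------------
def simulate_chopit(
    params: ChopitParams,
    X: np.ndarray,
    V: np.ndarray,
    vignette_mask: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (y, Z) from the CHOPIT data-generating process.

    ``vignette_mask`` (n, J) marks which vignette levels each respondent
    rates (default: all).  Returns integer ratings with NaN where unrated.
    """
    rng = np.random.default_rng(seed)
    n = len(V)
    J = len(params.theta)
    tau = thresholds_from_gamma(params.gamma, V)
    mu = X @ params.beta if X.shape[1] else np.zeros(n)
    eta = params.omega * rng.standard_normal(n)
    ystar = mu + eta + rng.standard_normal(n)
    y = (1 + (ystar[:, None] >= tau).sum(axis=1)).astype(float)
    Z = np.full((n, J), np.nan)
    for j in range(J):
        zstar = params.theta[j] + params.sigma[j] * rng.standard_normal(n)
        Z[:, j] = 1 + (zstar[:, None] >= tau).sum(axis=1)
    if vignette_mask is not None:
        Z[~vignette_mask.astype(bool)] = np.nan
    return y, Z
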