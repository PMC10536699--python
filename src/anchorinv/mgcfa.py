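"""Multi-group confirmatory factor analysis with mean structure.

One latent variable behind ``p`` indicators, fitted simultaneously in ``G``
groups by normal-theory maximum likelihood on sample moments:

    F = sum_g (n_g / N) [ log|Sigma_g| + tr(S_g Sigma_g^-1) - log|S_g| - p
                          + (m_g - mu_g)' Sigma_g^-1 (m_g - mu_g) ]

with chi^2 = (N - G) * F_min.  Identification: factor mean 0 and variance 1
in every group at every constraint level, so all loadings and intercepts are
estimated and can be constrained equal across groups (metric: equal
loadings; scalar: additionally equal intercepts).

Manifest covariates (the "covariate model") enter as exogenous observed
variables with saturated means/covariances, regressed on the indicators;
the latent variable stays independent of them.

Conventions emitted in fit metadata: divisor-n sample covariances,
chi2 = (N-G)*F_min, RMSEA with the sqrt(G) multi-group factor,
CFI against a per-group independence baseline (free means and variances),
sample-size-adjusted BIC with penalty ln((N+2)/24).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "CfaModelSpec",
    "GroupMoments",
    "FitResult",
    "ModIndex",
    "InvarianceReport",
    "DecisionRules",
    "moments_from_data",
    "implied_moments",
    "fit_mgcfa",
    "baseline_chisq",
    "fit_indices",
    "lrt_difference",
    "modification_indices",
    "invariance_sequence",
    "fit_covariate_model",
    "composite_reliability",
    "composite_reliability_from_standardized",
    "decide_configural",
    "decide_level",
]

LEVELS = ("configural", "metric", "scalar")


# ---------------------------------------------------------------------------
# specifications and containers
# ---------------------------------------------------------------------------
@dataclass
class CfaModelSpec:
    """One-factor multi-group CFA specification."""

    indicators: tuple[str, ...]
    level: str = "configural"
    error_covariances: tuple[tuple[str, str], ...] = ()
    equal_error_covariances: bool = True
    covariates: tuple[str, ...] = ()
    #: (covariate, indicator) regression paths; None means all pairs
    covariate_paths: tuple[tuple[str, str], ...] | None = None
    equal_covariate_paths: bool = False

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown constraint level {self.level!r}")
        for a, b in self.error_covariances:
            if a not in self.indicators or b not in self.indicators:
                raise ValueError(f"error covariance ({a!r}, {b!r}) names unknown indicator")
            if a == b:
                raise ValueError("error covariance must link two distinct indicators")
        if self.covariate_paths is not None:
            for cov, ind in self.covariate_paths:
                if cov not in self.covariates or ind not in self.indicators:
                    raise ValueError(f"unknown covariate path ({cov!r}, {ind!r})")

    @property
    def p(self) -> int:
        return len(self.indicators)

    @property
    def q(self) -> int:
        return len(self.covariates)

    def paths(self) -> list[tuple[int, int]]:
        """Active (indicator, covariate) index pairs of the Gamma matrix."""
        if self.covariate_paths is None:
            return [(i, j) for i in range(self.p) for j in range(self.q)]
        return [
            (self.indicators.index(ind), self.covariates.index(cov))
            for cov, ind in self.covariate_paths
        ]

    def at_level(self, level: str) -> "CfaModelSpec":
        return replace(self, level=level)


@dataclass
class GroupMoments:
    """Sufficient statistics of one group (divisor-n covariance)."""

    label: str
    mean: np.ndarray
    cov: np.ndarray
    n: int
    columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.cov = np.asarray(self.cov, float)
        p = len(self.mean)
        if self.cov.shape != (p, p):
            raise ValueError("mean/cov dimension mismatch")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")
        eig = np.linalg.eigvalsh((self.cov + self.cov.T) / 2)
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            raise ValueError(f"covariance of group {self.label!r} is not PSD")


@dataclass
class FitResult:
    model: CfaModelSpec
    groups: tuple[str, ...]
    estimates: dict
    loglik: float
    chi2: float
    df: int
    pvalue: float
    cfi: float
    rmsea: float
    abic: float
    n_per_group: dict[str, int]
    n_free: int
    converged: bool
    heywood: bool
    meta: dict = field(default_factory=dict)
    _x: np.ndarray | None = None
    _moments: list | None = None

    @property
    def N(self) -> int:
        return sum(self.n_per_group.values())


@dataclass
class ModIndex:
    label: tuple
    mi: float
    epc: float


@dataclass
class DecisionRules:
    """Goodness-of-fit benchmarks and change rules for invariance decisions."""

    cfi_min: float = 0.95
    rmsea_max: float = 0.08
    alpha: float = 0.05
    delta_cfi: float = 0.005
    delta_rmsea: float = 0.010
    delta_bic: float = 6.0
    use_lrt: bool = True
    use_cfi: bool = True
    use_rmsea: bool = True
    mi_threshold: float = 3.84
    max_modifications: int = 2


@dataclass
class LevelResult:
    level: str
    fit: FitResult
    delta_chi2: float | None = None
    delta_df: int | None = None
    delta_p: float | None = None
    delta_cfi: float | None = None
    delta_rmsea: float | None = None
    delta_abic: float | None = None
    decision: str = ""
    flags: list = field(default_factory=list)


@dataclass
class InvarianceReport:
    levels: list[LevelResult]
    rules: DecisionRules
    modifications: list = field(default_factory=list)

    def decisions(self) -> dict[str, str]:
        return {lv.level: lv.decision for lv in self.levels}

    def level(self, name: str) -> LevelResult:
        for lv in self.levels:
            if lv.level == name:
                return lv
        raise KeyError(name)


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------
def moments_from_data(
    df: pd.DataFrame,
    columns: Sequence[str],
    group_col: str = "group",
) -> list[GroupMoments]:
    """Listwise-complete per-group means and divisor-n covariances."""
    columns = list(columns)
    out: list[GroupMoments] = []
    for g in dict.fromkeys(df[group_col]):
        sub = df.loc[df[group_col] == g, columns].dropna()
        n, p = sub.shape
        if n <= p:
            raise ValueError(
                f"group {g!r} has only {n} complete rows for {p} variables"
            )
        arr = sub.to_numpy(float)
        sd = arr.std(axis=0)
        if np.any(sd == 0):
            zero = columns[int(np.argmin(sd))]
            raise ValueError(f"zero-variance column {zero!r} in group {g!r}")
        out.append(
            GroupMoments(
                label=str(g),
                mean=arr.mean(axis=0),
                cov=np.cov(arr, rowvar=False, bias=True),
                n=n,
                columns=tuple(columns),
            )
        )
    return out


def implied_moments(
    lam: np.ndarray,
    tau: np.ndarray,
    psi: np.ndarray,
    ecov: Mapping[tuple[int, int], float] | None = None,
    gamma: np.ndarray | None = None,
    nu: np.ndarray | None = None,
    phi: np.ndarray | None = None,
    factor_mean: float = 0.0,
    factor_var: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied (mu, Sigma) for one group; the population-moment
    algebra used both inside the fit and as an oracle in tests."""
    lam = np.asarray(lam, float)
    tau = np.asarray(tau, float)
    p = len(lam)
    theta = np.diag(np.asarray(psi, float))
    if ecov:
        for (i, j), v in ecov.items():
            theta[i, j] = theta[j, i] = v
    sig_y = factor_var * np.outer(lam, lam) + theta
    mu_y = tau + factor_mean * lam
    if gamma is None or gamma.shape[1] == 0:
        return mu_y, sig_y
    q = gamma.shape[1]
    B = np.vstack([gamma, np.eye(q)])
    sigma = B @ phi @ B.T
    sigma[:p, :p] += sig_y
    mu = np.concatenate([mu_y + gamma @ nu, nu])
    return mu, sigma


# ---------------------------------------------------------------------------
# free-parameter bookkeeping
# ---------------------------------------------------------------------------
class _ParamTable:
    """Maps named model parameters to positions in the free vector,
    implementing cross-group equality constraints by index sharing."""

    def __init__(self, model: CfaModelSpec, groups: Sequence[str]):
        self.model = model
        self.groups = list(groups)
        self.index: dict[tuple, int] = {}
        p, q = model.p, model.q
        eq_lam = model.level in ("metric", "scalar")
        eq_tau = model.level == "scalar"
        for g in self.groups:
            for i in range(p):
                self._add(("lambda", "all" if eq_lam else g, i))
            for i in range(p):
                self._add(("tau", "all" if eq_tau else g, i))
            for i in range(p):
                self._add(("psi", g, i))
            for a, b in model.error_covariances:
                i, j = sorted(
                    (model.indicators.index(a), model.indicators.index(b))
                )
                gg = "all" if model.equal_error_covariances else g
                self._add(("ecov", gg, i, j))
            for i, j in model.paths():
                gg = "all" if model.equal_covariate_paths else g
                self._add(("gamma", gg, i, j))
            for j in range(q):
                self._add(("nu", g, j))
            for a in range(q):
                for b in range(a, q):
                    self._add(("phi", g, a, b))

    def _add(self, key: tuple) -> None:
        if key not in self.index:
            self.index[key] = len(self.index)

    def __len__(self) -> int:
        return len(self.index)

    def key(self, kind: str, group: str, *idx: int) -> tuple:
        model = self.model
        if kind == "lambda" and model.level in ("metric", "scalar"):
            group = "all"
        elif kind == "tau" and model.level == "scalar":
            group = "all"
        elif kind == "ecov" and model.equal_error_covariances:
            group = "all"
        elif kind == "gamma" and model.equal_covariate_paths:
            group = "all"
        return (kind, group, *idx)

    def loc(self, kind: str, group: str, *idx: int) -> int:
        return self.index[self.key(kind, group, *idx)]

    def unpack(self, x: np.ndarray, g: str):
        model = self.model
        p, q = model.p, model.q
        lam = np.array([x[self.loc("lambda", g, i)] for i in range(p)])
        tau = np.array([x[self.loc("tau", g, i)] for i in range(p)])
        psi = np.array([x[self.loc("psi", g, i)] for i in range(p)])
        ecov = {}
        for a, b in model.error_covariances:
            i, j = sorted((model.indicators.index(a), model.indicators.index(b)))
            ecov[(i, j)] = x[self.loc("ecov", g, i, j)]
        gamma = np.zeros((p, q))
        for i, j in model.paths():
            gamma[i, j] = x[self.loc("gamma", g, i, j)]
        nu = np.array([x[self.loc("nu", g, j)] for j in range(q)])
        phi = np.zeros((q, q))
        for a in range(q):
            for b in range(a, q):
                phi[a, b] = phi[b, a] = x[self.loc("phi", g, a, b)]
        return lam, tau, psi, ecov, gamma, nu, phi


# ---------------------------------------------------------------------------
# discrepancy function and gradient
# ---------------------------------------------------------------------------
def _fit_function(
    x: np.ndarray,
    table: _ParamTable,
    moments: Sequence[GroupMoments],
    want_grad: bool = True,
) -> tuple[float, np.ndarray | None]:
    model = table.model
    p, q = model.p, model.q
    N = sum(m.n for m in moments)
    F = 0.0
    grad = np.zeros(len(table)) if want_grad else None
    for m in moments:
        g = m.label
        lam, tau, psi, ecov, gamma, nu, phi = table.unpack(x, g)
        mu, sigma = implied_moments(lam, tau, psi, ecov, gamma, nu, phi)
        w = m.n / N
        try:
            cf = linalg.cho_factor(sigma, check_finite=False)
        except linalg.LinAlgError:
            return 1e12 + float(np.sum(x**2)), (np.zeros(len(table)) if want_grad else None)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        sign_s, logdet_s = np.linalg.slogdet(m.cov)
        d = m.mean - mu
        sinv = linalg.cho_solve(cf, np.eye(len(mu)), check_finite=False)
        Sstar = m.cov + np.outer(d, d)
        F += w * (
            logdet
            + float(np.sum(sinv * Sstar))
            - logdet_s
            - len(mu)
        )
        if not want_grad:
            continue
        A = w * (sinv - sinv @ Sstar @ sinv)  # dF/dSigma
        gmu = -2.0 * w * (sinv @ d)  # dF/dmu
        if q:
            A_yy = A[:p, :p]
            gmu_y, gmu_x = gmu[:p], gmu[p:]
            B = np.vstack([gamma, np.eye(q)])
            ABphi = A @ B @ phi
            M = B.T @ A @ B
        else:
            A_yy = A
            gmu_y = gmu
        dlam = 2.0 * (A_yy @ lam)
        for i in range(p):
            grad[table.loc("lambda", g, i)] += dlam[i]
            grad[table.loc("tau", g, i)] += gmu_y[i]
            grad[table.loc("psi", g, i)] += A_yy[i, i]
        for a, b in model.error_covariances:
            i, j = sorted((model.indicators.index(a), model.indicators.index(b)))
            grad[table.loc("ecov", g, i, j)] += 2.0 * A_yy[i, j]
        if q:
            dgam = 2.0 * ABphi[:p, :] + np.outer(gmu_y, nu)
            for i, j in model.paths():
                grad[table.loc("gamma", g, i, j)] += dgam[i, j]
            dnu = gamma.T @ gmu_y + gmu_x
            for j in range(q):
                grad[table.loc("nu", g, j)] += dnu[j]
            for a in range(q):
                grad[table.loc("phi", g, a, a)] += M[a, a]
                for b in range(a + 1, q):
                    grad[table.loc("phi", g, a, b)] += 2.0 * M[a, b]
    return F, grad


def _start_values(table: _ParamTable, moments: Sequence[GroupMoments]) -> np.ndarray:
    model = table.model
    p, q = model.p, model.q
    x = np.zeros(len(table))
    counts = np.zeros(len(table))
    for m in moments:
        g = m.label
        S_yy = m.cov[:p, :p]
        m_y = m.mean[:p]
        evals, evecs = np.linalg.eigh(S_yy)
        v = evecs[:, -1]
        if v.sum() < 0:
            v = -v
        lam0 = np.sqrt(max(evals[-1], 1e-6)) * v
        psi0 = np.maximum(np.diag(S_yy) - lam0**2, 0.05 * np.diag(S_yy))
        if q:
            S_xx = m.cov[p:, p:]
            S_yx = m.cov[:p, p:]
            nu0 = m.mean[p:]
            phi0 = S_xx
            gam_full = S_yx @ np.linalg.pinv(S_xx)
            gam0 = np.zeros((p, q))
            for i, j in model.paths():
                gam0[i, j] = gam_full[i, j]
            tau0 = m_y - gam0 @ nu0
        else:
            tau0 = m_y
        upd = []
        for i in range(p):
            upd += [
                (table.loc("lambda", g, i), lam0[i]),
                (table.loc("tau", g, i), tau0[i]),
                (table.loc("psi", g, i), psi0[i]),
            ]
        if q:
            for i, j in model.paths():
                upd.append((table.loc("gamma", g, i, j), gam0[i, j]))
            for j in range(q):
                upd.append((table.loc("nu", g, j), nu0[j]))
            for a in range(q):
                for b in range(a, q):
                    upd.append((table.loc("phi", g, a, b), phi0[a, b]))
        for loc, val in upd:
            x[loc] += val
            counts[loc] += 1
    counts[counts == 0] = 1
    return x / counts


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------
def fit_mgcfa(
    model: CfaModelSpec,
    groups: Sequence[GroupMoments],
    tol: float = 1e-8,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Minimise the multi-group ML discrepancy under the model's
    cross-group equality constraints."""
    p, q = model.p, model.q
    for m in groups:
        if len(m.mean) != p + q:
            raise ValueError(
                f"group {m.label!r} moments have dimension {len(m.mean)}, "
                f"model expects {p + q}"
            )
    table = _ParamTable(model, [m.label for m in groups])
    n_moments = len(groups) * (p + q) * (p + q + 3) // 2
    df = n_moments - len(table)
    if df < 0:
        raise ValueError(
            f"model not identified: {len(table)} free parameters exceed "
            f"{n_moments} sample moments"
        )
    x_start = _start_values(table, groups) if x0 is None else np.asarray(x0, float)

    res = optimize.minimize(
        _fit_function,
        x_start,
        args=(table, groups),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 4000, "maxfun": 8000, "ftol": 1e-15, "gtol": tol},
    )
    # polish: a second pass helps reach exact-fit minima to high precision
    res2 = optimize.minimize(
        _fit_function,
        res.x,
        args=(table, groups),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "maxfun": 4000, "ftol": 1e-16, "gtol": tol * 1e-2},
    )
    if res2.fun <= res.fun:
        res = res2
    fmin = float(res.fun)
    converged = bool(res.success or np.linalg.norm(res.jac, np.inf) < 1e-5)

    N = sum(m.n for m in groups)
    G = len(groups)
    chi2 = max((N - G) * fmin, 0.0)
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    estimates: dict = {}
    heywood = False
    for m in groups:
        lam, tau, psi, ecov, gamma, nu, phi = table.unpack(res.x, m.label)
        if np.any(psi < 0):
            heywood = True
        estimates[m.label] = {
            "lambda": lam,
            "tau": tau,
            "psi": psi,
            "ecov": {
                (model.indicators[i], model.indicators[j]): float(v)
                for (i, j), v in ecov.items()
            },
            "gamma": gamma,
            "nu": nu,
            "phi": phi,
        }

    loglik = _loglik_at(res.x, table, groups)
    chi2_b, df_b = baseline_chisq(groups)
    cfi, rmsea = _cfi_rmsea(chi2, df, chi2_b, df_b, N, G)
    abic = -2.0 * loglik + len(table) * np.log((N + 2) / 24.0)

    return FitResult(
        model=model,
        groups=tuple(m.label for m in groups),
        estimates=estimates,
        loglik=loglik,
        chi2=chi2,
        df=df,
        pvalue=pval,
        cfi=cfi,
        rmsea=rmsea,
        abic=abic,
        n_per_group={m.label: m.n for m in groups},
        n_free=len(table),
        converged=converged,
        heywood=heywood,
        meta={
            "fmin": fmin,
            "chi2_convention": "(N-G)*F_min",
            "rmsea_convention": "sqrt(G)*sqrt(max(chi2-df,0)/(df*N))",
            "abic_penalty": "ln((N+2)/24)",
            "baseline": "per-group independence, free means and variances",
        },
        _x=res.x,
        _moments=list(groups),
    )


def _loglik_at(
    x: np.ndarray, table: _ParamTable, moments: Sequence[GroupMoments]
) -> float:
    ll = 0.0
    for m in moments:
        lam, tau, psi, ecov, gamma, nu, phi = table.unpack(x, m.label)
        mu, sigma = implied_moments(lam, tau, psi, ecov, gamma, nu, phi)
        pdim = len(mu)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return -np.inf
        sinv = np.linalg.inv(sigma)
        d = m.mean - mu
        ll += -0.5 * m.n * (
            logdet
            + float(np.sum(sinv * m.cov))
            + float(d @ sinv @ d)
            + pdim * np.log(2 * np.pi)
        )
    return float(ll)


def baseline_chisq(groups: Sequence[GroupMoments]) -> tuple[float, int]:
    """Chi-square and df of the per-group independence model (free means
    and variances, all covariances zero) -- closed form."""
    N = sum(m.n for m in groups)
    G = len(groups)
    F_b = 0.0
    pdim = len(groups[0].mean)
    for m in groups:
        sign, logdet_s = np.linalg.slogdet(m.cov)
        F_b += (m.n / N) * (float(np.sum(np.log(np.diag(m.cov)))) - logdet_s)
    chi2_b = (N - G) * F_b
    df_b = G * pdim * (pdim - 1) // 2
    return float(chi2_b), df_b


def _cfi_rmsea(
    chi2: float, df: int, chi2_b: float, df_b: int, N: int, G: int
) -> tuple[float, float]:
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    rmsea = 0.0 if df == 0 else float(np.sqrt(G) * np.sqrt(num / (df * N)))
    return float(np.clip(cfi, 0.0, 1.0)), rmsea


def fit_indices(fit: FitResult, baseline: tuple[float, int] | None = None) -> dict:
    """CFI/RMSEA/aBIC of a fit (recomputed; baseline defaults to the
    per-group independence model of the fit's own moments)."""
    if baseline is None:
        chi2_b, df_b = baseline_chisq(fit._moments)
    else:
        chi2_b, df_b = baseline
    cfi, rmsea = _cfi_rmsea(fit.chi2, fit.df, chi2_b, df_b, fit.N, len(fit.groups))
    abic = -2.0 * fit.loglik + fit.n_free * np.log((fit.N + 2) / 24.0)
    return {
        "cfi": cfi,
        "rmsea": rmsea,
        "abic": float(abic),
        "df_zero": fit.df == 0,
    }


def lrt_difference(restricted: FitResult, free: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio (chi-square difference) test of nested fits."""
    ddf = restricted.df - free.df
    if ddf <= 0:
        raise ValueError("models are not nested (restricted must have larger df)")
    dchi = restricted.chi2 - free.chi2
    if dchi < 0:
        dchi = 0.0
    return float(dchi), int(ddf), float(stats.chi2.sf(dchi, ddf))


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------
def _hessian(fun_grad, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        xp = x.copy()
        xp[i] += eps
        _, gp = fun_grad(xp)
        xm = x.copy()
        xm[i] -= eps
        _, gm = fun_grad(xm)
        H[:, i] = (gp - gm) / (2 * eps)
    return (H + H.T) / 2


def standard_errors(fit: FitResult) -> dict:
    """Observed-information standard errors, keyed like the free-parameter
    table (kind, group, indices)."""
    table = _ParamTable(fit.model, list(fit.groups))
    H = _hessian(lambda x: _fit_function(x, table, fit._moments), fit._x)
    N, G = fit.N, len(fit.groups)
    cov = 2.0 / (N - G) * np.linalg.pinv(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return {key: float(se[i]) for key, i in table.index.items()}


# ---------------------------------------------------------------------------
# modification indices
# ---------------------------------------------------------------------------
def candidate_error_covariances(
    model: CfaModelSpec, equal: bool = True
) -> list[tuple[str, str]]:
    existing = {tuple(sorted(pair)) for pair in model.error_covariances}
    out = []
    for i, a in enumerate(model.indicators):
        for b in model.indicators[i + 1 :]:
            if tuple(sorted((a, b))) not in existing:
                out.append((a, b))
    return out


def modification_indices(
    fit: FitResult,
    candidates: Sequence[tuple[str, str]] | None = None,
) -> list[ModIndex]:
    """Univariate score-test (Lagrange multiplier) statistics for freeing
    error covariances currently fixed at zero (added equal across groups),
    with expected parameter changes.  Sorted by MI, descending."""
    if candidates is None:
        candidates = candidate_error_covariances(fit.model)
    N, G = fit.N, len(fit.groups)
    out: list[ModIndex] = []
    for pair in candidates:
        ext_model = replace(
            fit.model,
            error_covariances=tuple(fit.model.error_covariances) + (tuple(pair),),
        )
        table = _ParamTable(ext_model, list(fit.groups))
        x_ext = np.zeros(len(table))
        base_table = _ParamTable(fit.model, list(fit.groups))
        for key, i in base_table.index.items():
            x_ext[table.index[key]] = fit._x[i]
        _, g0 = _fit_function(x_ext, table, fit._moments)
        i, j = sorted(
            (ext_model.indicators.index(pair[0]), ext_model.indicators.index(pair[1]))
        )
        c_idx = table.loc("ecov", "all" if ext_model.equal_error_covariances else fit.groups[0], i, j)
        H = _hessian(lambda x: _fit_function(x, table, fit._moments), x_ext)
        free_idx = [k for k in range(len(table)) if k != c_idx]
        Hff = H[np.ix_(free_idx, free_idx)]
        Hfc = H[np.ix_(free_idx, [c_idx])]
        try:
            schur = H[c_idx, c_idx] - float((Hfc.T @ np.linalg.solve(Hff, Hfc))[0, 0])
        except np.linalg.LinAlgError:
            continue
        if schur <= 0:
            continue
        gc = g0[c_idx]
        mi = (N - G) / 2.0 * gc**2 / schur
        epc = -gc / schur
        out.append(ModIndex(label=("ecov",) + tuple(pair), mi=float(mi), epc=float(epc)))
    out.sort(key=lambda r: -r.mi)
    return out


# ---------------------------------------------------------------------------
# decision engine
# ---------------------------------------------------------------------------
def decide_configural(cfi: float, rmsea: float, rules: DecisionRules | None = None) -> str:
    """Configural acceptance: CFI and RMSEA against absolute benchmarks."""
    rules = rules or DecisionRules()
    ok = cfi >= rules.cfi_min and rmsea <= rules.rmsea_max
    return "supported" if ok else "rejected"


def decide_level(
    delta_chi2: float,
    delta_df: int,
    delta_cfi: float,
    delta_rmsea: float,
    rules: DecisionRules | None = None,
) -> str:
    """Metric/scalar decision from fit changes: rejected if the chi-square
    difference is significant, or CFI drops by >= the benchmark, or RMSEA
    rises by >= the benchmark (each criterion can be switched off)."""
    rules = rules or DecisionRules()
    reject = False
    if rules.use_lrt and stats.chi2.sf(max(delta_chi2, 0.0), delta_df) < rules.alpha:
        reject = True
    if rules.use_cfi and delta_cfi >= rules.delta_cfi:
        reject = True
    if rules.use_rmsea and delta_rmsea >= rules.delta_rmsea:
        reject = True
    return "rejected" if reject else "supported"


def invariance_sequence(
    model: CfaModelSpec,
    groups: Sequence[GroupMoments],
    rules: DecisionRules | None = None,
    modification_search: bool = False,
) -> InvarianceReport:
    """Configural -> metric -> scalar sequence with decisions.

    With ``modification_search`` a rejected configural model is re-specified
    by adding the error covariance with the largest modification index
    (held equal across groups), at most ``rules.max_modifications`` times,
    before the constrained levels are evaluated.
    """
    rules = rules or DecisionRules()
    report = InvarianceReport(levels=[], rules=rules)

    config_model = model.at_level("configural")
    fit_c = fit_mgcfa(config_model, groups)
    decision = decide_configural(fit_c.cfi, fit_c.rmsea, rules)
    report.levels.append(LevelResult(level="configural", fit=fit_c, decision=decision))

    if modification_search and decision == "rejected":
        for _ in range(rules.max_modifications):
            mis = modification_indices(fit_c)
            if not mis or mis[0].mi <= rules.mi_threshold:
                break
            pair = mis[0].label[1:]
            config_model = replace(
                config_model,
                error_covariances=tuple(config_model.error_covariances) + (pair,),
            )
            report.modifications.append(
                {"added": pair, "mi": mis[0].mi, "epc": mis[0].epc}
            )
            fit_c = fit_mgcfa(config_model, groups)
            decision = decide_configural(fit_c.cfi, fit_c.rmsea, rules)
            report.levels.append(
                LevelResult(
                    level="configural_modified", fit=fit_c, decision=decision
                )
            )
            if decision == "supported":
                break

    prev = fit_c
    base_model = config_model
    for level in ("metric", "scalar"):
        lvl_model = base_model.at_level(level)
        warm = _warm_start(lvl_model, prev)
        fit_l = fit_mgcfa(lvl_model, groups, x0=warm)
        fit_cold = fit_mgcfa(lvl_model, groups)
        if fit_cold.chi2 < fit_l.chi2:
            fit_l = fit_cold
        dchi, ddf, dp = lrt_difference(fit_l, prev)
        dcfi = prev.cfi - fit_l.cfi
        drmsea = fit_l.rmsea - prev.rmsea
        both_finite = np.isfinite(fit_l.abic) and np.isfinite(prev.abic)
        dabic = fit_l.abic - prev.abic if both_finite else float("nan")
        decision = decide_level(dchi, ddf, dcfi, drmsea, rules)
        report.levels.append(
            LevelResult(
                level=level,
                fit=fit_l,
                delta_chi2=dchi,
                delta_df=ddf,
                delta_p=dp,
                delta_cfi=dcfi,
                delta_rmsea=drmsea,
                delta_abic=dabic,
                decision=decision,
            )
        )
        prev = fit_l
    return report


# ---------------------------------------------------------------------------
# covariate model and reliability
# ---------------------------------------------------------------------------
def _warm_start(model: CfaModelSpec, prev: FitResult) -> np.ndarray:
    """Free vector for ``model`` assembled from a (less constrained)
    previous fit's estimates; equality-constrained entries get the
    across-group average."""
    table = _ParamTable(model, list(prev.groups))
    sums = np.zeros(len(table))
    counts = np.zeros(len(table))
    inds = model.indicators
    for g in prev.groups:
        est = prev.estimates[g]
        vals: list[tuple[int, float]] = []
        for i in range(model.p):
            vals.append((table.loc("lambda", g, i), est["lambda"][i]))
            vals.append((table.loc("tau", g, i), est["tau"][i]))
            vals.append((table.loc("psi", g, i), est["psi"][i]))
        for (a, b), v in est["ecov"].items():
            i, j = sorted((inds.index(a), inds.index(b)))
            vals.append((table.loc("ecov", g, i, j), v))
        for i, j in model.paths():
            vals.append((table.loc("gamma", g, i, j), est["gamma"][i, j]))
        for j in range(model.q):
            vals.append((table.loc("nu", g, j), est["nu"][j]))
        for a in range(model.q):
            for b in range(a, model.q):
                vals.append((table.loc("phi", g, a, b), est["phi"][a, b]))
        for loc, v in vals:
            sums[loc] += v
            counts[loc] += 1
    counts[counts == 0] = 1
    return sums / counts


def fit_covariate_model(
    model: CfaModelSpec,
    df: pd.DataFrame,
    group_col: str = "group",
    tol: float = 1e-8,
) -> FitResult:
    """Fit the covariate MGCFA (indicators regressed on manifest exogenous
    covariates) from respondent-level data, listwise complete."""
    if model.q == 0:
        raise ValueError("model has no covariates; use fit_mgcfa")
    cols = list(model.indicators) + list(model.covariates)
    sub = df[cols + [group_col]].dropna()
    X = sub[list(model.covariates)].to_numpy(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    if rank < X.shape[1] + 1:
        raise ValueError(
            f"collinear covariate set: {list(model.covariates)} "
            f"(rank {rank - 1} < {X.shape[1]})"
        )
    moments = moments_from_data(sub, cols, group_col=group_col)
    return fit_mgcfa(model, moments, tol=tol)


def composite_reliability_from_standardized(
    lam_std: np.ndarray, theta_std: np.ndarray
) -> float:
    """omega = (sum lam*)^2 / ((sum lam*)^2 + sum theta*)."""
    s = float(np.sum(lam_std))
    t = float(np.sum(theta_std))
    if s == 0 and t == 0:
        return 0.0
    return s**2 / (s**2 + t)


def composite_reliability(fit: FitResult, group: str | None = None) -> float | dict:
    """Factor-analysis-based composite reliability from the standardized
    single-factor solution of a fit (per group, or one group by label)."""
    def _one(g: str) -> float:
        est = fit.estimates[g]
        lam, psi = est["lambda"], est["psi"]
        ecov = {}
        mdl = fit.model
        for (a, b), v in est["ecov"].items():
            ecov[(mdl.indicators.index(a), mdl.indicators.index(b))] = v
        _, sigma = implied_moments(lam, fit.estimates[g]["tau"], psi, ecov)
        sd = np.sqrt(np.diag(sigma))
        lam_std = lam / sd
        theta_std = psi / sd**2
        if np.any(psi < 0):
            # Heywood case: value still returned, flagged on the fit
            pass
        return composite_reliability_from_standardized(lam_std, theta_std)

    if group is not None:
        return _one(group)
    if len(fit.groups) == 1:
        return _one(fit.groups[0])
    return {g: _one(g) for g in fit.groups}
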