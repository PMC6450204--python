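"""Crossed random-effects variance partition with a maternal x paternal
social-group covariance.

The model for a cub-level response y (ln paternity distance or binary
extra-group paternity, both analysed as Gaussian in SD units) is

    y = X beta + u_year + u_M + u_P + a_MSG + b_PSG + e

where M/P are dam/sire identities and MSG/PSG are the *same* social-group
factor entering in maternal and paternal role, with per-group effects
(a_g, b_g) ~ N(0, [[V_MSG, COV], [COV, V_PSG]]).  The sign of COV is the
diagnostic of interest: negative means groups that export paternity in one
role import it in the other (source-sink gene flow).

Estimation is restricted maximum likelihood on the dense marginal covariance
V(theta) = sum_k theta_k A_k (the A_k are precomputed factor-sharing
indicator matrices), with the group pair parameterized through its Cholesky
factor so the implied 2x2 covariance is always positive semi-definite.
Analytic REML gradients make desk-scale replicate studies cheap.  Downstream
utilities compute intraclass correlations, likelihood-ratio tests with
conservative df (= number of constrained parameters), conditional Wald
F-tests with Satterthwaite-type denominator df, and per-group BLUPs together
with r_MSG.PSG = COV/sqrt(V_MSG*V_PSG) and the source-sink regression slope
COV/V_MSG.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

COMPONENT_NAMES = ["v_year", "v_m", "v_p", "v_msg", "v_psg", "cov_msg_psg", "v_r"]

_LOG2PI = math.log(2 * math.pi)


class LmmError(ValueError):
    pass


@dataclass(frozen=True)
class LmmSpec:
    """Model specification: which random terms are present, plus constraints.

    ``equal_dam_sire`` shares one variance between dam and sire identities
    (the mother-vs-father comparison).  Dropping ``cov`` keeps independent
    group effects; dropping ``msg`` or ``psg`` removes that role's variance
    and, necessarily, the covariance.
    """

    response: str = "response"
    fixed: tuple[str, ...] = ()
    year: bool = True
    dam: bool = True
    sire: bool = True
    msg: bool = True
    psg: bool = True
    cov: bool = True
    equal_dam_sire: bool = False

    def __post_init__(self) -> None:
        if self.cov and not (self.msg and self.psg):
            object.__setattr__(self, "cov", False)
        if self.equal_dam_sire and not (self.dam and self.sire):
            raise LmmError("equal_dam_sire requires both dam and sire terms")

    def n_variance_params(self) -> int:
        n = 1  # residual
        n += self.year
        n += (1 if self.equal_dam_sire else self.dam + self.sire)
        n += self.msg + self.psg + self.cov
        return n


def preprocess_response(
    records: pd.DataFrame,
    response: str = "pd",
    delta: float = 1.0,
    sdu: bool = True,
) -> pd.DataFrame:
    """Attach a model-ready ``response`` column to a cub-record table.

    ``response='pd'`` uses ln(pd_i + delta) (the offset handles within-group
    cubs at distance 0; ln(0 + 1) = 0); ``response='egp'`` uses the binary
    indicator directly.  With ``sdu`` the response is divided by its sample
    standard deviation, so variance components are in SD units.
    """
    out = records.copy()
    if response == "pd":
        if (out["pd_i"] < 0).any():
            raise LmmError("pd_i must be >= 0")
        y = np.log(out["pd_i"].to_numpy(dtype=float) + delta)
    elif response == "egp":
        vals = set(out["egp_i"].dropna().unique())
        if not vals <= {0, 1}:
            raise LmmError("egp_i must be binary")
        y = out["egp_i"].to_numpy(dtype=float)
    else:
        raise LmmError("response must be 'pd' or 'egp'")
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise LmmError("response has zero variance")
    out["response"] = y / sd if sdu else y
    return out


# ---------------------------------------------------------------------------
# parameterization
# ---------------------------------------------------------------------------

_VAR_FLOOR = 1e-10


class _Parameterization:
    """Map an unconstrained vector x to the 7-component theta and back."""

    def __init__(self, spec: LmmSpec):
        self.spec = spec
        names: list[str] = []
        if spec.year:
            names.append("log_sd_year")
        if spec.equal_dam_sire:
            names.append("log_sd_ds")
        else:
            if spec.dam:
                names.append("log_sd_m")
            if spec.sire:
                names.append("log_sd_p")
        if spec.msg and spec.psg and spec.cov:
            names += ["chol_11", "chol_21", "chol_22"]
        else:
            if spec.msg:
                names.append("log_sd_msg")
            if spec.psg:
                names.append("log_sd_psg")
        names.append("log_sd_r")
        self.names = names
        self.n = len(names)

    def theta(self, x: np.ndarray) -> np.ndarray:
        s = self.spec
        th = np.zeros(7)
        i = 0
        if s.year:
            th[0] = math.exp(2 * x[i]); i += 1
        if s.equal_dam_sire:
            th[1] = th[2] = math.exp(2 * x[i]); i += 1
        else:
            if s.dam:
                th[1] = math.exp(2 * x[i]); i += 1
            if s.sire:
                th[2] = math.exp(2 * x[i]); i += 1
        if s.msg and s.psg and s.cov:
            l11, l21, l22 = math.exp(x[i]), x[i + 1], math.exp(x[i + 2])
            th[3] = l11**2
            th[5] = l11 * l21
            th[4] = l21**2 + l22**2
            i += 3
        else:
            if s.msg:
                th[3] = math.exp(2 * x[i]); i += 1
            if s.psg:
                th[4] = math.exp(2 * x[i]); i += 1
        th[6] = math.exp(2 * x[i])
        return th

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """J[k, j] = d theta_k / d x_j."""
        s = self.spec
        J = np.zeros((7, self.n))
        i = 0
        if s.year:
            J[0, i] = 2 * math.exp(2 * x[i]); i += 1
        if s.equal_dam_sire:
            J[1, i] = J[2, i] = 2 * math.exp(2 * x[i]); i += 1
        else:
            if s.dam:
                J[1, i] = 2 * math.exp(2 * x[i]); i += 1
            if s.sire:
                J[2, i] = 2 * math.exp(2 * x[i]); i += 1
        if s.msg and s.psg and s.cov:
            l11, l21, l22 = math.exp(x[i]), x[i + 1], math.exp(x[i + 2])
            J[3, i] = 2 * l11**2
            J[5, i] = l11 * l21
            J[5, i + 1] = l11
            J[4, i + 1] = 2 * l21
            J[4, i + 2] = 2 * l22**2
            i += 3
        else:
            if s.msg:
                J[3, i] = 2 * math.exp(2 * x[i]); i += 1
            if s.psg:
                J[4, i] = 2 * math.exp(2 * x[i]); i += 1
        J[6, i] = 2 * math.exp(2 * x[i])
        return J

    def x0(self, var_y: float) -> np.ndarray:
        """Heuristic start: split the response variance across components."""
        k = max(self.n, 2)
        v = var_y / k
        x = np.full(self.n, 0.5 * math.log(max(v, 1e-4)))
        for j, name in enumerate(self.names):
            if name == "chol_21":
                x[j] = 0.0
        return x


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


class _Problem:
    """Design matrices and factor-sharing kernels for one dataset."""

    def __init__(self, data: pd.DataFrame, spec: LmmSpec):
        cols = [spec.response, "cohort_year", "dam_id", "sire_id", "msg", "psg", *spec.fixed]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise LmmError(f"data lacks columns {missing}")
        sub = data[cols].dropna().reset_index(drop=True)
        dropped = len(data) - len(sub)
        if dropped:
            logger.info("dropped %d rows with missing response/covariates", dropped)
        n = len(sub)
        if n < 5:
            raise LmmError("too few complete rows to fit")
        self.data = sub
        self.n = n
        self.y = sub[spec.response].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(n)] + [sub[c].to_numpy(dtype=float) for c in spec.fixed]
        )
        self.fixed_names = ["intercept", *spec.fixed]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise LmmError("fixed-effect design matrix is rank-deficient")
        self.X = X
        self.p = X.shape[1]

        def codes(col: str) -> np.ndarray:
            return pd.Categorical(sub[col]).codes

        year_i = codes("cohort_year")
        dam_i = codes("dam_id")
        sire_i = codes("sire_id")
        grp_levels = pd.Categorical(
            pd.concat([sub["msg"], sub["psg"]], ignore_index=True)
        ).categories
        msg_i = pd.Categorical(sub["msg"], categories=grp_levels).codes
        psg_i = pd.Categorical(sub["psg"], categories=grp_levels).codes
        self.group_levels = list(grp_levels)
        self.factors = {"year": year_i, "dam": dam_i, "sire": sire_i, "msg": msg_i, "psg": psg_i}
        for name, need in [("year", spec.year), ("dam", spec.dam), ("sire", spec.sire)]:
            if need and len(np.unique(self.factors[name])) < 2:
                raise LmmError(f"random factor {name} has < 2 levels")

        def share(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            return (a[:, None] == b[None, :]).astype(float)

        cross = share(msg_i, psg_i)
        self.A = [
            share(year_i, year_i),
            share(dam_i, dam_i),
            share(sire_i, sire_i),
            share(msg_i, msg_i),
            share(psg_i, psg_i),
            cross + cross.T,
            np.eye(n),
        ]
        self.msg_i, self.psg_i = msg_i, psg_i

    def V(self, theta: np.ndarray) -> np.ndarray:
        V = theta[6] * self.A[6]
        for k in range(6):
            if theta[k] != 0.0:
                V += theta[k] * self.A[k]
        return V

    def reml(self, theta: np.ndarray, grad: bool = False):
        """Restricted log-likelihood (and its theta-gradient)."""
        V = self.V(theta)
        try:
            c, low = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return (-np.inf, np.zeros(7)) if grad else -np.inf
        logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
        Vi_y = cho_solve((c, low), self.y, check_finite=False)
        Vi_X = cho_solve((c, low), self.X, check_finite=False)
        C = self.X.T @ Vi_X
        sign, logdetC = np.linalg.slogdet(C)
        if sign <= 0:
            return (-np.inf, np.zeros(7)) if grad else -np.inf
        beta = np.linalg.solve(C, self.X.T @ Vi_y)
        Py = Vi_y - Vi_X @ beta
        quad = float(self.y @ Py)
        ll = -0.5 * (logdetV + logdetC + quad + (self.n - self.p) * _LOG2PI)
        if not grad:
            return ll
        Vi = cho_solve((c, low), np.eye(self.n), check_finite=False)
        Ci = np.linalg.inv(C)
        P = Vi - Vi_X @ Ci @ Vi_X.T
        g = np.empty(7)
        for k in range(7):
            Ak = self.A[k]
            g[k] = -0.5 * (float(np.sum(P * Ak)) - float(Py @ (Ak @ Py)))
        return ll, g

    def gls(self, theta: np.ndarray):
        """beta-hat, its covariance, V inverse and P at the given theta."""
        V = self.V(theta)
        c, low = cho_factor(V, lower=True, check_finite=False)
        Vi = cho_solve((c, low), np.eye(self.n), check_finite=False)
        C = self.X.T @ Vi @ self.X
        Ci = np.linalg.inv(C)
        beta = Ci @ (self.X.T @ (Vi @ self.y))
        P = Vi - Vi @ self.X @ Ci @ self.X.T @ Vi
        return beta, Ci, Vi, P


@dataclass
class LmmFit:
    """A converged (or flagged) REML fit."""

    spec: LmmSpec
    components: dict[str, float]
    component_se: dict[str, float] | None
    loglik: float
    converged: bool
    boundary: bool
    beta: pd.Series
    beta_se: pd.Series
    beta_cov: np.ndarray
    n: int
    p: int
    theta: np.ndarray = field(repr=False)
    x_opt: np.ndarray = field(repr=False)
    x_cov: np.ndarray | None = field(repr=False, default=None)
    _problem: _Problem | None = field(repr=False, default=None, compare=False)
    _param: _Parameterization | None = field(repr=False, default=None, compare=False)

    @property
    def r_msg_psg(self) -> float:
        v1, v2, c = (
            self.components["v_msg"],
            self.components["v_psg"],
            self.components["cov_msg_psg"],
        )
        denom = math.sqrt(v1 * v2)
        return c / denom if denom > 0 else 0.0

    @property
    def source_sink_slope(self) -> float:
        v = self.components["v_msg"]
        return self.components["cov_msg_psg"] / v if v > 0 else 0.0


def fit_lmm(
    data: pd.DataFrame,
    spec: LmmSpec = LmmSpec(),
    compute_se: bool = False,
    n_starts: int = 1,
    seed: int = 0,
) -> LmmFit:
    """REML fit of the crossed random-effects model.

    Variance parameters are optimized on an unconstrained scale (log-SDs;
    the MSG/PSG pair through its Cholesky factor, so the implied 2x2 matrix
    is positive semi-definite by construction) with analytic gradients.
    ``n_starts > 1`` adds dispersed restarts and keeps the best optimum.
    ``compute_se`` derives component SEs from a numerical Hessian of the
    restricted likelihood (needed for Satterthwaite denominator df).
    """
    prob = _Problem(data, spec)
    par = _Parameterization(spec)
    var_y = float(np.var(prob.y, ddof=1))

    def neg(x):
        ll, g = prob.reml(par.theta(x), grad=True)
        if not np.isfinite(ll):
            return 1e10, np.zeros(par.n)
        return -ll, -(par.jacobian(x).T @ g)

    starts = [par.x0(var_y)]
    rng = np.random.default_rng(seed)
    for _ in range(n_starts - 1):
        starts.append(par.x0(var_y) + rng.normal(0, 1.0, par.n))
    best = None
    for x0 in starts:
        res = minimize(
            neg, x0, jac=True, method="L-BFGS-B",
            bounds=[(-12.0, 8.0)] * par.n,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    x_opt = best.x
    theta = par.theta(x_opt)
    ll = -float(best.fun)
    converged = bool(best.success) or best.status == 0
    if not converged:
        logger.warning("REML optimizer did not report convergence: %s", best.message)

    variances = theta[[0, 1, 2, 3, 4, 6]]
    active = [
        th for th, present in zip(
            variances,
            [spec.year, spec.dam, spec.sire, spec.msg, spec.psg, True],
        ) if present
    ]
    total = float(np.sum(active))
    boundary = any(th < 1e-6 * max(total, 1e-12) for th in active)

    beta, Ci, _, _ = prob.gls(theta)
    components = dict(zip(COMPONENT_NAMES, theta))

    fit = LmmFit(
        spec=spec,
        components=components,
        component_se=None,
        loglik=ll,
        converged=converged,
        boundary=boundary,
        beta=pd.Series(beta, index=prob.fixed_names),
        beta_se=pd.Series(np.sqrt(np.diag(Ci)), index=prob.fixed_names),
        beta_cov=Ci,
        n=prob.n,
        p=prob.p,
        theta=theta,
        x_opt=x_opt,
        _problem=prob,
        _param=par,
    )
    if compute_se:
        _attach_se(fit)
    return fit


def _attach_se(fit: LmmFit) -> None:
    """Component SEs via the observed information of the restricted likelihood."""
    prob, par = fit._problem, fit._param
    x = fit.x_opt
    h = 1e-4
    H = np.zeros((par.n, par.n))
    for j in range(par.n):
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        _, gp = prob.reml(par.theta(xp), grad=True)
        _, gm = prob.reml(par.theta(xm), grad=True)
        H[:, j] = -(par.jacobian(xp).T @ gp - par.jacobian(xm).T @ gm) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        x_cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        x_cov = np.linalg.pinv(H)
    # near-boundary Hessians can be indefinite; keep the PSD projection
    w, Q = np.linalg.eigh(x_cov)
    x_cov = (Q * np.clip(w, 0, None)) @ Q.T
    J = par.jacobian(x)
    th_cov = J @ x_cov @ J.T
    fit.x_cov = x_cov
    fit.component_se = {
        name: float(math.sqrt(max(th_cov[k, k], 0.0)))
        for k, name in enumerate(COMPONENT_NAMES)
    }


# ---------------------------------------------------------------------------
# derived quantities and tests
# ---------------------------------------------------------------------------


def icc(fit: LmmFit) -> dict[str, float]:
    """Intraclass correlations: each variance over the summed variances.

    The MSG-PSG covariance is excluded from the denominator (variances only,
    residual included), so the ICCs are nonnegative and sum to 1.
    """
    keys = ["v_year", "v_m", "v_p", "v_msg", "v_psg", "v_r"]
    total = sum(fit.components[k] for k in keys)
    return {f"icc_{k[2:]}": fit.components[k] / total for k in keys}


def lrt(full: LmmFit, reduced: LmmFit, df: int | None = None) -> dict:
    """Likelihood-ratio test of nested REML fits.

    The statistic is floored at zero; df defaults to the number of
    additional (co)variance parameters in the full model -- the conservative
    convention that ignores boundary corrections.  Fixed effects must match
    for restricted likelihoods to be comparable.
    """
    if list(full.spec.fixed) != list(reduced.spec.fixed):
        raise LmmError("LRT requires identical fixed effects in both models")
    extra = full.spec.n_variance_params() - reduced.spec.n_variance_params()
    if extra < 0:
        raise LmmError("`reduced` has more variance parameters than `full`")
    if df is None:
        df = extra
    if df == 0 and full.loglik != reduced.loglik:
        df = 1
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    if stat == 0.0:
        p = 1.0
    return {"statistic": stat, "df": df, "p_value": p}


def wald_fixed(fit: LmmFit) -> pd.DataFrame:
    """Conditional Wald F-tests of the fixed effects.

    Each term is tested adjusted for all others: F = (beta/SE)^2 with 1
    numerator df.  Denominator df use a Satterthwaite-type approximation,
    2*v^2 / Var(v) with v the estimated sampling variance of beta and Var(v)
    obtained by the delta method from the variance-parameter covariance
    (requires ``compute_se=True`` at fit time; falls back to n - p).
    """
    prob, par = fit._problem, fit._param
    rows = []
    v_grad = None
    if fit.x_cov is not None:
        h = 1e-4
        grads = []
        for j in range(par.n):
            xp, xm = fit.x_opt.copy(), fit.x_opt.copy()
            xp[j] += h
            xm[j] -= h
            _, Cp, _, _ = prob.gls(par.theta(xp))
            _, Cm, _, _ = prob.gls(par.theta(xm))
            grads.append((np.diag(Cp) - np.diag(Cm)) / (2 * h))
        v_grad = np.stack(grads, axis=1)  # (p, n_par)
    for k, name in enumerate(fit.beta.index):
        b, se = fit.beta.iloc[k], fit.beta_se.iloc[k]
        F = (b / se) ** 2
        if v_grad is not None:
            var_v = float(v_grad[k] @ fit.x_cov @ v_grad[k])
            df2 = 2 * (se**2) ** 2 / var_v if var_v > 0 else fit.n - fit.p
            df2 = min(max(df2, 1.0), 10.0 * fit.n)
        else:
            df2 = float(fit.n - fit.p)
        rows.append(
            {
                "term": name,
                "estimate": b,
                "se": se,
                "F": F,
                "df1": 1,
                "df2": df2,
                "p_value": float(stats.f.sf(F, 1, df2)),
            }
        )
    return pd.DataFrame(rows)


def group_effects(fit: LmmFit) -> dict:
    """Per-group BLUPs of the maternal- and paternal-role effects.

    The reported correlation and source-sink slope come from the variance
    estimates themselves (COV/sqrt(V_MSG*V_PSG) and COV/V_MSG), not from
    regressing the BLUP point predictions, which are shrunken.
    """
    if not (fit.spec.msg and fit.spec.psg):
        raise LmmError("group_effects requires both group terms in the model")
    prob = fit._problem
    th = fit.components
    q = len(prob.group_levels)
    n = prob.n
    Z = np.zeros((n, 2 * q))
    Z[np.arange(n), prob.msg_i] = 1.0
    Z[np.arange(n), q + prob.psg_i] = 1.0
    G = np.zeros((2 * q, 2 * q))
    idx = np.arange(q)
    G[idx, idx] = th["v_msg"]
    G[q + idx, q + idx] = th["v_psg"]
    G[idx, q + idx] = th["cov_msg_psg"]
    G[q + idx, idx] = th["cov_msg_psg"]
    _, _, _, P = prob.gls(fit.theta)
    u = G @ Z.T @ P @ prob.y
    pred_cov = G - G @ Z.T @ P @ Z @ G
    se = np.sqrt(np.clip(np.diag(pred_cov), 0, None))
    table = pd.DataFrame(
        {
            "group_id": prob.group_levels,
            "maternal_blup": u[:q],
            "paternal_blup": u[q:],
            "maternal_se": se[:q],
            "paternal_se": se[q:],
        }
    )
    return {
        "blups": table,
        "r_msg_psg": fit.r_msg_psg,
        "slope": fit.source_sink_slope,
    }


# ---------------------------------------------------------------------------
# the standard battery of random-effect tests
# ---------------------------------------------------------------------------


def standard_tests(data: pd.DataFrame, spec: LmmSpec, full: LmmFit | None = None) -> pd.DataFrame:
    """LRTs of each random term against the full model.

    Year, dam and sire variances are tested with df = 1; each group role is
    tested by dropping its variance and the covariance (df = 2); the
    covariance alone with df = 1.  Also tests the dam-variance = sire-variance
    constraint (df = 1).
    """
    if full is None:
        full = fit_lmm(data, spec)
    rows = []
    reductions = [
        ("v_year", replace(spec, year=False), 1),
        ("v_m", replace(spec, dam=False, equal_dam_sire=False), 1),
        ("v_p", replace(spec, sire=False, equal_dam_sire=False), 1),
        ("v_msg", replace(spec, msg=False, cov=False), 2),
        ("v_psg", replace(spec, psg=False, cov=False), 2),
        ("cov_msg_psg", replace(spec, cov=False), 1),
        ("v_m_eq_v_p", replace(spec, equal_dam_sire=True), 1),
    ]
    for name, rspec, df in reductions:
        red = fit_lmm(data, rspec)
        res = lrt(full, red, df=df)
        rows.append({"term": name, **res})
    return pd.DataFrame(rows)
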