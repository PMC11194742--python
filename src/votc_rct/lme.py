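"""Mixed-effects contrasts for the RCT design, plus effect size and power.

The trial's inferential backbone is a linear mixed-effects (LME) model of
window-averaged evoked responses with dummy-coded fixed effects of group
(Letter vs Language, reference Language), condition (Words / Faces / Cars,
reference Words) and time (pre vs post, reference pre), and per-subject
random intercepts and slopes for the within-subject effects.  Wald t and F
statistics use Satterthwaite approximate (generally fractional) denominator
degrees of freedom.

Estimation is restricted maximum likelihood via ``statsmodels`` MixedLM.
The Satterthwaite layer (REML expected-information matrix for the variance
parameters, per-contrast df, and the eigenvector-averaged df for multi-df F
tests) is implemented here, since statsmodels exposes no denominator-df
approximation.  When a random-effects structure fails to converge, a
fallback ladder simplifies only the random part (never the fixed-effect
coding) down to ordinary least squares in the degenerate noise-free limit;
every step is recorded in ``convergence_report``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "LMEResult",
    "fit_threeway",
    "fit_group_by_time",
    "fit_condition_by_group_single_time",
    "cohens_d_two_sample",
    "two_sample_t_power",
    "validate_response_table",
]

_GROUP_REF = "Language"
_COND_REF = "Words"
_TIME_REF = "pre"

_GROUP = f"C(group, Treatment('{_GROUP_REF}'))"
_COND = f"C(condition, Treatment('{_COND_REF}'))"
_TIME = f"C(time, Treatment('{_TIME_REF}'))"


def _tidy(name: str) -> str:
    """Shorten patsy's treatment-coded coefficient names."""
    name = re.sub(r"C\((\w+), Treatment\('[^']*'\)\)\[T\.([^\]]+)\]", r"\1[\2]", name)
    return name


@dataclass
class LMEResult:
    """Coefficients, Wald tests and bookkeeping from one model fit."""

    coefficients: dict[str, float]
    t_statistics: dict[str, dict[str, float]]
    F_tests: dict[str, dict[str, float]]
    p_values: dict[str, float]
    convergence_report: list[str]
    random_structure_used: str
    method: str = "reml-mixed"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "t_statistics": self.t_statistics,
            "F_tests": self.F_tests,
            "p_values": self.p_values,
            "convergence_report": self.convergence_report,
            "random_structure_used": self.random_structure_used,
            "method": self.method,
            "extra": self.extra,
        }


def validate_response_table(
    table: pd.DataFrame,
    response: str = "response",
    within: tuple[str, ...] = ("condition", "time"),
) -> pd.DataFrame:
    """Check the long-format response table and return it.

    Requires subject/group columns, a numeric response, and a group label
    constant within subject.
    """
    needed = {"subject", "group", response, *within}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"response table is missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(table[response].to_numpy(dtype=float))):
        raise ValueError("non-finite responses")
    per_subj = table.groupby("subject")["group"].nunique()
    if (per_subj > 1).any():
        bad = per_subj[per_subj > 1].index[0]
        raise ValueError(f"group is not constant within subject {bad!r}")
    return table


# ---------------------------------------------------------------------------
# Satterthwaite machinery
# ---------------------------------------------------------------------------


class _SatterthwaiteLME:
    """GLS fixed effects + Satterthwaite df at the fitted REML variance
    parameters.

    Parameters are theta = (vech(G), sigma^2) where G is the random-effects
    covariance.  The variance of theta-hat comes from the inverse expected
    REML information I_jk = tr(P dV_j P dV_k) / 2 with
    P = Vinv - Vinv X (X' Vinv X)^-1 X' Vinv, evaluated blockwise per
    subject.
    """

    def __init__(self, X, y, Z, group_idx, names, G, sigma2):
        self.names = list(names)
        p = X.shape[1]
        q = Z.shape[1]
        tri = [(a, b) for a in range(q) for b in range(a + 1)]
        m = len(tri) + 1  # vech(G) + sigma^2

        XtVX = np.zeros((p, p))
        Xty = np.zeros(p)
        S = np.zeros((m, m))
        A = np.zeros((m, p, p))
        B = np.zeros((m, m, p, p))
        for idx in group_idx:
            Xi, yi, Zi = X[idx], y[idx], Z[idx]
            ni = Xi.shape[0]
            Vi = Zi @ G @ Zi.T + sigma2 * np.eye(ni)
            Vinv = np.linalg.inv(Vi)
            Ti = Xi.T @ Vinv  # p x ni
            XtVX += Ti @ Xi
            Xty += Ti @ yi
            dV = np.empty((m, ni, ni))
            for j, (a, b) in enumerate(tri):
                outer = np.outer(Zi[:, a], Zi[:, b])
                dV[j] = outer + outer.T if a != b else outer
            dV[-1] = np.eye(ni)
            W = np.einsum("xy,jyz->jxz", Vinv, dV)
            S += np.einsum("jxy,kyx->jk", W, W)
            TdV = np.einsum("an,jnm->jam", Ti, dV)
            A += np.einsum("jam,bm->jab", TdV, Ti)
            WT = np.einsum("jxy,ay->jxa", W, Ti)
            B += np.einsum("jam,kmb->jkab", TdV, WT)

        self.C = np.linalg.inv(XtVX)
        self.beta = self.C @ Xty
        self.A = A
        M = np.einsum("ab,jbc->jac", self.C, A)
        term2 = np.einsum("ab,jkba->jk", self.C, B)
        term3 = np.einsum("jab,kba->jk", M, M)
        info = 0.5 * (S - 2 * term2 + term3)
        self.theta_cov = np.linalg.pinv(info)

    def _df_for(self, l: np.ndarray, f: float) -> float:
        g = np.einsum("a,jab,b->j", l @ self.C, self.A, l @ self.C)
        denom = g @ self.theta_cov @ g
        if denom <= 0 or not np.isfinite(denom):
            return np.inf
        return 2.0 * f * f / denom

    def contrast_t(self, l: np.ndarray) -> dict[str, float]:
        l = np.asarray(l, dtype=float)
        est = float(l @ self.beta)
        f = float(l @ self.C @ l)
        se = np.sqrt(f)
        df = self._df_for(l, f)
        tval = est / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(tval), df) if np.isfinite(df) else 2 * stats.norm.sf(abs(tval))
        return {"estimate": est, "se": se, "t": tval, "df": float(df), "p": float(p)}

    def contrast_F(self, L: np.ndarray) -> dict[str, float]:
        L = np.atleast_2d(np.asarray(L, dtype=float))
        k = L.shape[0]
        Phi = L @ self.C @ L.T
        Lb = L @ self.beta
        Fval = float(Lb @ np.linalg.solve(Phi, Lb)) / k
        # eigenvector-averaged Satterthwaite df (lmerTest-style)
        evals, evecs = np.linalg.eigh(Phi)
        nus = []
        for i in range(k):
            li = evecs[:, i] @ L
            nu = self._df_for(li, float(evals[i]))
            nus.append(nu)
        nus = np.asarray(nus)
        finite = nus[np.isfinite(nus) & (nus > 2)]
        E = float(np.sum(finite / (finite - 2)))
        if E > k:
            df2 = 2 * E / (E - k)
        else:
            df2 = float(max(1.0, np.min(nus[np.isfinite(nus)]) if np.isfinite(nus).any() else 1.0))
        p = float(stats.f.sf(Fval, k, df2))
        return {"F": Fval, "df1": float(k), "df2": float(df2), "p": p}


class _FixedDfModel:
    """OLS backend with classical residual degrees of freedom."""

    def __init__(self, res):
        self.names = [_tidy(n) for n in res.model.exog_names]
        self.beta = np.asarray(res.params)
        self.C = np.asarray(res.cov_params())
        self.df = float(res.df_resid)

    def contrast_t(self, l):
        l = np.asarray(l, dtype=float)
        est = float(l @ self.beta)
        se = float(np.sqrt(l @ self.C @ l))
        tval = est / se if se > 0 else np.nan
        return {
            "estimate": est,
            "se": se,
            "t": tval,
            "df": self.df,
            "p": float(2 * stats.t.sf(abs(tval), self.df)),
        }

    def contrast_F(self, L):
        L = np.atleast_2d(np.asarray(L, dtype=float))
        k = L.shape[0]
        Lb = L @ self.beta
        Fval = float(Lb @ np.linalg.solve(L @ self.C @ L.T, Lb)) / k
        return {
            "F": Fval,
            "df1": float(k),
            "df2": self.df,
            "p": float(stats.f.sf(Fval, k, self.df)),
        }


class _DegenerateFit(Exception):
    """Residual variance numerically zero (noise-free data)."""


def _balanced_layout(X, y, Z, group_idx):
    """Stack per-subject blocks when all subjects share one Z design."""
    ni = len(group_idx[0])
    if any(len(ix) != ni for ix in group_idx):
        return None
    Zs = Z[group_idx[0]]
    for ix in group_idx[1:]:
        if not np.array_equal(Z[ix], Zs):
            return None
    Xg = np.stack([X[ix] for ix in group_idx])
    yg = np.stack([y[ix] for ix in group_idx])
    return Xg, yg, Zs


def _fast_balanced_reml(Xg, yg, Zs):
    """Profiled REML for balanced designs, vectorized over subjects.

    The random-effects covariance is parameterized through the Cholesky
    factor of ``Gamma = G / sigma^2``; the residual variance is profiled
    out.  Returns (G, sigma2, converged).
    """
    n_grp, ni, p = Xg.shape
    q = Zs.shape[1]
    N = n_grp * ni
    tril = np.tril_indices(q)
    y_scale = float(np.var(yg)) + 1e-300

    # per-fit cross products: every REML evaluation then only touches
    # ni x ni matrices
    Mxx = np.einsum("gia,gjb->ijab", Xg, Xg)
    Mxy = np.einsum("gia,gj->ija", Xg, yg)
    Myy = np.einsum("gi,gj->ij", yg, yg)

    def pieces(params):
        L = np.zeros((q, q))
        L[tril] = params
        V0 = np.eye(ni) + Zs @ (L @ L.T) @ Zs.T
        c, low = cho_factor(V0)
        logdet_v0 = 2.0 * np.sum(np.log(np.diag(c)))
        W = cho_solve((c, low), np.eye(ni))
        XtWX = np.einsum("ij,ijab->ab", W, Mxx)
        XtWy = np.einsum("ij,ija->a", W, Mxy)
        ytWy = float(np.einsum("ij,ij->", W, Myy))
        beta = np.linalg.solve(XtWX, XtWy)
        quad = ytWy - float(XtWy @ beta)
        return L, XtWX, quad, logdet_v0

    def crit(params):
        try:
            _, XtWX, quad, logdet_v0 = pieces(params)
        except np.linalg.LinAlgError:
            return 1e12
        sign, logdet_x = np.linalg.slogdet(XtWX)
        if sign <= 0 or quad <= 1e-12 * y_scale * N:
            return 1e12
        return n_grp * logdet_v0 + logdet_x + (N - p) * np.log(quad)

    x0 = np.zeros(len(tril[0]))
    x0[np.equal(*tril)] = 0.5  # diagonal start
    res = minimize(crit, x0, method="L-BFGS-B")
    L, _XtWX, quad, _ = pieces(res.x)
    if quad <= 1e-10 * y_scale * N:
        raise _DegenerateFit
    sigma2 = quad / (N - p)
    G = sigma2 * (L @ L.T)
    return G, sigma2, bool(res.success)


def _fit_ladder(data: pd.DataFrame, formula: str, re_ladder: list[str]):
    """Fit with REML, simplifying the random structure on failure.

    Returns (model backend, convergence report, structure label, method).
    """
    report: list[str] = []
    for re_formula in re_ladder:
        try:
            model = MixedLM.from_formula(
                formula, data, re_formula=re_formula, groups=data["subject"]
            )
            X = np.asarray(model.exog)
            Z = np.asarray(model.exog_re)
            y = np.asarray(model.endog, dtype=float)
            labels = np.asarray(model.group_labels)
            groups = np.asarray(model.groups)
            group_idx = [np.nonzero(groups == lab)[0] for lab in labels]

            G = sigma2 = None
            layout = _balanced_layout(X, y, Z, group_idx)
            if layout is not None:
                G, sigma2, fast_ok = _fast_balanced_reml(*layout)
                if not fast_ok:
                    G = sigma2 = None
                    report.append(
                        f"re=({re_formula}): balanced REML optimizer stalled; "
                        "retrying with MixedLM"
                    )
            if G is None:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    res = model.fit(reml=True, method="lbfgs", maxiter=200)
                ok = (
                    bool(res.converged)
                    and np.all(np.isfinite(res.fe_params))
                    and np.all(np.isfinite(np.asarray(res.cov_re)))
                    and np.isfinite(res.scale)
                    and res.scale > 0
                )
                notes = sorted(
                    {
                        type(w.message).__name__
                        for w in caught
                        if issubclass(
                            w.category, (ConvergenceWarning, RuntimeWarning, UserWarning)
                        )
                    }
                )
                if notes:
                    report.append(f"re=({re_formula}): warnings {notes}")
                if not ok:
                    report.append(f"re=({re_formula}): did not converge; simplifying")
                    continue
                G, sigma2 = np.asarray(res.cov_re), float(res.scale)
            backend = _SatterthwaiteLME(
                X, y, Z, group_idx,
                [_tidy(n) for n in model.exog_names],
                G, sigma2,
            )
            return backend, report, re_formula, "reml-mixed"
        except _DegenerateFit:
            report.append(
                f"re=({re_formula}): residual variance numerically zero"
            )
            break
        except (np.linalg.LinAlgError, ValueError, OverflowError) as err:
            report.append(f"re=({re_formula}): {type(err).__name__}; simplifying")
    # degenerate limit: ordinary least squares
    res = smf.ols(formula, data).fit()
    report.append("random effects dropped entirely; ordinary least squares")
    return _FixedDfModel(res), report, "none (OLS)", "ols"


def _indicator(names: list[str], weights: dict[str, float]) -> np.ndarray:
    l = np.zeros(len(names))
    for nm, w in weights.items():
        if nm not in names:
            raise ValueError(f"coefficient {nm!r} not in design: {names}")
        l[names.index(nm)] = w
    return l


def _collect(backend, rank_deficient_check=True) -> tuple[dict, dict, dict]:
    if rank_deficient_check and not np.all(np.isfinite(backend.C)):
        raise ValueError("rank-deficient design")
    coefficients, t_stats, p_values = {}, {}, {}
    for i, nm in enumerate(backend.names):
        l = np.zeros(len(backend.names))
        l[i] = 1.0
        ts = backend.contrast_t(l)
        coefficients[nm] = ts["estimate"]
        t_stats[nm] = ts
        p_values[nm] = ts["p"]
    return coefficients, t_stats, p_values


_RE_LADDER_FULL = [
    f"1 + {_COND} * {_TIME}",
    f"1 + {_COND} + {_TIME}",
    f"1 + {_TIME}",
    "1",
]


def fit_threeway(table: pd.DataFrame, re_ladder: list[str] | None = None) -> LMEResult:
    """Group x condition x time model with the maximal random structure.

    Fixed effects: full factorial with Words, pre and Language as reference
    levels.  Random effects: per-subject intercept and slopes for condition,
    time and their interaction (correlated), simplified by the fallback
    ladder only if estimation fails.  Reported tests: the 2-df omnibus
    three-way interaction F, and the per-contrast three-way t's for
    Words-vs-Cars and Words-vs-Faces.
    """
    validate_response_table(table)
    for col, lv in (("time", 2), ("group", 2)):
        if table[col].nunique() != lv:
            raise ValueError(f"need both levels of {col!r}")
    if table.groupby("group")["subject"].nunique().min() < 2:
        raise ValueError("need >= 2 subjects per group")
    formula = f"response ~ {_GROUP} * {_COND} * {_TIME}"
    backend, report, structure, method = _fit_ladder(
        table, formula, re_ladder if re_ladder is not None else _RE_LADDER_FULL
    )
    coefficients, t_stats, p_values = _collect(backend)
    names = backend.names
    c3_faces = "group[Letter]:condition[Faces]:time[post]"
    c3_cars = "group[Letter]:condition[Cars]:time[post]"
    L3 = np.vstack(
        [_indicator(names, {c3_faces: 1.0}), _indicator(names, {c3_cars: 1.0})]
    )
    F_tests = {"group:condition:time": backend.contrast_F(L3)}
    extra = {
        "threeway_words_vs_cars": t_stats[c3_cars],
        "threeway_words_vs_faces": t_stats[c3_faces],
    }
    return LMEResult(
        coefficients, t_stats, F_tests, p_values, report, structure, method, extra
    )


def fit_group_by_time(
    table: pd.DataFrame, response: str = "response"
) -> LMEResult:
    """Group x time model for one condition or one behavioral measure.

    Returns the group-by-time interaction t and, in ``extra``, the
    within-group time slopes from separate per-group fits ("modeling
    intervention-driven growth separately for each group").
    """
    validate_response_table(table, response=response, within=("time",))
    data = table.rename(columns={response: "response"}) if response != "response" else table
    formula = f"response ~ {_GROUP} * {_TIME}"
    ladder = [f"1 + {_TIME}", "1"]
    backend, report, structure, method = _fit_ladder(data, formula, ladder)
    coefficients, t_stats, p_values = _collect(backend)
    extra = {"group_by_time": t_stats["group[Letter]:time[post]"]}
    for grp in ("Letter", "Language"):
        sub = data[data["group"] == grp]
        b2, rep2, _, _ = _fit_ladder(sub, f"response ~ {_TIME}", ladder)
        ts = b2.contrast_t(_indicator(b2.names, {"time[post]": 1.0}))
        extra[f"time_within_{grp}"] = ts
        report.extend(f"[{grp}] {r}" for r in rep2)
    return LMEResult(
        coefficients, t_stats, {}, p_values, report, structure, method, extra
    )


def fit_condition_by_group_single_time(table: pd.DataFrame) -> LMEResult:
    """Condition x group model at a single time point.

    Reports Type-III style main-effect F's for condition and group
    (marginal means averaged over the other factor under dummy coding), the
    group x condition interaction F, and the pairwise group-difference t's
    for the Words-Cars and Words-Faces selectivity contrasts.
    """
    validate_response_table(table, within=("condition",))
    if table["time"].nunique() != 1:
        raise ValueError("table must contain a single time point")
    formula = f"response ~ {_GROUP} * {_COND}"
    ladder = [f"1 + {_COND}", "1"]
    backend, report, structure, method = _fit_ladder(table, formula, ladder)
    coefficients, t_stats, p_values = _collect(backend)
    names = backend.names
    gf = "group[Letter]:condition[Faces]"
    gc = "group[Letter]:condition[Cars]"
    # condition marginal effect averaged over the two groups
    L_cond = np.vstack(
        [
            _indicator(names, {"condition[Faces]": 1.0, gf: 0.5}),
            _indicator(names, {"condition[Cars]": 1.0, gc: 0.5}),
        ]
    )
    # group marginal effect averaged over the three conditions
    L_group = _indicator(
        names, {"group[Letter]": 1.0, gf: 1.0 / 3.0, gc: 1.0 / 3.0}
    )[None, :]
    L_int = np.vstack([_indicator(names, {gf: 1.0}), _indicator(names, {gc: 1.0})])
    F_tests = {
        "condition": backend.contrast_F(L_cond),
        "group": backend.contrast_F(L_group),
        "group:condition": backend.contrast_F(L_int),
    }
    extra = {
        "group_diff_words_vs_cars": t_stats[gc],
        "group_diff_words_vs_faces": t_stats[gf],
    }
    return LMEResult(
        coefficients, t_stats, F_tests, p_values, report, structure, method, extra
    )


# ---------------------------------------------------------------------------
# Effect size and power
# ---------------------------------------------------------------------------


def cohens_d_two_sample(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Cohen's d with the equal-n pooled SD, sqrt((sd1^2 + sd2^2)/2)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    pooled = np.sqrt((sd1**2 + sd2**2) / 2.0)
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((mean1 - mean2) / pooled)


def two_sample_t_power(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test via the noncentral t.

    Noncentrality ``d * sqrt(n/2)``, df ``2n - 2``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    df = 2 * n_per_group - 2
    nc = d * np.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    upper = stats.nct.sf(tcrit, df, nc)
    lower = stats.nct.cdf(-tcrit, df, nc)
    # scipy's nct tail can underflow to nan far from the noncentrality
    if not np.isfinite(upper):
        upper = 1.0 if nc > tcrit else 0.0
    if not np.isfinite(lower):
        lower = 1.0 if nc < -tcrit else 0.0
    return float(upper + lower)
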