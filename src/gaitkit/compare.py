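"""Mixed-model comparison of kinematic metrics across condition groups.

For each per-stride metric the model is a linear mixed model with two
crossed binary fixed factors — skin-disease presence and snare-wound
presence — and a random intercept for individual-within-clip:

    y_ij = b0 + b1 * gsd_i + b2 * snare_i (+ b3 * speed_ij) + u_i + e_ij

with u_i ~ N(0, tau^2) per grouping unit and e_ij ~ N(0, sigma^2),
fitted by REML.  Relative speed enters as a (grand-mean-centred)
covariate for the mean-NSL and neck-ROM models, where speed is a known
confounder.  The factors are additive (no interaction), so the four
condition cells (healthy / disease / snare / both) are linear functions
of the coefficients; marginal (Type III) F tests for the two 1-df factors
reduce to squared t statistics.

Denominator degrees of freedom use the Satterthwaite approximation,
computed from the curvature of the REML log-likelihood in the variance
parameters: for a contrast ``L`` with variance ``f(theta) = L C(theta) L'``
(``C`` the fixed-effect covariance), ``df = 2 f^2 / (g' A g)`` where ``g``
is the gradient of ``f`` and ``A`` the asymptotic covariance of the
variance-parameter estimates.  When a variance component is estimated at
the boundary the model falls back to residual df with a logged flag.

Estimated marginal means (EMMs) are reported per condition cell at the
covariate grand mean; the six pairwise condition contrasts are adjusted
by the Benjamini-Hochberg false discovery rate.

Usage follows the model/results convention::

    model = ConditionModel.from_dataframe(metrics, "relative_stride_length")
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.numdiff import approx_fprime, approx_hess

logger = logging.getLogger("gaitkit")

#: Metrics for which relative speed is a covariate.
SPEED_COVARIATE_METRICS = frozenset({"mean_nsl", "rom_deg"})

CONDITION_CELLS = (
    ("healthy", 0, 0),
    ("gsd", 1, 0),
    ("snare", 0, 1),
    ("gsd_snare", 1, 1),
)


class ModelSpecificationError(ValueError):
    """The data cannot support the requested model."""


class ConvergenceError(RuntimeError):
    """The REML optimizer failed; carries optimizer diagnostics."""


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up FDR adjustment (thin wrapper kept as the single entry
    point so the whole package shares one correction routine)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


class _RandomInterceptREML:
    """REML log-likelihood machinery for a single-random-intercept LMM.

    Used only for the Satterthwaite computation on top of the statsmodels
    fit: it evaluates the profiled REML log-likelihood and the GLS
    fixed-effect covariance at any (sigma2, tau2), which statsmodels does
    not expose as a function of the variance parameters.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> None:
        self.X, self.y = X, y
        self.blocks = [np.flatnonzero(groups == g) for g in np.unique(groups)]
        self.n, self.p = X.shape

    def _assemble(self, sigma2: float, tau2: float):
        XtViX = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        ytViy = 0.0
        logdet = 0.0
        for idx in self.blocks:
            Xi, yi = self.X[idx], self.y[idx]
            ni = len(idx)
            denom = sigma2 + ni * tau2
            c = tau2 / denom
            x1 = Xi.sum(axis=0)
            y1 = yi.sum()
            XtViX += (Xi.T @ Xi - c * np.outer(x1, x1)) / sigma2
            XtViy += (Xi.T @ yi - c * x1 * y1) / sigma2
            ytViy += (yi @ yi - c * y1 * y1) / sigma2
            logdet += (ni - 1) * np.log(sigma2) + np.log(denom)
        return XtViX, XtViy, ytViy, logdet

    def cov_beta(self, theta: np.ndarray) -> np.ndarray:
        XtViX, _, _, _ = self._assemble(theta[0], theta[1])
        return np.linalg.inv(XtViX)

    def beta(self, theta: np.ndarray) -> np.ndarray:
        XtViX, XtViy, _, _ = self._assemble(theta[0], theta[1])
        return np.linalg.solve(XtViX, XtViy)

    def neg_reml_loglik(self, theta: np.ndarray) -> float:
        sigma2, tau2 = theta
        if sigma2 <= 0 or tau2 < 0:
            return np.inf
        XtViX, XtViy, ytViy, logdet = self._assemble(sigma2, tau2)
        beta = np.linalg.solve(XtViX, XtViy)
        rss = ytViy - beta @ XtViy
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        return 0.5 * (logdet + logdet_x + rss)


@dataclass
class ConditionResults:
    """Fitted comparison for one metric (returned by ConditionModel.fit)."""

    metric: str
    params: pd.Series
    cov_params: pd.DataFrame
    sigma2: float
    tau2: float
    nobs: int
    ngroups: int
    anova: pd.DataFrame
    emmeans: pd.DataFrame
    pairwise: pd.DataFrame
    covariate_used: bool
    satterthwaite: bool
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Condition comparison: {self.metric}",
            "=" * 60,
            f"N strides: {self.nobs}    grouping units: {self.ngroups}",
            f"residual var: {self.sigma2:.6g}    intercept var: {self.tau2:.6g}",
            f"speed covariate: {'yes' if self.covariate_used else 'no'}    "
            f"denominator df: {'Satterthwaite' if self.satterthwaite else 'residual (fallback)'}",
            "",
            "Fixed-effect (Type III) tests",
            self.anova.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
            "Estimated marginal means (95% CI)",
            self.emmeans.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
            "Pairwise contrasts (BH-adjusted)",
            self.pairwise.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        if self.notes:
            lines += [""] + [f"note: {n}" for n in self.notes]
        return "\n".join(lines)


class ConditionModel:
    """Linear mixed model of one kinematic metric on condition factors.

    Parameters
    ----------
    data
        Per-stride table with columns ``gsd_present``, ``snare_present``,
        ``clip_id``, ``individual_id``, the metric column and, when the
        speed covariate is used, ``relative_speed``.
    metric
        Name of the response column.
    use_speed_covariate
        Override the default covariate rule (speed enters for mean NSL
        and neck ROM).
    grouping
        ``"clip_individual"`` (default, individual nested within clip) or
        ``"individual"``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        metric: str,
        use_speed_covariate: bool | None = None,
        grouping: str = "clip_individual",
    ) -> None:
        if metric not in data.columns:
            raise ModelSpecificationError(f"metric column {metric!r} not in data")
        if grouping not in ("clip_individual", "individual"):
            raise ModelSpecificationError(f"unknown grouping {grouping!r}")
        data = data.dropna(subset=[metric]).copy()
        if use_speed_covariate is None:
            use_speed_covariate = metric in SPEED_COVARIATE_METRICS
        if use_speed_covariate and "relative_speed" not in data.columns:
            raise ModelSpecificationError(
                "speed covariate requested but no relative_speed column"
            )
        self.data = data
        self.metric = metric
        self.use_speed_covariate = bool(use_speed_covariate)
        self.grouping = grouping

        if grouping == "clip_individual":
            self.group_labels = (
                data["clip_id"].astype(str) + "/" + data["individual_id"].astype(str)
            ).to_numpy()
        else:
            self.group_labels = data["individual_id"].astype(str).to_numpy()

        conds = set(zip(data["gsd_present"].astype(int), data["snare_present"].astype(int)))
        if len(conds) < 2:
            raise ModelSpecificationError("need at least 2 condition cells present")
        if len(np.unique(data["individual_id"].astype(str))) < 2:
            raise ModelSpecificationError(
                "need at least 2 individuals for a random-intercept model"
            )

        cols = {"const": np.ones(len(data))}
        cols["gsd"] = data["gsd_present"].astype(float).to_numpy()
        cols["snare"] = data["snare_present"].astype(float).to_numpy()
        if self.use_speed_covariate:
            speed = data["relative_speed"].astype(float).to_numpy()
            self._speed_mean = float(speed.mean())
            cols["speed_c"] = speed - self._speed_mean
        self.exog_names = list(cols)
        self.X = np.column_stack(list(cols.values()))
        self.y = data[self.metric].astype(float).to_numpy()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, metric: str, **kwargs) -> "ConditionModel":
        return cls(data, metric, **kwargs)

    # ---- fitting -----------------------------------------------------

    def fit(self) -> ConditionResults:
        if np.ptp(self.y) == 0.0:
            return self._degenerate_results(float(self.y[0]))

        reml = _RandomInterceptREML(self.X, self.y, self.group_labels)
        sigma2, tau2 = self._fit_theta(reml)
        theta = np.array([sigma2, tau2])
        beta = reml.beta(theta)
        C = reml.cov_beta(theta)

        satter, A, notes = self._variance_param_cov(reml, theta)
        n, p = self.X.shape
        resid_df = float(n - p)

        def contrast_stats(L: np.ndarray) -> tuple[float, float, float]:
            """(estimate, se, df) for the scalar contrast L @ beta."""
            est = float(L @ beta)
            f_val = float(L @ C @ L)
            se = np.sqrt(f_val)
            if satter:
                g = approx_fprime(
                    theta, lambda th: float(L @ reml.cov_beta(th) @ L), centered=True
                )
                denom = float(g @ A @ g)
                df = 2.0 * f_val**2 / denom if denom > 0 else resid_df
                df = float(np.clip(df, 1.0, resid_df))
            else:
                df = resid_df
            return est, se, df

        anova = self._anova(contrast_stats)
        emmeans = self._emmeans(contrast_stats)
        pairwise = self._pairwise(contrast_stats)

        return ConditionResults(
            metric=self.metric,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(C, index=self.exog_names, columns=self.exog_names),
            sigma2=sigma2,
            tau2=tau2,
            nobs=n,
            ngroups=len(np.unique(self.group_labels)),
            anova=anova,
            emmeans=emmeans,
            pairwise=pairwise,
            covariate_used=self.use_speed_covariate,
            satterthwaite=satter,
            notes=notes,
        )

    def _fit_theta(self, reml: _RandomInterceptREML) -> tuple[float, float]:
        """REML variance-parameter estimates (sigma2, tau2).

        Primary path is statsmodels MixedLM; when its optimizer fails on a
        near-boundary variance ratio, the same profiled REML objective is
        minimized directly (Nelder-Mead in log-variance space, which cannot
        leave the parameter domain).
        """
        import warnings

        try:
            # convergence is checked explicitly; statsmodels' boundary
            # warning fires even at interior optima
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = MixedLM(self.y, self.X, groups=self.group_labels).fit(
                    reml=True, method=["lbfgs", "powell"]
                )
            if res.converged:
                return float(res.scale), float(np.asarray(res.cov_re)[0, 0])
            diag = res.mle_retvals
        except (np.linalg.LinAlgError, ValueError) as exc:
            diag = exc
        logger.info("%s: statsmodels optimizer failed (%s); refitting directly", self.metric, diag)

        var0 = float(np.var(self.y, ddof=1))
        from scipy.optimize import minimize

        best = None
        for frac in (0.5, 0.05, 0.95):
            opt = minimize(
                lambda x: reml.neg_reml_loglik(np.exp(x)),
                x0=np.log([max(var0 * (1 - frac), 1e-10), max(var0 * frac, 1e-10)]),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
            )
            if best is None or opt.fun < best.fun:
                best = opt
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError(
                f"REML optimization failed for {self.metric}: {best}"
            )
        sigma2, tau2 = np.exp(best.x)
        return float(sigma2), float(tau2)

    def _variance_param_cov(self, reml: _RandomInterceptREML, theta: np.ndarray):
        """Asymptotic covariance of (sigma2, tau2) from the REML Hessian;
        falls back (with a logged note) near the tau2 = 0 boundary or if
        the Hessian is not positive definite."""
        notes: list[str] = []
        if theta[1] < 1e-8 * max(theta[0], 1e-12):
            msg = (
                f"{self.metric}: random-intercept variance at boundary; "
                "using residual-df approximation instead of Satterthwaite"
            )
            logger.warning(msg)
            notes.append(msg)
            return False, None, notes
        H = approx_hess(theta, reml.neg_reml_loglik)
        try:
            eigv = np.linalg.eigvalsh(H)
            if eigv.min() <= 0:
                raise np.linalg.LinAlgError("non-PD REML Hessian")
            A = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            msg = (
                f"{self.metric}: REML information matrix not positive definite; "
                "using residual-df approximation instead of Satterthwaite"
            )
            logger.warning(msg)
            notes.append(msg)
            return False, None, notes
        return True, A, notes

    # ---- summaries ---------------------------------------------------

    def _cell_vector(self, gsd: int, snare: int) -> np.ndarray:
        L = np.zeros(self.X.shape[1])
        L[0] = 1.0
        L[1] = gsd
        L[2] = snare
        # covariate column stays 0: EMMs are at the covariate grand mean
        return L

    def _anova(self, contrast_stats) -> pd.DataFrame:
        rows = []
        for name, col in (("gsd", 1), ("snare", 2)):
            L = np.zeros(self.X.shape[1])
            L[col] = 1.0
            est, se, df = contrast_stats(L)
            F = (est / se) ** 2
            rows.append(
                {
                    "factor": name,
                    "F": F,
                    "df_num": 1.0,
                    "df_den": df,
                    "p": float(stats.f.sf(F, 1.0, df)),
                }
            )
        return pd.DataFrame(rows)

    def _emmeans(self, contrast_stats) -> pd.DataFrame:
        rows = []
        for cond, g, s in CONDITION_CELLS:
            est, se, df = contrast_stats(self._cell_vector(g, s))
            tcrit = stats.t.ppf(0.975, df)
            rows.append(
                {
                    "condition": cond,
                    "estimate": est,
                    "se": se,
                    "df": df,
                    "ci_low": est - tcrit * se,
                    "ci_high": est + tcrit * se,
                }
            )
        return pd.DataFrame(rows)

    def _pairwise(self, contrast_stats) -> pd.DataFrame:
        rows = []
        for (ca, ga, sa), (cb, gb, sb) in itertools.combinations(CONDITION_CELLS, 2):
            L = self._cell_vector(ga, sa) - self._cell_vector(gb, sb)
            est, se, df = contrast_stats(L)
            t = est / se if se > 0 else 0.0
            rows.append(
                {
                    "pair": f"{ca} - {cb}",
                    "estimate": est,
                    "se": se,
                    "df": df,
                    "t": t,
                    "p_raw": float(2 * stats.t.sf(abs(t), df)),
                }
            )
        out = pd.DataFrame(rows)
        out["p_fdr"] = benjamini_hochberg(out["p_raw"].to_numpy())
        return out

    def _degenerate_results(self, c: float) -> ConditionResults:
        """All responses identical: every EMM is c, all contrasts 0."""
        p = self.X.shape[1]
        names = self.exog_names
        params = pd.Series(np.r_[c, np.zeros(p - 1)], index=names)
        emm = pd.DataFrame(
            {
                "condition": [cell[0] for cell in CONDITION_CELLS],
                "estimate": c,
                "se": 0.0,
                "df": float(len(self.y) - p),
                "ci_low": c,
                "ci_high": c,
            }
        )
        pairs = [
            f"{a} - {b}"
            for (a, _, _), (b, _, _) in itertools.combinations(CONDITION_CELLS, 2)
        ]
        pairwise = pd.DataFrame(
            {
                "pair": pairs,
                "estimate": 0.0,
                "se": 0.0,
                "df": float(len(self.y) - p),
                "t": 0.0,
                "p_raw": 1.0,
                "p_fdr": 1.0,
            }
        )
        anova = pd.DataFrame(
            {
                "factor": ["gsd", "snare"],
                "F": 0.0,
                "df_num": 1.0,
                "df_den": float(len(self.y) - p),
                "p": 1.0,
            }
        )
        return ConditionResults(
            metric=self.metric,
            params=params,
            cov_params=pd.DataFrame(np.zeros((p, p)), index=names, columns=names),
            sigma2=0.0,
            tau2=0.0,
            nobs=len(self.y),
            ngroups=len(np.unique(self.group_labels)),
            anova=anova,
            emmeans=emm,
            pairwise=pairwise,
            covariate_used=self.use_speed_covariate,
            satterthwaite=False,
            notes=["constant response: degenerate fit"],
        )


def summarize_by_condition(
    metric_table: pd.DataFrame, metrics: list[str] | None = None
) -> pd.DataFrame:
    """Stride-level mean and sample SD per condition per metric.

    SD is reported as missing for single-stride conditions; empty
    conditions are omitted with a logged warning.
    """
    if metric_table.empty:
        raise ValueError("metric table is empty")
    if metrics is None:
        exclude = {
            "clip_id",
            "individual_id",
            "stride_index",
            "condition",
            "gsd_present",
            "snare_present",
        }
        metrics = [
            c
            for c in metric_table.columns
            if c not in exclude and pd.api.types.is_numeric_dtype(metric_table[c])
        ]
    present = set(metric_table["condition"].unique())
    for cond, *_ in CONDITION_CELLS:
        if cond not in present:
            logger.warning("condition %s has no strides; omitted from summary", cond)
    rows = []
    for cond, grp in metric_table.groupby("condition", sort=True):
        for m in metrics:
            vals = grp[m].dropna()
            rows.append(
                {
                    "condition": cond,
                    "metric": m,
                    "n": len(vals),
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
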