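"""Mediation path models: pairwise, parallel and serial configurations.

The effect of an exposure X on an outcome Y is decomposed through one or
two mediators M using a recursive system of regression equations

    Y = i1 + c*X + e1                      (total effect)
    Y = i2 + c'*X + b*M + e2               (direct effect, outcome eq.)
    M = i3 + a*X + e3                      (mediator eq.)

so the indirect effect is the product a*b and, for a continuous
outcome, total = c' + a*b = c exactly on the same estimation sample.
With two mediators the parallel form adds a2/b2 and the serial form a
mediator-to-mediator path d, contributing the chained product a1*d*b2.

Estimation is equation-by-equation (OLS for linear equations, ML
logistic for a binary outcome equation), which for this recursive
observed-variable system coincides with joint ML in the linear case.
Inference on the composite effects uses nonparametric case-resampling
bootstrap with percentile intervals; binary outcomes additionally get
probability-scale average mediation effects via the potential-outcomes
simulation estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MediationSpec",
    "MediationModel",
    "MediationResults",
    "fit_paths",
    "bootstrap_effects",
    "nested_model_test",
    "vif_screen",
    "bh_fdr",
    "run_mediation_grid",
]

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
BINARY = "binary-logistic"


@dataclass
class MediationSpec:
    """Configuration of one exposure-mediator(s)-outcome analysis.

    ``configuration`` is inferred from the mediator count when omitted
    (one mediator -> pairwise, two -> parallel); serial ordering follows
    the order of ``mediators``.
    """

    exposure: str
    mediators: Sequence[str]
    outcome: str
    outcome_family: str = CONTINUOUS
    confounders: Sequence[str] = ()
    configuration: str | None = None
    bootstrap_draws: int = 5000
    seed: int | None = None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        self.mediators = tuple(self.mediators)
        self.confounders = tuple(self.confounders)
        if self.configuration is None:
            self.configuration = "pairwise" if len(self.mediators) == 1 else "parallel"
        if self.configuration == "pairwise" and len(self.mediators) != 1:
            raise ValueError("pairwise mediation requires exactly 1 mediator")
        if self.configuration in ("parallel", "serial") and len(self.mediators) != 2:
            raise ValueError(f"{self.configuration} mediation requires exactly 2 mediators")
        if self.configuration not in ("pairwise", "parallel", "serial"):
            raise ValueError(f"unknown configuration {self.configuration!r}")
        if self.outcome_family not in (CONTINUOUS, BINARY):
            raise ValueError(f"unknown outcome family {self.outcome_family!r}")
        if self.bootstrap_draws < 1:
            raise ValueError("bootstrap draws must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("CI level must be in (0, 1)")

    @property
    def variables(self) -> list[str]:
        return [self.exposure, *self.mediators, *self.confounders, self.outcome]


def _logit_irls(X: np.ndarray, y: np.ndarray, maxiter: int = 50, tol: float = 1e-10):
    """Newton-Raphson logistic fit; returns coefficients or None on failure."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        grad = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return None
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            if np.max(np.abs(beta)) > 1e3:  # quasi-separation
                return None
            return beta
    return None


class MediationModel:
    """Recursive path model for one exposure-mediator(s)-outcome triple.

    Parameters
    ----------
    data
        Cohort table holding every variable named in ``spec``.  Rows
        with a missing value in any in-model variable are dropped
        (complete-case analysis); the count is recorded.
    spec
        A :class:`MediationSpec`.
    """

    def __init__(self, data: pd.DataFrame, spec: MediationSpec):
        missing_cols = [v for v in spec.variables if v not in data.columns]
        if missing_cols:
            raise KeyError(f"columns not in data: {missing_cols}")
        self.spec = spec
        sub = data[spec.variables].apply(pd.to_numeric)
        complete = sub.dropna()
        self.n_dropped = len(sub) - len(complete)
        if self.n_dropped:
            logger.info("dropped %d incomplete cases", self.n_dropped)
        self.data = complete.reset_index(drop=True)
        self.nobs = len(self.data)
        if self.nobs < len(spec.variables) + 2:
            raise ValueError("too few complete cases to fit the path system")
        if self.data[spec.exposure].nunique() < 2:
            raise ValueError("exposure has zero variance; paths are not identified")
        if spec.outcome_family == BINARY:
            uniq = set(self.data[spec.outcome].unique())
            if not uniq <= {0, 1}:
                raise ValueError("binary-logistic outcome must be coded 0/1")
        self._build_design()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, exposure: str, mediators, outcome: str,
                       **spec_kwargs) -> "MediationModel":
        return cls(data, MediationSpec(exposure, mediators, outcome, **spec_kwargs))

    # -- design ---------------------------------------------------------

    def _build_design(self) -> None:
        s = self.spec
        cols = ["const", s.exposure, *s.mediators, *s.confounders, s.outcome]
        W = np.column_stack(
            [np.ones(self.nobs)]
            + [self.data[c].to_numpy(float) for c in cols[1:]]
        )
        self._W = W
        self._col = {name: i for i, name in enumerate(cols)}
        c = self._col
        conf = [c[v] for v in s.confounders]
        xc = [c["const"], c[s.exposure]] + conf
        m_idx = [c[m] for m in s.mediators]
        # (response index, predictor indices) per equation
        self._equations: dict[str, tuple[int, list[int]]] = {
            "m1": (m_idx[0], xc),
        }
        if len(s.mediators) == 2:
            if s.configuration == "serial":
                self._equations["m2"] = (m_idx[1], [c["const"], m_idx[0], c[s.exposure]] + conf)
            else:
                self._equations["m2"] = (m_idx[1], xc)
        self._equations["y"] = (c[s.outcome], [c["const"], c[s.exposure]] + m_idx + conf)
        self._equations["total"] = (c[s.outcome], xc)

    # -- fitting --------------------------------------------------------

    def fit(self, bootstrap: bool = True) -> "MediationResults":
        """Fit every path equation; optionally bootstrap the effects."""
        s = self.spec
        eqfits: dict[str, object] = {}
        for name, (resp, preds) in self._equations.items():
            y = self._W[:, resp]
            X = self._W[:, preds]
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError(f"rank-deficient design in equation {name!r}")
            if s.outcome_family == BINARY and name in ("y", "total"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(y, X).fit(disp=0, maxiter=100)
                if not res.mle_retvals.get("converged", False):
                    raise RuntimeError(
                        f"logistic fit for equation {name!r} did not converge "
                        "(possible separation)"
                    )
            else:
                res = sm.OLS(y, X).fit()
            eqfits[name] = res

        paths = self._extract_paths(eqfits)
        effects = self._compose_effects(paths)
        boot = self._bootstrap(effects.index) if bootstrap else None
        return MediationResults(self, eqfits, paths, effects, boot)

    def _path_positions(self) -> dict[str, tuple[str, int]]:
        """Map path name -> (equation, coefficient position in that eq)."""
        s = self.spec
        pos: dict[str, tuple[str, int]] = {}
        if len(s.mediators) == 1:
            pos["a"] = ("m1", 1)
            pos["b"] = ("y", 2)
        else:
            pos["a1"] = ("m1", 1)
            if s.configuration == "serial":
                pos["d"] = ("m2", 1)
                pos["a2"] = ("m2", 2)
            else:
                pos["a2"] = ("m2", 1)
            pos["b1"] = ("y", 2)
            pos["b2"] = ("y", 3)
        pos["c_prime"] = ("y", 1)
        pos["c_total"] = ("total", 1)
        return pos

    def _extract_paths(self, eqfits) -> pd.DataFrame:
        rows = {}
        for name, (eq, j) in self._path_positions().items():
            res = eqfits[eq]
            rows[name] = {
                "estimate": res.params[j],
                "se": res.bse[j],
                "p": res.pvalues[j],
            }
        return pd.DataFrame(rows).T

    def _effects_from_coefvec(self, coef: dict[str, float]) -> dict[str, float]:
        """Compose indirect/direct/total effects from raw path values."""
        s = self.spec
        eff: dict[str, float] = {}
        if len(s.mediators) == 1:
            eff[f"indirect_{s.mediators[0]}"] = coef["a"] * coef["b"]
        else:
            eff[f"indirect_{s.mediators[0]}"] = coef["a1"] * coef["b1"]
            eff[f"indirect_{s.mediators[1]}"] = coef["a2"] * coef["b2"]
            if s.configuration == "serial":
                eff["indirect_serial"] = coef["a1"] * coef["d"] * coef["b2"]
        eff["total_indirect"] = sum(
            v for k, v in eff.items() if k.startswith("indirect")
        )
        eff["direct"] = coef["c_prime"]
        eff["total"] = eff["direct"] + eff["total_indirect"]
        return eff

    def _compose_effects(self, paths: pd.DataFrame) -> pd.DataFrame:
        coef = paths["estimate"].to_dict()
        eff = self._effects_from_coefvec(coef)
        out = pd.DataFrame({"estimate": pd.Series(eff)})
        # delta-method (Sobel) SEs for the product terms
        se = paths["se"].to_dict()
        sobel: dict[str, float] = {}
        s = self.spec
        if len(s.mediators) == 1:
            m = s.mediators[0]
            sobel[f"indirect_{m}"] = np.hypot(coef["a"] * se["b"], coef["b"] * se["a"])
        else:
            m1, m2 = s.mediators
            sobel[f"indirect_{m1}"] = np.hypot(coef["a1"] * se["b1"], coef["b1"] * se["a1"])
            sobel[f"indirect_{m2}"] = np.hypot(coef["a2"] * se["b2"], coef["b2"] * se["a2"])
            if s.configuration == "serial":
                sobel["indirect_serial"] = np.sqrt(
                    (coef["d"] * coef["b2"] * se["a1"]) ** 2
                    + (coef["a1"] * coef["b2"] * se["d"]) ** 2
                    + (coef["a1"] * coef["d"] * se["b2"]) ** 2
                )
        sobel["direct"] = se["c_prime"]
        out["se_analytic"] = pd.Series(sobel).reindex(out.index)
        return out

    # -- bootstrap ------------------------------------------------------

    def _fit_coefvec_at(self, idx: np.ndarray) -> dict[str, float] | None:
        """Refit all equations on a row resample; None if degenerate."""
        Wb = self._W[idx]
        # degenerate resample: any non-constant design column went constant
        for j in range(1, Wb.shape[1]):
            if np.ptp(self._W[:, j]) > 0 and np.ptp(Wb[:, j]) == 0:
                return None
        binary = self.spec.outcome_family == BINARY
        G = Wb.T @ Wb
        coef: dict[str, float] = {}
        for name, (eq, j) in self._path_positions().items():
            resp, preds = self._equations[eq]
            if binary and eq in ("y", "total"):
                beta = _logit_irls(Wb[:, preds], Wb[:, resp])
                if beta is None:
                    return None
            else:
                A = G[np.ix_(preds, preds)]
                h = G[preds, resp]
                try:
                    beta = np.linalg.solve(A, h)
                except np.linalg.LinAlgError:
                    return None
            coef[name] = beta[j]
        return coef

    def _bootstrap(self, effect_names) -> pd.DataFrame:
        """Case-resampling bootstrap of paths and composite effects."""
        s = self.spec
        B = s.bootstrap_draws
        rng = np.random.default_rng(s.seed)
        rows = []
        skipped = 0
        path_names = list(self._path_positions())
        for _ in range(B):
            idx = rng.integers(0, self.nobs, self.nobs)
            coef = self._fit_coefvec_at(idx)
            if coef is None:
                skipped += 1
                if skipped > 0.1 * B:
                    raise RuntimeError(
                        f"more than 10% of bootstrap resamples degenerate "
                        f"({skipped}/{B}); data too sparse for resampling"
                    )
                continue
            eff = self._effects_from_coefvec(coef)
            rows.append([coef[p] for p in path_names] + [eff[e] for e in effect_names])
        if skipped:
            logger.warning("skipped %d degenerate bootstrap resamples", skipped)
        return pd.DataFrame(rows, columns=path_names + list(effect_names))


class MediationResults:
    """Fitted path system with decomposition and bootstrap inference.

    Attributes
    ----------
    paths : DataFrame
        Raw path coefficients (a, b, c', d, and the total-effect
        coefficient ``c_total``) with analytic SEs and p-values.
    effects : DataFrame
        Indirect/direct/total effects with bootstrap SEs, percentile
        CIs and normal-approximation p-values (when bootstrapped).
    """

    def __init__(self, model, eqfits, paths, effects, boot):
        self.model = model
        self.spec = model.spec
        self.equation_results = eqfits
        self.paths = paths
        self.boot_draws = boot
        self.effects = self._attach_bootstrap(effects, boot)
        self.vif = vif_screen(self._vif_design())[0]
        self.nobs = model.nobs
        self.n_dropped = model.n_dropped

    def _vif_design(self) -> pd.DataFrame:
        s = self.spec
        cols = [s.exposure, *s.mediators, *s.confounders]
        return self.model.data[cols]

    def _attach_bootstrap(self, effects: pd.DataFrame, boot) -> pd.DataFrame:
        if boot is None:
            return effects
        lvl = self.spec.ci_level
        lo_q, hi_q = (1 - lvl) / 2, 1 - (1 - lvl) / 2
        se, lo, hi, pvals = {}, {}, {}, {}
        low_precision = len(boot) < 30
        if low_precision:
            logger.warning(
                "only %d usable bootstrap draws; CIs are low-precision", len(boot)
            )
        for name in effects.index:
            draws = boot[name].to_numpy()
            se[name] = draws.std(ddof=1) if len(draws) > 1 else np.nan
            lo[name], hi[name] = np.quantile(draws, [lo_q, hi_q])
            if se[name] and np.isfinite(se[name]) and se[name] > 0:
                z = effects.loc[name, "estimate"] / se[name]
                pvals[name] = 2 * stats.norm.sf(abs(z))
            else:
                pvals[name] = np.nan
        effects = effects.copy()
        effects["se_boot"] = pd.Series(se)
        effects["ci_low"] = pd.Series(lo)
        effects["ci_high"] = pd.Series(hi)
        effects["p"] = pd.Series(pvals)
        effects.attrs["ci_low_precision"] = low_precision
        bad = effects.index[
            (effects["ci_low"] > effects["estimate"])
            | (effects["ci_high"] < effects["estimate"])
        ]
        for name in bad:
            logger.warning("bootstrap CI for %r does not bracket the point estimate", name)
        return effects

    # -- derived quantities --------------------------------------------

    @property
    def total_effect(self) -> float:
        """Direct plus total indirect effect (linear-predictor scale)."""
        return float(self.effects.loc["total", "estimate"])

    @property
    def total_effect_unadjusted(self) -> float:
        """Coefficient of the exposure in the no-mediator regression."""
        return float(self.paths.loc["c_total", "estimate"])

    @property
    def loglike(self) -> dict[str, float]:
        return {k: float(r.llf) for k, r in self.equation_results.items()}

    @property
    def aic(self) -> dict[str, float]:
        return {k: float(r.aic) for k, r in self.equation_results.items()}

    @property
    def bic(self) -> dict[str, float]:
        return {k: float(r.bic) for k, r in self.equation_results.items()}

    def nested_model_test(self) -> tuple[float, int, float]:
        """Chi-squared difference test of the full vs fully-mediated model.

        Compares the outcome equation with and without the direct path
        c' (likelihood-ratio statistic on 1 df).  A small p favours
        retaining the direct effect (partial mediation).
        """
        resp, preds = self.model._equations["y"]
        reduced_preds = [j for j in preds if j != self.model._col[self.spec.exposure]]
        W = self.model._W
        y, Xf, Xr = W[:, resp], W[:, preds], W[:, reduced_preds]
        if self.spec.outcome_family == BINARY:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ll_full = sm.Logit(y, Xf).fit(disp=0).llf
                ll_red = sm.Logit(y, Xr).fit(disp=0).llf
        else:
            ll_full = sm.OLS(y, Xf).fit().llf
            ll_red = sm.OLS(y, Xr).fit().llf
        stat = max(0.0, -2.0 * (ll_red - ll_full))
        p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
        return float(stat), 1, p

    def binary_effects(self, draws: int = 1000, seed: int | None = None) -> pd.DataFrame:
        """Probability-scale average mediation effects (binary outcome).

        Potential-outcomes simulation: coefficient vectors are drawn
        from their asymptotic normal distributions, mediator values are
        simulated under the observed exposure and under a one-unit
        increase, and model-implied outcome probabilities are averaged
        over participants and draws.  Returns ACME (indirect), ADE
        (direct) and their sum (total), each with simulation CIs.
        """
        if self.spec.outcome_family != BINARY:
            raise ValueError("probability-scale effects require a binary outcome")
        if draws < 1:
            raise ValueError("draws must be >= 1")
        rng = np.random.default_rng(seed)
        s = self.spec
        model = self.model
        W = model._W
        n = model.nobs
        x_col = model._col[s.exposure]

        def _draw_coefs(eq):
            res = self.equation_results[eq]
            mean = np.asarray(res.params)
            cov = np.asarray(res.cov_params())
            return rng.multivariate_normal(mean, cov, size=draws)

        coefs = {eq: _draw_coefs(eq) for eq in model._equations if eq != "total"}
        sigmas = {
            eq: np.sqrt(self.equation_results[eq].mse_resid)
            for eq in coefs
            if eq != "y"
        }

        def _linpred(eq, beta, overrides):
            resp, preds = model._equations[eq]
            Xd = W[:, preds].copy()
            for j_global, values in overrides.items():
                if j_global in preds:
                    Xd[:, preds.index(j_global)] = values
            return Xd @ beta

        x_obs = W[:, x_col]
        m_cols = [model._col[m] for m in s.mediators]
        acme = np.empty(draws)
        ade = np.empty(draws)
        for t in range(draws):
            eps = {eq: sigmas[eq] * rng.standard_normal(n) for eq in sigmas}

            def mediators_at(xval):
                over = {x_col: xval}
                m1 = _linpred("m1", coefs["m1"][t], over) + eps["m1"]
                med = {m_cols[0]: m1}
                if "m2" in coefs:
                    over2 = {x_col: xval, m_cols[0]: m1}
                    med[m_cols[1]] = _linpred("m2", coefs["m2"][t], over2) + eps["m2"]
                return med

            m_treat = mediators_at(x_obs + 1.0)
            m_ctrl = mediators_at(x_obs)

            def prob(xval, med):
                over = {x_col: xval, **med}
                eta = np.clip(_linpred("y", coefs["y"][t], over), -30, 30)
                return 1.0 / (1.0 + np.exp(-eta))

            acme[t] = np.mean(prob(x_obs + 1.0, m_treat) - prob(x_obs + 1.0, m_ctrl))
            ade[t] = np.mean(prob(x_obs + 1.0, m_ctrl) - prob(x_obs, m_ctrl))

        lvl = s.ci_level
        qs = [(1 - lvl) / 2, 1 - (1 - lvl) / 2]
        rows = {}
        for name, arr in (("acme", acme), ("ade", ade), ("total", acme + ade)):
            lo, hi = np.quantile(arr, qs)
            rows[name] = {
                "estimate": arr.mean(),
                "se": arr.std(ddof=1) if draws > 1 else np.nan,
                "ci_low": lo,
                "ci_high": hi,
            }
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        s = self.spec
        lines = [
            f"Mediation path model ({s.configuration}, {s.outcome_family})",
            f"  exposure={s.exposure}  mediators={list(s.mediators)}  outcome={s.outcome}",
            f"  n={self.nobs} complete cases ({self.n_dropped} dropped)",
            "",
            "Path coefficients:",
            self.paths.to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            "Effect decomposition:",
            self.effects.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        flagged = self.vif[self.vif > 10]
        if len(flagged):
            lines += ["", f"VIF > 10 (collinearity flags): {flagged.to_dict()}"]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<MediationResults {self.spec.configuration} "
            f"{self.spec.exposure}->{list(self.spec.mediators)}->{self.spec.outcome} "
            f"n={self.nobs}>"
        )


# -- module-level operation wrappers -----------------------------------


def fit_paths(data: pd.DataFrame, spec: MediationSpec) -> MediationResults:
    """Fit the path system without bootstrap (point estimates + analytic SEs)."""
    return MediationModel(data, spec).fit(bootstrap=False)


def bootstrap_effects(data: pd.DataFrame, spec: MediationSpec) -> pd.DataFrame:
    """Fit with case-resampling bootstrap; returns the effects table."""
    if spec.bootstrap_draws < 2:
        raise ValueError("need at least 2 bootstrap draws for SEs")
    return MediationModel(data, spec).fit(bootstrap=True).effects


def nested_model_test(data: pd.DataFrame, spec: MediationSpec) -> tuple[float, int, float]:
    """Chi-squared difference test between partial and full mediation."""
    return fit_paths(data, spec).nested_model_test()


def vif_screen(design: pd.DataFrame, threshold: float = 10.0):
    """Variance inflation factor per column, with removal flags.

    VIF_j = 1/(1-R^2_j) from regressing column j on the remaining
    columns (with intercept).  Perfectly collinear columns get inf.
    """
    X = pd.DataFrame(design)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two columns")
    vifs = {}
    arr = X.to_numpy(float)
    n = len(X)
    for j, name in enumerate(X.columns):
        others = np.column_stack([np.ones(n), np.delete(arr, j, axis=1)])
        y = arr[:, j]
        beta, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = resid @ resid
        ss_tot = ((y - y.mean()) ** 2).sum()
        if ss_tot == 0:
            vifs[name] = np.inf
            continue
        r2 = 1 - ss_res / ss_tot
        vifs[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    vif = pd.Series(vifs)
    return vif, vif > threshold


def bh_fdr(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up adjustment and rejections at ``q``."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def run_mediation_grid(
    data: pd.DataFrame,
    exposures: Sequence[str],
    mediator_sets: Sequence[Sequence[str]],
    outcomes: Sequence[str],
    confounders: Sequence[str] = (),
    binary_outcomes: Sequence[str] = (),
    configuration: str | None = None,
    bootstrap_draws: int = 5000,
    seed: int | None = None,
    ci_level: float = 0.95,
    fdr_q: float = 0.05,
    tobacco_column: str | None = "tobacco",
    cvd_outcomes: Sequence[str] = ("CVD", "cvd"),
) -> pd.DataFrame:
    """Sweep exposures x mediator sets x outcomes; tidy results table.

    One row per combination with direct/indirect/total estimates, CIs,
    raw p-values and BH-adjusted p-values (adjusted within each effect
    column across the whole grid).  Cardiovascular outcomes are
    additionally adjusted for tobacco use when the column exists.
    Failing cells are logged and marked, and the sweep continues.
    """
    if not len(exposures):
        warnings.warn("empty exposure list; returning empty results table")
        return pd.DataFrame()
    rows = []
    for outcome in outcomes:
        conf = list(confounders)
        if (
            tobacco_column
            and outcome in cvd_outcomes
            and tobacco_column in data.columns
            and tobacco_column not in conf
        ):
            conf.append(tobacco_column)
        family = BINARY if outcome in binary_outcomes else CONTINUOUS
        for exposure in exposures:
            for mediators in mediator_sets:
                spec = MediationSpec(
                    exposure,
                    tuple(mediators),
                    outcome,
                    outcome_family=family,
                    confounders=tuple(conf),
                    configuration=configuration if len(mediators) == 2 else None,
                    bootstrap_draws=bootstrap_draws,
                    seed=seed,
                    ci_level=ci_level,
                )
                row = {
                    "exposure": exposure,
                    "mediators": "+".join(mediators),
                    "configuration": spec.configuration,
                    "outcome": outcome,
                    "status": "ok",
                }
                try:
                    res = MediationModel(data, spec).fit(bootstrap=True)
                    eff = res.effects
                    for name in ("direct", "total_indirect", "total"):
                        row[f"{name}_est"] = eff.loc[name, "estimate"]
                        row[f"{name}_ci_low"] = eff.loc[name, "ci_low"]
                        row[f"{name}_ci_high"] = eff.loc[name, "ci_high"]
                        row[f"{name}_p"] = eff.loc[name, "p"]
                    row["n"] = res.nobs
                except Exception as exc:  # keep sweeping; mark the cell
                    logger.error("grid cell failed (%s): %s", row, exc)
                    row["status"] = f"failed: {exc}"
                rows.append(row)
    out = pd.DataFrame(rows)
    ok = out["status"] == "ok"
    for name in ("direct", "total_indirect", "total"):
        col = f"{name}_p"
        if col in out.columns and ok.any():
            adj = np.full(len(out), np.nan)
            mask = ok & out[col].notna()
            if mask.any():
                adj[mask.to_numpy()], _ = bh_fdr(out.loc[mask, col])
            out[f"{name}_p_fdr"] = adj
    return out
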