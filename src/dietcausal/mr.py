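"""Two-sample Mendelian randomization on GWAS summary statistics.

Instrument selection (p-value threshold + greedy LD clumping),
exposure/outcome harmonization, and an estimator battery: per-variant
Wald ratios, inverse-variance weighting (IVW), MR-Egger regression,
the weighted median, the robust adjusted profile score (RAPS), and the
PRESSO residual-sum-of-squares outlier framework, plus Cochran's Q
heterogeneity, per-variant F-statistics and leave-one-out sensitivity.

All estimators operate on a :class:`~dietcausal.gwas.HarmonizedInstrumentSet`
and return plain named-tuple-like dataclasses; :class:`MRModel` wires the
full pipeline together and its :meth:`MRModel.fit` returns an
:class:`MRResults` with a Table-style summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .gwas import (
    GwasSummarySet,
    HarmonizedInstrumentSet,
    COMPLEMENT,
    is_palindromic,
)

__all__ = [
    "select_instruments",
    "build_adjusted_instrument",
    "harmonize",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mr_raps",
    "mr_presso",
    "instrument_strength",
    "leave_one_out",
    "MRModel",
    "MRResults",
    "run_mr",
]

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------
# instrument selection and harmonization
# ---------------------------------------------------------------------


def select_instruments(
    exposure: GwasSummarySet,
    p_threshold: float = 5e-6,
    ld: pd.DataFrame | None = None,
    r2_max: float = 0.2,
    window_kb: float = 1000.0,
) -> GwasSummarySet:
    """Keep variants below the p-value threshold, then greedily LD-clump.

    Clumping repeatedly retains the lowest-p variant and removes every
    other variant within ``window_kb`` on the same chromosome whose
    squared correlation with it is >= ``r2_max``.  Without an LD matrix
    only the p-value filter applies (a warning is logged when more than
    one variant survives).
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    t = exposure.table
    kept = t[t["P"] < p_threshold].copy()
    if ld is None:
        if len(kept) > 1:
            logger.info("no LD matrix supplied; clumping skipped")
        return GwasSummarySet(kept, trait=exposure.trait)

    snps = kept["SNP"].tolist()
    missing = [s for s in snps if s not in ld.index or s not in ld.columns]
    if missing:
        raise ValueError(f"LD matrix missing variants: {missing[:5]}")
    sub = ld.loc[snps, snps]
    if not np.allclose(sub.to_numpy(), sub.to_numpy().T, atol=1e-8):
        raise ValueError("LD matrix must be symmetric")
    if not np.allclose(np.diag(sub.to_numpy()), 1.0, atol=1e-6):
        raise ValueError("LD matrix must have unit diagonal")

    order = kept.sort_values("P")
    retained: list[str] = []
    removed: set[str] = set()
    by_id = kept.set_index("SNP")
    for snp in order["SNP"]:
        if snp in removed:
            continue
        retained.append(snp)
        chrom, pos = by_id.loc[snp, "CHR"], by_id.loc[snp, "POS"]
        for other in order["SNP"]:
            if other == snp or other in removed or other in retained:
                continue
            same_chr = by_id.loc[other, "CHR"] == chrom
            close = abs(by_id.loc[other, "POS"] - pos) <= window_kb * 1000
            if same_chr and close and sub.loc[snp, other] >= r2_max:
                removed.add(other)
    out = kept[kept["SNP"].isin(retained)]
    return GwasSummarySet(out.copy(), trait=exposure.trait)


def build_adjusted_instrument(
    set_a: GwasSummarySet, set_b: GwasSummarySet
) -> GwasSummarySet:
    """Union of two selected instrument sets minus their overlap.

    Variants present in both sets are removed on pleiotropy grounds
    (they tag both traits); provenance is recorded in a ``source``
    column ('a' or 'b').
    """
    ids_a = set(set_a.table["SNP"])
    ids_b = set(set_b.table["SNP"])
    shared = ids_a & ids_b
    only_a = set_a.table[~set_a.table["SNP"].isin(shared)].copy()
    only_b = set_b.table[~set_b.table["SNP"].isin(shared)].copy()
    only_a["source"] = "a"
    only_b["source"] = "b"
    merged = pd.concat([only_a, only_b], ignore_index=True)
    if merged.empty:
        raise ValueError(
            f"all {len(shared)} variants overlap between the two sets; "
            "no instrument remains"
        )
    logger.info("adjusted instrument: %d kept, %d overlapping removed", len(merged), len(shared))
    return GwasSummarySet(merged, trait=f"{set_a.trait}+{set_b.trait}")


def harmonize(exposure: GwasSummarySet, outcome: GwasSummarySet) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure effect allele.

    Inner-joins on variant id; flips the outcome beta (and EAF) when its
    alleles are swapped relative to the exposure, resolves strand flips
    via allele complements, removes palindromic (A/T, C/G) variants and
    unresolvable allele pairs, and records the action per variant.
    Retained variants get per-variant Wald ratios.
    """
    out_by_id = outcome.table.set_index("SNP")
    rows = []
    for _, e in exposure.table.iterrows():
        rec = {
            "SNP": e["SNP"],
            "beta_exposure": e["BETA"],
            "se_exposure": e["SE"],
            "p_exposure": e["P"],
            "beta_outcome": np.nan,
            "se_outcome": np.nan,
        }
        ea, oa = str(e["EA"]), str(e["OA"])
        if is_palindromic(ea, oa):
            rec["action"] = "removed_palindromic"
            rows.append(rec)
            continue
        if e["SNP"] not in out_by_id.index:
            rec["action"] = "removed_missing"
            rows.append(rec)
            continue
        o = out_by_id.loc[e["SNP"]]
        oea, ooa = str(o["EA"]), str(o["OA"])
        cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
        if (oea, ooa) in ((ea, oa), (cea, coa)):
            action, sign = "kept", 1.0
        elif (oea, ooa) in ((oa, ea), (coa, cea)):
            action, sign = "flipped", -1.0
        else:
            rec["action"] = "removed_mismatch"
            rows.append(rec)
            continue
        rec["action"] = action
        rec["beta_outcome"] = sign * o["BETA"]
        rec["se_outcome"] = o["SE"]
        rows.append(rec)
    table = pd.DataFrame(rows)
    retained = table["action"].isin(HarmonizedInstrumentSet.RETAINED_ACTIONS)
    bx = table.loc[retained, "beta_exposure"]
    table.loc[retained, "wald_ratio"] = table.loc[retained, "beta_outcome"] / bx
    table.loc[retained, "wald_se"] = table.loc[retained, "se_outcome"] / bx.abs()
    return HarmonizedInstrumentSet(
        table, exposure_trait=exposure.trait, outcome_trait=outcome.trait
    )


# ---------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------


@dataclass
class MrEstimate:
    method: str
    estimate: float
    se: float
    p: float
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)
    q_statistic: float = np.nan
    q_p: float = np.nan
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low):
            self.ci_low = self.estimate - Z95 * self.se
            self.ci_high = self.estimate + Z95 * self.se


def _arrays(instruments) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(instruments, HarmonizedInstrumentSet):
        return instruments.arrays()
    bx, sx, by, sy = (np.asarray(a, float) for a in instruments)
    return bx, sx, by, sy


def wald_ratio(instruments) -> MrEstimate:
    """Single-variant causal estimate beta_Y/beta_X with delta-method SE."""
    bx, sx, by, sy = _arrays(instruments)
    if len(bx) != 1:
        raise ValueError("wald_ratio expects exactly one variant")
    if bx[0] == 0:
        raise ZeroDivisionError("exposure beta is zero; Wald ratio undefined")
    est = by[0] / bx[0]
    se = sy[0] / abs(bx[0])
    p = 2 * stats.norm.sf(abs(est / se))
    return MrEstimate("wald_ratio", est, se, p)


def ivw(instruments) -> MrEstimate:
    """Inverse-variance-weighted estimate (regression through the origin).

    Weights are 1/se_outcome^2; the SE uses a multiplicative
    random-effects model with the residual scale floored at 1, so it can
    never shrink below the fixed-effects SE.  Cochran's Q is reported on
    k-1 degrees of freedom.
    """
    bx, sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k == 0:
        raise ValueError("no instruments")
    if k == 1:  # exact reduction to the Wald ratio
        w = wald_ratio((bx, sx, by, sy))
        return MrEstimate("ivw", w.estimate, w.se, w.p, q_statistic=0.0, q_p=np.nan)
    w = 1.0 / sy**2
    s2 = np.sum(w * bx**2)
    est = np.sum(w * bx * by) / s2
    q = float(np.sum(w * (by - est * bx) ** 2))
    phi = max(1.0, q / (k - 1))
    q_p = float(stats.chi2.sf(q, df=k - 1))
    se = np.sqrt(phi / s2)
    p = 2 * stats.norm.sf(abs(est / se))
    return MrEstimate("ivw", float(est), float(se), float(p), q_statistic=q, q_p=q_p)


def mr_egger(instruments) -> MrEstimate:
    """MR-Egger weighted regression with intercept.

    Variants are oriented so every exposure beta is non-negative (the
    estimate is otherwise not identified); the intercept estimates the
    average directional pleiotropy under the InSIDE assumption.  SEs use
    the multiplicative random-effects scale floored at 1; Q on k-2 df.
    """
    bx, sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    y = by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), x])
    WX = X * w[:, None]
    A = WX.T @ X
    coef = np.linalg.solve(A, WX.T @ y)
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (k - 2))
    cov = phi * np.linalg.inv(A)
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))
    p_slope = 2 * stats.norm.sf(abs(slope / se_slope))
    p_int = 2 * stats.norm.sf(abs(intercept / se_int))
    return MrEstimate(
        "mr_egger",
        float(slope),
        float(se_slope),
        float(p_slope),
        q_statistic=q,
        q_p=float(stats.chi2.sf(q, df=k - 2)),
        extra={
            "intercept": float(intercept),
            "intercept_se": float(se_int),
            "intercept_p": float(p_int),
        },
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, r))


def weighted_median(
    instruments, bootstrap_draws: int = 1000, seed: int | None = None
) -> MrEstimate:
    """Weighted-median estimator, consistent when >=50% of weight is valid.

    Per-variant Wald ratios are ordered and the estimate interpolates
    the inverse-variance-weighted cumulative distribution at 0.5.  The
    SE comes from a seeded parametric bootstrap resampling the summary
    betas from their normal distributions.
    """
    bx, sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    ratios = by / bx
    weights = (bx / sy) ** 2  # inverse first-order variance of the ratio
    est = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    boot = np.empty(bootstrap_draws)
    for b in range(bootstrap_draws):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        ok = bxs != 0
        boot[b] = _weighted_median_point(bys[ok] / bxs[ok], (bxs[ok] / sy[ok]) ** 2)
    se = float(boot.std(ddof=1))
    p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
    return MrEstimate("weighted_median", est, se, float(p))


def _huber_rho_psi(c: float):
    def rho(t):
        a = np.abs(t)
        return np.where(a <= c, 0.5 * t**2, c * a - 0.5 * c**2)

    kappa = 2 * stats.norm.cdf(c) - 1  # E[psi_c(Z) Z] for Z ~ N(0,1)
    return rho, kappa


def mr_raps(
    instruments,
    loss: str = "squared",
    tuning: float = 1.345,
) -> MrEstimate:
    """Robust adjusted profile score estimator.

    Models the exposure betas as noisy (errors in both variables) and
    maximizes the profile likelihood of the causal effect theta with an
    overdispersion variance tau^2 >= 0 capturing systematic (balanced)
    pleiotropy.  ``loss='huber'`` downweights outlying standardized
    residuals with the consistency-corrected Huber objective.  The SE is
    a sandwich estimate from per-variant scores.
    """
    bx, sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 3:
        raise ValueError("MR-RAPS requires at least 3 instruments")
    if loss not in ("squared", "huber"):
        raise ValueError("loss must be 'squared' or 'huber'")
    if loss == "huber":
        rho, kappa = _huber_rho_psi(tuning)
    else:
        rho, kappa = (lambda t: 0.5 * t**2), 1.0

    def per_variant_obj(params):
        theta, tau2 = params
        v = sy**2 + theta**2 * sx**2 + tau2
        t = (by - theta * bx) / np.sqrt(v)
        return rho(t) + 0.5 * kappa * np.log(v)

    def objective(params):
        return float(np.sum(per_variant_obj(params)))

    theta0 = ivw((bx, sx, by, sy)).estimate
    best = None
    for t0, tau0 in ((theta0, 0.0), (theta0, 1e-4), (0.0, 1e-4)):
        res = optimize.minimize(
            objective,
            x0=[t0, tau0],
            bounds=[(None, None), (0.0, None)],
            method="L-BFGS-B",
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not best.success and not np.isfinite(best.fun):
        raise RuntimeError(f"MR-RAPS optimization failed: {best}")
    theta_hat, tau2_hat = best.x

    # sandwich variance from numerically differentiated per-variant scores
    h = 1e-5 * max(1.0, abs(theta_hat))
    ht = 1e-6 + 1e-4 * tau2_hat

    def scores(params):
        s_theta = (
            per_variant_obj([params[0] + h, params[1]])
            - per_variant_obj([params[0] - h, params[1]])
        ) / (2 * h)
        s_tau = (
            per_variant_obj([params[0], params[1] + ht])
            - per_variant_obj([params[0], max(0.0, params[1] - ht)])
        ) / (ht + min(ht, params[1]))
        return np.column_stack([s_theta, s_tau])

    S = scores(best.x)
    B = S.T @ S
    # Hessian by finite differences of the total score
    def total_score(params):
        return scores(params).sum(axis=0)

    H = np.zeros((2, 2))
    steps = (h, ht)
    for j in range(2):
        up = np.array(best.x, float)
        dn = np.array(best.x, float)
        up[j] += steps[j]
        dn[j] = max(0.0, dn[j] - steps[j]) if j == 1 else dn[j] - steps[j]
        H[:, j] = (total_score(up) - total_score(dn)) / (up[j] - dn[j])
    try:
        Hinv = np.linalg.inv(H)
        V = Hinv @ B @ Hinv.T
        se = float(np.sqrt(max(V[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se = np.nan
    if not np.isfinite(se) or se == 0:
        raise RuntimeError(
            "MR-RAPS sandwich variance not computable "
            f"(theta={theta_hat:.4g}, tau2={tau2_hat:.4g})"
        )
    p = 2 * stats.norm.sf(abs(theta_hat / se))
    return MrEstimate(
        "mr_raps",
        float(theta_hat),
        se,
        float(p),
        extra={"overdispersion": float(tau2_hat), "loss": loss},
    )


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outlier_indices: list[int]
    outlier_p: np.ndarray
    distortion_p: float
    corrected: MrEstimate | None
    n_sim: int


def _loo_ivw_matrix(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates for each variant, vectorized.

    Accepts 1-D arrays or 2-D (n_sim, k) matrices sharing weights w.
    """
    s1 = np.sum(w * bx * by, axis=-1, keepdims=True)
    s2 = np.sum(w * bx**2, axis=-1, keepdims=True)
    return (s1 - w * bx * by) / (s2 - w * bx**2)


def mr_presso(
    instruments,
    n_sim: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Pleiotropy residual sum and outlier (PRESSO) framework.

    Global test: the observed weighted RSS of each outcome beta against
    its leave-one-out IVW prediction is compared with ``n_sim``
    parametric simulations under the fitted model.  Outlier test:
    per-variant RSS contributions against their simulated null, with
    Bonferroni correction at ``outlier_alpha``.  Distortion test: the
    relative change of the IVW estimate after removing outliers against
    the change from randomly chosen variant sets of the same size.  The
    corrected estimate is IVW on the non-outliers.
    """
    bx, sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy**2

    theta_loo = _loo_ivw_matrix(bx, by, w)
    contrib_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(contrib_obs))

    # parametric null draws under the LOO-predicted model
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    theta_loo_sim = _loo_ivw_matrix(bx_sim, by_sim, w)
    contrib_sim = w * (by_sim - theta_loo_sim * bx_sim) ** 2
    rss_sim = contrib_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    outlier_p = (1 + np.sum(contrib_sim >= contrib_obs, axis=0)) / (n_sim + 1)
    outliers = [int(j) for j in np.where(outlier_p * k < outlier_alpha)[0]]

    corrected = None
    distortion_p = np.nan
    if outliers and len(outliers) < k:
        keep = np.setdiff1d(np.arange(k), outliers)
        corrected = ivw((bx[keep], sx[keep], by[keep], sy[keep]))
        theta_all = ivw((bx, sx, by, sy)).estimate
        d_obs = (theta_all - corrected.estimate) / abs(corrected.estimate)
        d_null = np.empty(n_sim)
        for b in range(n_sim):
            drop = rng.choice(k, size=len(outliers), replace=False)
            kp = np.setdiff1d(np.arange(k), drop)
            th = ivw((bx[kp], sx[kp], by[kp], sy[kp])).estimate
            d_null[b] = (theta_all - th) / abs(th) if th != 0 else np.inf
        distortion_p = float(
            (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1)
        )
    return PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        outlier_indices=outliers,
        outlier_p=outlier_p,
        distortion_p=distortion_p,
        corrected=corrected,
        n_sim=n_sim,
    )


def instrument_strength(instruments) -> tuple[np.ndarray, float]:
    """Per-variant F-statistics (beta_X/se_X)^2 and their median."""
    bx, sx, _, _ = _arrays(instruments)
    f = (bx / sx) ** 2
    return f, float(np.median(f)) if len(f) else np.nan


def leave_one_out(instruments) -> pd.DataFrame:
    """IVW re-estimated omitting each variant in turn.

    Flags variants whose omission moves the estimate by more than one
    SE of the re-estimate (the precision of the remaining instruments).
    """
    bx, sx, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 2:
        raise ValueError("leave-one-out requires at least 2 instruments")
    full = ivw((bx, sx, by, sy))
    rows = []
    for j in range(k):
        keep = np.arange(k) != j
        sub = ivw((bx[keep], sx[keep], by[keep], sy[keep]))
        rows.append(
            {
                "omitted": j,
                "estimate": sub.estimate,
                "se": sub.se,
                "shift": sub.estimate - full.estimate,
                "influential": abs(sub.estimate - full.estimate) > sub.se,
            }
        )
    out = pd.DataFrame(rows)
    if isinstance(instruments, HarmonizedInstrumentSet):
        out.insert(0, "SNP", instruments.retained["SNP"].to_numpy())
    return out


# ---------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------


@dataclass
class MRConfig:
    p_threshold: float = 5e-6
    clump_r2: float = 0.2
    clump_kb: float = 1000.0
    binary_outcome: bool = False
    median_draws: int = 1000
    presso_sim: int = 1000
    presso_alpha: float = 0.05
    raps_loss: str = "squared"
    seed: int | None = None


class MRModel:
    """Two-sample MR analysis of one exposure-outcome pair.

    Build either from a ready :class:`HarmonizedInstrumentSet` or from
    raw summary-statistic sets with :meth:`from_summary_stats`, which
    runs selection (p-value filter + optional LD clumping) and
    harmonization first.
    """

    def __init__(
        self,
        instruments: HarmonizedInstrumentSet,
        config: MRConfig | None = None,
    ):
        self.instruments = instruments
        self.config = config or MRConfig()
        if instruments.n_retained == 0:
            raise ValueError("no instruments survived harmonization")

    @classmethod
    def from_summary_stats(
        cls,
        exposure: GwasSummarySet,
        outcome: GwasSummarySet,
        config: MRConfig | None = None,
        ld: pd.DataFrame | None = None,
    ) -> "MRModel":
        config = config or MRConfig()
        selected = select_instruments(
            exposure,
            p_threshold=config.p_threshold,
            ld=ld,
            r2_max=config.clump_r2,
            window_kb=config.clump_kb,
        )
        if len(selected) == 0:
            raise ValueError("no variants pass the instrument p-value threshold")
        harmonized = harmonize(selected, outcome)
        return cls(harmonized, config)

    def fit(self, seed: int | None = None) -> "MRResults":
        """Run the full estimator battery and diagnostics."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        inst = self.instruments
        k = inst.n_retained
        estimates: dict[str, MrEstimate] = {}
        skipped: dict[str, str] = {}

        if k == 1:
            estimates["wald_ratio"] = wald_ratio(inst)
        estimates["ivw"] = ivw(inst)
        for name, fn in (
            ("mr_egger", lambda: mr_egger(inst)),
            (
                "weighted_median",
                lambda: weighted_median(inst, cfg.median_draws, seed),
            ),
            ("mr_raps", lambda: mr_raps(inst, loss=cfg.raps_loss)),
        ):
            try:
                estimates[name] = fn()
            except (ValueError, RuntimeError) as exc:
                skipped[name] = str(exc)
                logger.info("%s skipped: %s", name, exc)

        presso = None
        if k >= 4:
            presso = mr_presso(inst, n_sim=cfg.presso_sim, seed=seed, alpha=cfg.presso_alpha)
        else:
            skipped["mr_presso"] = f"requires >= 4 instruments (have {k})"

        f_stats, f_median = instrument_strength(inst)
        loo = leave_one_out(inst) if k >= 2 else None
        return MRResults(self, estimates, skipped, presso, f_stats, f_median, loo)


class MRResults:
    """Estimates from every MR method plus heterogeneity diagnostics."""

    def __init__(self, model, estimates, skipped, presso, f_stats, f_median, loo):
        self.model = model
        self.instruments = model.instruments
        self.estimates = estimates
        self.skipped = skipped
        self.presso = presso
        self.f_statistics = f_stats
        self.f_median = f_median
        self.leave_one_out = loo
        self.n_instruments = model.instruments.n_retained

    @property
    def egger_intercept(self) -> dict | None:
        est = self.estimates.get("mr_egger")
        return est.extra if est else None

    def odds_ratio(self, method: str = "ivw") -> tuple[float, float, float]:
        """(OR, CI low, CI high) for a binary (logistic) outcome."""
        est = self.estimates[method]
        return tuple(np.exp([est.estimate, est.ci_low, est.ci_high]))

    @property
    def verdict(self) -> str:
        """Declare significance only under cross-method consistency.

        Requires IVW, weighted median and MR-Egger to agree in direction
        with p < 0.05 each, and no significant PRESSO global
        pleiotropy (p > 0.05).  Anything else — including instruments
        too few to run the consistency methods — is 'not significant'.
        """
        needed = ("ivw", "weighted_median", "mr_egger")
        if any(m not in self.estimates for m in needed):
            return "not significant"
        ests = [self.estimates[m] for m in needed]
        signs = {np.sign(e.estimate) for e in ests}
        consistent = len(signs) == 1 and all(e.p < 0.05 for e in ests)
        clean = self.presso is None or self.presso.global_p > 0.05
        return "significant" if consistent and clean else "not significant"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, est in self.estimates.items():
            row = {
                "method": name,
                "estimate": est.estimate,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p": est.p,
                "q_statistic": est.q_statistic,
                "q_p": est.q_p,
            }
            row.update(est.extra)
            if self.model.config.binary_outcome:
                row["or"], row["or_ci_low"], row["or_ci_high"] = self.odds_ratio(name)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        inst = self.instruments
        lines = [
            f"Two-sample MR: {inst.exposure_trait or 'exposure'} -> "
            f"{inst.outcome_trait or 'outcome'}",
            f"  instruments: {self.n_instruments} retained "
            f"({inst.action_counts()})",
            f"  median F-statistic: {self.f_median:.2f}",
            "",
            self.to_frame().to_string(index=False, float_format=lambda v: f"{v: .4g}"),
        ]
        if self.presso is not None:
            lines += [
                "",
                f"MR-PRESSO: global p = {self.presso.global_p:.4g}, "
                f"outliers = {self.presso.outlier_indices}, "
                f"distortion p = {self.presso.distortion_p:.4g}",
            ]
        for name, why in self.skipped.items():
            lines.append(f"  [{name} not estimable: {why}]")
        lines.append(f"verdict: {self.verdict}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"<MRResults k={self.n_instruments} verdict={self.verdict!r}>"


def run_mr(
    exposure: GwasSummarySet,
    outcome: GwasSummarySet,
    config: MRConfig | None = None,
    ld: pd.DataFrame | None = None,
) -> MRResults:
    """Full pipeline: select -> harmonize -> estimator battery."""
    return MRModel.from_summary_stats(exposure, outcome, config=config, ld=ld).fit()
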