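"""Synthetic cohorts and GWAS summary-statistic pairs with known truth.

Every downstream stage (mediation decomposition, two-sample MR) is
testable by parameter recovery against the generating values, so the
generators here are first-class, seeded and exactly reproducible.

The cohort generator draws a recursive linear path system

    M1 = a1*X + conf + e1
    M2 = d*M1 + a2*X + conf + e2
    Y  = c'*X + b1*M1 + b2*M2 + conf + e_y

with independent standard-normal confounders entering each equation
through declared loadings.  Binary outcomes pass the linear predictor
through an inverse-logit with an intercept controlling baseline
prevalence.  The GWAS generator emulates the two-sample setting: the
exposure study reports beta_X ~ N(gamma_j, sigma_Xj^2) and the outcome
study beta_Y ~ N(theta*gamma_j + alpha_j, sigma_Yj^2), with standard
errors from the usual GWAS approximation sigma ~ 1/sqrt(2*N*maf*(1-maf)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import GwasSummarySet

__all__ = ["CohortTruth", "GwasTruth", "generate_cohort", "generate_gwas_pair"]

#: Logistic intercept giving roughly 10% baseline prevalence.
DEFAULT_BINARY_INTERCEPT = -2.2

#: Non-palindromic and palindromic allele pairs used when labelling variants.
_NONPALINDROMIC = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "C"), ("G", "T")]
_PALINDROMIC = [("A", "T"), ("C", "G")]


@dataclass
class CohortTruth:
    """Generating parameters for one synthetic cohort.

    ``a_coefs`` has one entry per mediator (1 or 2); effects are on the
    standardized scale.  ``noise_sd`` is the residual SD shared by every
    structural equation.  ``confounder_effects`` maps 'x', 'm' and 'y'
    to per-confounder loading sequences ('m' may be a sequence per
    mediator); the number of confounders is inferred from the longest.
    """

    n: int
    a_coefs: Sequence[float] = (0.0,)
    b_coefs: Sequence[float] = (0.0,)
    c_prime: float = 0.0
    d_coef: float = 0.0
    confounder_effects: dict | None = None
    outcome_family: str = "continuous"
    noise_sd: float = 1.0
    binary_intercept: float = DEFAULT_BINARY_INTERCEPT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("participant count n must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.outcome_family not in ("continuous", "binary-logistic"):
            raise ValueError(f"unknown outcome_family: {self.outcome_family!r}")
        if len(self.a_coefs) not in (1, 2) or len(self.b_coefs) != len(self.a_coefs):
            raise ValueError("a_coefs and b_coefs must both have length 1 or 2")

    @property
    def n_mediators(self) -> int:
        return len(self.a_coefs)

    def n_confounders(self) -> int:
        ce = self.confounder_effects or {}
        n = 0
        for key in ("x", "y"):
            n = max(n, len(ce.get(key, ())))
        m = ce.get("m", ())
        if m and isinstance(m[0], (list, tuple)):
            n = max(n, max(len(row) for row in m))
        else:
            n = max(n, len(m))
        return n


def _conf_loadings(truth: CohortTruth, key: str, n_conf: int) -> np.ndarray:
    ce = truth.confounder_effects or {}
    v = np.zeros(n_conf)
    raw = ce.get(key, ())
    v[: len(raw)] = raw
    return v


def _conf_loadings_m(truth: CohortTruth, n_conf: int) -> np.ndarray:
    ce = truth.confounder_effects or {}
    raw = ce.get("m", ())
    out = np.zeros((truth.n_mediators, n_conf))
    if raw and isinstance(raw[0], (list, tuple)):
        for i, row in enumerate(raw):
            out[i, : len(row)] = row
    elif raw:
        for i in range(truth.n_mediators):
            out[i, : len(raw)] = raw
    return out


def generate_cohort(truth: CohortTruth) -> pd.DataFrame:
    """Draw one cohort table from the recursive path system.

    Returns a DataFrame with columns X, M1 (and M2 for two mediators),
    C1..Ck confounders, and Y.  Identical truth (including seed) gives a
    bit-identical table.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n
    n_conf = truth.n_confounders()
    C = rng.standard_normal((n, n_conf)) if n_conf else np.zeros((n, 0))

    gx = _conf_loadings(truth, "x", n_conf)
    gm = _conf_loadings_m(truth, n_conf)
    gy = _conf_loadings(truth, "y", n_conf)

    X = C @ gx + rng.standard_normal(n)

    a = np.asarray(truth.a_coefs, float)
    b = np.asarray(truth.b_coefs, float)
    M1 = a[0] * X + C @ gm[0] + truth.noise_sd * rng.standard_normal(n)
    cols = {"X": X, "M1": M1}
    eta = truth.c_prime * X + b[0] * M1 + C @ gy
    if truth.n_mediators == 2:
        M2 = (
            truth.d_coef * M1
            + a[1] * X
            + C @ gm[1]
            + truth.noise_sd * rng.standard_normal(n)
        )
        cols["M2"] = M2
        eta = eta + b[1] * M2

    if truth.outcome_family == "continuous":
        Y = eta + truth.noise_sd * rng.standard_normal(n)
    else:
        p = 1.0 / (1.0 + np.exp(-(truth.binary_intercept + eta)))
        Y = (rng.random(n) < p).astype(int)

    for j in range(n_conf):
        cols[f"C{j + 1}"] = C[:, j]
    cols["Y"] = Y
    return pd.DataFrame(cols)


@dataclass
class GwasTruth:
    """Generating parameters for a two-sample GWAS summary pair.

    ``theta`` is the true causal effect of the exposure on the outcome.
    Per-SNP exposure effects ``gamma`` default to draws from
    N(0, gamma_sd^2); ``alpha`` holds per-SNP direct (pleiotropic)
    outcome effects controlled by ``pleiotropy_mode``:

    - ``none``: all alpha = 0 (valid instruments)
    - ``balanced``: alpha ~ N(0, alpha_sd^2), re-centred to mean 0
    - ``directional``: alpha ~ N(mu_alpha, alpha_sd^2) (InSIDE holds)
    - ``inside_violating``: alpha correlated with gamma
    """

    k_snps: int
    theta: float = 0.0
    gamma: Sequence[float] | None = None
    gamma_sd: float = 0.05
    pleiotropy_mode: str = "none"
    mu_alpha: float = 0.0
    alpha_sd: float = 0.02
    n_exposure: int = 250_000
    n_outcome: int = 250_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_fraction: float = 0.1
    invalid_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_snps < 1:
            raise ValueError("k_snps must be >= 1")
        if self.n_exposure < 1 or self.n_outcome < 1:
            raise ValueError("GWAS sample sizes must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range bounds must lie in (0, 0.5]")
        if self.pleiotropy_mode not in (
            "none",
            "balanced",
            "directional",
            "inside_violating",
        ):
            raise ValueError(f"unknown pleiotropy_mode: {self.pleiotropy_mode!r}")


def _draw_alpha(truth: GwasTruth, gamma: np.ndarray, rng) -> np.ndarray:
    k = truth.k_snps
    mode = truth.pleiotropy_mode
    if mode == "none":
        return np.zeros(k)
    if mode == "balanced":
        alpha = rng.normal(0.0, truth.alpha_sd, k)
        return alpha - alpha.mean()  # mean 0 by construction
    if mode == "directional":
        alpha = rng.normal(truth.mu_alpha, truth.alpha_sd, k)
        # re-centre the noise so the declared mean is exact
        return alpha - alpha.mean() + truth.mu_alpha
    # inside_violating: a fraction of SNPs carry pleiotropy proportional
    # to their exposure effect, correlating alpha with gamma
    n_invalid = int(round(truth.invalid_fraction * k))
    alpha = np.zeros(k)
    idx = rng.choice(k, size=n_invalid, replace=False)
    alpha[idx] = truth.mu_alpha + 0.5 * gamma[idx]
    return alpha


def generate_gwas_pair(truth: GwasTruth) -> tuple[GwasSummarySet, GwasSummarySet]:
    """Draw exposure and outcome summary-statistic sets for one instrument.

    Variants are placed 1 Mb apart along chromosomes so that default
    clumping windows treat them as independent; a configurable fraction
    is labelled with palindromic (A/T or C/G) alleles to exercise
    harmonization filters.
    """
    rng = np.random.default_rng(truth.seed)
    k = truth.k_snps
    maf = rng.uniform(*truth.maf_range, k)
    if truth.gamma is not None:
        gamma = np.asarray(truth.gamma, float)
        if gamma.shape != (k,):
            raise ValueError("gamma must have length k_snps")
    else:
        gamma = rng.normal(0.0, truth.gamma_sd, k)
    alpha = _draw_alpha(truth, gamma, rng)

    se_x = 1.0 / np.sqrt(2.0 * truth.n_exposure * maf * (1 - maf))
    se_y = 1.0 / np.sqrt(2.0 * truth.n_outcome * maf * (1 - maf))
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(truth.theta * gamma + alpha, se_y)

    n_pal = int(round(truth.palindromic_fraction * k))
    pal_idx = set(rng.choice(k, size=n_pal, replace=False).tolist())
    ea, oa = [], []
    for j in range(k):
        pool = _PALINDROMIC if j in pal_idx else _NONPALINDROMIC
        pair = pool[rng.integers(len(pool))]
        ea.append(pair[0])
        oa.append(pair[1])

    chrom = 1 + (np.arange(k) % 22)
    pos = 1_000_000 * (1 + np.arange(k) // 22 * 22 + np.arange(k) % 22)

    def _set(beta, se, n, trait):
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return GwasSummarySet(
            pd.DataFrame(
                {
                    "SNP": [f"rs{j + 1:05d}" for j in range(k)],
                    "CHR": chrom,
                    "POS": pos,
                    "EA": ea,
                    "OA": oa,
                    "EAF": maf,
                    "BETA": beta,
                    "SE": se,
                    "P": p,
                    "N": n,
                }
            ),
            trait=trait,
        )

    return (
        _set(beta_x, se_x, truth.n_exposure, "exposure"),
        _set(beta_y, se_y, truth.n_outcome, "outcome"),
    )


def write_cohort(table: pd.DataFrame, path, truth: CohortTruth | None = None) -> None:
    """Write a cohort CSV; if truth is given, a sidecar JSON records it."""
    path = Path(path)
    table.to_csv(path, index=False)
    if truth is not None:
        sidecar = path.with_suffix(path.suffix + ".truth.json")
        sidecar.write_text(json.dumps(asdict(truth), default=list, indent=2))


def write_gwas_pair(
    exposure: GwasSummarySet,
    outcome: GwasSummarySet,
    exposure_path,
    outcome_path,
    truth: GwasTruth | None = None,
) -> None:
    """Write exposure/outcome TSVs; truth goes to a sidecar JSON if given."""
    exposure.to_tsv(exposure_path)
    outcome.to_tsv(outcome_path)
    if truth is not None:
        p = Path(exposure_path)
        sidecar = p.with_suffix(p.suffix + ".truth.json")
        sidecar.write_text(json.dumps(asdict(truth), default=list, indent=2))
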