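"""Derivation of analysis-ready dietary exposures and outcome traits.

Covers the standard preprocessing chain of FFQ-based nutritional
epidemiology: log transformation of skewed intakes, energy adjustment by
the Willett residual method, energy-percent (E%) conversion, added/total
sugar derivation, Friedewald LDL-C, lipid-lowering-medication
correction, principal-component nutrient patterns, and rule-based
record exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

__all__ = [
    "LOG_SHIFT",
    "ATWATER_FACTORS",
    "LIPID_MEDICATION_OFFSETS",
    "log_shift_transform",
    "energy_residual_adjust",
    "energy_percent",
    "derive_sugars",
    "friedewald_ldl",
    "lipid_medication_correct",
    "nutrient_pattern_pca",
    "NutrientPatternResult",
    "ExclusionRule",
    "exclude_records",
    "load_exclusion_rules",
]

#: Constant added to dietary variables before log-transforming, so that
#: zero intakes remain defined.
LOG_SHIFT = 0.1

#: Metabolizable energy conversion factors, kcal per gram (Atwater).
ATWATER_FACTORS = {
    "protein": 4.0,
    "carbohydrate": 4.0,
    "fat": 9.0,
    "alcohol": 7.0,
}

#: Additive corrections (mmol/L) applied to lipid levels of participants
#: on lipid-lowering medication, restoring approximate untreated values.
LIPID_MEDICATION_OFFSETS = {"tg": 0.208, "tc": 1.347, "hdl": -0.060, "ldl": 1.290}

#: Triglyceride bound (mmol/L) above which the Friedewald formula is
#: considered invalid and LDL-C is set missing.
FRIEDEWALD_TG_BOUND = 4.5


def log_shift_transform(values, shift: float = LOG_SHIFT) -> np.ndarray:
    """ln(x + shift) elementwise for non-negative intakes."""
    x = np.asarray(values, float)
    if np.any(x < 0):
        raise ValueError("dietary intakes must be non-negative")
    return np.log(x + shift)


def energy_residual_adjust(nutrient, tei) -> np.ndarray:
    """Energy-adjust a nutrient by the residual method.

    Regresses the (typically log-transformed) nutrient on total energy
    intake and returns the residuals re-centred at the nutrient mean, so
    the output is uncorrelated with TEI but keeps the original scale.
    """
    y = np.asarray(nutrient, float)
    t = np.asarray(tei, float)
    if y.shape != t.shape:
        raise ValueError("nutrient and TEI must have equal length")
    if np.ptp(t) == 0:
        raise ValueError("TEI is constant; residual regression undefined")
    tc = t - t.mean()
    slope = (tc @ (y - y.mean())) / (tc @ tc)
    return y - slope * tc


def energy_percent(grams, tei_kcal, factor: float) -> np.ndarray:
    """Macronutrient energy percent: 100 * grams * kcal-per-gram / TEI."""
    g = np.asarray(grams, float)
    t = np.asarray(tei_kcal, float)
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    if np.any(g < 0):
        raise ValueError("intake in grams must be non-negative")
    if np.any(t <= 0):
        raise ValueError("total energy intake must be positive")
    return 100.0 * g * factor / t


def derive_sugars(sucrose, monosaccharides, disaccharides, fruit_veg_sugars):
    """(added_sugar, total_sugar) in g/day.

    Added sugar is sucrose plus monosaccharides minus sugars naturally
    present in fruit and vegetables, clamped at zero (a negative intake
    is physically meaningless).  Total sugar is the sum of all mono- and
    disaccharides.
    """
    suc, mono, di, fv = (
        np.asarray(a, float)
        for a in (sucrose, monosaccharides, disaccharides, fruit_veg_sugars)
    )
    for arr in (suc, mono, di, fv):
        if np.any(arr < 0):
            raise ValueError("sugar intakes must be non-negative")
    added = np.maximum(0.0, suc + mono - fv)
    total = mono + di
    return added, total


def friedewald_ldl(tc, hdl, tg, tg_bound: float = FRIEDEWALD_TG_BOUND):
    """LDL-C = TC - HDL-C - TG/2.2 (mmol/L), with a validity bound.

    Returns ``(ldl, invalid)``: rows with TG above ``tg_bound`` get NaN
    LDL and are flagged in the boolean ``invalid`` array.
    """
    tc, hdl, tg = (np.asarray(a, float) for a in (tc, hdl, tg))
    invalid = tg > tg_bound
    ldl = tc - hdl - tg / 2.2
    ldl = np.where(invalid, np.nan, ldl)
    return ldl, invalid


def lipid_medication_correct(tc, hdl, ldl, tg, on_medication) -> pd.DataFrame:
    """Add published offsets to lipid levels of treated participants.

    Untreated rows pass through unchanged.  Returns a DataFrame with
    columns tc, hdl, ldl, tg.
    """
    flag = np.asarray(on_medication, bool).astype(float)
    out = {}
    for name, vals in zip(("tc", "hdl", "ldl", "tg"), (tc, hdl, ldl, tg)):
        out[name] = np.asarray(vals, float) + flag * LIPID_MEDICATION_OFFSETS[name]
    return pd.DataFrame(out)


@dataclass
class NutrientPatternResult:
    """Principal-component dietary patterns.

    ``loadings`` columns (PC1..) are orthonormal eigenvectors of the
    nutrient correlation matrix; ``explained_variance_ratio`` covers all
    components (sums to 1); ``scores`` holds per-participant values for
    the retained components.
    """

    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame

    @property
    def n_retained(self) -> int:
        return self.loadings.shape[1]


def nutrient_pattern_pca(matrix: pd.DataFrame, n_components: int = 3) -> NutrientPatternResult:
    """Centred-and-scaled PCA of a participants x nutrients matrix.

    Standardizes each nutrient and eigendecomposes the correlation
    structure; the top ``n_components`` (default 3) are retained for
    scores and loadings while variance fractions are reported for all.
    """
    X = pd.DataFrame(matrix)
    if X.shape[1] < 2:
        raise ValueError("need at least two nutrient columns")
    if X.isna().any().any():
        raise ValueError("missing values must be filtered before PCA")
    sd = X.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance nutrient columns: {zero}")
    Z = (X - X.mean()) / sd

    n_total = min(X.shape)
    pca = PCA(n_components=n_total)
    all_scores = pca.fit_transform(Z.to_numpy())
    keep = min(n_components, n_total)
    names = [f"PC{i + 1}" for i in range(keep)]
    loadings = pd.DataFrame(pca.components_[:keep].T, index=X.columns, columns=names)
    scores = pd.DataFrame(all_scores[:, :keep], index=X.index, columns=names)
    return NutrientPatternResult(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores,
    )


@dataclass
class ExclusionRule:
    """Range/flag rule for dropping implausible or ineligible records.

    A row is excluded when the variable falls outside [min, max] (either
    bound optional) or, for ``action='exclude_flagged'``, when the flag
    is truthy.  Missing values never trigger a range rule.
    """

    variable: str
    min: float | None = None
    max: float | None = None
    action: str = "exclude_outside_range"


def exclude_records(
    table: pd.DataFrame, rules: list[ExclusionRule]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply exclusion rules; returns (filtered table, removed-count per rule).

    Counts are attributed sequentially: a row already removed by an
    earlier rule is not counted again by a later one.
    """
    keep = pd.Series(True, index=table.index)
    counts: dict[str, int] = {}
    for rule in rules:
        if rule.variable not in table.columns:
            raise KeyError(f"exclusion rule references unknown column {rule.variable!r}")
        col = table[rule.variable]
        if rule.action == "exclude_flagged":
            viol = col.fillna(0).astype(bool)
        else:
            viol = pd.Series(False, index=table.index)
            if rule.min is not None:
                viol |= col < rule.min
            if rule.max is not None:
                viol |= col > rule.max
        newly = viol & keep
        counts[rule.variable] = int(newly.sum())
        keep &= ~viol
    return table.loc[keep].copy(), counts


def load_exclusion_rules(path=None) -> list[ExclusionRule]:
    """Load exclusion rules from YAML (list of variable/min/max/action).

    Without a path, the packaged defaults are used.  Shipped defaults
    are conventional plausibility screens, not cohort-specific limits;
    real analyses should supply ranges from their own data managers.
    """
    if path is None:
        path = Path(__file__).parent / "config" / "default_exclusions.yaml"
    raw = yaml.safe_load(Path(path).read_text())
    return [ExclusionRule(**entry) for entry in raw]
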