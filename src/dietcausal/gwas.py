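"""Containers for GWAS summary statistics and harmonized instruments.

Summary-statistic sets are thin validated wrappers around a pandas
DataFrame using the conventional column layout of consortium downloads
(SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N) with per-allele effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")
#: Strand-ambiguous allele pairs: the complement equals the swap, so
#: orientation cannot be resolved from alleles alone.
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

REQUIRED_COLUMNS = ("SNP", "EA", "OA", "BETA", "SE", "P")
OPTIONAL_COLUMNS = ("CHR", "POS", "EAF", "N")


def is_palindromic(ea: str, oa: str) -> bool:
    return (ea, oa) in PALINDROMIC_PAIRS


@dataclass
class GwasSummarySet:
    """Per-variant association records for one trait.

    Parameters
    ----------
    table
        DataFrame with required columns SNP, EA, OA, BETA, SE, P and
        optional CHR, POS (1-based), EAF, N.
    trait
        Free-text trait label used in rendered tables.
    """

    table: pd.DataFrame
    trait: str = ""

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        if t["SNP"].duplicated().any():
            dupes = t.loc[t["SNP"].duplicated(), "SNP"].tolist()
            raise ValueError(f"duplicate variant ids within set: {dupes[:5]}")
        alleles = set(t["EA"].astype(str)) | set(t["OA"].astype(str))
        bad = alleles - VALID_ALLELES
        if bad:
            raise ValueError(f"non-ACGT alleles: {sorted(bad)}")
        if (t["EA"].astype(str) == t["OA"].astype(str)).any():
            raise ValueError("effect allele equals other allele for some variants")
        if (t["SE"] <= 0).any():
            raise ValueError("non-positive standard errors")
        if ((t["P"] < 0) | (t["P"] > 1)).any():
            raise ValueError("p-values outside [0, 1]")
        if "EAF" in t.columns:
            eaf = t["EAF"].dropna()
            if ((eaf <= 0) | (eaf >= 1)).any():
                raise ValueError("effect-allele frequencies outside (0, 1)")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path, trait: str = "") -> "GwasSummarySet":
        return cls(pd.read_csv(path, sep="\t"), trait=trait)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def subset(self, mask_or_ids) -> "GwasSummarySet":
        t = self.table
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and (
            np.asarray(mask_or_ids).dtype == bool
        ):
            sub = t.loc[np.asarray(mask_or_ids)]
        else:
            sub = t[t["SNP"].isin(mask_or_ids)]
        return GwasSummarySet(sub.copy(), trait=self.trait)


@dataclass
class HarmonizedInstrumentSet:
    """Allele-aligned exposure/outcome effect pairs after harmonization QC.

    ``table`` has one row per exposure variant with columns SNP,
    beta_exposure, se_exposure, beta_outcome, se_outcome, action and,
    for retained variants, wald_ratio and wald_se.  ``action`` is one of
    kept, flipped, removed_palindromic, removed_missing, removed_mismatch.
    """

    table: pd.DataFrame
    exposure_trait: str = ""
    outcome_trait: str = ""

    RETAINED_ACTIONS = ("kept", "flipped")

    @property
    def retained(self) -> pd.DataFrame:
        """Rows that survived harmonization, with aligned effect pairs."""
        return self.table[self.table["action"].isin(self.RETAINED_ACTIONS)]

    @property
    def n_retained(self) -> int:
        return int(len(self.retained))

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exposure, se_exposure, beta_outcome, se_outcome) arrays."""
        r = self.retained
        return (
            r["beta_exposure"].to_numpy(float),
            r["se_exposure"].to_numpy(float),
            r["beta_outcome"].to_numpy(float),
            r["se_outcome"].to_numpy(float),
        )

    def action_counts(self) -> dict[str, int]:
        return self.table["action"].value_counts().to_dict()
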