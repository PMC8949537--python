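"""Result rendering and run manifests.

Renders MR result bundles into delimited effect tables (one row per
exposure-outcome pair, method columns side by side, non-estimable cells
as "-"), forest-plot data tables (per-variant Wald ratios plus method
summary rows), and JSON run manifests recording seeds, input digests and
filter counts so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .mr import MRResults, Z95

__all__ = ["render_effect_table", "render_forest_data", "RunManifest", "write_manifest"]

NOT_ESTIMABLE = "-"


def _fmt_effect(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return NOT_ESTIMABLE
    return f"{v:.2f}"


def _fmt_p(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return NOT_ESTIMABLE
    return f"{v:.2e}" if v < 1e-3 else f"{v:.2f}"


METHOD_ORDER = ("ivw", "mr_egger", "mr_presso", "mr_raps", "weighted_median", "wald_ratio")


def render_effect_table(results: list[MRResults]) -> pd.DataFrame:
    """One row per exposure-outcome pair with method columns side by side.

    Binary outcomes are rendered as odds ratios with exp-transformed
    CIs; methods that could not run appear as "-".
    """
    columns = ["exposure", "outcome", "n_snps", "F"]
    for m in METHOD_ORDER:
        if m == "mr_presso":
            columns += ["mr_presso_global_p", "mr_presso_distortion_p"]
            continue
        columns += [f"{m}_beta", f"{m}_ci_low", f"{m}_ci_high", f"{m}_p"]
        if m in ("ivw", "mr_egger"):
            columns += [f"{m}_q", f"{m}_q_p"]
        if m == "mr_egger":
            columns += ["mr_egger_intercept", "mr_egger_intercept_p"]
    rows = []
    for res in results:
        inst = res.instruments
        row = {c: NOT_ESTIMABLE for c in columns}
        row["exposure"] = inst.exposure_trait or "exposure"
        row["outcome"] = inst.outcome_trait or "outcome"
        row["n_snps"] = res.n_instruments
        row["F"] = _fmt_effect(res.f_median)
        binary = res.model.config.binary_outcome
        for m, est in res.estimates.items():
            if binary:
                e, lo, hi = np.exp([est.estimate, est.ci_low, est.ci_high])
            else:
                e, lo, hi = est.estimate, est.ci_low, est.ci_high
            row[f"{m}_beta"] = _fmt_effect(e)
            row[f"{m}_ci_low"] = _fmt_effect(lo)
            row[f"{m}_ci_high"] = _fmt_effect(hi)
            row[f"{m}_p"] = _fmt_p(est.p)
            if m in ("ivw", "mr_egger") and np.isfinite(est.q_statistic):
                row[f"{m}_q"] = _fmt_effect(est.q_statistic)
                row[f"{m}_q_p"] = _fmt_p(est.q_p)
            if m == "mr_egger":
                row["mr_egger_intercept"] = _fmt_effect(est.extra["intercept"])
                row["mr_egger_intercept_p"] = _fmt_p(est.extra["intercept_p"])
        if res.presso is not None:
            row["mr_presso_global_p"] = _fmt_p(res.presso.global_p)
            row["mr_presso_distortion_p"] = _fmt_p(res.presso.distortion_p)
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def render_forest_data(res: MRResults) -> pd.DataFrame:
    """Per-variant Wald ratios with CIs plus one summary row per method.

    CI half-widths are 1.96*SE throughout; plotting happens downstream.
    """
    retained = res.instruments.retained
    rows = []
    for _, r in retained.iterrows():
        rows.append(
            {
                "label": r["SNP"],
                "kind": "variant",
                "estimate": r["wald_ratio"],
                "se": r["wald_se"],
                "ci_low": r["wald_ratio"] - Z95 * r["wald_se"],
                "ci_high": r["wald_ratio"] + Z95 * r["wald_se"],
            }
        )
    for name, est in res.estimates.items():
        rows.append(
            {
                "label": name,
                "kind": "summary",
                "estimate": est.estimate,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    return pd.DataFrame(rows)


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    command: str
    seeds: dict = field(default_factory=dict)
    config_hash: str = ""
    input_digests: dict = field(default_factory=dict)
    filter_counts: dict = field(default_factory=dict)
    software_version: str = ""
    status: str = "completed"
    failed_stage: str | None = None
    timestamp: str = ""

    def __post_init__(self) -> None:
        for name, removed in self.filter_counts.items():
            if removed < 0:
                raise ValueError(f"negative removed-count for filter {name!r}")
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        if not self.software_version:
            from . import __version__

            self.software_version = __version__


def write_manifest(
    path,
    command: str,
    seeds: dict | None = None,
    config: dict | None = None,
    input_paths: dict | None = None,
    filter_counts: dict | None = None,
    status: str = "completed",
    failed_stage: str | None = None,
) -> RunManifest:
    """Write a JSON run manifest and return it.

    ``filter_counts`` maps filter names to the number of records removed
    (all non-negative); ``input_paths`` maps labels to files, which are
    digested.  Failed runs record the failing stage.
    """
    manifest = RunManifest(
        command=command,
        seeds=seeds or {},
        config_hash=(
            hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest()[:16]
            if config
            else ""
        ),
        input_digests={k: _digest(v) for k, v in (input_paths or {}).items()},
        filter_counts=filter_counts or {},
        status=status,
        failed_stage=failed_stage,
    )
    Path(path).write_text(json.dumps(asdict(manifest), indent=2, default=str))
    return manifest
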