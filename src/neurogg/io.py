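"""Table readers/writers, pipeline configuration and the report driver.

All tables are UTF-8 CSV with a mandatory header row and "." decimals.
Validation errors name the offending column and line.  The report driver
chains quantification → profiling → group statistics and emits a cohort
CSV plus a summary JSON with a provenance block (config hash, seed,
version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .pathway import ANCHOR_WHITELIST
from .profiling import (ClassifierConfig, anchor_distribution, classify_anchor_group,
                        cohort_table, summarize)
from .quantify import default_is_map, quantify
from .stats import mann_whitney_exact, spearman_rho

__all__ = [
    "PipelineConfig", "ValidationError",
    "read_peak_areas", "read_quant", "read_metadata", "read_expression",
    "write_table", "run_report",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Input table failed schema validation; message names the location."""


@dataclass
class PipelineConfig:
    """Everything tunable in one serialisable object."""

    is_amount_nmol: dict[str, float] = field(default_factory=lambda: {
        "D5-GM3": 1.0, "D3-GM2": 1.0, "D5-GM1a": 1.0, "D3-GD3": 1.0,
    })
    response_factors: dict[str, float] = field(default_factory=dict)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    anchor_whitelist: tuple[str, ...] = ANCHOR_WHITELIST
    exact_enumeration_cap: int = 200_000
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["anchor_whitelist"] = list(self.anchor_whitelist)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "classifier" in d and isinstance(d["classifier"], Mapping):
            d["classifier"] = ClassifierConfig(**d["classifier"])
        if "anchor_whitelist" in d:
            d["anchor_whitelist"] = tuple(d["anchor_whitelist"])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def make_is_map(self):
        return default_is_map(self.is_amount_nmol, self.response_factors)


def _read_csv(path: str, required: dict[str, type], numeric_nonneg: tuple[str, ...] = (),
              key_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file is empty (header row is mandatory)") from None
    missing = set(required) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    for col, typ in required.items():
        if typ is float:
            values = pd.to_numeric(df[col], errors="coerce")
            bad = values.isna() & (df[col] != "")
            if bad.any():
                line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
                raise ValidationError(f"{path}: non-numeric value in column {col!r} at line {line}")
            df[col] = values
    for col in numeric_nonneg:
        bad = df[col] < 0
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValidationError(f"{path}: negative value in column {col!r} at line {line}")
    if key_cols:
        dup = df.duplicated(subset=list(key_cols))
        if dup.any():
            line = int(dup.idxmax()) + 2
            raise ValidationError(f"{path}: duplicate key {tuple(key_cols)} at line {line}")
    if len(df) == 0:
        logger.warning("%s: empty table (header only)", path)
    logger.info("%s: read %d rows x %d columns", path, len(df), len(df.columns))
    return df


def read_peak_areas(path: str) -> pd.DataFrame:
    return _read_csv(
        path,
        {"sample_id": str, "species": str, "anchor": str, "channel": str, "area": float},
        numeric_nonneg=("area",),
    )


def read_quant(path: str) -> pd.DataFrame:
    df = _read_csv(
        path,
        {"sample_id": str, "glycan": str, "anchor": str, "conc_nmol_per_mg": float},
        numeric_nonneg=("conc_nmol_per_mg",),
        key_cols=("sample_id", "glycan", "anchor"),
    )
    return df


def read_metadata(path: str) -> pd.DataFrame:
    return _read_csv(path, {"sample_id": str, "risk": str}, key_cols=("sample_id",))


def read_expression(path: str) -> pd.DataFrame:
    return _read_csv(
        path,
        {"sample_id": str, "b4galnt1_expression": float},
        key_cols=("sample_id",),
    )


def read_protein(path: str) -> dict[str, float]:
    df = _read_csv(path, {"sample_id": str, "protein_mg": float},
                   numeric_nonneg=("protein_mg",), key_cols=("sample_id",))
    return dict(zip(df["sample_id"], df["protein_mg"]))


def write_table(df: pd.DataFrame, path: str) -> None:
    """CSV with header, '.' decimals; infinities serialise as 'inf'."""
    df.to_csv(path, index=False)


_COMPARED = ("total_gg", "GT1b", "GD2")


def run_report(
    quant: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
    expression: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Cohort report: per-sample labels plus LR-vs-HR group statistics.

    Mann–Whitney comparisons (LR vs HR) are computed for total GG, GT1b
    and GD2; the GD2–B4GALNT1 Spearman correlation is computed on HR
    samples when an expression table is supplied.  Comparisons are skipped
    with a warning when a group has fewer than 2 samples.
    """
    config = config or PipelineConfig()
    summaries = summarize(quant)
    dist = anchor_distribution(quant, "GD2")
    groups = {
        sid: classify_anchor_group(dist.loc[sid].to_dict() if sid in dist.index else None,
                                   config.classifier)
        for sid in summaries.index
    }
    cohort = cohort_table(summaries, groups, metadata, config.classifier)

    summary: dict[str, Any] = {
        "provenance": {
            "package": "neurogg",
            "version": __version__,
            "config_hash": config.hash,
            "seed": config.seed,
        },
        "n_samples": int(len(cohort)),
        "group_counts": cohort.groupby(["risk", "profile"]).size()
                               .rename("n").reset_index().to_dict("records"),
        "comparisons": [],
        "warnings": [],
    }

    by_risk = dict(tuple(cohort.groupby("risk")))
    lr = by_risk.get("LR", pd.DataFrame())
    hr = by_risk.get("HR", pd.DataFrame())
    if len(lr) < 2 or len(hr) < 2:
        msg = f"comparisons skipped: need >=2 samples per group (LR={len(lr)}, HR={len(hr)})"
        summary["warnings"].append(msg)
        logger.warning(msg)
    else:
        for quantity in _COMPARED:
            col = "total_gg" if quantity == "total_gg" else None
            if col is None:
                lr_vals = summaries.loc[lr["sample_id"], quantity]
                hr_vals = summaries.loc[hr["sample_id"], quantity]
            else:
                lr_vals = summaries.loc[lr["sample_id"], col]
                hr_vals = summaries.loc[hr["sample_id"], col]
            res = mann_whitney_exact(lr_vals.tolist(), hr_vals.tolist())
            summary["comparisons"].append({
                "quantity": quantity, "groups": "LR-vs-HR",
                "U": res.U, "p_two_sided": res.p_two_sided,
                "method": res.method, "n1": res.n1, "n2": res.n2,
            })
            logger.info("LR vs HR %s: U=%.1f p=%.4g (%s)",
                        quantity, res.U, res.p_two_sided, res.method)

    if expression is not None and len(hr) > 0:
        expr = expression.set_index("sample_id")["b4galnt1_expression"]
        ids = [s for s in hr["sample_id"] if s in expr.index]
        gd2 = summaries.loc[ids, "GD2"]
        if len(ids) >= 3 and gd2.nunique() > 1 and expr.loc[ids].nunique() > 1:
            corr = spearman_rho(gd2.tolist(), expr.loc[ids].tolist())
            summary["spearman_gd2_b4galnt1"] = {"rho": corr.rho, "n": corr.n}
            logger.info("GD2 vs B4GALNT1 (HR): rho=%.3f n=%d", corr.rho, corr.n)
        else:
            msg = "Spearman skipped: need >=3 HR samples with non-constant GD2/expression"
            summary["warnings"].append(msg)
            logger.warning(msg)

    return cohort, summary


def summary_to_json(summary: Mapping[str, Any], path: str) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serialisable: {type(o)}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
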