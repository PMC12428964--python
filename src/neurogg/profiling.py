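"""Composition summaries, ratio statistics and the A–E profile classes.

Per sample the module computes anchor-summed totals for the ten
quantified gangliosides, series sums (0/a/b), the a/b-series ratio
Sa/Sb and the simple-species ratio (GM3+GD3)/(all others), ceramide
anchor-length distributions of GD2 (short 32–34 / normal 36–38 / long
40–44 carbons), and assigns each sample one of the composition profiles
observed in neuroblastoma:

    A — GT1b-dominant (the low-risk-like pattern)
    B — almost only GD2
    C — only GM3/GD3 (synthesis arrest at the GM2/GD2 synthase)
    D — complex a- and b-series species with strong GD1a and GT1b
    E — GD1a and GM2 prevalent (a-series shift)

The published class definitions are verbal, so the thresholds are
configuration with stated defaults; classification is a deterministic
first-match decision list with precedence C → B → D → A → E (the
exclusivity-defined classes preempt the shape-based ones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .pathway import QUANTIFIED_SPECIES, SERIES_MEMBERS

__all__ = [
    "SHORT_CARBONS", "NORMAL_CARBONS", "LONG_CARBONS",
    "ClassifierConfig", "summarize", "anchor_distribution",
    "classify_anchor_group", "classify_profile",
    "cohort_table", "count_by", "load_table1", "load_table3",
]

logger = logging.getLogger(__name__)

SHORT_CARBONS = frozenset({32, 34})
NORMAL_CARBONS = frozenset({36, 38})
LONG_CARBONS = frozenset({40, 41, 42, 43, 44})

#: fixed tie-break order for the arg-max species rule (GT1b first)
_ARGMAX_ORDER = ("GT1b", "GD2", "GD3", "GM3", "GD1a", "GM2", "GD1b", "GM1a", "GM1b", "GD1alpha")

_A_SERIES = sorted(SERIES_MEMBERS["a"] & set(QUANTIFIED_SPECIES))
_B_SERIES = sorted(SERIES_MEMBERS["b"] & set(QUANTIFIED_SPECIES))
_0_SERIES = sorted(SERIES_MEMBERS["0"] & set(QUANTIFIED_SPECIES))


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds (fractions of total GG) for the profile/anchor rules."""

    theta_C: float = 0.75        # (GM3+GD3)/total for "only GM3 or GD3"
    theta_B: float = 0.50        # GD2/total for "almost only GD2"
    theta_D_gd1a: float = 0.15   # GD1a fraction for profile D
    theta_D_gt1b: float = 0.10   # GT1b fraction for profile D
    theta_E: float = 0.50        # (GD1a+GM2)/total for profile E
    theta_E_bmax: float = 0.10   # max (GD1b+GT1b)/total compatible with E
    theta_long: float = 0.60     # long-anchor fraction for group "long"
    theta_short: float = 0.25    # short-anchor fraction for group "short"

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")


def _anchor_carbons(anchor: str) -> int:
    return int(str(anchor).split(":", 1)[0])


def summarize(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-sample composition summary from a quant table.

    Returns one row per sample: per-glycan totals (anchor-summed),
    ``total_gg``, series sums ``S0``/``Sa``/``Sb``, ``ratio_ab`` = Sa/Sb,
    ``ratio_simple`` = (GM3+GD3)/(all others) and per-glycan fractions
    (``frac_<glycan>``).  Empty denominators yield ``inf``; samples with
    zero total are flagged (logged) and omitted.
    """
    pivot = (
        quant.pivot_table(
            index="sample_id", columns="glycan", values="conc_nmol_per_mg",
            aggfunc="sum", fill_value=0.0,
        )
        .reindex(columns=list(QUANTIFIED_SPECIES), fill_value=0.0)
    )
    total = pivot.sum(axis=1)
    zero = total == 0
    if zero.any():
        logger.warning("samples with zero total GG flagged and dropped: %s",
                       list(pivot.index[zero]))
        pivot, total = pivot[~zero], total[~zero]

    out = pivot.copy()
    out["total_gg"] = total
    out["S0"] = pivot[_0_SERIES].sum(axis=1)
    out["Sa"] = pivot[_A_SERIES].sum(axis=1)
    out["Sb"] = pivot[_B_SERIES].sum(axis=1)
    with np.errstate(divide="ignore"):
        out["ratio_ab"] = np.where(out["Sb"] > 0, out["Sa"] / out["Sb"], np.inf)
        simple = pivot["GM3"] + pivot["GD3"]
        others = total - simple
        out["ratio_simple"] = np.where(others > 0, simple / others, np.inf)
    for sp in QUANTIFIED_SPECIES:
        out[f"frac_{sp}"] = pivot[sp] / total
    return out


def anchor_distribution(quant: pd.DataFrame, species: str = "GD2") -> pd.DataFrame:
    """Short/normal/long anchor-bin fractions of one species per sample.

    Carbon bins: 32–34 short, 36–38 normal, 40–44 long.  Samples without
    anchor-resolved rows for ``species`` are absent from the result
    (anchor group "nd" downstream).
    """
    rows = quant[(quant["glycan"] == species) & quant["anchor"].fillna("").ne("")]
    if len(rows) == 0:
        return pd.DataFrame(columns=["f_short", "f_normal", "f_long"]).rename_axis("sample_id")
    carbons = rows["anchor"].map(_anchor_carbons)
    bins = np.select(
        [carbons.isin(SHORT_CARBONS), carbons.isin(NORMAL_CARBONS), carbons.isin(LONG_CARBONS)],
        ["f_short", "f_normal", "f_long"],
        default="other",
    )
    binned = (
        rows.assign(bin=bins)
        .pivot_table(index="sample_id", columns="bin", values="conc_nmol_per_mg",
                     aggfunc="sum", fill_value=0.0)
        .reindex(columns=["f_short", "f_normal", "f_long"], fill_value=0.0)
    )
    total = binned.sum(axis=1)
    binned = binned[total > 0]
    return binned.div(binned.sum(axis=1), axis=0)


def classify_anchor_group(dist: Mapping[str, float] | None,
                          cfg: ClassifierConfig | None = None) -> str:
    """Assign "long"/"short"/"normal" from a bin distribution ("nd" if None).

    Decision list: long when f_long >= theta_long, else short when
    f_short >= theta_short, else normal.
    """
    cfg = cfg or ClassifierConfig()
    if dist is None:
        return "nd"
    if dist["f_long"] >= cfg.theta_long:
        return "long"
    if dist["f_short"] >= cfg.theta_short:
        return "short"
    return "normal"


def classify_profile(summary: Mapping[str, float],
                     cfg: ClassifierConfig | None = None) -> str:
    """Assign a profile label A–E to one sample's composition summary.

    ``summary`` must expose ``frac_<glycan>`` fields (a row of
    :func:`summarize` works).  First-match precedence C → B → D → A → E;
    arg-max ties for A are broken by a fixed species order (GT1b first)
    with a logged warning.
    """
    cfg = cfg or ClassifierConfig()
    f = {sp: float(summary[f"frac_{sp}"]) for sp in QUANTIFIED_SPECIES}
    if f["GM3"] + f["GD3"] >= cfg.theta_C:
        return "C"
    if f["GD2"] >= cfg.theta_B:
        return "B"
    if f["GD1a"] >= cfg.theta_D_gd1a and f["GT1b"] >= cfg.theta_D_gt1b:
        return "D"
    top = max(f.values())
    argmax = [sp for sp in _ARGMAX_ORDER if f[sp] == top]
    if len(argmax) > 1:
        logger.warning("arg-max tie between %s broken by fixed order", argmax)
    if argmax[0] == "GT1b" and top > 0:
        return "A"
    if f["GD1a"] + f["GM2"] >= cfg.theta_E and f["GD1b"] + f["GT1b"] <= cfg.theta_E_bmax:
        return "E"
    return "unclassified"


def cohort_table(
    summaries: pd.DataFrame,
    anchor_groups: Mapping[str, str] | pd.Series,
    metadata: pd.DataFrame,
    cfg: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """One tidy row per sample: risk, composition statistics, labels.

    ``metadata`` needs ``sample_id`` and ``risk`` columns; sample ids must
    match the summaries exactly (orphans on either side raise).
    """
    cfg = cfg or ClassifierConfig()
    meta = metadata.set_index("sample_id")
    orphans = set(summaries.index).symmetric_difference(meta.index)
    if orphans:
        raise ValueError(f"sample_id mismatch between summaries and metadata: {sorted(orphans)}")
    groups = pd.Series(dict(anchor_groups)) if not isinstance(anchor_groups, pd.Series) else anchor_groups
    rows = []
    for sample_id, s in summaries.iterrows():
        rows.append({
            "sample_id": sample_id,
            "risk": meta.loc[sample_id, "risk"],
            "total_gg": s["total_gg"],
            "S0": s["S0"], "Sa": s["Sa"], "Sb": s["Sb"],
            "ratio_ab": s["ratio_ab"], "ratio_simple": s["ratio_simple"],
            "gd2_fraction": s["frac_GD2"],
            "profile": classify_profile(s, cfg),
            "anchor_group": groups.get(sample_id, "nd"),
        })
    return pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)


def count_by(table: pd.DataFrame, **criteria) -> int:
    """Count rows matching all column=value criteria (Table-1/3 style tallies)."""
    mask = pd.Series(True, index=table.index)
    for col, value in criteria.items():
        mask &= table[col] == value
    return int(mask.sum())


def _load_fixture(name: str) -> pd.DataFrame:
    text = resources.files("neurogg.data").joinpath(name)
    with text.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """Published characteristics of the 18 tumor samples (transcription).

    Columns: sample_id, risk, stage_4s, therapy, mycn, profile,
    anchor_group.  These published labels are ground truth for table
    logic, not classifier output.
    """
    return _load_fixture("table1_cohort.csv")


def load_table3() -> pd.DataFrame:
    """Published characteristics of the 11 cell lines (transcription).

    Columns: cell_line, species, subtype, mycn, alk, profile,
    profile_partial (1 where the published label was parenthesised,
    i.e. a partial match).
    """
    return _load_fixture("table3_cell_lines.csv")
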