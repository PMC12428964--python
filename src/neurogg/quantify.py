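"""Internal-standard MRM quantification and qRT-PCR relative expression.

Peak areas from multiple-reaction-monitoring (MRM) runs are converted to
absolute concentrations by ratioing each analyte against a deuterated
internal standard (IS) spiked at known amount:

    conc [nmol/mg] = (area_analyte / area_IS) * amount_IS * RF / protein_mg

Only four labelled standards exist (D5-GM3, D3-GM2, D5-GM1a, D3-GD3), so
most disialo/trisialo species are quantified against D3-GD3 with a
response factor (RF) calibrated from unlabeled standards.  Gangliosides
are monitored in negative mode via their sialic-acid fragments (Neu5Ac
m/z 290.1 for all species; Neu5Gc m/z 306.1 for GM3/GM2 only, kept out of
the quantitative totals).

Also here: the 2^-ddCt relative-expression calculation with the
calibrator defined as max cycle number minus the cohort-average Ct of the
housekeeping gene HPRT1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .pathway import ANCHOR_WHITELIST, QUANTIFIED_SPECIES, sialic_count

__all__ = [
    "ANALYTE", "INTERNAL_STANDARD",
    "TransitionRecord", "default_transitions",
    "InternalStandardMap", "default_is_map",
    "compute_response_factor", "quantify", "validate_anchors",
    "ddct_expression", "QcFailure",
]

logger = logging.getLogger(__name__)

ANALYTE = "analyte"
INTERNAL_STANDARD = "internal_standard"

NEU5AC_FRAGMENT = 290.1
NEU5GC_FRAGMENT = 306.1


@dataclass(frozen=True)
class TransitionRecord:
    """One MRM transition: precursor charge state and sialic-acid fragment."""

    species: str
    q1_charge: str  # "1-" or "2-"
    q3_fragment: float  # 290.1 (Neu5Ac) or 306.1 (Neu5Gc)

    def __post_init__(self) -> None:
        if self.q1_charge not in ("1-", "2-"):
            raise ValueError(f"q1_charge must be '1-' or '2-', got {self.q1_charge!r}")
        if self.q3_fragment not in (NEU5AC_FRAGMENT, NEU5GC_FRAGMENT):
            raise ValueError(f"unknown Q3 fragment m/z {self.q3_fragment}")
        try:
            n_sialic = sialic_count(self.species)
        except ValueError:
            n_sialic = None  # IS names etc. are not validated against the graph
        if n_sialic is not None:
            if self.q1_charge == "2-" and n_sialic < 2:
                raise ValueError(
                    f"double-deprotonated Q1 requires >=2 sialic acids ({self.species})"
                )
            if self.q3_fragment == NEU5GC_FRAGMENT and self.species not in ("GM3", "GM2"):
                raise ValueError("Neu5Gc fragment (306.1) is monitored for GM3/GM2 only")


def default_transitions() -> list[TransitionRecord]:
    """Quantifier transitions for the ten-species panel.

    Monosialo species and GD3 fly singly deprotonated; GD2, GD1a, GD1b,
    GD1alpha and GT1b doubly deprotonated.  All fragment to Neu5Ac 290.1;
    GM3 and GM2 additionally carry a Neu5Gc 306.1 qualifier.
    """
    single = {"GM3", "GM2", "GM1a", "GM1b", "GD3"}
    out = []
    for sp in QUANTIFIED_SPECIES:
        q1 = "1-" if sp in single else "2-"
        out.append(TransitionRecord(sp, q1, NEU5AC_FRAGMENT))
    out.append(TransitionRecord("GM3", "1-", NEU5GC_FRAGMENT))
    out.append(TransitionRecord("GM2", "1-", NEU5GC_FRAGMENT))
    return out


@dataclass
class InternalStandardMap:
    """Analyte → IS assignment with spike amounts and response factors."""

    assignment: dict[str, str]                 # glycan -> IS name
    is_amount_nmol: dict[str, float]           # IS name -> spiked amount
    response_factor: dict[str, float] = field(default_factory=dict)  # glycan -> RF

    def __post_init__(self) -> None:
        for name, amount in self.is_amount_nmol.items():
            if amount <= 0:
                raise ValueError(f"IS amount for {name} must be positive")
        for glycan in self.assignment:
            self.response_factor.setdefault(glycan, 1.0)
        for glycan, rf in self.response_factor.items():
            if rf <= 0:
                raise ValueError(f"response factor for {glycan} must be positive")

    def is_name(self, glycan: str) -> str:
        return self.assignment[glycan]

    def amount(self, glycan: str) -> float:
        return self.is_amount_nmol[self.assignment[glycan]]

    def rf(self, glycan: str) -> float:
        return self.response_factor.get(glycan, 1.0)


def default_is_map(
    is_amount_nmol: float | Mapping[str, float] = 1.0,
    response_factors: Mapping[str, float] | None = None,
) -> InternalStandardMap:
    """The study's IS assignment.

    GM3→D5-GM3, GM2→D3-GM2, GM1a and GM1b→D5-GM1a, and all GD-/GT-species
    →D3-GD3 (no labelled standards existed for those).  Matched pairs get
    RF 1; RFs for the species quantified against D3-GD3 are calibration
    inputs (default 1).
    """
    assignment = {
        "GM3": "D5-GM3",
        "GM2": "D3-GM2",
        "GM1a": "D5-GM1a",
        "GM1b": "D5-GM1a",
        "GD3": "D3-GD3",
        "GD2": "D3-GD3",
        "GD1a": "D3-GD3",
        "GD1b": "D3-GD3",
        "GD1c": "D3-GD3",
        "GD1alpha": "D3-GD3",
        "GT1b": "D3-GD3",
    }
    if isinstance(is_amount_nmol, Mapping):
        amounts = dict(is_amount_nmol)
    else:
        amounts = {name: float(is_amount_nmol) for name in set(assignment.values())}
    rfs = dict(response_factors) if response_factors else {}
    return InternalStandardMap(assignment, amounts, rfs)


def compute_response_factor(
    area_std: float, amount_std_nmol: float, area_is: float, amount_is_nmol: float
) -> float:
    """RF from a calibration run of an unlabeled standard against its IS.

    RF = (amount_std / amount_is) * (area_is / area_std), so that
    ``quantify`` exactly recovers the standard amount on the calibration
    mixture.
    """
    for name, v in (
        ("area_std", area_std), ("amount_std_nmol", amount_std_nmol),
        ("area_is", area_is), ("amount_is_nmol", amount_is_nmol),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (amount_std_nmol / amount_is_nmol) * (area_is / area_std)


@dataclass(frozen=True)
class QcFailure:
    sample_id: str
    reason: str


def quantify(
    areas: pd.DataFrame,
    is_map: InternalStandardMap,
    protein_mg: Mapping[str, float],
) -> tuple[pd.DataFrame, list[QcFailure]]:
    """Convert a peak-area table into nmol/mg-protein concentrations.

    ``areas`` columns: ``sample_id``, ``species`` (glycan or IS name),
    ``anchor`` (may be empty for IS rows), ``channel``
    (``analyte``/``internal_standard``), ``area``; an optional
    ``fragment`` column lets Neu5Gc (306.1) qualifier rows ride along —
    they are excluded from quantification.  Duplicate keys are summed
    (quantifier + qualifier acquisitions).  Samples whose mapped IS row is
    missing or has zero area are excluded and reported as QC failures.
    """
    required = {"sample_id", "species", "anchor", "channel", "area"}
    missing = required - set(areas.columns)
    if missing:
        raise ValueError(f"peak-area table is missing columns: {sorted(missing)}")
    if (areas["area"] < 0).any():
        raise ValueError("negative peak areas are not allowed")

    work = areas.copy()
    if "fragment" in work.columns:
        frag = pd.to_numeric(work["fragment"], errors="coerce")
        n_gc = int((frag == NEU5GC_FRAGMENT).sum())
        if n_gc:
            logger.info("excluding %d Neu5Gc qualifier rows from quantification", n_gc)
        work = work[frag != NEU5GC_FRAGMENT]
    work = (
        work.groupby(["sample_id", "species", "anchor", "channel"], dropna=False)["area"]
        .sum()
        .reset_index()
    )

    is_rows = work[work["channel"] == INTERNAL_STANDARD]
    is_area: dict[tuple[str, str], float] = {
        (r.sample_id, r.species): r.area for r in is_rows.itertuples()
    }

    failures: list[QcFailure] = []
    records = []
    analyte_rows = work[work["channel"] == ANALYTE]
    for sample_id, group in analyte_rows.groupby("sample_id", sort=True):
        if sample_id not in protein_mg:
            failures.append(QcFailure(str(sample_id), "no protein mass recorded"))
            continue
        prot = float(protein_mg[sample_id])
        if prot <= 0:
            failures.append(QcFailure(str(sample_id), "non-positive protein mass"))
            continue
        bad = None
        sample_records = []
        for row in group.itertuples():
            glycan = row.species
            if glycan not in is_map.assignment:
                failures.append(
                    QcFailure(str(sample_id), f"no IS assignment for analyte {glycan!r}")
                )
                bad = glycan
                break
            is_name = is_map.is_name(glycan)
            a_is = is_area.get((sample_id, is_name))
            if a_is is None or a_is == 0:
                reason = "missing" if a_is is None else "zero-area"
                bad = f"{reason} IS row {is_name!r}"
                failures.append(QcFailure(str(sample_id), bad))
                break
            conc = (row.area / a_is) * is_map.amount(glycan) * is_map.rf(glycan) / prot
            sample_records.append((sample_id, glycan, row.anchor, conc))
        if bad is None:
            records.extend(sample_records)
        else:
            logger.warning("sample %s failed QC (%s); excluded", sample_id, bad)

    quant = pd.DataFrame(records, columns=["sample_id", "glycan", "anchor", "conc_nmol_per_mg"])
    return quant, failures


def validate_anchors(quant: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop rows whose ceramide anchor is off the 11-member whitelist.

    Anchor-free rows (empty/NaN anchor) are kept.  Returns the filtered
    table and a list of warning strings (also logged).
    """
    anchors = quant["anchor"].fillna("")
    keep = (anchors == "") | anchors.isin(ANCHOR_WHITELIST)
    warnings_: list[str] = []
    n_dropped = int((~keep).sum())
    if n_dropped:
        offending = sorted(anchors[~keep].unique())
        msg = f"dropped {n_dropped} rows with off-whitelist anchors: {offending}"
        warnings_.append(msg)
        logger.warning(msg)
    return quant[keep].reset_index(drop=True), warnings_


def ddct_expression(records: pd.DataFrame) -> pd.Series:
    """2^-ddCt relative expression, HPRT1-normalised.

    ``records`` columns: ``sample_id``, ``ct_target``, ``ct_ref``,
    ``max_cycle``.  dCt_s = ct_target,s − ct_ref,s; the calibrator is
    K = max_cycle − mean_s(ct_ref); expression_s = 2^−(dCt_s − K).
    """
    if len(records) == 0:
        raise ValueError("empty qPCR table")
    required = {"sample_id", "ct_target", "ct_ref", "max_cycle"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"qPCR table is missing columns: {sorted(missing)}")
    max_cycles = records["max_cycle"].unique()
    if len(max_cycles) != 1:
        raise ValueError("all records must share one max_cycle")
    max_cycle = float(max_cycles[0])
    for col in ("ct_target", "ct_ref"):
        ct = records[col]
        if ((ct <= 0) | (ct > max_cycle)).any():
            raise ValueError(f"{col} values must lie in (0, max_cycle]")
    dct = records["ct_target"].to_numpy(float) - records["ct_ref"].to_numpy(float)
    calibrator = max_cycle - records["ct_ref"].mean()
    expr = np.power(2.0, -(dct - calibrator))
    return pd.Series(expr, index=pd.Index(records["sample_id"], name="sample_id"), name="expression")
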