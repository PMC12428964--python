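"""Flux-model generator: mass balance, archetypes, round trips, survival."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from conftest import quant_from_conc
from neurogg.pathway import QUANTIFIED_SPECIES
from neurogg.profiling import classify_anchor_group, classify_profile, summarize
from neurogg.quantify import default_is_map, quantify
from neurogg.stats import cox_fit_single, spearman_rho
from neurogg.synthetic import (
    ARCHETYPES,
    CerSWeights,
    FluxParams,
    SurvivalSimParams,
    flux_masses,
    simulate_anchor_mix,
    simulate_cohort,
    simulate_composition,
    simulate_peak_areas,
    simulate_survival_study,
)


def _label_of(conc: dict) -> str:
    return classify_profile(summarize(quant_from_conc(conc)).iloc[0])


# --- flux model -------------------------------------------------------------

def test_mass_conservation_across_presets():
    for arch in ARCHETYPES.values():
        masses = flux_masses(arch.flux)
        assert sum(masses.values()) == pytest.approx(arch.flux.total_flux_T, abs=1e-12)


def test_single_step_retention_is_half():
    # a = kappa = 1 on LacCer->GM3, nothing downstream: GM3 receives half
    # of LacCer's inflow (share a/(kappa+a) = 1/2) and retains all of it
    params = FluxParams(activity={"UGCG": 1e9, "B4GALT5/6": 1e9, "ST3GAL5": 1.0})
    masses = flux_masses(params)
    assert masses["GM3"] == pytest.approx(0.5, rel=1e-6)
    assert masses["LacCer"] == pytest.approx(0.5, rel=1e-6)


def test_two_level_hand_example():
    # UGCG = B4GALT5/6 = ST3GAL5 = 9, ST8SIA1 = B4GALNT1 = 1, kappa = 1:
    # shares worked out by hand down the tree
    params = FluxParams(activity={"UGCG": 9.0, "B4GALT5/6": 9.0, "ST3GAL5": 9.0,
                                  "ST8SIA1": 1.0, "B4GALNT1": 1.0})
    m = flux_masses(params)
    assert m["Cer"] == pytest.approx(0.1)
    assert m["GlcCer"] == pytest.approx(0.09)
    assert m["LacCer"] == pytest.approx(0.081)
    assert m["GM3"] == pytest.approx(0.243)
    assert m["GM2"] == pytest.approx(0.243)
    assert m["GD3"] == pytest.approx(0.1215)
    assert m["GD2"] == pytest.approx(0.1215)
    assert m["GT1b"] == 0.0


def test_silent_branches_receive_no_flux():
    for arch in ARCHETYPES.values():
        m = flux_masses(arch.flux)
        assert m["GA2"] == 0.0 and m["GM1b"] == 0.0 and m["GT3"] == 0.0


def test_b4galnt1_knockout_yields_profile_c():
    arch = ARCHETYPES["HR-C"]
    activity = dict(arch.flux.activity)
    activity["B4GALNT1"] = 0.0
    conc = simulate_composition(replace(arch.flux, activity=activity))
    nonzero = {k for k, v in conc.items() if v > 0}
    assert nonzero == {"GM3", "GD3"}
    assert _label_of(conc) == "C"


def test_all_zero_upstream_gives_empty_composition():
    params = FluxParams(activity={"UGCG": 0.0})
    assert simulate_composition(params) == {}


def test_monotone_b4galnt1_knockdown():
    """Scaling B4GALNT1 down from any preset never raises a downstream species."""
    downstream = {"GM2", "GM1a", "GD1a", "GD2", "GD1b", "GT1b"}
    for arch in ARCHETYPES.values():
        base = arch.flux.activity.get("B4GALNT1", 0.0)
        prev = None
        for factor in np.linspace(1.0, 0.0, 11):
            activity = dict(arch.flux.activity)
            activity["B4GALNT1"] = base * factor
            conc = simulate_composition(replace(arch.flux, activity=activity))
            cur = {sp: conc.get(sp, 0.0) for sp in downstream}
            if prev is not None:
                for sp in downstream:
                    assert cur[sp] <= prev[sp] + 1e-12, (arch.name, sp, factor)
            prev = cur


def test_archetype_fidelity_at_zero_noise():
    for arch in ARCHETYPES.values():
        conc = simulate_composition(arch.flux)
        assert _label_of(conc) == arch.expected_profile, arch.name
        mix = simulate_anchor_mix(arch.cers)  # no jitter without a generator
        dist = {"f_short": 0.0, "f_normal": 0.0, "f_long": 0.0}
        for anchor, frac in mix.items():
            carbons = int(anchor.split(":")[0])
            key = ("f_short" if carbons <= 34 else
                   "f_normal" if carbons <= 38 else "f_long")
            dist[key] += frac
        assert classify_anchor_group(dist) == arch.expected_anchor_group, arch.name


# --- anchor mixtures --------------------------------------------------------

def test_anchor_mix_pure_normal():
    mix = simulate_anchor_mix(CerSWeights(0, 1, 0))
    assert set(mix) == {"36:1;O2", "38:1;O2"}
    assert sum(mix.values()) == pytest.approx(1.0)


def test_anchor_mix_pure_long_classifies_long():
    mix = simulate_anchor_mix(CerSWeights(0, 0, 1))
    f_long = sum(v for a, v in mix.items() if int(a.split(":")[0]) >= 40)
    assert f_long == pytest.approx(1.0)
    assert classify_anchor_group({"f_short": 0, "f_normal": 0, "f_long": f_long}) == "long"


def test_anchor_mix_proportions():
    mix = simulate_anchor_mix(CerSWeights(3, 5, 2))
    bins = {"short": 0.0, "normal": 0.0, "long": 0.0}
    for a, v in mix.items():
        c = int(a.split(":")[0])
        bins["short" if c <= 34 else "normal" if c <= 38 else "long"] += v
    assert bins["short"] == pytest.approx(0.3)
    assert bins["normal"] == pytest.approx(0.5)
    assert bins["long"] == pytest.approx(0.2)


def test_anchor_mix_requires_positive_weight():
    with pytest.raises(ValueError):
        CerSWeights(0, 0, 0)


def test_anchor_mix_jitter_sums_to_one(rng):
    mix = simulate_anchor_mix(CerSWeights(1, 2, 1, concentration=30.0), rng=rng)
    assert sum(mix.values()) == pytest.approx(1.0)


# --- peak-area round trips --------------------------------------------------

def test_round_trip_exact_at_zero_noise():
    quant, meta, _ = simulate_cohort(2, 2, noise_cv=0.0, seed=5)
    is_map = default_is_map(response_factors={"GD2": 1.4, "GT1b": 2.0})
    protein = {s: 0.6 for s in meta["sample_id"]}
    areas = simulate_peak_areas(quant, is_map, protein)
    out, fails = quantify(areas, is_map, protein)
    assert not fails
    merged = quant.merge(out, on=["sample_id", "glycan", "anchor"],
                         suffixes=("_in", "_out"))
    assert len(merged) == len(quant)
    assert np.allclose(merged["conc_nmol_per_mg_in"],
                       merged["conc_nmol_per_mg_out"], rtol=0, atol=1e-12)


def test_round_trip_error_tracks_noise(rng):
    quant = quant_from_conc({"GD2": 2.0, "GT1b": 5.0, "GM3": 0.5})
    is_map = default_is_map()
    protein = {"s1": 1.0}
    errors = []
    for _ in range(200):
        areas = simulate_peak_areas(quant, is_map, protein, noise_cv=0.1, rng=rng)
        out, _ = quantify(areas, is_map, protein)
        merged = quant.merge(out, on=["sample_id", "glycan", "anchor"],
                             suffixes=("_in", "_out"))
        rel = ((merged["conc_nmol_per_mg_out"] - merged["conc_nmol_per_mg_in"]).abs()
               / merged["conc_nmol_per_mg_in"])
        errors.extend(rel.tolist())
    assert np.median(errors) < 0.1


# --- cohorts ----------------------------------------------------------------

def test_cohort_shapes_and_determinism():
    a = simulate_cohort(8, 10, seed=42)
    b = simulate_cohort(8, 10, seed=42)
    for x, y in zip(a, b):
        assert x.to_csv(index=False) == y.to_csv(index=False)
    quant, meta, expr = a
    assert meta["risk"].tolist() == ["LR"] * 8 + ["HR"] * 10
    assert set(meta["sample_id"]) == set(expr["sample_id"])
    assert (quant["conc_nmol_per_mg"] >= 0).all()


def test_cohort_pure_hr_c_classifies_c():
    quant, meta, _ = simulate_cohort(0, 6, archetype_weights={"HR-C": 1.0},
                                     noise_cv=0.0, seed=11)
    summaries = summarize(quant)
    labels = [classify_profile(s) for _, s in summaries.iterrows()]
    assert labels == ["C"] * 6


def test_gd2_expression_monotone_at_zero_noise():
    # within one archetype the coupled B4GALNT1 activity is the only source
    # of variation, and GD2 output is strictly monotone in it
    quant, _, expr = simulate_cohort(0, 9, archetype_weights={"HR-C": 1.0},
                                     noise_cv=0.0, seed=6)
    gd2 = (quant[quant["glycan"] == "GD2"].groupby("sample_id")["conc_nmol_per_mg"]
           .sum().reindex(expr["sample_id"]).fillna(0.0))
    rho = spearman_rho(gd2.tolist(), expr["b4galnt1_expression"].tolist()).rho
    assert rho == pytest.approx(1.0)


def test_gd2_expression_correlation_under_noise():
    """B4GALNT1-limited cohorts reproduce a strong GD2-expression correlation."""
    rhos = []
    for seed in range(500):
        quant, _, expr = simulate_cohort(0, 9, archetype_weights={"HR-C": 1.0},
                                         noise_cv=0.2, seed=10_000 + seed)
        gd2 = (quant[quant["glycan"] == "GD2"].groupby("sample_id")["conc_nmol_per_mg"]
               .sum().reindex(expr["sample_id"]).fillna(0.0))
        rhos.append(spearman_rho(gd2.tolist(), expr["b4galnt1_expression"].tolist()).rho)
    assert float(np.median(rhos)) >= 0.9


def test_cohort_invalid_weights_raise():
    with pytest.raises(ValueError):
        simulate_cohort(1, 1, archetype_weights={"nope": 1.0})
    with pytest.raises(ValueError):
        simulate_cohort(0, 0)


# --- survival ---------------------------------------------------------------

def test_null_hazard_recovery():
    df = simulate_survival_study(SurvivalSimParams(n=400, hazard_ratio=1.0, seed=2))
    fit = cox_fit_single(df["time"], df["event"], df["x"])
    assert abs(fit.log_hr) < 3 * fit.se


def test_no_censoring_means_all_events():
    df = simulate_survival_study(
        SurvivalSimParams(n=50, hazard_ratio=0.8, censoring_fraction=0.0, seed=3))
    assert df["event"].sum() == 50


def test_censoring_fraction_calibration():
    df = simulate_survival_study(
        SurvivalSimParams(n=100_000, hazard_ratio=0.67, censoring_fraction=0.3, seed=4))
    assert 1.0 - df["event"].mean() == pytest.approx(0.3, abs=0.02)


def test_mean_estimated_hr_near_truth(rng):
    # Monte-Carlo consistency of the Cox implementation at the largest study size
    hrs = []
    for _ in range(200):
        df = simulate_survival_study(SurvivalSimParams(n=498, hazard_ratio=0.67), rng=rng)
        hrs.append(cox_fit_single(df["time"], df["event"], df["x"]).hr)
    assert float(np.mean(hrs)) == pytest.approx(0.67, rel=0.02)


def test_survival_params_validation():
    with pytest.raises(ValueError):
        SurvivalSimParams(n=1, hazard_ratio=0.5)
    with pytest.raises(ValueError):
        SurvivalSimParams(n=10, hazard_ratio=-1.0)
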