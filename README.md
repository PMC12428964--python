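# neurogg

Ganglioside (GG) profiling of neuroblastoma as a reusable, tested Python
pipeline.

Neuroblastoma risk groups differ in their ganglioside composition:
low-risk (LR) tumors are dominated by complex b-series species
(particularly GT1b), while high-risk (HR) tumors show heterogeneous
profiles — GT1b-dominant (A), GD2-dominant (B), GM3/GD3-arrested (C,
the loss of the GM2/GD2 synthase *B4GALNT1*), mixed complex a+b series
with strong GD1a (D), or a-series-shifted GD1a+GM2 (E).  The ceramide
anchor of GD2 further splits samples into short (C32–34), normal
(C36–38) and very-long (C40–44) groups, reflecting ceramide-synthase
(CerS5/6, CerS1, CerS2) usage.  `neurogg` implements the full
computational side of such a study for lipidomics and bioinformatics
practitioners:

* **pathway** — ganglio-series nomenclature, series membership, the
  enzyme-labelled biosynthesis DAG, unique biosynthetic routes, and
  inference of enzymatic blocks from presence/absence patterns
  (GM3/GD3-only ⇒ `{B4GALNT1}`).
* **quantify** — internal-standard MRM quantification,
  `conc = (A_analyte/A_IS) · n_IS · RF / m_protein` (nmol/mg), response
  factors, the 11-anchor whitelist, and 2^−ΔΔCt relative expression with
  the calibrator `K = max cycle − mean Ct(HPRT1)`.
* **profiling** — per-sample composition summaries, series sums, the
  ratios `Sa/Sb` and `(GM3+GD3)/others`, anchor-bin distributions, and
  the deterministic A–E profile classifier (precedence C → B → D → A → E).
* **stats** — a from-scratch inference layer: enumeration-exact
  Mann–Whitney (two-sided p = twice the smaller tail), Spearman
  correlation on mid-ranks, single-covariate Cox regression (Breslow
  partial likelihood, Newton–Raphson), and common-effect /
  DerSimonian–Laird random-effects meta-analysis with Q, τ² and I².
* **synthetic** — an enzyme-activity flux model that generates every
  input: at each pathway node an edge with activity `a` receives the
  share `a/(κ+Σa)` of the inflow, so single-enzyme knockouts reproduce
  the arrest profiles; plus CerS-weighted anchor mixtures, peak-area
  tables (the algebraic inverse of quantification) and expression-linked
  exponential survival cohorts.
* **io / cli** — CSV readers/writers with schema validation, YAML
  config, and the `neurogg` command (`simulate`, `quantify`, `classify`,
  `report`, `stats {mw,spearman,cox,meta}`).

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated cohort (8 LR + 10 HR samples, archetype mixture matching the
published HR profile frequencies):

```
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_quantify.py
python analysis/03_profile_cohort.py
python analysis/04_group_statistics.py --seed 1
python analysis/05_survival_meta.py --seed 1
```

With seed 1 this prints (abridged):

```
profile counts by risk:
HR    A 2   B 3   C 2   E 1   unclassified 2
LR    A 8

LR vs HR exact Mann-Whitney:
  total_gg  U= 80.0  p=0.0000 (exact)
  GT1b      U= 80.0  p=0.0000 (exact)
  GD2       U= 57.0  p=0.1415 (exact)
B4GALNT1-limited subcohort: rho=0.967 (n=9)

  pooled common:  HR=0.638 (SE 0.045)
  tau2=0.0000  I2=0.0%  Q(2)=0.991  p_Q=0.609
recovery over 200 replicates: mean pooled HR = 0.6646 (true 0.67)
```

Read: every LR sample is GT1b-dominant while the HR samples scatter
across profiles; total GG and GT1b are significantly higher in LR but
GD2 is not; GD2 concentration tracks *B4GALNT1* expression where the
last synthesis step is rate-limiting; and pooling three simulated
survival studies under a shared per-unit hazard ratio of 0.67 recovers
that value with no between-study heterogeneity.

As a library:

```python
from neurogg.stats import mann_whitney_exact
mann_whitney_exact([1, 2, 3, 4, 5, 6, 7], [8, 9, 10, 11]).p_two_sided
# 0.00606... = 2/330, the exact two-sided tail for complete separation at 7 vs 4
```

## Layout

```
src/neurogg/        library (pathway, quantify, profiling, stats, synthetic, io, cli)
src/neurogg/data/   biosynthesis edge list + published-table transcriptions
analysis/           numbered narrative drivers writing under results/
tests/              pytest suite (property tests seeded/derandomised)
docs/methods.md     model assumptions, parameter choices, limitations
```
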