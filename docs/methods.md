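# Methods

## Quantification model

Analyte concentrations are obtained by internal-standard ratioing:

    conc = (A_analyte / A_IS) · n_IS · RF / m_protein   [nmol/mg protein]

with one deuterated standard per assignment group (D5-GM3 → GM3,
D3-GM2 → GM2, D5-GM1a → GM1a and GM1b, D3-GD3 → all GD-/GT-species).
The response factor RF corrects for per-mole signal differences when an
analyte is quantified against a non-matching standard; it is computed
from a calibration run as `RF = (n_std/n_IS)·(A_IS/A_std)`, which makes
quantification an exact algebraic inverse of the calibration.  RFs
default to 1 (including GM1b against D5-GM1a); no published values
exist, so they are config inputs with no pretense of matching any
laboratory's calibration.  A missing analyte row means concentration 0;
a missing or zero-area IS row is a QC failure that excludes the sample.
Ceramide anchors outside the 11-member whitelist (32:1;O2 … 44:1;O2)
are dropped with a warning.  Duplicate acquisition rows are summed;
rows flagged as Neu5Gc (m/z 306.1) qualifiers are excluded from
quantitative totals.

qRT-PCR expression uses 2^−ΔΔCt with the calibrator defined as the
maximal cycle number minus the cohort-mean Ct of HPRT1.  Whether that
mean is per-cohort or per-plate is not specified anywhere we know of;
per-cohort is implemented.

## Profile classification

The published class definitions are verbal ("only", "almost only",
"dominance"), so the classifier is a deterministic first-match decision
list over fractions of total GG with configurable thresholds:

| rule | default | meaning |
|---|---|---|
| C: (GM3+GD3)/total ≥ θ_C | 0.75 | synthesis arrest at the GM2/GD2 synthase |
| B: GD2/total ≥ θ_B | 0.50 | GD2 accumulation |
| D: GD1a ≥ θ_D_gd1a and GT1b ≥ θ_D_gt1b | 0.15 / 0.10 | complex a+b co-expression |
| A: GT1b is the arg-max species | — | the LR-like pattern |
| E: (GD1a+GM2) ≥ θ_E and (GD1b+GT1b) ≤ θ_E_bmax | 0.50 / 0.10 | a-series shift |

Exclusivity-defined classes preempt shape-based ones (C → B → D → A →
E); D precedes A because the GT1b-dominant-with-strong-GD1a pattern is
the published D.  Arg-max ties are broken by a fixed species order
(GT1b first) with a logged warning.  Anything else is `unclassified`
rather than forced into a class.  All ratios and labels are invariant
under rescaling a sample's concentrations.

Anchor groups are computed on GD2 only (the species the study analysed):
long if f_long ≥ 0.60, else short if f_short ≥ 0.25 (the "about 30%"
verbal rule with margin), else normal; carbon bins are 32–34 / 36–38 /
40–44.  Samples without GD2 anchor data are `nd`.  The "short" rule
uses f_short alone; whether very-long mass should also count toward it
is ambiguous in the source description and was resolved this way.

## Statistics

* **Mann–Whitney**: U = #{x_i > y_j} + ½·ties.  The exact two-sided p
  enumerates all C(n1+n2, n1) assignments of the observed values (tie-safe
  by construction) and doubles the smaller tail, capping at 1.  This
  convention reproduces 2/330 ≈ 0.0061 (complete separation) and 4/330 ≈
  0.0121 (one inversion) at 7 vs 4.  Enumeration is used while
  C(n1+n2,n1) ≤ 2·10⁵; beyond that a tie-corrected normal approximation
  with continuity correction takes over.  No multiple-testing correction
  is applied anywhere.
* **Spearman**: Pearson correlation of mid-ranks; undefined (error) for
  n < 3 or constant input.
* **Cox**: single continuous covariate, Breslow tie handling,
  Newton–Raphson with step-halving on the partial likelihood, tolerance
  1e-8 on the score, at most 50 iterations; SE from the observed
  information; the covariate is centred internally.  Degenerate inputs
  (no events, constant covariate) raise; monotone likelihoods return a
  flagged, estimate-free fit.  Breslow was chosen as the simplest
  published convention; with continuous simulated times there are no
  ties and Breslow coincides with Efron, which is how the implementation
  is cross-checked against lifelines.
* **Meta-analysis**: inverse-variance common effect; DerSimonian–Laird
  τ² = max(0, (Q−df)/(Σw−Σw²/Σw)); I² = max(0, (Q−df)/Q), defined as 0
  when Q = 0; random-effects weights 1/(se²+τ²); p_Q from χ²(k−1).
  Pooling is on the log-HR scale; HRs are exponentiated for reporting.
  Confidence intervals for τ² and I² are out of scope.

## The flux generator

No per-sample concentration data are deposited, so cohorts are
simulated.  The generative model is this package's own construction: a
total flux T (nmol/mg) enters the pathway at Cer; at each node an
outgoing edge with enzyme activity a_e receives the share a_e/(κ+Σa)
of the node's inflow and the node retains κ/(κ+Σa).  Retained mass over
all nodes sums to T exactly (tested to 1e-12).  The 0-series and
c-series branches are present in the graph but default-silent (the
0-series was not expressed in the tissue data); κ defaults to 1.
Multiplicative mean-preserving log-normal noise (cv `noise_cv`, default
0.2) is applied per species and never renormalised.

This is the simplest mass-conserving model in which single-enzyme
knockouts reproduce the observed arrest profiles: B4GALNT1 = 0 leaves
only GM3/GD3 (profile C), ST8SIA1 = 0 shifts everything to the a-series
(profile E).  One known property: species downstream of GD3 are
monotone in B4GALNT1 activity only while a_B4 ≤ √(κ(κ+a_ST8SIA1));
above that bound, raising B4GALNT1 starves the GD3 branch faster than
it drains it.  All archetype presets sit inside the monotone regime and
the knockdown property is tested by scaling B4GALNT1 downward from each
preset.

Archetype presets (activities for ST8SIA1 / B4GALNT1 / B3GALT4 /
ST3GAL2-3, with upstream enzymes at 50 and κ = 1 unless noted) are
calibrated only to the verbal profile definitions:

| preset | activities | T (nmol/mg) | zero-noise profile |
|---|---|---|---|
| LR-A | 30 / 4.5 / 6 / 6 | 12 | A (GT1b 0.51 of total) |
| HR-A | 30 / 4.5 / 6 / 6 | 4 | A |
| HR-B | 30 / 4 / 0.05 / 1 | 3 | B (GD2 0.65) |
| HR-C | 3 / 0.05 / 6 / 6 | 2 | C (GM3+GD3 0.95) |
| HR-D | 3 / 2 / 15 / 15 | 5 | D (GD1a = GT1b = 0.29) |
| HR-E | 0 / 0.8 / 0.25 / 1.5, κ = 0.2 | 3 | E (GM2+GD1a 0.75) |

LR totals exceed HR totals, matching the reported direction of the
group comparisons.  At noise_cv = 0.2 every preset returns its intended
label in ≥ 95% of draws (measured ≈ 99% over 500 seeded draws).

Ceramide mixtures draw bin proportions (short/normal/long) from a
Dirichlet centred on per-archetype CerS-like weights (concentration 60)
and split mass uniformly within each bin; the HR-C preset is
long-dominant and HR-A short-leaning, mirroring the published anchor
groups.  One mixture per sample is applied to all species, since only
GD2 anchors are analysed downstream.

Cohorts couple each HR sample's B4GALNT1 activity to a log-normal
expression covariate, `a = a_preset·exp(0.7·g)` with g standard normal
winsorised at ±2 — a roughly 16-fold central range, the order of spread
tumor mRNA levels show.  Coupling is restricted to HR samples because
the low-risk group is uniformly differentiated (every LR sample shows
profile A) and the expression covariate enters the HR analyses only.
Within one archetype GD2 output is strictly monotone in the covariate
(Spearman ρ = 1 at zero noise).  Across a mixed-archetype cohort GD2 is
additionally controlled by B3GALT4, which caps the achievable
correlation near ρ ≈ 0.7 — a structural limitation of the generator, so
the strong-correlation property (median ρ ≥ 0.9 over 500 cohorts at
noise_cv 0.2) is evaluated in the B4GALNT1-limited regime where the
final synthesis step is rate-limiting.

Survival studies draw x ~ N(0,1), exponential event times with rate
λ0·HR^x (λ0 = 0.1/year), and Uniform(0,c) censoring with c solved
analytically (Gauss–Hermite quadrature + root finding) so the expected
censoring fraction matches the request (default 20%).

## Problem sizes and numerical choices

The shipped analyses use an 18-sample cohort (8 LR + 10 HR), 200
replicates of the three-study meta-analysis design (n = 124/95/498) and
1000 replicates for Cox CI coverage at n = 300 — sizes at which every
Monte-Carlo property is stable to well within its stated tolerance.
Ratios with empty denominators return an explicit `inf` sentinel that
round-trips through CSV.  Identical seeds produce byte-identical
outputs.

## What passing tests do and do not show

The generator emulates composition archetypes, anchor mixtures and
expression-linked hazards with independent log-normal species noise; it
does not emulate correlated measurement error across species,
batch/run-order effects, chromatographic interferences,
species-specific anchor distributions, or treatment dynamics.  Passing
tests therefore validate the pipeline's algebra, invariances and
estimator calibration — not the biological fidelity of any particular
tumor dataset.  Published per-sample labels shipped as fixtures are used
to verify table logic, never to train or validate the classifier.
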