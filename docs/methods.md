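# Methods

This note documents the models and procedures radscreen implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical choices that matter.

## Clonogenic survival

A colony formation assay plates a known number of single cells and counts
the colonies that grow. Plating efficiency is PE = mean colony count /
cells plated; the surviving fraction at dose D is SF(D) = PE(D)/PE(0 Gy).
SF may exceed 1 with noisy counts; it is flagged
(`OverUnitySurvivalWarning`) but never clipped, because clipping the upper
tail would bias α downward.

**Linear-quadratic fit.** SF(D) = exp(−(αD + βD²)) is linear in (α, β) on
the log scale, so the fit minimises ‖√w (X·b + ln SF)‖ with X = [D, D²]
under b ≥ 0 (scipy's NNLS). The non-negativity constraint excludes
non-physical rising curves; when the true β is interior the constraint is
inactive and the fit coincides with ordinary weighted least squares.
Options:

* `weights=None` (default): unweighted, matching common practice when
  technical-replicate curves are fitted without a stated weighting scheme.
* `weights="se"`: inverse variance from the per-dose SF standard errors,
  propagated to the log scale as (sf/se)².
* `weights="poisson"`: known-covariance generalised least squares. For
  Poisson colony counts, Var(ln SF_D) ≈ 1/C_D + 1/C₀ where C_D and C₀ are
  the total colony counts at dose D and 0 Gy, and every point shares the
  +1/C₀ term because all SFs divide by the same 0 Gy plating efficiency.
  The fit whitens with the Cholesky factor of Σ = diag(1/C_D) + 1/C₀ and
  reports the exact (XᵀΣ⁻¹X)⁻¹ parameter covariance with no estimated
  residual variance. This is the mode the parameter-recovery study uses:
  with it, ±2 se intervals for α cover the truth at ≈ 92–96% in simulation,
  whereas the naive unweighted covariance undercovers (≈ 75%) because the
  errors are heteroscedastic and correlated through the shared denominator.
* `fix_beta=True` fits the purely exponential model (β ≡ 0), which makes a
  two-dose design identifiable.

The structural 0 Gy point (sf = 1 by construction, zero residual) is
excluded from the residual degrees of freedom in the s²-based modes and from
the GLS system entirely.

**Dose at a target SF.** βD² + αD + ln(s) = 0 is solved as
D = 2L/(α + √(α² + 4βL)) with L = −ln s. This algebraically equivalent form
of the quadratic root is numerically stable as β → 0 (the textbook
(−α + √…)/2β form loses ~8 digits when a fitted β sits at the constraint
boundary, ~1e−17) and reduces smoothly to L/α. SER₁₀ is the ratio of the
control to treated dose at SF = 0.10; values above 1 mean sensitization.

**Curve comparison.** Two-way fixed-effects ANOVA (statsmodels OLS +
`anova_lm`, type-II sums of squares) with survival as the response and dose
and condition as categorical factors. Dose is categorical rather than
continuous so the test does not presuppose the LQ shape. The interaction
term is included by default and the condition main effect is reported as
"the" curve p-value; `log_sf` switches the response to ln SF. Both switches
exist because published descriptions of this ANOVA rarely state either
choice. Empty dose × condition cells raise an error naming the cells; a
saturated fit with no residual degrees of freedom is rejected.

## Screen scoring

Each siRNA occupies one well, and each plate exists as an unirradiated and
an irradiated copy (7 Gy screening dose); per-well SF is the ratio of the
paired plating efficiencies, paired by the base plate id.

* **Normalization**: SF is divided by the per-run *median* of NT-control
  wells. The median resists control outliers; the reference recipe is a
  deliberate, documented choice since "normalized SF" alone does not fix
  one.
* **R-score**: (normalized SF − 1) / meanAD(NT normalized SF), with meanAD
  the mean absolute deviation about the mean — the literal reading of the
  statistic's definition; `mad_center="median"` switches to the more robust
  median-based MAD. Targets rank ascending (rank 1 = most sensitizing),
  average ranks on ties; control wells are scored but not ranked.
* **Rank product**: geometric mean of a gene's per-run ranks, requiring the
  same gene set in every run (k ≥ 2). The significance null permutes each
  run's rank column independently. Monte Carlo p-values (default 10,000
  permutations) carry a +1 pseudo-count so they are never zero. When
  exhaustive enumeration is feasible ((n!)^k ≤ 10⁶) the collapsed null —
  independent uniform ranks on {1..n} per run — is enumerated and the exact
  tail probability count/n^k is returned; no pseudo-count is needed there
  because the observed tuple is part of the enumeration, and this is what
  the Monte Carlo estimate converges to.
* **Z-factor**: 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋| on normalized SF of the positive
  (PRKDC-like) and NT controls, sample sd (n−1). Undefined when the means
  coincide.
* **Hit selection**: first n by ascending R-score (primary, single pooled
  run) or ascending rank product (confirmation, triplicate), default
  n = 240; ties break by mean per-run rank then lexicographic gene id, so
  selections are reproducible.

## Cytogenetics and reporters

Metaphase records carry six non-negative counts (breaks/gaps/exchanges ×
chromatid/chromosome type). Summaries report class-wise and dichotomized
means ± sample sd (n−1) per condition × timepoint. The per-100-cells rate
multiplies the per-metaphase mean by the externally measured mitotic
(p-H3-positive) fraction and by 100; it is linear in both arguments and the
package never touches raw flow-cytometry events — the fraction is an input.
SCE rates and foci counts use the same group summaries. Reporter repair
efficiency is the GFP-positive percentage of a condition divided by its
control (1 = no change). Group comparisons use the two-sided two-sample
t-test, Student by default with a Welch switch, since the underlying
convention is rarely stated.

## Lineage-fate classification

The classifier consumes annotated event logs, not images: five event types
(condensation_start, karyokinesis_complete, cytokinesis_complete,
daughter_fusion, death) with explicit interphase/mitosis labels on deaths —
inference of the death phase from surrounding events is deliberately out of
scope, keeping the classifier faithful to manual annotation. Rules:

* surviving ⇔ no cell in the lineage died; otherwise the fate is death in
  interphase or in mitosis;
* with deaths in parallel branches, the death whose event *starts* earliest
  decides the sub-class ("initiated earlier" is read as event start time;
  simultaneous times break ties by the lower cell id — the rule's clock is
  an interpretation and is documented as such);
* polyploidization (daughter fusion, or karyokinesis never followed by
  cytokinesis) is flagged only in surviving lineages;
* mitosis length = cytokinesis − condensation, or karyokinesis −
  condensation when cytokinesis never occurs; undefined for cells dying in
  mitosis.

Validation rejects order violations (karyokinesis before condensation,
etc.), unknown parents and unlabelled deaths. Classification is exhaustive
and deterministic given distinct event times.

## Synthetic-data generators

The generators define the study conditions for every test and for
`scripts/acceptance.py`.

**Screen** (`ScreenSimConfig`): colony counts are Poisson with mean
cells_plated × base_pe × plate_effect × SF(dose; α₀·m_g, β₀). Knockdown
effects multiply α only (`effect_model="alpha_multiplier"`): the simplest
one-parameter radiosensitization consistent with "more negative score =
more sensitizing". Plate effects are multiplicative lognormal on plating
efficiency, drawn independently for the unirradiated and irradiated copy of
each plate — a known confounder against which NT normalization can be
tested. Defaults that mirror the screening design this emulates: 7 Gy
screening dose, NT negative controls, a strong positive control (α
multiplier 2.5, chosen so the Z-factor is positive at default noise),
triplicate confirmation runs. Defaults the published design does not state
and which are therefore invented here: cells_plated = 2000, base_pe = 0.5,
α₀ = 0.25 Gy⁻¹, β₀ = 0.03 Gy⁻² (a typical radioresistant epithelial-line
curve), plate_effect_sd = 0.1, hit multipliers uniform on (1.6, 3.0).
A `noise_free` flag replaces draws by rounded expectations (closed-form
checks hold exactly), and a `dispersion` switch substitutes gamma-Poisson
(negative-binomial) counts for robustness work. Identical config + seed
gives bit-identical tables.

**Dose-response experiments**: Poisson counts at arbitrary dose lists
(0 Gy required), used for parameter-recovery studies.

**Lineage logs**: two-generation branching processes — the founder divides,
dies (interphase or mitosis), or polyploidizes by karyokinesis-only;
daughters independently die or survive, or fuse — with uniform interphase
timings (600–1200 min) and normal mitosis lengths (mean 45 min, typical of
the cell line this emulates). The generator returns the realized truth per
lineage, and the death/survival split has a closed form
(`lineage_fate_probabilities`) that is timing-independent and serves as the
recovery oracle. The interphase/mitosis death split depends on the timing
distributions and is checked against the realized truth instead.

**Metaphases**: independent Poisson counts per class, the chromatid and
chromosome means split 60/30/10 over breaks/gaps/exchanges by default.

What the generators do *not* emulate — and hence what passing tests do not
show about real data: siRNA off-target structure, strand-level seed
effects, spatial within-plate gradients, edge effects, count overdispersion
beyond the optional negative-binomial switch, cell-cycle-dependent
radiosensitivity, lineages deeper than two generations, and inter-class
correlation of aberration counts.

## Problem sizes

The recovery and calibration studies run at deliberately desk-scale sizes:
200 simulated dose-response experiments (6 doses × 3 wells, 500
cells/well); 1,000-gene screens in triplicate for null calibration
(4,000 permutations) and planted-hit recovery (50 sensitizers); 1,000
lineages; 500 metaphases. These sizes put Monte Carlo error well inside the
tolerances asserted (binomial 3 s.e. bands, KS at α = 0.01) while keeping
the whole suite and the acceptance script in the seconds-to-minutes range
on one CPU.

## Known limitations

* The LQ fit linearises on ln SF; zero-colony doses (SF = 0) cannot enter
  the fit and raise an error listing the point.
* Exhaustive rank-product enumeration uses integer ranks 1..n; observed
  average-tie ranks are compared against that integer null, which is exact
  only in the absence of ties.
* The ANOVA assumes homoscedastic cells; survival variances in practice
  shrink with dose, which `log_sf=True` partly absorbs.
* The per-100-cells estimator propagates no uncertainty from the mitotic
  fraction, which enters as a point measurement.
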