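# Methods

## Scope and model chain

The package implements a screening pipeline, not a kinetic model. Its
chain is:

1. dialysis concentrations → unbound fraction f_u (per replicate);
2. replicate/lab aggregation → f_u min/median/max per (API, species);
3. fish:human ratios Rf_u (median and worst-case) → prioritization
   flags;
4. blood:water partitioning → original and refined therapeutic water
   concentrations (TWC) → conservatism against chronic effect data;
5. an additive model relating f_u to molecular descriptors.

Key assumptions, in the order they enter:

- **Equilibrium dialysis is at equilibrium.** f_u = C_buffer/C_plasma
  presumes the free concentration has equalized across the membrane and
  that membrane/plate binding is captured by the recovery QC rather
  than modelled.
- **Linear binding for the dilution correction.**
  `f_u = f_u,D / (D − (D−1)·f_u,D)` assumes the bound:free ratio scales
  with protein concentration (no site saturation). The test suite
  verifies the correction against an exact single-site mass-action
  simulation in the trace-drug regime, where it is algebraically exact.
- **Hydrophobic partitioning.** `P_b:w = 10^(0.73·LogD − 0.88)` with
  LogD at pH 7.4 for the generic ("fish") model and at the species'
  plasma pH (7.9 for rainbow trout) for the refined model. Coefficients
  are configurable but default to these regression values.
- **Read-across of C_max.** The refined TWC
  `(C_max/Rf_u)/P_b:w` assumes human therapeutic plasma levels mark the
  onset of pharmacological activity in fish, adjusted only for
  availability; metabolism and uptake kinetics are explicitly out of
  scope.

## Aggregation and QC conventions

Within a laboratory, replicate f_u values are averaged (arithmetic
mean); across laboratories, min/median/max are taken over lab means,
with the midpoint convention for the median of an even count (the
convention is not forced by the source data; it is recorded here as the
package's choice). A single-lab API therefore has min = median = max.

f_u > 1 can arise under measurement noise. Such values are retained and
flagged (`fu_above_one`), never clamped or silently dropped — clamping
would bias worst-case ratios downward. Mass recovery is classified
pass (≥ 70%), caution (50–70%) or fail (< 50%); bands are configurable.
Both thresholds are inclusive at the boundary.

Rf_u thresholds (median ≥ 3, worst-case ≥ 10) are inclusive.
Group summaries over speciation codes support two named collapses:
`charge_class` ({A,a}→anionic, {C,c}→cationic, N→neutral,
Z→zwitterion) for modelling, and `ionization_group` ({a,N,c}→unionized)
for proportion reporting. Group denominators are configurable
(`measured` excludes below-quantification ratios; `all` counts every
classified row) because the appropriate denominator depends on whether
unquantifiable APIs belong in the reported proportion.

An Rf_u recorded as 0 is treated as below quantification: it yields no
refined TWC (absent, not zero, and not infinite priority). Similarly,
missing C_max propagates as absent TWC fields.

## Reference-table reproduction and printed precision

The packaged 44-API table stores printed values verbatim; the pipeline
never re-derives its inputs. When recomputed TWC columns are compared
against the printed ones, tolerance is the larger of a relative band
(5% in the acceptance check; most cells agree within 1%) and half an
ulp at the printed decimal precision — a cell printed as `0.01` is only
determined to ±0.005. Columns that depend on the Rf_u input
additionally inherit that input's printed precision: a worst-case ratio
printed as the integer `1` (true value anywhere in [0.5, 1.5)) only
determines refined quantities to ±50%. One consequence worth noting:
recomputing the original/refined reduction factor from the printed
integer Rf_u puts meloxicam at 10.06 whereas the table's own (unrounded
Rf_u) value is 9.91, so counts of APIs in the 10–100× reduction band
are taken from the stored ratio column, not recomputed.

## The descriptor GAM

Model: fourth-root f_u ~ s(MW, k=4) + s(LogD, k=4) + s(pKa, k=4) +
charge (4-level factor), Gamma family with log link, fitted by
penalized IRLS (statsmodels `GLMGam`, cubic B-splines). Choices:

- **Transform ladder.** Candidates are applied in the order none,
  log10, square root, fourth root, stopping at the first whose
  Shapiro–Wilk p exceeds 0.05; if none passes, the fourth root is used.
  The ladder order is kept as stated even though the square root is
  conventionally a milder transform than the logarithm; in practice
  strongly right-skewed f_u panels terminate at the fourth root, which
  is also the fitting default. The response is transformed first and
  the Gamma/log-link family then applied to the transformed response —
  a literal reading of the procedure; a Gamma GLM on the raw fractions
  would be the more conventional alternative.
- **Smoothing selection.** Per-term smoothing weights are chosen by
  generalized cross-validation: coordinate descent over a log-spaced
  grid (10⁻³…10⁶), two sweeps. k = 4 caps each smooth at 3 effective
  degrees of freedom, appropriate for panels well under 100 compounds.
  The basis-dimension diagnostic flags a smooth as inadequate when its
  edf exceeds 0.9·(k−1).
- **Term significance.** Wald-type tests on each smooth's coefficient
  block (statsmodels `test_significance`); the charge factor is tested
  as a joint Wald test of its dummy coefficients. A seeded permutation
  test (shuffle one predictor, refit, compare residual deviance;
  ≥ 1000 permutations) is provided as a fitting-framework-independent
  check. On 50 seeded synthetic panels (n = 200) the Wald test flags
  the generative LogD effect in 100% of panels and the null MW
  predictor in 4% — acceptable power and type-I behaviour at this
  design size.
- **Degenerate inputs.** A constant response returns a zero-deviance-
  explained result rather than an error; constant predictors are
  dropped with a warning.
- Reported fit metrics: deviance explained
  `100·(D_null − D_res)/D_null` (preferred) and an adjusted R² computed
  on the transformed-response scale using total effective degrees of
  freedom.

Per-species reference fit statistics from the source study cannot be
recomputed here because the per-species measured f_u values behind them
are available only graphically; the package substitutes the
property-based checks above on synthetic panels with known truth.

## Synthetic study generator

`SyntheticConfig` defaults encode the reference study design: 44
compounds, triplicate wells, one laboratory, 10 µM nominal spike,
10-fold plasma dilution for fathead minnow only, 10% measurement CV
(multiplicative lognormal on each chamber concentration), per-lab
lognormal bias (sd 0.10, keeping cross-lab f_u spread under the 3×
observed in inter-laboratory comparisons), and uniform recovery loss up
to 30% applied proportionally to both chambers before measurement.
Descriptor envelopes are MW 150–800 g/mol, pKa 0–12, LogD −2…5, with
the charge mix matching the 44-API panel (≈ 39% anionic, 55% cationic).

Latent truth is phenomenological: logit(bound) is linear in LogD with
charge-class offsets per species. The human anionic offset (+5 vs +1
in trout) makes the latent anionic Rf_u median ≈ 40–55, the 10–100×
decade that motivates the refinement; cationic compounds sit near or
below parity because their LogD rises at the higher fish plasma pH.
What the generator does **not** emulate: saturable or multi-protein
binding (albumin vs AGP competition), pH-dependent binding beyond the
LogD shift, correlated descriptors, assay-plate effects, or
concentration-dependent recovery. Passing tests therefore demonstrate
the pipeline's arithmetic and statistical behaviour under the assumed
noise structure, not the biology of any real species.

Problem sizes used by the checked properties: 50 panels of n = 200 for
detection rates, n = 200 for estimator recovery (triplicates, 10% CV:
≥ 95% of compounds with f_u > 0.05 estimated within ±20%), n = 30
noiseless for exact end-to-end recovery (tolerance 1e-9 relative).

## Numerical conventions

- Dilution correction and its inverse round-trip to 1e-12 relative; at
  D = 10 the general formula matches `f_u10/(10 − 9·f_u10)` to 1e-15.
- Unicode minus and en-dash signs in input tables are normalized to
  ASCII; numeric parsing is locale-independent.
- Missing values are represented as absences (`None`/empty CSV cells),
  never 0; a printed `0` Rf_u is below-quantification (see above).
- All randomness flows from a single integer seed per generator config;
  per-species streams are derived via CRC32 of the species name so that
  adding a species does not disturb the others.

## Known limitations

- The screen is a prioritization tool: no uptake kinetics, metabolism,
  or bioaccumulation, and effect read-across assumes pharmacological
  plasma levels transfer across vertebrates.
- The partition regression was calibrated on neutral-dominated
  chemistry; using LogD at plasma pH mitigates but does not remove its
  limitations for permanently charged species.
- The GAM's Wald tests are approximate under penalization; p-values
  near a decision threshold deserve the permutation check.
- Recovery QC uses equal chamber volumes by default; pass actual
  volumes where they differ.
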