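# Methods

This note documents the models and procedures implemented in `flavoperm`,
the numerical choices behind them, what the synthetic-data generators do and
do not emulate, and the design decisions taken where the analysis left
genuine freedom.

## Transport analytics

Apparent permeability is computed as Papp = (ΔQ/Δt)/(A·C0), the receiver
appearance rate (μmol/s) normalized by insert area (cm²) and donor
concentration (μmol/cm³), giving cm/s. Values are held internally in cm/s;
files and reports use the conventional ×10⁻⁶ cm/s display scale to avoid
magnitude bugs while matching how such data are tabulated.

The efflux ratio ratio_p = Papp(B→A)/Papp(A→B) is computed from
replicate-mean Papp values (not per-replicate then averaged), matching how
the reference tables were produced. Mechanism bands:

| ratio_p | class |
|---|---|
| ≤ 0.5 | preferential_absorptive |
| (0.5, 0.8) | indeterminate |
| [0.8, 1.5] | passive |
| (1.5, 2.0] | indeterminate |
| > 2.0 | efflux_implicated |

The passive band is closed and the efflux bound strict, a literal reading of
the stated cut-offs. The absorptive bound is *inclusive* at 0.5: the
reference study groups a compound whose ratio prints as exactly 0.50 with
the absorptive class, so a strict `< 0.5` could not reproduce its grouping
from the printed data. The two unnamed gaps map to `indeterminate`; the
study itself treats a compound at 1.84 as unresolved.

Cellular accumulation (μmol compound per g cell protein) is analysed the
same way via ratio_c. `ND` (not detected) and `NT` (not tested) are distinct
missing codes and are excluded from every statistic, never zero-filled.
Direction differences use the two-sided *pooled-variance* Student t-test
(not Welch), the form named by the reference analysis; with fewer than two
replicates on either side the comparison is `unevaluable`. The
permeability–accumulation association is summarized as a Pearson R² over
compounds with complete pairs (≥ 3 required).

## Stability and monolayer QC

Relative concentration (%) is the D-Hank's/methanol peak-area ratio × 100;
values above 100% are legal. Classes: ≥ 50% stable, < 40% unstable, and the
unnamed [40, 50)% gap is reported as `questionable` rather than silently
assigned to either side. Mass-balance recovery is the dosed fraction
recovered over receiver + donor + cells; the 60% acceptance gate is exposed
as a configurable threshold. Monolayers pass QC only with TEER strictly
above 600 Ω·cm² *and* Lucifer yellow flux strictly below 0.5 × 10⁻⁶ cm/s;
failures list every violated gate.

## QSPR engine

The response is pPapp = −log₁₀ Papp(A→B) (cm/s). The workflow:

1. **Correlation matrix** — pairwise Pearson coefficients among response
   and descriptors; constant columns raise an error naming the column.
2. **Collinearity filter** (threshold 0.7) — while any descriptor pair has
   |r| above threshold, the member of the worst pair with the weaker
   |r| to the response is dropped (greedy, deterministic).
3. **Stepwise selection** — forward entry on the smallest partial-F
   p-value below 0.05, then backward removal of any member above 0.10
   (classic SPSS-style defaults, configurable). Ties break on the lower
   p-value, then alphabetically, making the path deterministic. When a fit
   is numerically exact (residual sum of squares below 10⁻¹⁰ of the total),
   t-ratios are 0/0 noise; terms are then scored decisive (p = 0) if they
   contribute fitted variance and vacuous (p = 1) otherwise.
4. **Fit** — OLS via QR on the intercept-augmented design (rank-deficient
   designs raise), or PLS1 by NIPALS on autoscaled (mean-centred,
   unit-variance) data with coefficients back-transformed to original
   units. With as many components as descriptors on full-rank data, PLS
   reproduces OLS to numerical precision, which the tests assert; the
   default reproduction path is OLS since the reference model's component
   count is unstated and full-rank PLS is identical. `n_components="auto"`
   picks the count maximizing leave-one-out Q², standard chemometric
   practice. Reported statistics: R², R²_adj = 1−(1−R²)(n−1)/(n−k−1),
   F = (R²/k)/((1−R²)/(n−k−1)), SEE (residual SD on n−k−1 df), and RMSE
   (√(SS_res/n)).
5. **Validation** — leave-one-out Q² = 1 − PRESS/SS_tot with a full refit
   per fold (verified exactly against a brute-force oracle in the tests);
   external R²_pred = 1 − Σ(y−ŷ)²/Σ(y−ȳ_train)², the train-mean-referenced
   convention; test RMSE.
6. **Outlier screen** — a single pass: fit on all candidates, exclude
   compounds with |observed − predicted| > 0.600 log units, refit once.
   Deliberately not iterated: the reference analysis retains a training
   compound whose residual exceeds the threshold only after the refit.
   The absolute value is used rather than the signed difference; both
   screened compounds in the reference data have positive residuals, so
   the outcome there is identical, and the symmetric form also catches
   gross over-predictions.

On the packaged training block (22 compounds, 4 descriptors) the OLS fit
gives R² = 0.881, R²_adj = 0.853, RMSE = 0.141, Q² = 0.809, and
coefficients (4.715; 1.362, 0.059, 0.020, 0.056) — the packaged study's
published equation to within rounding of the third decimal. The F statistic
is reported on k = 4 numerator degrees of freedom (31.6 here); the
reference prints an F consistent with 3 df, which cannot be resolved from
its text and is left as-is.

## Synthetic data

`gen_qspr_dataset` draws descriptors from a multivariate normal whose
marginals and inter-correlations default to the empirical values of the 28
modelled study compounds, then forms
pPapp = β₀ + Σβx + ε, ε ~ N(0, σ²). Defaults are the study conditions: the
published coefficients as truth, σ = 0.141 (the published training RMSE),
28 compounds split 22/6 at random. `gen_transport_experiment` produces
replicate receiver rates Papp·A·C0 with *multiplicative* Gaussian noise of
given CV (chromatographic quantification error scales with signal, whereas
pPapp noise is additive on the log scale), the secretory direction scaled
by a true efflux ratio; geometry defaults to a 12-well hanging insert
(1.13 cm², apical 0.4 cm³ / basolateral 1.95 cm³, 40 μM, 60 min). Parameter
sets whose noise-free flux would move ≥ 10% of the donor dose violate the
sink assumption and are rejected with advice to shorten the assay.

What the generators do **not** emulate: the real SlogP_V3 column is
semi-discrete (four structural levels), not Gaussian; real assays show
saturable efflux kinetics, metabolism and recovery losses; accumulation is
not simulated at all. Passing recovery tests therefore demonstrates
correctness of the estimators under the linear-Gaussian assumptions, not
robustness to those real-data features.

All generators are pure functions of their spec including the seed
(default 20171129); identical inputs give bit-identical outputs.

## Numerical and data-handling choices

- Reported tables round to the reference precision (2 decimals for
  Papp ×10⁻⁶, 3 for pPapp and descriptors); full precision is kept
  internally. Printed-value cross-checks in the tests therefore carry the
  rounding envelope of their inputs: e.g. a Papp printed as 0.29 × 10⁻⁶
  bounds the derived pPapp only to ±0.0075.
- Record invariants re-derive printed ratios (ratio_p, ratio_c, RSD) from
  their components at load time and reject inconsistencies beyond rounding.
- The pipeline writes nothing until every stage succeeds, logs package
  version, config hash and seed, and produces byte-identical output for an
  unchanged configuration.

## Known limitations

- Descriptor values are consumed as inputs; computing Q_C3′, E_sol,
  SlogP_V3 or vsurf_ID1 from structures (DFT, VSA/VolSurf machinery) is out
  of scope, as are structure-file parsing and 3D-QSAR.
- Raw replicate-level data behind the packaged means/SDs are not available,
  so the accumulation significance flags can be property-tested but not
  reproduced exactly.
- The insert membrane area of the reference assays is not recorded;
  computing Papp from raw rates requires a user-supplied area.
- The reference's printed predicted-pPapp column is not exactly reproducible
  from its printed equation (its generating model is not fully
  recoverable); the engine's own refit statistics match the published ones,
  and the printed predictions are retained in the dataset for error
  analyses.
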