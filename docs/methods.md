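# Methods

## Model and estimation

The core object is a dynamic factor model for a centered river × year
panel of mean fork lengths (mm):

    y_t = Z x_t + a + D d_t + v_t,   v_t ~ MVN(0, R)
    x_t = x_{t-1} + w_t,             w_t ~ MVN(0, Q)

**Identifiability.** `Q` is fixed at the identity and the entries of `Z`
above the diagonal are constrained to zero during estimation; the loadings
carry all scale. After fitting, a varimax rotation (`Z → ZH`,
`x → Hᵀx`, `H` orthogonal) is available for interpretation; fitted values
are invariant to it. Because `Q = I` is rotation-invariant, the trend
*basis* is only identified up to an orthogonal transformation — individual
trends are interpretable objects, but any comparison of estimated trends
with an external reference must allow for rotation and sign.

**Initial state.** `x_0` is a fixed parameter with zero prior variance
(`x_1 ~ N(x_0, I)`). This makes the joint distribution of the stacked
observations an ordinary multivariate normal, so the absolute
log-likelihood is well defined and can be cross-checked against a direct
joint-density evaluation (`loglik_exact`, used in the tests as an
independent oracle; it agrees with the Kalman filter to < 1e-6 on small
panels, with and without missing cells). Absolute log-likelihoods under
other initial-state conventions (e.g. diffuse priors) differ by a
constant-like term; all comparisons inside this package use one
convention.

**Offsets.** Panels are fitted on the centered scale (river means
removed), so the offsets `a` default to zero; estimating them jointly with
`x_0` would be confounded (a shift of `x_0` can be absorbed by `a`).
`estimate_offsets=True` exists for uncentered work but is not the
supported path — the fitting entry points require a centered panel.

**Missing data.** A missing river-year simply shortens the observation
vector at that time step: the filter, smoother and likelihood use only the
observed components, and no imputation is performed anywhere.

**EM.** The E-step is a Kalman filter plus RTS smoother; the M-step
updates, in turn, the initial state (`x_0 ← E[x_1 | y]`), the free entries
of `[Z | a | D]` jointly from weighted normal equations (weights from the
current `R`, grouped by missing-data pattern), and the `R` parameters.
For the two diagonal structures the `R` update is the exact closed form.
For `equalvarcov` (`R = σ²I + c(J − I)`) no closed form exists once
missing-data patterns vary, so the two parameters are updated by an inner
numerical maximization of the expected complete-data objective (compound-
symmetry eigenstructure, per-pattern sufficient statistics), started at
the current values and kept only if it improves — a generalized-EM step.
The whole iteration is therefore an ECM scheme and the log-likelihood is
non-decreasing (asserted in tests to 1e-8 slack). Variances are floored
at 1e-10 so noise-free panels remain filterable.

**Convergence defaults.** Absolute log-likelihood change < 1e-6 or
50,000 iterations (configurable up to the millions; EM for factor models
has a notoriously slow tail, so tests and examples that only need
parameter estimates — not terminal-digit likelihoods — use a few hundred
to a few thousand iterations, sizes chosen so the whole suite runs on one
CPU in minutes). A fit that hits the cap is returned flagged
`converged=False` rather than raising; the selection loop drops such fits.

**AICc.** `-2 logL + 2Kn/(n − K − 1)` with `n` = number of non-missing
observations (a `cells` switch uses S·T instead). `K` counts free
loadings (Sm − m(m−1)/2), the m initial-state entries, the R parameters
(1, 2 or S), S coefficients per covariate, and offsets if estimated.

**Covariate inference.** `D` enters the observation mean linearly, so with
the other parameters held at their MLEs its observed information is exact:
`I(D) = Xᵀ Σ⁻¹ X` over the stacked non-missing observations, with `Σ` the
model-implied joint covariance. Standard errors and 95% CIs come from
`I(D)⁻¹`; they do not propagate uncertainty in `Z`, `R` or `x_0`.

**Confidence bands on fitted series.** The band for river s at year t is
`Z_s x̂_t ± z·sqrt(Z_s V_t Z_sᵀ)` from the smoothed state covariance
`V_t` — state uncertainty only, conditioned on the estimated parameters.
Two consequences, both measured in the tests: empirical coverage of the
latent signal plateaus around 85% rather than the nominal 95% (parameter
uncertainty is excluded by construction), and on noise-only panels the
bands around a spurious smooth factor are narrow, which matters for the
significance rule below.

## Inference conventions

**Model selection** fits every combination of trend count (1–4) and error
structure, drops non-converged fits, ranks by AICc and reports Akaike
weights. Among fits within two AICc units, fits containing an
"unimportant" trend are set aside first — a trend whose largest absolute
loading, measured relative to the spread of the whole loading matrix, is
below 0.2 — then the fewest-parameter fit wins. The winner is
varimax-rotated when m > 1.

**Significance of a river's change** requires the 95% band of its fitted
series to sit entirely above zero (the river mean) in at least one run of
years and entirely below zero in at least one other; the reported change
is the maximum fitted value inside above-runs minus the minimum inside
below-runs, with the percent change dividing by the raw river mean. A
switch accepts any two zero-excluding runs regardless of sign. The rule
operates on pointwise intervals, so over a 51-year series it embeds a
multiplicity problem: on pure-noise panels at the 19-river study scale the
fitted model extracts a spurious smooth factor with confident (narrow)
bands and the river-level false-flag rate approaches 80–100%, while power
against a genuine shared 50 mm / 20 yr change at 10 mm noise is
essentially 1. The rule is faithful to its definition; treat its
positives on weakly-informative panels with caution. (Small
cross-sections, S ≤ 5, largely remove the spurious factor and the
false-flag rate drops to ~0–12%.)

**Clustering.** Loadings are centered and scaled per trend, distances are
Euclidean, linkage is complete; the gap statistic compares log
within-cluster dispersion against 100 uniform draws over the scaled
bounding box (seedable) for k = 1..6 and applies the one-SE rule.

**Covariate evaluation** refits the selected base model once per
covariate (no multi-covariate search: the candidate covariates are
strongly collinear, so joint fits would be uninterpretable), reports ΔAICc against the base
(negative = improvement), flags fits that improve on both AICc and
log-likelihood, and carries the conventional 2 × S reference threshold
(38 for 19 rivers, 16 for 8) alongside per-river coefficient CIs.

## Covariate constructions

- **Climate windows**: calendar-year means, and Dec–Mar means labelled by
  the January–March year.
- **Thermal habitat**: piecewise-linear growth-potential weight — 0 below
  1 °C and under ice ≥ 0.5; linear 1→6 °C; 1 on the optimal band
  (6–14 °C first year, 6–12 °C second); linear back to 0 at 18 °C
  (first) / 15 °C (second); 0 above. Weight × spherical block area
  (R = 6371 km), summed over the polygon per month, then averaged over
  the season window (a `sum` switch exists; the mean keeps the index an
  area comparable across windows of different length). Winter (Dec–Apr)
  indices are labelled by the January year. First-year polygon
  45–61° N × 64–40° W; second-year adds the Labrador Sea to 70° N and the
  Irminger/eastern Atlantic to 66° N out to 6° W, split at 45° W (Cape
  Farewell; configurable, since the verbal boundary leaves the meridian
  open). Cells with SST missing in every month are treated as land.
  Window-to-return-year lags are an explicit table (`RETURN_YEAR_LAGS`).
- **Food availability**: PC1 of centered/scaled annual prey-biomass
  series, sign-oriented so a positive loading sum makes low-biomass years
  negative; variance explained = leading correlation eigenvalue / number
  of series.
- **Density**: first sea-year = (maturing + non-maturing North American
  PFA) × e^(0.03·7) per smolt cohort; second = adjusted NAC non-maturing
  plus the SNEAC non-maturing component (already a 1 January value).
- **Exploitation rates**: the pooled NL + Labrador + St-Pierre catch of a
  size class divided by catch + returns — the standard exploitation rate,
  bounded in [0, 1], chosen over the literal catch / returns ratio
  because returns are counted after the fishery (the literal reading is a
  switch). West Greenland: catch over the non-maturing PFA as reported
  (1 August basis; configurable).
- **Scaling**: per-series z-scores with the n−1 SD convention, stored for
  inversion; covariates enter the DFA scaled.

## Synthetic data

The generators produce exactly the structures the analysis assumes, from
seeds: panels drawn from the factor model itself (19 rivers × 51 years,
1971–2021, 3 trends, loadings U(−2, 2), river mean lengths
N(543, 20²) mm, observation SD 15 mm by default, with each river observed
in one contiguous run of ≥ 20 years and overall missingness capped at
30% — monitoring gaps are head/tail blocks, not scattered holes, and DFA
behaves differently under the two); monthly 1° SST/ice fields with a
north–south gradient, an August-peaked seasonal cycle, an interannual
trend (0.25 °C/decade default) and a logistic ice ramp below 0 °C; and
stationary AR(1) covariate series (φ = 0.6 default). They emulate the
statistical structure only — no ocean dynamics, no survey sampling
pattern, no fish-level length distributions beyond normal within-river
noise — so passing tests demonstrate that the machinery is correct under
its own assumptions, not that those assumptions hold for any real river.

One consequence worth stating: with unit-innovation random walks and
U(−2, 2) loadings against 15 mm noise, a realized walk can wander very
little over 51 years (SD ~1–2), in which case its trend is close to
unidentifiable — even smoothing at the *true* parameters recovers such
trends poorly. Trend-recovery checks are therefore sharp only in the
lower-noise regime (the suite includes a 3 mm-noise recovery test), and
study-scale recovery is reported as measured.

## Numerical choices

- Kalman update in Joseph form; covariance symmetrization each step;
  Cholesky-based likelihood evaluation.
- Loadings initialized from the SVD of the zero-imputed centered panel
  (upper triangle zeroed, tiny entries nudged off zero); `R` initialized
  at half the sample variance; `x_0` at zero.
- The `equalvarcov` inner maximization parameterizes `σ² = e^u` and the
  correlation `ρ = c/σ² ∈ (−1/(S−1), 1)` through a logistic map, which
  enforces positive definiteness for every observed sub-block size.
- Varimax by the standard SVD iteration; `H` is returned so trends and
  state covariances are counter-rotated exactly.
- Gap statistic: within-cluster dispersion `Σ_r D_r / (2 n_r)` from
  squared Euclidean distances; B = 100 reference draws; ties in the
  one-SE rule resolve to the smallest k.

## Limitations

- No `unconstrained` R (rarely estimable on gappy panels) and no
  spatially-informed error structures.
- Coefficient and fitted-value intervals condition on the point estimates
  of `Z`, `R`, `x_0`; they under-cover, as quantified above.
- The significance rule is pointwise and anti-conservative on
  weakly-informative panels (quantified above).
- AICc model selection with capped EM iterations can mis-rank models that
  are within a few likelihood units of each other; selection tests use a
  strong-signal regime where the ranking is stable.
- The synthetic grid's ice field is a deterministic function of the
  noise-free SST, so SST–ice consistency is exact by construction rather
  than physical.
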