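# Methods

## Model

Bone remodeling is represented as a discrete cycle of length 4 weeks:
osteoclasts resorb a unit of *old* (mature) bone and osteoblasts form
new bone in the cavity, and the next cycle acts on the residual old
bone only. The 4-week cycle corresponds to the pre-osteoblast phase
plus the initial mineralization lag, and matches the observed week-4
peak of the formation marker; it is deliberately much shorter than a
complete histomorphometric remodeling period.

**Preliminary (single-compartment) model.** With resorption rate
`a` and formation rate `b` per cycle (0 < a < b < 1 under anabolic
treatment) and initial old bone `x0`, cycle *t* resorbs
R_t = a(1−a)^(t−1) x0, forms F_t = b(1−a)^(t−1) x0 and leaves
X_t = (1−a)^t x0 of old bone. Newly formed bone is never itself
remodeled; cumulative volume is a passive sum, in closed form
x0·(1 + (b−a)(1−(1−a)^t)/a). The looped recurrence is tested against
these closed forms at 1e−10 relative tolerance.

**Plenary (two-compartment) model.** State (V_OLD, V_NEW) evolves by
the linear map M = [[1−r_R, f_MAT], [r_F, 1−f_MAT]]; BMD is
V_OLD + f_BMD·V_NEW and the markers are P1NP(t+1) = r_F·V_OLD(t),
NTX(t+1) = r_R·V_OLD(t). Markers exist from cycle 1; state and BMD
from cycle 0. The total initial volume is normalized to 1 so k is
exactly the initial old-bone proportion; all comparisons with data in
measurement units go through per-outcome scale factors. Useful exact
consequences, all enforced as tests: NTX/P1NP = r_R/r_F at every
cycle; the per-cycle change of total volume is (r_F − r_R)·V_OLD(t);
the dominant eigenvalue of M exceeds 1 exactly when r_F > r_R. The
loop is verified against matrix-power propagation (200 random
parameter sets, 1e−10 relative tolerance).

Within the default search ranges the resorptive outflow r_R·k always
exceeds the maturation inflow f_MAT·(1−k), so old bone — and with it
both markers — declines over the first cycle everywhere on the grid.
The *global* 18-cycle marker maximum is at cycle 1 for most but not
all grid combinations: in strongly growing corners (small r_R, large
r_F and f_MAT) V_OLD overtakes its starting value late in the horizon.
The week-4 peak statement is therefore asserted at the reference
best-fit parameter set, and only the first-cycle decline is asserted
grid-wide.

## Observation model

Marker visits at weeks 0, 1, 4, 12, 24, 48, 72 and BMD at weeks 0, 24,
48, 72 are mapped to cycles by w/4; non-integral weeks are flagged,
never rounded. Fitted points are markers at weeks 4–72 (cycles 1, 3,
6, 12, 18) and BMD at weeks 0–72 (cycles 0, 6, 12, 18). Week-1
markers are excluded because a 4-week cycle cannot represent them;
baseline markers because the model defines markers only under the
treatment rates (there is no pre-treatment turnover parameter).
Whether the original analysis fitted those visits is unknown; both
exclusions are configurable.

## Likelihood

The exact error model used in the original analysis is not published
beyond "correlated errors clustered by subject", so the package
declares its own minimal version of that structure. For subject i,
outcome o ∈ {P1NP, NTX, BMD} and fitted week w:

    log y_{i,o,w} = log s_o + log μ_o(w; θ) + ε_{i,o,w}

with ε within a subject and outcome multivariate normal, variance
σ_o², exchangeable correlation ρ_o; subjects and outcomes independent.
Per grid point θ:

- s_o is profiled in closed form: for an intercept shared by
  identically distributed clusters the GLS estimate is the grand mean
  of log residuals.
- Balanced data (no missing visits): the exchangeable covariance has
  eigenvalues λ1 = σ²(1+(m−1)ρ) along the cluster mean and
  λ2 = σ²(1−ρ) within; their MLEs are the between/within mean squares,
  and any positive (λ1, λ2) pair corresponds to a valid (σ², ρ), so
  the profile is closed-form. −2 log L is accumulated per outcome.
- Missing visits: σ² and the intercept are profiled in closed form
  given ρ and a bounded 1-D search over ρ finishes the job.

A variance floor of 1e−12 keeps the deviance finite on noise-free
synthetic data. Grid evaluations are independent and computed in
fixed lexicographic chunks, so the surface is identical however the
work is batched; ties at the minimum are broken lexicographically in
(r_R, r_F, f_MAT, f_BMD, k) and all reported.

Because both markers are proportional to the same V_OLD sequence,
profiling the scales removes their absolute levels and the fit is
driven by curve *shapes* (plus the BMD shape); this is sufficient to
identify (r_R, r_F, f_MAT, f_BMD) at the grid resolution — verified by
noise-free exhaustive evaluation at 20 random generating grid points —
while k is only weakly identified: its likelihood-difference profile
spans a small fraction (under 15% in tests) of every other
parameter's, matching the qualitative finding that the likelihood is
insensitive to the initial old-bone proportion.

## Synthetic cohorts

The generator emulates a once-weekly-teriparatide arm on the trial
schedule: every subject shares the model mean trajectory, scaled into
measurement units, with multiplicative log-normal noise

    ε = σ_o (√ρ_o g_i + √(1−ρ_o) h_{i,w}) − σ_o²/2,

so each observation's expectation equals the scaled prediction, the
log-scale standard deviation is σ_o and the within-subject correlation
is ρ_o. Defaults, chosen once:

- assay CVs at the midpoints of the reported inter-assay ranges —
  P1NP 3.85% (range 2.7–5.0%), NTX 9.0% (range 6.9–11.1%); BMD 1.5%,
  a typical lumbar DXA precision (no assay value exists for DXA);
- biological CVs 0 (no between-subject trajectory heterogeneity is
  reported); ρ_o = 0.2, a modest subject-level shared error component;
- scale factors s_P1NP = 250 µg/L, s_NTX = 220 nmolBCE/mmolCr,
  s_BMD = 0.88 g/cm² per model volume unit, placing baseline values
  near typical postmenopausal osteoporosis levels (P1NP ≈ 41 µg/L,
  NTX ≈ 44, BMD ≈ 0.85 g/cm²);
- missingness completely at random, default rate 0.

Week-0/week-1 marker visits, when requested, are *synthetic
pre-treatment levels*: the on-treatment cycle-1 value divided by
1 + (percent change)/100 with defaults +20% (P1NP) and −20% (NTX), so
percent-change summaries have the familiar trial shape. They are not
model output and are excluded from fitting by default.

What passing tests show — and do not. Recovery experiments confirm
the estimator finds the generating grid point when the data follow the
assumed error structure at assay-level noise. Real cohorts add
between-subject heterogeneity, non-exchangeable serial correlation,
assay drift and informative dropout, none of which the generator
emulates; recovery here does not certify behavior under those
violations, nor does it reproduce the original trial fit, whose raw
data are not public.

## Numerical choices and limitations

- All recurrences run in double precision; at 18 cycles no compensated
  summation is needed and oracle comparisons use 1e−10 relative
  tolerance.
- Parameter validation enforces strict open intervals and the
  anabolic prerequisite r_R < r_F (a < b); an explicit `override` flag
  admits boundary values and rate-reversed regimes for analysis and
  testing.
- Grid values are generated by `arange` and rounded to 12 decimals so
  printed percentages compare exactly; the r_R < r_F filter uses a
  1e−12 guard.
- The acceptance/recovery problem size is 20 replicates of n=100
  subjects over the full 12 960-point grid — a few seconds per
  replicate via a vectorized batched simulator and chunked likelihood
  (chunks of 4096 combinations bound memory near 50 MB).
- Limitations: no continuous-time dynamics or within-week
  pharmacodynamics; no cortical/trabecular split; no late NTX rise
  (weeks 48–72), which the discrete-cycle model cannot produce; no
  placebo arm, covariates or informative missingness; the likelihood's
  exchangeable-correlation family is a declared stand-in for an
  unpublished specification.
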