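# bonecycle

Discrete-cycle simulation of bone remodeling under once-weekly
teriparatide, with exhaustive grid-search likelihood fitting to
longitudinal bone-turnover-marker and BMD trajectories.

## The problem

Once-weekly teriparatide (PTH 1–34, 56.5 µg) produces a distinctive
pattern in osteoporosis trials: the bone-formation marker (serum P1NP)
rises ~20% with a peak at week 4 and then falls to and below baseline,
the resorption marker (urinary NTX) trends below baseline, yet lumbar
BMD climbs throughout 72 weeks. `bonecycle` implements a mechanistic
explanation: each weekly injection stimulates a remodeling cycle on the
*residual old bone*, so as old bone is progressively replaced by new
bone, the active remodeling surface — and with it the marker signal —
shrinks while bone volume accumulates. The package is aimed at
researchers modeling bone-turnover pharmacodynamics and at
methodologists studying grid-search likelihood fitting of discrete
linear recurrences to clustered longitudinal data.

## The model

With a 4-week remodeling cycle (index *t*), the two-compartment
("plenary") model tracks old and new bone volume:

    V_OLD(t+1) = (1 − r_R) V_OLD(t) + f_MAT V_NEW(t)
    V_NEW(t+1) = r_F V_OLD(t) + (1 − f_MAT) V_NEW(t)
    BMD(t)     = V_OLD(t) + f_BMD V_NEW(t)
    P1NP(t+1)  = r_F V_OLD(t)
    NTX(t+1)   = r_R V_OLD(t)

with V_OLD(0) = k, V_NEW(0) = 1 − k. The five parameters are the
per-cycle resorption and formation rates r_R < r_F (anabolic
prerequisite), the new-bone maturation fraction f_MAT, the fraction
f_BMD of new bone visible to densitometry, and the initial old-bone
proportion k. A single-compartment "preliminary" variant (rates *a*,
*b*) has closed geometric forms and shows the same rise-then-fall of
formation.

Fitting enumerates the parameter grid r_R 4–31% (by 3%), r_F 8–32%
(by 3%), f_MAT 1–10% (by 1%), f_BMD 10–80% (by 10%), k 85–95% (by 5%)
— exactly 12 960 combinations under r_R < r_F — and scores each with a
−2 log-likelihood treating observations as log-normal around the scaled
model prediction with subject-clustered, exchangeably correlated
errors; per-outcome measurement-scale factors are profiled in closed
form. Results are reported as likelihood differences
Δ = (−2 log L) − min and per-parameter profile tables. See
`docs/methods.md` for the likelihood in full and all defaults.

## Worked example

Generate a 100-subject synthetic cohort at the reference best-fit
parameter set with assay-level noise and fit the full grid
(`examples/04_grid_fit_recovery.py`):

```
evaluated 12960 combinations in 0.47 s
-2 log L at the optimum: -5133.52

parameter   true   recovered
r_R         0.19       0.19
r_F         0.23       0.23
f_MAT       0.02       0.02
f_BMD       0.80       0.80
k           0.85       0.85

profiled scales (generating values 250, 220, 0.88): s_P1NP=249.2, s_NTX=219.7, s_BMD=0.880
```

Every grid parameter is recovered at its generating value and the
profiled unit-conversion factors land on the generating scales — the
grid, the likelihood and the noise model are mutually consistent.
The other examples show the preliminary rise-then-fall curves, the
week-4 P1NP peak on the visit schedule, percent-change summaries with
95% CIs, and the near-flat likelihood profile of k (the data barely
constrain the initial old-bone proportion, unlike the rate parameters
whose wrong values cost thousands of deviance units).

A thin CLI wraps the same calls:

```sh
bonecycle simulate --model preliminary -a 0.10 -b 0.20 --x0 100 --out-dir out/
bonecycle generate --n-subjects 100 --seed 1 --out-dir out/
bonecycle fit --cohort out/cohort.csv --out-dir out/fit/
bonecycle profile --surface out/fit/surface.csv --parameter k --out k.csv
```

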