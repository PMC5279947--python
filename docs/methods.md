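# Methods

## The redistribution model

The model treats the dentate gyrus as a closed synaptic economy. At t = 0
(the day of the genetic manipulation, in 8-week-old animals) the network
holds 200,000 granule cells, 95% mature with 100 perforant-path synapses
each (S_M = 19.0×10⁶ synapses) and 5% immature. The pre-existing immature
pool is valued by spreading the 10,000 immature cells uniformly over the
43-day maturation span, one cohort per strength value:

    S_I(0) = 10,000 / 43 × Σ_{d=1..43} Y(d) / 100 × 100 ≈ 0.62×10⁶

giving a static total S_M + S_I(0) ≈ 19.62×10⁶ that is conserved at every
simulated day: the model moves synapses between populations, it never
creates or destroys them. %im + %mat = 100 holds identically by
construction.

**Integration curve.** Y(d) = 71.1 ln(14 + d) − 187.7 (percent of the
mature complement) describes how quickly a newly integrating cell acquires
synapses. The raw curve is −0.06 at d = 0 and 99.8 at d = 43; we clamp it
to [0, 100] so that the narrated endpoints (0% at onset, 100% at maturity)
hold exactly without changing any intermediate value. Day indices are
integers, and a cohort incorporated on day k is evaluated at age
(t − k + 1), matching the convolution
S_I(t) = I(t)·Y(1) + I(t−1)·Y(2) + … term for term.

**Cohorts.** Proliferation P(t) = 4×10⁶ (42 + t)^−1.5 cells/day feeds one
cohort per day over t = 1..43, scaled by a survival rate of 20%
(wild type). In the enhanced-survival condition, cohorts incorporating on
or after day 14 — the recombination-to-integration lag — survive at 70%
and carry a 1.35× per-cell strength multiplier (synapses that escape
Bax-dependent pruning). The multiplier applies outside the [0, 100] clamp:
a mature knockout cell may hold 135 synapse-equivalents. Proliferation is
identical in both conditions (the manipulation does not alter
proliferation), cohort sizes are expected values (no sampling anywhere),
and no cohort matures within the window (horizon ≤ 43 enforced).

Two points in the source formulation are genuinely open and were resolved
as follows:

* P(14) ≈ 9,545 under the formula, although the curve is described as
  calibrated to ~8,000 progenitors at t = 14 (the formula gives 8,000 at
  t = 21). We evaluate the formula as printed; `prolif_age_offset` is a
  config field for exploring the alternative calibration.
* The immature-share numerator uses only newly appropriated synapses
  S_I(t); whether the pre-existing immature pool should count toward %im
  is ambiguous. The literal formula (excluded) is the default;
  `include_baseline_in_numerator=True` switches to the variant, which
  shifts %im by a constant ≈3.2 points and leaves every knockout/control
  comparison essentially unchanged.

The headline output is 100 × %mat_ko(t) / %mat_ctrl(t) over t = 36..43. At
the defaults this falls monotonically from 63.9% to 42.7%.

## The evoked-response pipeline

Recordings are represented as sweep tables (slice, group, cell, stimulus
intensity in V, FV amplitude in μV, fEPSP slope, EPSC amplitude in pA,
saturation flag). Amplitudes are stored as magnitudes — inward currents
positive — normalized on CSV ingest.

Pipeline order matters and mirrors the recording conventions: the 10
sweeps at each intensity are averaged first (saturation flag by majority
vote); responses with saturated axonal recruitment are dropped; remaining
responses are binned by FV amplitude, which normalizes for between-slice
differences in stimulation efficacy and removes stimulus intensity as a
variable. Bins are half-open [k·w, (k+1)·w) anchored at 0 μV (the source
conventions use w = 100 μV or 75 μV but state no anchor); empty bins are
omitted, and SEM (n−1 variance) is undefined for singleton bins.

The overall EPSC/FV ratio averages *per-response* ratios — each averaged
(cell, intensity) response is one observation — matching the per-response
n of the summary statistic; dividing grand means is the noted alternative.
Rows with zero FV are excluded with a warning. Where no explicit
saturation flag exists, a plateau rule stands in for the operator's
judgment: a response is flagged when its FV and its lower-intensity
neighbor are both within 5% of the cell's maximum.

**Unweighted-means ANOVA.** Binning by FV yields unequal cell counts, so
group comparisons use the two-factor unweighted-means procedure: main
effects are computed on the unweighted cell means with the harmonic mean
of the cell sizes, n_h = ab / Σ(1/n_ij), replacing n in the sums of
squares, and the error term pools the within-cell variance with
df = Σ(n_ij − 1) (the exact error df of the original analysis being
unstated, pooled within-cell df is the natural choice and is documented
here). In balanced designs this reduces exactly to the classical two-way
ANOVA, which the tests verify against an independent brute-force
sums-of-squares oracle. The test requires a complete group × bin crossing
with n ≥ 2 per cell; `complete_bins` restricts a summary to bins shared by
all groups before testing.

Percent changes (e.g. between stereological cell counts) are reported
rounded to the nearest integer; ratios to two decimals in printed output.

## The synthetic-data generator

The generator emulates, per slice: a saturating hyperbolic FV
input–output curve FV = g_slice · FV_max · I/(I + I_half) (the recordings
show saturating axonal recruitment but no functional form is given, so a
hyperbola is the minimal saturating choice); fEPSP slope and EPSC linear
in the *realized* FV, with the group effect entering only through the EPSC
gain — mirroring the finding that FVs and fEPSPs do not differ between
groups; multiplicative noise (1 + cv·z, truncated at 0.1 to keep
magnitudes positive); and a saturation flag when FV exceeds 90% of
FV_max. Event trains are homogeneous Poisson with lognormal amplitudes;
paired-pulse trials scatter around a true depression factor; count pairs
are rounded normal draws with sd = cv·mean.

Defaults are the study's conditions: 15 slices per group, one recorded
cell per slice, 9 intensities spanning 5–100 V with 10 sweeps each,
FV_max = 400 μV (the largest reported FV bin is 300–400 μV), half-maximal
recruitment at 20 V, 20% between-slice gain variability, 15% measurement
noise, paired-pulse ratio 0.9 (mildly depressing), event rate 0.5 Hz and
lognormal amplitude median ~20 pA (typical spontaneous-EPSC scale). EPSC
gain presets are the published overall EPSC/FV ratios: mature control
2.44 pA/μV, immature control 1.24, Bax-deleted immature 1.59,
ablated-neurogenesis 3.7 vs 2.2, enriched environment 2.6 vs 1.6. All
generators require an explicit seed and are byte-reproducible.

What the generator does *not* emulate — and hence what passing tests do
not show about real recordings: correlated noise across simultaneously
recorded measures, within-cell serial dependence between sweeps,
rundown/drift over a recording session, non-linear EPSC–FV relations near
saturation, and operator-dependent saturation judgments. Parameter
recovery here demonstrates that the pipeline is unbiased and adequately
powered under the stated statistical structure, not that the structure is
a complete model of slice electrophysiology.

## Numerical choices and problem sizes

Plain double precision throughout; the simulation is noise-free and
tolerances in tests are 1e−9 (conservation) to 1e−12 (oracle
equivalence). The power property (group-effect detection at gains 2.44 vs
1.6, 15 cells/group, α = 0.05) is estimated over 200 seeded replicates of
the full generator-plus-pipeline loop; the parameter-recovery check uses
one seeded dataset of ~125 non-saturated responses (≥ 86, the published
per-group response count). Degenerate inputs are handled explicitly:
all-saturated tables return empty with a warning, empty event trains have
frequency 0 and undefined amplitude, zero-FV rows are excluded from
ratios, and a zero within-cell error term yields an infinite F for any
non-zero effect.
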