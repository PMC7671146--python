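# Methods

This note documents the models behind `hotrocks`: what each stage
assumes, which parameters matter, how the synthetic-data generator was
calibrated, and where the design was genuinely open.

## Tide model

Water height is a generic mixed semidiurnal harmonic,
`h(t) = m + Σ aᵢ·cos(2π t/Tᵢ + φᵢ)`, with four default constituents
(periods 12.42, 23.93, 25.82 and 12.00 h) around a mean level of 0.93 m
above MLLW, plus an optional time/height offset correction for
transferring predictions between nearby sites. The defaults are chosen so
that high-intertidal rocks (0.31–1.10 m) are emersed regularly (≈ 39 % of
records at the default field) and mid-intertidal rocks (−0.32–0.23 m)
only at the lowest tides (≈ 6 %). The model is not tied to any harmonic
database; constituents are plain config entries.

A rock is *emersed* when tide height is strictly below its elevation; an
exact tie counts as immersed. The same rule feeds the air/water switch in
the metabolic model, so "tie → immersed" is the conservative choice
(water metabolism, no air heating).

## Synthetic rock fields

Per zone, elevations are drawn from a power distribution on the zone's
elevation range whose mean matches the zone target (0.0 m MIZ, 0.8 m
HIZ), using one jittered quantile per stratum. Stratification mirrors a
survey design that deliberately spans the elevation gradient and keeps
the zone mean stable across seeds. Surface areas (568–2671 cm²) and
volumes (5162–50472 cm³) are uniform. Rock size does not influence the
default temperature model (a deliberate simplification; elevation is the
dominant driver, and a volume covariate could be added to the air-target
without structural change).

## Under-rock temperature synthesis

Each 30-minute record is either **immersed** — equal to a single shared
water process — or **emersed** — relaxing toward an air-driven target.

Water: `w(t) = μ + A_s·cos(seasonal) + A_d·cos(diurnal) + AR(1)`, with
annual mean μ = 12.55 °C, seasonal amplitude 0.45 °C peaking in late
August, diurnal amplitude 0.40 °C peaking mid-afternoon, and an AR(1)
anomaly (per-step coefficient 0.95, stationary SD 0.55 °C) shared by all
rocks. Immersed equality across rocks is exact by construction.

Air target while emersed:

```
target_j(t) = μ + A_s·cos(seasonal)
            + r_j · [ A_day·f_day(t)·day(t)^s  −  A_night·f_night(t)·night(t) ]
            + σ_w · w_{zone,d} · day(t)^s  +  ε
```

`day(t)`/`night(t)` are complementary half-cosine bumps peaking at 14:00
and 02:00; `f_day = 1 + m_day·cos(seasonal)` amplifies daytime heating in
summer while `f_night = 1 − m_night·cos(seasonal)` strengthens night
cooling in winter; `w_{zone,d}` is a standard-normal day-level weather
anomaly shared within a zone; ε is small within-day noise. The per-rock
factor `r_j = (1 + c·(elev_j − elev_ref))·(1 + σ_r·z_j)` makes excursions
grow with height on the shore — the among-rock heterogeneity that gives
the high zone its wide spread of thermal conditions. The exponent `s`
(`day_sharpness`, 2 in the HIZ) narrows the daytime bump so heating is
midday-peaked: it raises daily maxima relative to the heat's contribution
to the overall mean, which is what lets the zones differ by 2.5 °C in
daily maxima while differing by only ~0.3 °C in overall mean.

The rock's temperature relaxes toward the target with a Newtonian time
constant τ (1.2 h HIZ, 1.5 h MIZ) while emersed, and snaps back to the
water process at immersion — reproducing the saw-tooth traces loggers
record around low tides.

### Calibration

The field study this emulates published only summary statistics, so the
generative model above is this package's construction, and its constants
were fitted once (grid search over seed-averaged statistics, five seeds)
so that a default 12 + 12-rock year reproduces the printed zone summary:
HIZ/MIZ grand mean daily maxima ≈ 16.4/13.9 °C, mean daily ranges
≈ 5.2/2.2 °C, HIZ mean daily minimum ≈ 11.2 °C, overall HIZ−MIZ gap
≈ 0.3 °C, no MIZ rock-day above 30.5 °C but a handful of HIZ rock-days
above it each spring/summer, among-rock SD of mean daily maxima more than
twice as large in the HIZ, and daily maxima rank-correlated with
elevation. The constants live in `data/default_config.yaml` and are
labelled calibration values, not field measurements.

What the generator does **not** emulate: weather autocorrelation (heat
waves are single independent days), rock-size effects, logger
quantization (0.5 °C rounding is available but off by default), data
gaps (an exclusion-window list reproduces them when wanted), fog,
substrate conduction, or any true heat-budget physics. Tests passing on
synthetic data therefore validate the pipeline's logic and the printed
summary statistics, not micro-scale physical fidelity.

## Thermal traits

Mean trait functions are the published regressions: CT_max = 33.0 −
0.14·cw, T_esc = 35.12 − 0.88·cw, T_pref = 15.0 °C (size-independent);
`t_pref < t_esc(cw) < ct_max(cw)` holds across the natural 4–21 mm range.
Individual sampling adds independent Gaussian residuals (defaults 1.5 °C
for CT_max, 2.0 °C for T_esc, chosen to roughly match the original
regressions' R² of ~0.1 and ~0.4 given uniform 4–21 mm sizes). The
break-point estimator fits OLS lines to the first 200 and final 60
points of a cardiac ramp trace after truncating the trailing flatline;
"flatline" is the trailing run where heart rate falls below 5 % of the
trace's peak (configurable — the underlying lab practice does not define
it), and near-parallel segments or intersections outside the observed
temperature range are rejected rather than returned.

## Metabolism

Rates follow `log10(rate µL O₂/h) = a + b·T` per size class × medium.
The printed source coefficients are not in the main text, so the shipped
set is an explicit calibration: Q10 = 2 (b = 0.030103 °C⁻¹) in all four
lines, water rates anchored at 20 (large, 4.3 g) and 4 (small, 0.9 g)
µL O₂/h at the 13 °C holding temperature, and air depression factors 0.6
(large) and 0.8 (small) — metabolism is depressed in air, more strongly
in large crabs. A `mass_specific: true` config flag accepts per-gram
intercepts and converts by log10(mass) at load. Records strictly above
30.5 °C are censored (the animal would flee or die); a record exactly at
threshold is computed. Cumulative daily expenditure integrates rate ×
interval-to-next-record within local calendar days; the day's last record
carries the nominal 30-minute interval, and mixed 30/15-minute spacing is
handled per interval.

## Individual-based model

2000 rock cells (100 columns × 20 rows; lower ten rows MIZ, upper ten
HIZ), 1000 crabs seeded 250 per size bin with widths uniform within each
bin's intersection with 4–21 mm, positions uniform, thresholds set
deterministically from the size functions (population means 20.5/30.5 °C
under the null model). Each day every cell draws independently from its
zone × calendar-day (±1, years combined) pool of daily maxima; within a
day cell temperatures are fixed. Update order per crab: mortality check
first (cell ≥ CT_max → dies with `p_die`), then escape (cell ≥ T_esc →
with probability `p_move`, gating the whole day's relocation chain, the
crab hops to uniformly random 8-neighbourhood cells — edges clamped, no
wraparound — with mortality re-checked at every visited hot cell, until
it lands below T_esc or exhausts 50 moves; exhaustions are counted and
reported). Crabs do not interact, dead crabs are not replaced, and there
is no recruitment or growth: the model isolates how thermally driven
movement and mortality redistribute a fixed cohort. Replicates run on
independent child streams spawned from the master seed.

Default pools built from a gap-free synthetic year cover all 365
calendar days, so a default run simulates 365 days; `n_days` caps the
run, and pools built from summaries with data gaps simply skip the
uncovered days. Simulation scale in the shipped tests is 50 replicates
per parameter set (the qualitative zone contrast is ~50 standard errors
wide at that size, so more replication changes nothing but the decimals).

## Demography

Size bins partition (0, ∞) as (0, 7], (7, 10], (10, 13], (13, ∞) mm —
the printed bin labels leave the 0.1 mm measurement gaps undefined, and
inclusive upper edges are the convention adopted. Density divides counts
by the rock's measured top surface area (cm² → m²); per-bin densities
sum exactly to the total. The same zone-structure summary accepts survey
frames (adding across-rock density SEs) and IBM count frames, so field
and simulated size structure are compared on identical footing.

## Numerical and reproducibility choices

All stochastic stages consume `numpy` Generators seeded through
`config.seed_for(master_seed, label)` (SeedSequence over a CRC-32 label
hash), so any stage can be replayed alone; identical seeds give
bit-identical records, populations and CSV outputs. Degenerate inputs
fail loudly: empty rock lists, reversed date ranges, constant OLS
predictors, parallel break-point segments, unsorted record frames, grids
too small for adjacency, and probabilities outside [0, 1] all raise with
specific messages. Temperatures are clipped to a [−5, 45] °C sanity
band; timestamps are naive local time with no DST handling.
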