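# Methods

## Model structure

The simulator tracks individual cells along independent radial files at a
daily timestep.  A cell's state is its radial length L_r (axial and
tangential lengths La = 2680 μm and Lt = 50.1 μm are fixed), wall mass M,
cytoplasmic carbohydrate concentration θ, its growth factor ε and division
threshold L_{r,d}, and a life-cycle status (proliferating → enlarging →
thickening → mature; transitions are forward-only).  Position is the
distance of the cell's centre from the inner phloem edge,
x_i = Σ_{j<i} L_{r,j} + L_{r,i}/2, with index 0 the cambial initial.
Status follows position relative to the day's three developmental zone
widths.

Units are fixed throughout: μm, mg, ml, day, °C in forcing, K inside
Arrhenius expressions.

## Daily update order

1. classify cells by centre distance against (z_p, z_e, z_t);
2. if non-dormant, enlarge proliferation- and enlargement-zone cells
   (ΔL_r = L_r(e^{εμ} − 1), μ Boltzmann–Arrhenius in air temperature);
3. divide proliferating cells at/above their division length (at most one
   division per cell per day — daily relative growth is ≲ 10%, so a second
   threshold crossing within a day is impossible at realistic
   temperatures);
4. build per-cell saturated wall demands at post-enlargement geometry and
   solve the transport equilibrium (demands need the day's final lumen
   volumes, which fixes the growth → division → transport order);
5. deposit wall mass and store the solved θ per cell;
6. cells whose centre lies beyond z_t lose their protoplasm and become
   mature, leaving the transport domain from the next day.

At the last calendar day of the year, cells outside the (dormant)
proliferation zone are finalized into the annual ring, ordered innermost
(earliest-formed) first; proliferation-zone cells, including the initial,
carry over with their full state.  Cells still enlarging or thickening at
the year boundary are finalized as-is and logged as a warning on the file —
rare under boreal forcing, common and intended under the frozen-zone
scenarios.

## Transport solution

At equilibrium, the flux into cell i equals the summed wall growth of
cells i..n, so a trial innermost concentration θ_n determines the entire
profile by an outward sweep; the reconstructed phloem boundary value is
strictly increasing in θ_n, equals 0 at θ_n = 0 and is ≥ θ_p at
θ_n = θ_p, so a unique root always lies in [0, θ_p].  Brent's method is
run to machine tolerance (xtol = 1e-14), which leaves the conservation
identity flux_in = Σ ΔM satisfied to well below 1e-9 mg day⁻¹.  An
independent damped Picard iteration on the full concentration vector
serves as a cross-check in the test suite; its damping is set from a
Lipschitz bound of the update map (MM slope ≤ ΔM_max/K_m) and halved
whenever a checkpoint shows a limit cycle caused by the clip at θ = 0.

## Phenology

Chill days (T < 0 °C) are counted from DOY 306 through DOY 31; degree-days
Σ max(T, 0) accumulate from DOY 32; dormancy is released on the first day
with DOY ≤ 182 whose degree-day sum reaches
dd_req(cd) = 15 + 4401.8·e^{−0.042·cd}, and re-imposed on DOY 231.  The
sequential chilling-then-forcing window is deliberate: if chill days kept
accumulating through spring, dd_req would collapse to its ~15 °C·day
asymptote at any boreal site and release would occur unrealistically early
(~DOY 105); with the sequential window, dd_req ≈ 120–140 and release falls
in mid-May, matching observed cambial reactivation at the study latitude.
T = 0 °C counts toward neither sum.  The first simulated year starts with
cd = 0 (there is no prior autumn), which the spin-up absorbs.

## Zone widths

z_k = a_k + b_k·dl (dl in hours) for the proliferation (−50.9, 7.47) and
thickening (−427, 68.8) zones, with each width capped at its 24-h-daylength
value (needed for sites north of the Arctic circle) and the ordering
z_t ≥ z_e ≥ z_p enforced by raising outer widths to inner ones.  The
proliferation zone is pinned at its DOY-185 (seasonal-maximum) width on
earlier non-dormant days and at its DOY-231 width while dormant.  The
enlargement-only zone follows its daylength regression (−744, 51.7) from
DOY 185 onward; before DOY 185 it follows a linear extension **in time** of
that line's seasonal rate of change, z_e = 1257 − 5.01·DOY.  The (1257,
−5.01) pair only makes dimensional and dynamical sense as a line in
day-of-year: the post-185 line's time derivative is
(59.9 − 297)/(231 − 185) ≈ −5.15 μm day⁻¹ ≈ −5.01, and reading the pair
against daylength instead would put z_e ≈ 1150 μm above z_t all spring,
leaving a zero-width thickening zone and physically impossible
primary-wall-only earlywood.

Daylength uses standard solar-declination/hour-angle astronomy with the
conventional apparent-sunrise horizon (solar altitude −0.833°), the
convention under which observed daylengths — and hence the zone
regressions — are reported; accuracy is a few tenths of an hour, which the
linear zone responses tolerate.

## Stochasticity and reproducibility

Division asymmetry Z_a ~ N(0, 0.105) is clamped to ±0.49 (numerical
stability); birth-size noise Z ~ N(0, 0.227) is unclamped.  Each radial
file owns a generator spawned deterministically from the master seed
(`numpy` SeedSequence), so ensembles are bit-reproducible and file f of an
n-file ensemble is identical to file f of any larger ensemble with the same
seed.  Mother wall mass is split between daughters in proportion to birth
length, so division conserves both length (exactly) and mass.  Cells
created at initialization start with a complete primary wall for their
size (M = ρ·V_wp), the natural state of a living cambial cell; the choice
washes out within the spin-up because mass is repartitioned at every
division.

## Synthetic forcing

The generator produces t(d) = mean_C + amplitude_K·cos(2π(doy −
peak_doy)/365.25) plus AR(1) noise (φ = 0.7, innovation SD 3 K), with
defaults mean_C = 1 °C, amplitude 14 K, peak DOY 200 — the seasonality of
the boreal-Sweden study region (annual mean ≈ 1 °C, July ≈ 15 °C).  Years
are 365 days; DOY 366 of user-supplied forcing is treated as DOY 365 for
all threshold logic.  What the generator does **not** emulate: the skewed
winter temperature distribution of the real site (maritime warm spells
above 0 °C in Nov–Jan), synoptic persistence beyond one-day AR(1) memory,
and any trend.  The chilling sum is therefore biased high (~85–90 chill
days vs ~70–75 at the real site), dd_req biased low, and dormancy release
~10 days early, which lengthens the season and adds a few cells per file
relative to runs driven by observed temperatures.  Consequences for what
passing tests show are discussed under Limitations.

## Scenario machinery

`fixed_temp` substitutes a constant (10 °C) for the air temperature seen by
the enlargement and wall-growth kinetics; `fixed_zw` freezes all three zone
widths at their 20-June (DOY 171) values; `sugar_saturation` sets
ΔM = ΔM_max, bypassing the transport solve; `delta_T` adds a step anomaly
to the temperature used by any subset of {enlargement rate, thickening
rate, proliferation-zone cells only, enlargement-zone cells only}, while
dormancy phenology always sees the unmodified climate.  The anomaly sweep
runs a 0.5 K grid and smooths responses with a running mean over a 1.5-K
window.  An anomaly of zero with no targets is byte-identical to the
default run.

## Derived variables

Cell density is (M/V_c)/1000 g cm⁻³.  Profiles place each cell at its
cumulative mid-point distance from the ring start (earlywood side), binned
at 0.02 ring-fraction (or 40/100 μm absolute), cell-unweighted within
bins, pooled across files, smoothed by a running mean over three adjacent
bins with empty bins propagated as missing; multi-year figures are the
mean of per-year profiles.  `max_density` is the maximum of the 40-μm
smoothed profile; the earlywood fraction diagnostic uses a 0.55 g cm⁻³
threshold (a reporting convention; the earlywood/latewood transition is
not a model object).

## Numerical choices and degenerate inputs

ω·(Arrhenius factor) < ρ holds for T ≲ 33 °C, so a daily deposition step
can never occlude the lumen under boreal forcing; `lumen_volume` raises if
wall volume ever exceeds cell volume (an integration-bug guard).  All-zero
demand days skip the solver and set θ = θ_p.  An initialization that fits
no cell inside the DOY-1 proliferation zone is an error.  Ties at zone
edges (x exactly equal to a width) classify the cell into the outer zone.

## Scaled problem sizes

Tests and the acceptance script run 10–25 files over 3–12 years — the
ensemble statistics of interest (profile shape, paired scenario contrasts)
are stable at this size, with the full 100-file protocol available through
the CLI.

## Limitations

* The earlywood density plateau is quantitatively sensitive to the deep
  thickening-zone carbohydrate concentration (a few mg ml⁻¹, the residual
  of a ~90 mg ml⁻¹ source-to-sink drop), and therefore to forcing realism
  and file cell counts; under the synthetic generator the plateau sits
  near 0.28–0.30 g cm⁻³, below the ~0.4 g cm⁻³ observed and simulated
  with real gridded forcing, while the latewood peak, terminal decline,
  and every scenario ordering (sugar saturation, fixed temperature, frozen
  zones with/without dormancy) are reproduced.
* No turgor, water, or nutrient limitation; enlargement responds to
  temperature only.
* Constant phloem concentration: no whole-tree carbon dynamics or seasonal
  source variation.
* No tangential/axial growth, no inter-file interaction, no phloem
  anatomy; conifer tracheids only.
* Parameters are the published site calibration; no re-fitting machinery
  is included.
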