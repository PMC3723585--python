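# Methods

## Forward model of single-cell reporter expression

A prescribed transcription-rate generator A(t) (constant, step, square
pulse, or cycle-modulated two-level) drives a linear cascade

    dM/dt  = A(t) − γ_M·M            mRNA copies
    dPi/dt = k_t·M − k_m·Pi          immature (dark) protein, AU
    dPm/dt = k_m·Pi                  mature (fluorescent) protein, AU

and the observable is Pm plus additive white Gaussian measurement noise of
variance σ².  Protein is stable: reporter loss in a growing cell is
dilution, which total (not concentration) bookkeeping already captures, so
no γ_P appears outside the chase model.  Integration uses exact
matrix-exponential stepping with the input held constant on 0.1-min
substeps, so generator discontinuities are resolved far below the 5-min
sampling grid; in SSA mode the mRNA is an exact Gillespie birth–death jump
process and the protein equations are integrated in closed form between
jumps.

Cells grow exponentially, slowly in G1 (rate g1) and twice as fast after
budding, divide on a fixed cycle clock t_cyc with budding at fraction b of
the cycle, and partition content at division: the daughter receives the
volume grown since budding, plus the matching share of molecules
(deterministic in ODE mode, Binomial(m, volume fraction) for discrete
mRNA in SSA mode).  Simulated daughters continue with their own cycle
clock but do not divide again within the horizon (a bookkeeping cut-off
that leaves running totals and conservation untouched).  Because cycle
timing is deterministic, a mother's birth volume drifts ≈11% per cycle;
no size-control feedback is modelled.

Defaults (chosen once, with reasoning):

| parameter | default | why |
|---|---|---|
| sampling_interval | 5 min | imaging cadence of time-lapse data |
| t_cyc | 100 min | typical budded-yeast cycle in glucose |
| bud_fraction | 0.27 | population-average budding point |
| γ_M | ln2/20 min⁻¹ | typical yeast mRNA half-life (20 min) |
| k_m | ln2/10 min⁻¹ | CFP maturation half-life (10 min); YFP ln2/32, RFP ln2/150 |
| μ (steady-state mRNA) | 10 | canonical calibration level |
| pt_ratio | 2 | observed post-bud:pre-bud transcription ratio |
| σ² | 2.4·10⁴ AU² | canonical measurement-noise variance |
| k_t | 10 AU/(mRNA·min) | puts one cycle's integrated-fluorescence gain at ~10⁴ AU for μ = 10, making σ² the few-percent high-frequency noise such traces carry |
| transition window W | 40 min | randomized G1→S/G2/M transition variant |

The cycle-modulated generator's two levels are scaled so the time-averaged
steady-state mRNA equals μ.  The noise is white; empirical measurement
noise is high-frequency but not exactly white, and spectrum matching is a
possible extension.  Passing tests on these synthetic data therefore
demonstrate correctness of the pipeline under the stated model — not
robustness to segmentation errors, focus drift, photobleaching, or
cycle-length variability, none of which are simulated.

## Rate inference

The running total P(t) (mother plus separated progeny fluorescence) is fit
with a cubic smoothing spline minimizing Σ residual² + β·∫f″², and rates
follow as M = P′/k_t, A = (P″ + γ_M·P′)/k_t.  k_t is unidentifiable from
fluorescence and defaults to 1 in inference (relative units).  Derivatives
within two samples of a fitted boundary are flagged low-confidence and
excluded from event detection.  For cycle-resolved analysis,
`infer.per_cycle_rates` fits each division-to-division window separately,
extending past the closing division with the newly separated daughter's
total only — older progeny's later production belongs to their own
lineages and would otherwise inflate the inferred rate, roughly doubling
it per generation.

### Smoothing-parameter calibration

β is convention-dependent (it multiplies the roughness penalty with time
in minutes and fluorescence in raw AU), so it is set by a simulation
study, not by fiat: noisy asynchronous traces (step at t = 0 into the
cycle-modulated steady state) are generated for parameter sets spanning
t_cyc ∈ {70, 100, 130} min and pt_ratio ∈ {2, 4} at the canonical (μ, σ²)
pair, rates are inferred across a 7-point log grid of β, and the RMS
residual against the generator truth is averaged over 100 repetitions.
Expression level is held fixed in the calibration because the noise
variance is matched to data at that level; varying μ against a fixed σ²
would change the signal-to-noise ratio rather than the trace shape.  The
summed residual has an interior minimum at β = 3000, frozen as
`DEFAULT_BETA`; re-run it with `cyclescope infer select-beta`.  On
noiseless traces the residual decreases monotonically toward small β
(nothing to over-fit), a property the acceptance suite checks.

### Event timing with maturation

The timing-accuracy study simulates square-pulse transcription with the
maturation step in the forward model but not in the inference (the
realistic mismatch), then detects activation/deactivation as the first
sustained crossing of 50% of the population steady-state rate.  The
first-order maturation filter shifts threshold crossings by ≈ ln2/k_m,
and smoothing adds a little more, so inferred events lag truth by 10–15
min with a dispersion of ~2–3 min at the canonical noise level; the exact
numbers are recomputed by `scripts/acceptance.py` and the test suite, not
asserted as constants.  The dispersion scales with σ/k_t, i.e. with the
(unidentifiable) absolute fluorescence scale of the data.

### Maturation and decay fits

Cycloheximide-chase traces are fit by nonlinear least squares to the
two-pool solution Pm(t) = e^(−γ_P·t)·(Pm0 + Pi0·(1 − e^(−k_m·t))), with
γ_P fixable at 0 for stable reporters; flat traces (no immature pool) are
flagged rather than fitted.  `check_decay` fits M0·e^(−γ(t−t_off)) to
inferred mRNA after a shutoff and compares γ with the configured γ_M.

## Cycle synchronization and profiles

Traces are cut at divisions; each complete segment (exactly one bud
between consecutive divisions) is mapped by a two-piece linear map to a
progression coordinate with division at 0 and 1 and budding at the
population-average pre-bud fraction b (computed, not assumed; an
unscaled synchronize-at-budding variant is available).  Profiles average
cycles in 20 equal-width progression bins; the bootstrap SEM resamples
whole cycles (the exchangeable unit), 1000 replicates by default.
Segments are sorted by (cell, cycle) before bootstrapping so results are
independent of input order.

## Step-test response delays

The five-step effective-threshold procedure: (1) transcription threshold
= 50% of the population steady-state rate; (2) per cell, read the
localization level τ_obs = 15 min before its transcription crossing
(τ_obs is the maturation-dominated observation lag); (3) pool these
levels; (4) effective localization threshold = their 5th percentile — a
level at which many cells do transcribe, so nuclear TF is no longer
limiting; (5) localization time = first crossing of that threshold;
delay = activation − localization.  Cells that never cross are censored,
counted, and excluded from delay statistics.  The procedure is
deterministic given its inputs.

## Co-activation of homologous loci

Per S/G2/M period, each locus is scored ON/OFF; association is the
Pearson χ² (no continuity correction) on the 2×2 table and the φ
coefficient (the natural correlation for binary outcomes; whether a
reported binary-outcome ρ is φ or a Pearson r on some continuous summary
is ambiguous, so φ is the default and the raw table is exposed).  Among
dual-ON periods, the fraction activating within a 15-min window is
reported.  The synthetic coupled-loci generator uses a shared Bernoulli
trigger with independent per-locus failures; φ = s(1−p_t)/(1−p_t·s) is
inverted to hit a target φ exactly.

## Phase-dependent snapshot models

mRNA at age a is Poisson with mean m(a), the cycle-periodic solution of
dm/da = A(a) − γ_M·m with m(0) = q·m(t_cyc); Poisson closure is exact
because the dynamics are linear and binomial thinning preserves Poisson
laws.  The snapshot law mixes these over p(a) ∝ 2^(−a/t_cyc).  The
division retention q is ½ in the snapshot models (keeps a single
self-consistent periodic solution; the lineage simulator's volume-based
asymmetric split is a per-cell refinement the snapshot model deliberately
ignores).  Variants: gene-dosage doubling at a replication point inside S
(default 0.35 of the cycle, shortly after budding); and a transition time
uniform on [t_bud, t_bud + W] — analytically treated as a per-lineage
mixture over the window (the SSA redraws it each cycle; the difference
appears only in G1 carryover and is small).  Bud-size thirds are mapped
to equal thirds of S/G2/M *duration*; note that ranked (equal-count)
terciles of an asynchronous sample differ from duration thirds by ~11% of
budded cells at the default geometry — an intrinsic coarseness of the
bud-size proxy, not an implementation error.

Fitting: the fold-change f is profiled on a log grid with the G1 rate
maximized out by bounded 1-D search and refined between grid neighbours;
the 95% CI is the likelihood-ratio set on the grid (so its resolution is
grid-limited), and a maximum on the upper grid edge is reported censored
("f exceeds the grid") — the expected presentation of data with no G1
transcription.  The basal limit is parametrized explicitly (G1 rate 0
with a finite S/G2/M rate) rather than through a literal infinite f.
The negative-binomial baseline uses moment estimators b = var/mean − 1,
a = mean/b, flagging underdispersed data as the Poisson limit.
`compare_models` reports per-phase predicted vs empirical mean/SD and a
χ² distance between pooled pmfs.

## FISH quantification

Input is the 2-D maximum projection of a z-stack with cell and nuclear
masks given.  The pixel threshold is calibrated as the smallest grid
value with a false-positive spot rate < 5% per cell on negative
controls.  Spots are local maxima above the threshold (maxima within 3 px
merge — unresolvable below the PSF width); intensity is the
background-subtracted sum over a 7×7-px window (background = image
median).  The single-mRNA intensity is the mode of the spot-intensity
histogram (parabolic refinement of the peak bin); spots ≥ 2× the mode
count as round(I/mode) transcripts; spots > 4× the mode (the flat tail of
the histogram; the plausible range extends to 5–10×) that fall in the
nuclear mask are nascent transcription sites, included in per-cell counts
by default with a flag to exclude.  Unbudded cells are G1; budded cells
are split into equal-count thirds by ranked bud size, remainder to the
earlier bins, stable ties.

## Pipeline and reproducibility

All randomness flows from one integer seed via per-stage derived seeds
(CRC32 of "seed:stage", kept below 2³¹) so enabling or disabling one
stage never shifts another's stream; the run manifest records the seed
and a config hash, and identical config+seed reruns are byte-identical.
Problem sizes in the shipped studies (1000 traces for timing accuracy,
20 000 SSA cells for the oracle-equivalence check, 50 replicates × 2000
cells for fold-change recovery) were chosen as comfortably sufficient for
the Monte-Carlo tolerances quoted with each test.

## Known limitations

- White measurement noise; no empirical noise spectrum.
- Deterministic cycle length and budding fraction; no mother/daughter
  asymmetry in timing, no size control.
- Daughters do not divide within a simulation horizon.
- The analytic randomized-transition law fixes the transition draw per
  lineage rather than per cycle.
- No bright-field segmentation, no 3-D spot fitting, no telegraph-model
  fitting (the package implements threshold-based state calls and the
  phase-dependent Poisson-mixture family only).
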