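# cyclescope

Cell-cycle-resolved analysis of stochastic gene expression in budding
yeast, built around a deconvolution idea: a stable fluorescent reporter
integrates expression history, so the **running total** of mother-plus-
progeny fluorescence P(t) encodes the instantaneous transcription rate,
recoverable through the derivatives of a smoothing spline.

The package is aimed at quantitative single-cell biologists who want to
ask whether "noisy" promoters are really bursting at random, or whether
their variability is driven by the cell cycle — and to test that question
end to end on synthetic data with known ground truth.

## The model

Transcription and translation of a stable reporter follow

```
dM/dt = A(t) − γ_M · M          (mRNA)
dP/dt = k_t · M                 (total protein)
```

so, given a cubic smoothing spline fitted to P(t) (penalty weight β on the
integrated squared second derivative),

```
M(t) = P′(t) / k_t,     A(t) = (P″(t) + γ_M · P′(t)) / k_t .
```

k_t is unidentifiable from fluorescence alone, so M and A are *relative*
(AU).  Fluorophore maturation (dark → bright at rate k_m) delays what the
inference sees; the timing-accuracy study quantifies that delay.  For
static snapshot data, mRNA counts in an asynchronous population follow a
mixture of Poisson laws over cell age, with transcription at k_G1 in G1
and f·k_G1 in S/G2/M, binomial partitioning at division, and the
exponential-growth age density p(a) ∝ 2^(−a/t_cyc).

Modules: `simkit` (synthetic lineages, snapshots, FISH images, chase
traces), `infer` (spline inversion, β calibration, maturation fits),
`cycle` (in-silico synchronization and bootstrap profiles), `events`
(ON/OFF calls, step-test delays, co-activation), `distmodels`
(phase-dependent Poisson-mixture models, negative-binomial baseline),
`fishquant` (spot counting), `cli` (pipeline orchestration).

## Worked example

Simulate 40 lineages under the canonical conditions (100-min cycle,
budding at 27% progression, 2:1 post-bud/pre-bud transcription ratio,
measurement noise σ² = 2.4·10⁴ AU²), infer each cycle's transcription
rate from the noisy running totals, synchronize by budding, and profile:

```python
import numpy as np
from cyclescope.simkit import SimConfig, cycle_modulated_generator, simulate_cell
from cyclescope.infer import per_cycle_rates
from cyclescope.cycle import CycleSegment, profile

cfg = SimConfig(seed=42)
segs = []
for i in range(40):
    gen = cycle_modulated_generator(cfg)
    cell = simulate_cell(cfg, gen, n_cycles=4,
                         rng=np.random.default_rng(100 + i))
    rates = per_cycle_rates(cell, cell.progeny,
                            gamma_M=cfg.gamma_M, k_t=cfg.k_t)
    divs = sorted(cell.division_times)
    for k, r in enumerate(rates):
        t_bud = [b for b in cell.bud_times if divs[k] < b < divs[k + 1]]
        segs.append(CycleSegment(cell.cell_id, k, divs[k], t_bud[0],
                                 divs[k + 1], r.times, {"A": r.A}))

prof = profile(segs, "A", n_bins=20, n_boot=1000, seed=1)
c, b = prof.bin_centers, prof.bud_point
pre = prof.mean[(c > 0.05) & (c < b - 0.07)].mean()
post = prof.mean[(c > b + 0.15) & (c < 0.95)].mean()
print(f"cycles {int(prof.n[0])}, bud point {b:.2f}, "
      f"pre {pre:.3f}, post {post:.3f}, ratio {post/pre:.2f}")
```

This prints

```
cycles 160, bud point 0.27, pre 0.181, post 0.375, ratio 2.07
```

i.e. from noisy fluorescence alone the pipeline recovers the configured
trough/peak rates (truth 0.200 and 0.400 mRNA/min) and the two-fold
post-bud increase; bins adjacent to budding are excluded because the
15–20-min smoothing window blurs the transition.

The same stages run from the shell:

```
cyclescope simulate --n-cells 10 --cycles 3 --seed 1 --out run/
cyclescope infer rates --traces run/traces.tsv --gamma-m 0.0347 --out run/rates.tsv
cyclescope cycle profile --traces run/traces.tsv --events run/events.tsv \
    --quantity fluorescence --bins 20 --boot 1000 --seed 1 --out run/profile.tsv
cyclescope infer select-beta --reps 100 --seed 1     # β calibration study
```

## Notes

See `docs/methods.md` for the full model description, parameter defaults
(and why), numerical choices, and known limitations.
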