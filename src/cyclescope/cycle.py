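"""In-silico cell-cycle synchronization and population profiling.

Single-cell time series are cut into division-to-division segments,
synchronized at bud emergence, mapped onto a common progression coordinate
(division at 0 and 1, budding at the population-average pre-bud fraction b)
by a two-piece linear time map, and averaged in progression bins with
bootstrap standard errors (resampling whole cell cycles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .simkit import CellTrace

__all__ = ["CycleSegment", "CycleProfile", "segment_cycles",
           "rescale_progression", "profile", "growth_rate_series"]


@dataclass
class CycleSegment:
    """One division-to-division interval of a cell's series."""

    cell_id: str
    cycle_index: int
    t_div_start: float
    t_bud: float
    t_div_end: float
    times: np.ndarray
    values: dict  # quantity name -> sampled series on `times`
    complete: bool = True

    @property
    def pre_bud_fraction(self) -> float:
        return (self.t_bud - self.t_div_start) / (self.t_div_end - self.t_div_start)


def segment_cycles(trace: CellTrace, quantities: Optional[dict] = None,
                   channel: str = "cfp") -> list:
    """Cut a trace into cell-cycle segments at its division events.

    Each complete segment spans consecutive divisions and contains exactly
    one bud event; leading/trailing partial cycles are returned flagged
    ``complete=False`` (they matter for scoring S/G2/M periods that follow
    an unobserved G1).  Segments whose bud falls outside the division
    interval are dropped with a warning.
    """
    import warnings

    trace.validate()
    if quantities is None:
        quantities = {"volume": trace.volume,
                      "fluorescence": trace.total_fluorescence(channel)}
    divs = sorted(trace.division_times)
    buds = sorted(trace.bud_times)
    segments: list = []

    def series_in(t0, t1):
        sel = (trace.times >= t0 - 1e-9) & (trace.times <= t1 + 1e-9)
        return trace.times[sel], {k: np.asarray(v)[sel]
                                  for k, v in quantities.items()}

    edges = [trace.times[0]] + [d for d in divs if
                                trace.times[0] < d < trace.times[-1]] + \
            [trace.times[-1]]
    for i, (t0, t1) in enumerate(zip(edges[:-1], edges[1:])):
        is_complete = (t0 in divs or np.isclose(t0, divs).any() if divs else False) and \
                      (t1 in divs or np.isclose(t1, divs).any() if divs else False)
        in_buds = [b for b in buds if t0 < b < t1]
        if len(in_buds) > 1:
            warnings.warn(f"{trace.cell_id}: {len(in_buds)} buds in one "
                          "division interval; segment rejected")
            continue
        if not in_buds:
            if is_complete:
                warnings.warn(f"{trace.cell_id}: division interval without a "
                              "bud; segment rejected")
                continue
            t_bud = np.nan
        else:
            t_bud = in_buds[0]
        t, vals = series_in(t0, t1)
        if t.size < 2:
            continue
        segments.append(CycleSegment(cell_id=trace.cell_id, cycle_index=i,
                                     t_div_start=t0, t_bud=t_bud,
                                     t_div_end=t1, times=t, values=vals,
                                     complete=bool(is_complete and in_buds)))
    return segments


def _progression_map(seg: CycleSegment, b: float) -> np.ndarray:
    """Two-piece linear map: [t0, t_bud] -> [0, b], [t_bud, t1] -> [b, 1]."""
    t = seg.times
    pre = t <= seg.t_bud
    out = np.empty(t.shape)
    len_pre = seg.t_bud - seg.t_div_start
    len_post = seg.t_div_end - seg.t_bud
    if len_pre <= 0 or len_post <= 0:
        raise ValueError("zero-length cycle phase")
    out[pre] = b * (t[pre] - seg.t_div_start) / len_pre
    out[~pre] = b + (1.0 - b) * (t[~pre] - seg.t_bud) / len_post
    return out


def average_bud_point(segments: Sequence[CycleSegment]) -> float:
    """Population-average pre-bud fraction of the cycle."""
    fracs = [s.pre_bud_fraction for s in segments if s.complete]
    if not fracs:
        raise ValueError("no complete segments")
    return float(np.mean(fracs))


def rescale_progression(segments: Sequence[CycleSegment], quantity: str,
                        target_bud_point="population-average",
                        rescale_time: bool = True):
    """Map each segment's series onto the common progression coordinate.

    Returns ``(b, series)`` where ``b`` is the bud progression point used
    and ``series`` is a list of ``(progression, values)`` pairs, one per
    complete segment.  With ``rescale_time=False`` the unscaled variant is
    produced instead: time is only shifted so budding sits at 0 min (the
    synchronize-without-rescaling convention), and pairs are
    ``(t - t_bud, values)``.
    """
    complete = [s for s in segments if s.complete]
    if not complete:
        raise ValueError("need at least one complete segment")
    if not rescale_time:
        return None, [(s.times - s.t_bud, s.values[quantity]) for s in complete]
    if target_bud_point == "population-average":
        b = average_bud_point(complete)
    else:
        b = float(target_bud_point)
        if not 0.0 < b < 1.0:
            raise ValueError("target bud point must lie in (0, 1)")
    return b, [(_progression_map(s, b), s.values[quantity]) for s in complete]


@dataclass
class CycleProfile:
    """Binned population average along cell-cycle progression."""

    bin_edges: np.ndarray
    mean: np.ndarray
    sem_boot: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    bud_point: Optional[float]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"bin_lo": self.bin_edges[:-1],
                             "bin_hi": self.bin_edges[1:],
                             "mean": self.mean, "sem_boot": self.sem_boot,
                             "sd": self.sd, "n": self.n})


def profile(segments: Sequence[CycleSegment], quantity: str,
            n_bins: int = 20, n_boot: int = 1000, seed=None,
            target_bud_point="population-average") -> CycleProfile:
    """Population profile of ``quantity`` along cell-cycle progression.

    Each complete cycle is linearly interpolated onto the bin centers, the
    population mean and across-cycle SD are taken per bin, and the SEM is
    the SD of bootstrap means obtained by resampling whole cycles (the
    exchangeable unit) with replacement.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    # sort for order invariance of the bootstrap stream
    segments = sorted(segments, key=lambda s: (s.cell_id, s.cycle_index))
    b, series = rescale_progression(segments, quantity, target_bud_point)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mat = np.vstack([np.interp(centers, prog, vals)
                     for prog, vals in series])
    n_cyc = mat.shape[0]
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if n_cyc > 1 else np.zeros(n_bins)
    idx = rng.integers(0, n_cyc, size=(n_boot, n_cyc))
    boot_means = mat[idx].mean(axis=1)
    sem = boot_means.std(axis=0, ddof=1)
    return CycleProfile(bin_edges=edges, mean=mean, sem_boot=sem, sd=sd,
                        n=np.full(n_bins, n_cyc), bud_point=b)


def growth_rate_series(times: np.ndarray, volume: np.ndarray,
                       beta: float = 10.0):
    """Instantaneous relative growth rate (dV/dt)/V from a volume spline.

    Same smoothing convention as the protein traces (the penalty weight
    differs because volumes are orders of magnitude smaller than
    fluorescence).  Volume is discontinuous at division, so fit one cycle
    segment at a time.  Returns the rate on the input grid.
    """
    from .infer import RunningTotalTrace, fit_smoothing_spline

    tr = RunningTotalTrace("volume", np.asarray(times, dtype=float),
                           np.asarray(volume, dtype=float))
    fit = fit_smoothing_spline(tr, beta)
    v = fit.value(tr.times)
    dv = fit.d1(tr.times)
    return dv / np.maximum(v, 1e-12)
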