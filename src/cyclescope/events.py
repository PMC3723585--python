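"""Transcription ON/OFF event detection and co-activation statistics.

Transcription states are assigned by thresholding the inferred rate A(t);
crossing times are linearly interpolated between grid samples and brief
spurious runs are debounced.  Step-test response delays follow a five-step
effective-threshold procedure that separates slow transcription activation
from slow transcription-factor nuclear accumulation.  Co-activation of
homologous loci is scored per S/G2/M period with a 2x2 chi-square test and
the phi correlation coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .infer import ExpressionRates

__all__ = ["EventRecord", "StepTestConfig", "StepTestResult",
           "CoActivationStats", "binarize", "background_threshold",
           "steptest_delays", "coactivation", "on_probability_profile"]


@dataclass
class EventRecord:
    """Binarized transcription state of one cell/channel."""

    cell_id: str
    channel: str
    times: np.ndarray
    on_series: np.ndarray
    activation_times: list
    deactivation_times: list
    threshold: float
    cycle_index: Optional[int] = None


def background_threshold(A_off: np.ndarray, n_mad: float = 3.0) -> float:
    """Detection floor: ``n_mad`` x the median absolute deviation of A(t)
    over annotated OFF reference periods (or basal-strain simulations)."""
    A_off = np.asarray(A_off, dtype=float)
    med = np.median(A_off)
    mad = np.median(np.abs(A_off - med))
    return float(med + n_mad * mad)


def _crossings(times, x, threshold, upward=True, t_min=-np.inf,
               min_run: int = 2):
    """Interpolated threshold-crossing times, debounced to ``min_run`` samples."""
    out = []
    above = x >= threshold
    n = x.size
    for i in range(n - 1):
        if times[i + 1] < t_min:
            continue
        crossed = (not above[i] and above[i + 1]) if upward else \
                  (above[i] and not above[i + 1])
        if not crossed:
            continue
        run = 1
        while i + 1 + run < n and (above[i + 1 + run] == above[i + 1]):
            run += 1
        if run < min_run and i + 1 + run < n:
            continue
        frac = (threshold - x[i]) / (x[i + 1] - x[i])
        out.append(float(times[i] + frac * (times[i + 1] - times[i])))
    return out


def binarize(rates: ExpressionRates, background_threshold: float,
             min_run: int = 2, channel: str = "cfp") -> EventRecord:
    """Threshold A(t) into ON/OFF with debounced, interpolated event times.

    ON wherever A(t) exceeds the background threshold; ON (and OFF) runs
    shorter than ``min_run`` samples are treated as noise and removed.
    Low-confidence boundary samples are excluded from event detection.
    """
    if background_threshold <= 0:
        raise ValueError("threshold must be positive")
    t = rates.times
    ok = ~rates.low_confidence
    on = (rates.A > background_threshold) & ok
    # debounce: flip short runs (ON first, then OFF)
    for target in (True, False):
        i = 0
        n = on.size
        while i < n:
            j = i
            while j < n and on[j] == on[i]:
                j += 1
            if on[i] == target and (j - i) < min_run and i > 0 and j < n:
                on[i:j] = not target
            i = j
    acts, deacts = [], []
    for i in range(1, on.size):
        if on[i] and not on[i - 1]:
            a0, a1 = rates.A[i - 1], rates.A[i]
            frac = 0.0 if a1 == a0 else (background_threshold - a0) / (a1 - a0)
            acts.append(float(t[i - 1] + np.clip(frac, 0, 1) * (t[i] - t[i - 1])))
        if not on[i] and on[i - 1]:
            a0, a1 = rates.A[i - 1], rates.A[i]
            frac = 0.0 if a1 == a0 else (background_threshold - a0) / (a1 - a0)
            deacts.append(float(t[i - 1] + np.clip(frac, 0, 1) * (t[i] - t[i - 1])))
    return EventRecord(cell_id=rates.cell_id, channel=channel, times=t,
                       on_series=on.astype(int),
                       activation_times=acts, deactivation_times=deacts,
                       threshold=float(background_threshold))


@dataclass
class StepTestConfig:
    """Constants of the five-step response-delay procedure.

    ``transcription_threshold_fraction``: activation threshold as a fraction
    of the population steady-state transcription rate (0.5).
    ``tau_obs``: observation lag (min) between true transcription onset and
    its appearance in inferred rates, dominated by fluorophore maturation;
    used to back-reference the localization level that was present when
    transcription actually started.
    ``localization_percentile``: percentile of the pooled back-referenced
    localization values taken as the effective localization threshold (5).
    """

    transcription_threshold_fraction: float = 0.5
    tau_obs: float = 15.0
    localization_percentile: float = 5.0

    def validate(self):
        if not 0.0 < self.transcription_threshold_fraction < 1.0:
            raise ValueError("threshold fraction must be in (0, 1)")
        if not 0.0 < self.localization_percentile < 100.0:
            raise ValueError("percentile must be in (0, 100)")


@dataclass
class StepTestResult:
    """Per-cell step-test timing."""

    cell_id: str
    localization_time: float
    transcription_activation_time: float
    response_delay: float
    phase_at_localization: Optional[str] = None
    progression_at_localization: Optional[float] = None
    progression_at_activation: Optional[float] = None
    censored: bool = False


def steptest_delays(rates_per_cell: Sequence[ExpressionRates],
                    localization_per_cell: Sequence[tuple],
                    cfg: Optional[StepTestConfig] = None,
                    steady_state_window: tuple = (80.0, 140.0),
                    step_time: float = 0.0,
                    bud_times: Optional[Sequence] = None,
                    min_run: int = 2) -> list:
    """Five-step response-delay assignment after a TF step at ``step_time``.

    1. The transcription threshold is 50% of the population steady-state
       rate (mean inferred A over ``steady_state_window`` across cells).
    2. For each cell, the localization level ``tau_obs`` minutes before its
       transcription-threshold crossing is read off.
    3. Those values are pooled across cells.
    4. The effective localization threshold is their 5th percentile (a TF
       level at which many cells do activate, so nuclear TF is no longer
       limiting).
    5. Each cell's localization time is its first crossing of that
       threshold; delay = activation - localization.

    ``localization_per_cell`` holds ``(times, level)`` pairs.  Cells whose
    rate never crosses the transcription threshold are returned censored
    and excluded from delay statistics.  Deterministic: no RNG involved.
    """
    if cfg is None:
        cfg = StepTestConfig()
    cfg.validate()
    lo, hi = steady_state_window
    ss_vals = []
    for r in rates_per_cell:
        sel = (r.times >= lo) & (r.times <= hi)
        ss_vals.append(r.A[sel])
    ss_rate = float(np.mean(np.concatenate(ss_vals)))
    thr_A = cfg.transcription_threshold_fraction * ss_rate

    act_times = []
    for r in rates_per_cell:
        ok = ~r.low_confidence
        cr = _crossings(r.times[ok], r.A[ok], thr_A, upward=True,
                        t_min=step_time, min_run=min_run)
        act_times.append(cr[0] if cr else None)

    pooled = []
    for (loc_t, loc_v), t_act in zip(localization_per_cell, act_times):
        if t_act is None:
            continue
        pooled.append(float(np.interp(t_act - cfg.tau_obs, loc_t, loc_v)))
    if not pooled:
        raise ValueError("no cell crossed the transcription threshold")
    thr_loc = float(np.percentile(pooled, cfg.localization_percentile))

    results = []
    for r, (loc_t, loc_v), t_act in zip(rates_per_cell,
                                        localization_per_cell, act_times):
        if t_act is None:
            results.append(StepTestResult(cell_id=r.cell_id,
                                          localization_time=math.nan,
                                          transcription_activation_time=math.nan,
                                          response_delay=math.nan,
                                          censored=True))
            continue
        cr = _crossings(np.asarray(loc_t), np.asarray(loc_v), thr_loc,
                        upward=True, t_min=step_time, min_run=1)
        t_loc = cr[0] if cr else float(loc_t[0])
        res = StepTestResult(cell_id=r.cell_id, localization_time=t_loc,
                             transcription_activation_time=t_act,
                             response_delay=t_act - t_loc)
        if bud_times is not None:
            bt = bud_times[rates_per_cell.index(r)] if not isinstance(
                bud_times, dict) else bud_times.get(r.cell_id)
            if bt is not None:
                res.phase_at_localization = ("G1" if t_loc < bt
                                             else "S/G2/M")
        results.append(res)
    return results


@dataclass
class CoActivationStats:
    """2x2 ON/OFF association between homologous loci per S/G2/M period."""

    table: np.ndarray  # [[both_on, A_only], [B_only, neither]]
    chi2: Optional[float]
    p_value: Optional[float]
    phi: Optional[float]
    dual_on_within_window: Optional[float]
    n_periods: int
    window: float
    flag: Optional[str] = None


def coactivation(records_a: Sequence, records_b: Sequence,
                 window: float = 15.0) -> CoActivationStats:
    """Score paired per-period ON/OFF calls from two homologous loci.

    ``records_a``/``records_b`` are paired per cell per S/G2/M period;
    each element exposes ``activation_times`` (non-empty means the locus
    turned ON that period).  Reports the Pearson chi-square statistic
    without continuity correction, the phi coefficient, and among dual-ON
    periods the fraction whose activation times fall within ``window``
    minutes of each other.
    """
    if len(records_a) != len(records_b):
        raise ValueError("records must be paired per period")
    a_on = np.array([bool(r.activation_times) for r in records_a])
    b_on = np.array([bool(r.activation_times) for r in records_b])
    n = a_on.size
    n11 = int(np.sum(a_on & b_on))
    n10 = int(np.sum(a_on & ~b_on))
    n01 = int(np.sum(~a_on & b_on))
    n00 = int(np.sum(~a_on & ~b_on))
    table = np.array([[n11, n10], [n01, n00]])
    margins = [n11 + n10, n01 + n00, n11 + n01, n10 + n00]
    if min(margins) == 0:
        return CoActivationStats(table=table, chi2=None, p_value=None,
                                 phi=None, dual_on_within_window=None,
                                 n_periods=n, window=window,
                                 flag="degenerate margins: chi-square undefined")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    phi = (n11 * n00 - n10 * n01) / math.sqrt(
        float(margins[0]) * margins[1] * margins[2] * margins[3])
    frac = None
    if n11 > 0:
        dts = []
        for ra, rb in zip(records_a, records_b):
            if ra.activation_times and rb.activation_times:
                dts.append(abs(ra.activation_times[0] - rb.activation_times[0]))
        frac = float(np.mean(np.asarray(dts) <= window))
    return CoActivationStats(table=table, chi2=float(chi2), p_value=float(p),
                             phi=float(phi), dual_on_within_window=frac,
                             n_periods=n, window=window)


def on_probability_profile(records: Sequence[EventRecord],
                           segments_per_record: Sequence,
                           n_bins: int = 20, n_boot: int = 1000, seed=None):
    """Probability of being ON per cell-cycle progression bin.

    Averages binarized (ON = 1 / OFF = 0) responses across cycles in each
    progression bin; the record/segment pairing supplies the progression
    map.  Returns a :class:`cyclescope.cycle.CycleProfile`.
    """
    from .cycle import CycleSegment, profile as cycle_profile

    segs = []
    for rec, seg in zip(records, segments_per_record):
        on_interp = np.interp(seg.times, rec.times, rec.on_series)
        s = CycleSegment(cell_id=seg.cell_id, cycle_index=seg.cycle_index,
                         t_div_start=seg.t_div_start, t_bud=seg.t_bud,
                         t_div_end=seg.t_div_end, times=seg.times,
                         values={"on": on_interp}, complete=seg.complete)
        segs.append(s)
    return cycle_profile(segs, "on", n_bins=n_bins, n_boot=n_boot, seed=seed)
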