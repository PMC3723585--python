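"""Cell-cycle-phase-dependent stochastic mRNA distribution models.

The central model: transcription proceeds at a constant rate k_G1 in G1 and
at f * k_G1 in S/G2/M, mRNA decays first-order at gamma_M, and at division
each transcript is retained with probability q (binomial thinning).  For an
asynchronous, exponentially growing population the mRNA count of a cell at
age a is then Poisson with mean m(a), the cycle-periodic solution of

    dm/da = A(a) - gamma_M * m,      m(0) = q * m(t_cyc),

because the Poisson law is closed under both linear birth-death dynamics
and binomial thinning.  The population snapshot law is the mixture of these
Poisson laws over the exponential-growth age density
p(a) = (2 ln2 / t_cyc) 2^(-a/t_cyc).  Variants: gene-dosage doubling at a
replication point inside S, and a G1->S/G2/M transition time randomized
uniformly over a window after budding.

Phase-stratified FISH counts (G1 plus three ranked-bud-size thirds of
S/G2/M, mapped here to equal thirds of S/G2/M duration) are fitted by
maximum likelihood on the exact Poisson-mixture law; the negative-binomial
(bursting) baseline is provided for comparison with the standard model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

__all__ = ["ModelSpec", "ModelPrediction", "NBFit", "PHASES",
           "rate_profile", "mean_trajectory", "predict", "sample_counts",
           "fit_f", "fit_negative_binomial", "compare_models",
           "age_density"]

PHASES = ("G1", "S1", "S2", "S3")


@dataclass
class ModelSpec:
    """Parameters of the phase-dependent transcription model.

    ``f`` multiplies the G1 rate after the G1->S/G2/M transition (by default
    sharp at budding).  ``dosage_doubling`` instead doubles the rate at
    ``replication_fraction`` of the cycle (within S); with f = 1 this is the
    pure gene-dosage model.  ``transition_model`` is ``"sharp"`` or
    ``"uniform_window"`` (transition uniformly distributed over
    ``transition_window`` minutes after budding, truncated at division).
    """

    k_G1: float = 0.2
    f: float = 2.0
    #: explicit S/G2/M rate; overrides k_G1 * f when set (lets the basal
    #: f -> infinity limit be written as k_G1 = 0 with a finite S rate)
    k_SG2M: Optional[float] = None
    gamma_M: float = math.log(2.0) / 20.0
    t_cyc: float = 100.0
    bud_fraction: float = 0.27
    dosage_doubling: bool = False
    replication_fraction: float = 0.35
    transition_model: str = "sharp"
    transition_window: float = 40.0
    division_fraction: float = 0.5

    def validate(self) -> None:
        if self.k_G1 < 0 or self.f < 0 or self.gamma_M < 0:
            raise ValueError("rates must be non-negative")
        if self.k_SG2M is not None and self.k_SG2M < 0:
            raise ValueError("rates must be non-negative")
        if self.transition_window < 0:
            raise ValueError("transition window must be >= 0")
        if not 0.0 < self.bud_fraction < 1.0:
            raise ValueError("bud_fraction must lie in (0, 1)")
        if self.dosage_doubling and not (
                self.bud_fraction <= self.replication_fraction < 1.0):
            raise ValueError("replication time must fall within S phase")
        if self.transition_model not in ("sharp", "uniform_window"):
            raise ValueError("unknown transition model")
        if not 0.0 < self.division_fraction < 1.0:
            raise ValueError("division_fraction must lie in (0, 1)")

    @property
    def t_bud(self) -> float:
        return self.bud_fraction * self.t_cyc

    def transition_nodes(self, n: int = 16):
        """Midpoint nodes for the uniform transition-time mixture."""
        hi = min(self.t_bud + self.transition_window, self.t_cyc)
        if self.transition_model == "sharp" or hi <= self.t_bud:
            return np.array([self.t_bud]), np.array([1.0])
        edges = np.linspace(self.t_bud, hi, n + 1)
        return 0.5 * (edges[:-1] + edges[1:]), np.full(n, 1.0 / n)

    def draw_transition(self, rng: np.random.Generator) -> float:
        if self.transition_model == "sharp":
            return self.t_bud
        hi = min(self.t_bud + self.transition_window, self.t_cyc)
        return float(rng.uniform(self.t_bud, hi))


def rate_profile(model: ModelSpec, transition_time: Optional[float] = None):
    """Piecewise-constant transcription rate over one cycle.

    Returns segments ``[(a0, a1, rate), ...]`` covering [0, t_cyc].
    """
    T = model.t_bud if transition_time is None else transition_time
    pts = {0.0, model.t_cyc, min(T, model.t_cyc)}
    if model.dosage_doubling:
        pts.add(model.replication_fraction * model.t_cyc)
    edges = sorted(pts)
    segs = []
    post_rate = (model.k_SG2M if model.k_SG2M is not None
                 else model.k_G1 * model.f)
    for a0, a1 in zip(edges[:-1], edges[1:]):
        if a1 <= a0:
            continue
        mid = 0.5 * (a0 + a1)
        r = post_rate if mid >= T else model.k_G1
        if model.dosage_doubling and mid >= model.replication_fraction * model.t_cyc:
            r *= 2.0
        segs.append((a0, a1, r))
    return segs


def mean_trajectory(model: ModelSpec, ages: np.ndarray,
                    transition_time: Optional[float] = None) -> np.ndarray:
    """Cycle-periodic mean mRNA m(a) at the given ages.

    Solves dm/da = A(a) - gamma_M m with the division boundary condition
    m(0) = q * m(t_cyc) in closed form for the piecewise-constant profile.
    """
    segs = rate_profile(model, transition_time)
    g = model.gamma_M
    q = model.division_fraction
    ages = np.asarray(ages, dtype=float)

    def forced(a):
        """Particular solution from rate input, zero initial condition."""
        a = np.atleast_1d(a)
        out = np.zeros(a.shape)
        for (s0, s1, r) in segs:
            if r == 0:
                continue
            hi = np.minimum(a, s1)
            active = a > s0
            if g > 0:
                contrib = (r / g) * (np.exp(-g * (a - hi)) - np.exp(-g * (a - s0)))
            else:
                contrib = r * (hi - s0)
            out += np.where(active, contrib, 0.0)
        return out

    E = math.exp(-g * model.t_cyc)
    C = float(forced(np.array([model.t_cyc]))[0])
    denom = 1.0 - q * E
    m0 = q * C / denom if denom > 0 else 0.0
    return m0 * np.exp(-g * ages) + forced(ages)


def age_density(ages: np.ndarray, t_cyc: float) -> np.ndarray:
    """Asynchronous exponential-growth age density on [0, t_cyc]."""
    ages = np.asarray(ages, dtype=float)
    return (2.0 * math.log(2.0) / t_cyc) * np.exp2(-ages / t_cyc)


def _phase_bounds(model: ModelSpec):
    tb, tc = model.t_bud, model.t_cyc
    third = (tc - tb) / 3.0
    return {"G1": (0.0, tb), "S1": (tb, tb + third),
            "S2": (tb + third, tb + 2 * third), "S3": (tb + 2 * third, tc)}


def _poisson_pmf_matrix(means: np.ndarray, kmax: int) -> np.ndarray:
    """Poisson pmf table, shape (len(means), kmax + 1)."""
    k = np.arange(kmax + 1)
    m = np.asarray(means, dtype=float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = k * np.log(np.where(m > 0, m, 1.0)) - m - gammaln(k + 1)
    pmf = np.exp(logp)
    zero = (m[:, 0] <= 0)
    if zero.any():
        pmf[zero] = 0.0
        pmf[zero, 0] = 1.0
    return pmf


@dataclass
class ModelPrediction:
    """Snapshot law of a phase model: per-phase and aggregate moments/pmfs."""

    phases: tuple
    mean: dict
    sd: dict
    pmf: dict
    phase_weight: dict
    aggregate_pmf: np.ndarray
    aggregate_mean: float
    aggregate_sd: float
    method: str
    n_cells: Optional[int] = None


def _phase_quadrature(model: ModelSpec, n_nodes: int):
    """Midpoint age nodes and density weights per phase."""
    out = {}
    for ph, (a0, a1) in _phase_bounds(model).items():
        edges = np.linspace(a0, a1, n_nodes + 1)
        nodes = 0.5 * (edges[:-1] + edges[1:])
        w = age_density(nodes, model.t_cyc) * (a1 - a0) / n_nodes
        out[ph] = (nodes, w)
    return out


def predict(model: ModelSpec, method: str = "analytic",
            n_cells: int = 20000, seed=None, n_age_nodes: int = 48,
            kmax: Optional[int] = None) -> ModelPrediction:
    """Snapshot distribution of the model, per phase and aggregate.

    ``analytic`` mixes Poisson laws over the age density (and, for the
    randomized-transition variant, over the uniform transition-time window,
    with the drawn transition treated as a property of the cell's lineage);
    ``ssa`` estimates the same law by exact stochastic simulation via
    :func:`cyclescope.simkit.simulate_population_snapshot`.
    """
    model.validate()
    if method == "ssa":
        from .simkit import simulate_population_snapshot

        df = simulate_population_snapshot(model, n_cells, seed=seed)
        km = int(df["count"].max()) if kmax is None else kmax
        mean, sd, pmf, wts = {}, {}, {}, {}
        for ph in PHASES:
            c = df.loc[df["phase"] == ph, "count"].to_numpy()
            mean[ph] = float(c.mean()) if c.size else math.nan
            sd[ph] = float(c.std(ddof=1)) if c.size > 1 else math.nan
            h = np.bincount(c, minlength=km + 1).astype(float)
            pmf[ph] = h / max(h.sum(), 1.0)
            wts[ph] = c.size / len(df)
        agg = np.bincount(df["count"].to_numpy(), minlength=km + 1).astype(float)
        agg /= agg.sum()
        return ModelPrediction(phases=PHASES, mean=mean, sd=sd, pmf=pmf,
                               phase_weight=wts, aggregate_pmf=agg,
                               aggregate_mean=float(df["count"].mean()),
                               aggregate_sd=float(df["count"].std(ddof=1)),
                               method="ssa", n_cells=n_cells)
    if method != "analytic":
        raise ValueError("method must be 'analytic' or 'ssa'")

    t_nodes, t_w = model.transition_nodes()
    quad = _phase_quadrature(model, n_age_nodes)
    # peak mean bounds kmax
    peak = 0.0
    means_cache = {}
    for ph in PHASES:
        nodes, w = quad[ph]
        m_mix = np.zeros((t_nodes.size, nodes.size))
        for i, T in enumerate(t_nodes):
            m_mix[i] = mean_trajectory(model, nodes, T)
        means_cache[ph] = m_mix
        peak = max(peak, float(m_mix.max(initial=0.0)))
    if kmax is None:
        kmax = int(math.ceil(peak + 10.0 * math.sqrt(peak + 1.0) + 10))

    mean, sd, pmf, wts = {}, {}, {}, {}
    agg = np.zeros(kmax + 1)
    agg_m1 = agg_m2 = 0.0
    for ph in PHASES:
        nodes, w = quad[ph]
        wsum = w.sum()
        m_mix = means_cache[ph]
        # mixture over transition times and ages
        w2 = (t_w[:, None] * w[None, :]).ravel()
        means_flat = m_mix.ravel()
        P = _poisson_pmf_matrix(means_flat, kmax)
        ph_pmf = (w2[:, None] * P).sum(axis=0) / wsum
        m1 = float((w2 * means_flat).sum() / wsum)
        m2 = float((w2 * (means_flat + means_flat ** 2)).sum() / wsum)
        mean[ph] = m1
        sd[ph] = math.sqrt(max(m2 - m1 ** 2, 0.0))
        pmf[ph] = ph_pmf
        wts[ph] = float(wsum)
        agg += wsum * ph_pmf
        agg_m1 += wsum * m1
        agg_m2 += wsum * m2
    tot = sum(wts.values())
    agg /= tot
    agg_m1 /= tot
    agg_m2 /= tot
    for ph in PHASES:
        wts[ph] /= tot
    return ModelPrediction(phases=PHASES, mean=mean, sd=sd, pmf=pmf,
                           phase_weight=wts, aggregate_pmf=agg,
                           aggregate_mean=agg_m1,
                           aggregate_sd=math.sqrt(max(agg_m2 - agg_m1 ** 2, 0.0)),
                           method="analytic")


def sample_counts(model: ModelSpec, n_cells: int, seed=None):
    """Exact sample from the model's snapshot law (age + Poisson draw).

    Equivalent in law to the SSA population snapshot (Poisson closure is
    exact for this linear model) but much faster; used to generate
    synthetic phase-stratified count data for recovery studies.
    """
    import pandas as pd

    from .simkit import phase_label, sample_asynchronous_ages

    model.validate()
    rng = np.random.default_rng(seed)
    ages = sample_asynchronous_ages(model.t_cyc, n_cells, rng)
    T = np.array([model.draw_transition(rng) for _ in range(n_cells)])
    means = np.array([mean_trajectory(model, np.array([a]), t)[0]
                      for a, t in zip(ages, T)])
    counts = rng.poisson(means)
    return pd.DataFrame({"cell_id": [f"c{i}" for i in range(n_cells)],
                         "phase": phase_label(ages, model.t_cyc,
                                              model.bud_fraction),
                         "count": counts, "age": ages})


def _loglik(counts_by_phase: dict, model: ModelSpec,
            n_age_nodes: int = 32) -> float:
    kmax = max(int(c.max()) for c in counts_by_phase.values() if c.size)
    t_nodes, t_w = model.transition_nodes()
    quad = _phase_quadrature(model, n_age_nodes)
    ll = 0.0
    for ph, counts in counts_by_phase.items():
        if not counts.size:
            continue
        nodes, w = quad[ph]
        w2 = (t_w[:, None] * w[None, :]).ravel()
        means = np.concatenate([mean_trajectory(model, nodes, T)
                                for T in t_nodes])
        P = _poisson_pmf_matrix(means, kmax)
        ph_pmf = (w2[:, None] * P).sum(axis=0) / w.sum()
        hist = np.bincount(counts, minlength=kmax + 1)
        with np.errstate(divide="ignore"):
            logp = np.log(np.maximum(ph_pmf, 1e-300))
        ll += float((hist * logp).sum())
    return ll


@dataclass
class FFit:
    """Profile-likelihood fit of the fold-change f."""

    f_hat: float
    k_G1_hat: float
    censored: bool
    f_grid: np.ndarray
    profile_loglik: np.ndarray
    ci: tuple
    flag: Optional[str] = None


def fit_f(data, fixed: Optional[dict] = None,
          f_grid: Optional[Sequence[float]] = None,
          n_age_nodes: int = 32) -> FFit:
    """Maximum-likelihood fold-change between G1 and S/G2/M rates.

    ``data`` is a DataFrame with columns ``phase`` (G1/S1/S2/S3) and
    ``count``.  For each f on a log grid the G1 rate is profiled out by a
    bounded 1-D search, then f-hat is refined between its grid neighbours.
    The CI is the likelihood-ratio interval at 95%.  A maximum on the upper
    grid edge is reported censored ("f exceeds the grid"), which is how a
    no-G1-transcription dataset presents.
    """
    from scipy.optimize import minimize_scalar

    fixed = fixed or {}
    counts_by_phase = {ph: data.loc[data["phase"] == ph, "count"]
                       .to_numpy(dtype=int) for ph in PHASES}
    if all(c.size == 0 or (c == 0).all() for c in counts_by_phase.values()):
        return FFit(f_hat=math.nan, k_G1_hat=0.0, censored=False,
                    f_grid=np.array([]), profile_loglik=np.array([]),
                    ci=(math.nan, math.nan),
                    flag="all counts zero: f unidentifiable")
    missing = [ph for ph in PHASES if counts_by_phase[ph].size == 0]
    if missing:
        raise ValueError(f"phases missing from data: {missing}")
    if f_grid is None:
        f_grid = np.geomspace(0.25, 256.0, 21)
    f_grid = np.asarray(sorted(f_grid), dtype=float)

    base = ModelSpec(**{**ModelSpec().__dict__, **fixed})
    overall_mean = float(np.concatenate(list(counts_by_phase.values())).mean())
    k_hi = max(base.gamma_M * overall_mean * 8.0, 1e-3)

    def profiled(f):
        def nll(log_k):
            spec = ModelSpec(**{**base.__dict__, "k_G1": math.exp(log_k),
                                "f": f})
            return -_loglik(counts_by_phase, spec, n_age_nodes)
        res = minimize_scalar(nll, bounds=(math.log(1e-6), math.log(k_hi)),
                              method="bounded",
                              options={"xatol": 1e-3})
        return -res.fun, math.exp(res.x)

    prof = np.empty(f_grid.size)
    ks = np.empty(f_grid.size)
    for i, f in enumerate(f_grid):
        prof[i], ks[i] = profiled(f)
    i_best = int(np.argmax(prof))
    censored = i_best == f_grid.size - 1
    f_hat, k_hat, ll_best = f_grid[i_best], ks[i_best], prof[i_best]
    if not censored and 0 < i_best < f_grid.size - 1:
        from scipy.optimize import minimize_scalar as ms

        res = ms(lambda lf: -profiled(math.exp(lf))[0],
                 bounds=(math.log(f_grid[i_best - 1]),
                         math.log(f_grid[i_best + 1])),
                 method="bounded", options={"xatol": 5e-3})
        if -res.fun >= ll_best:
            f_hat = math.exp(res.x)
            ll_best = -res.fun
            k_hat = profiled(f_hat)[1]
    # likelihood-ratio CI on the grid
    cut = ll_best - 0.5 * chi2_dist.ppf(0.95, 1)
    inside = f_grid[prof >= cut]
    ci = (float(inside.min()), float(inside.max())) if inside.size else \
        (f_hat, f_hat)
    if censored:
        ci = (ci[0], math.inf)
    return FFit(f_hat=float(f_hat), k_G1_hat=float(k_hat),
                censored=censored, f_grid=f_grid, profile_loglik=prof,
                ci=ci, flag="f exceeds grid upper bound" if censored else None)


@dataclass
class NBFit:
    """Negative-binomial (bursting) moment fit: mean = a*b, var = a*b(1+b)."""

    burst_size: float
    burst_frequency: float
    mean: float
    variance: float
    poisson_limit: bool
    flag: Optional[str] = None


def fit_negative_binomial(counts) -> NBFit:
    """Moment-match counts to the negative binomial of the standard model.

    Burst size b = var/mean - 1 and burst frequency (per mRNA lifetime)
    a = mean/b.  Underdispersed data degenerate to the Poisson limit
    (b = 0, flagged).
    """
    c = np.asarray(counts, dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("need at least 2 distinct count values")
    mean = float(c.mean())
    var = float(c.var(ddof=1))
    if mean == 0:
        return NBFit(burst_size=math.nan, burst_frequency=math.nan,
                     mean=mean, variance=var, poisson_limit=False,
                     flag="zero mean: undefined")
    b = var / mean - 1.0
    if b <= 0:
        return NBFit(burst_size=0.0, burst_frequency=math.inf, mean=mean,
                     variance=var, poisson_limit=True,
                     flag="var <= mean: Poisson limit")
    return NBFit(burst_size=float(b), burst_frequency=float(mean / b),
                 mean=mean, variance=var, poisson_limit=False)


def compare_models(data, models: Sequence[ModelSpec],
                   n_age_nodes: int = 48):
    """Predicted vs empirical per-phase moments and pooled chi-square.

    Returns a DataFrame with one row per model: per-phase predicted
    mean/SD, the empirical values, and a chi-square distance between the
    pooled empirical histogram and the model's aggregate pmf.
    """
    import pandas as pd

    gm = {round(m.gamma_M, 12) for m in models}
    tc = {m.t_cyc for m in models}
    if len(gm) > 1 or len(tc) > 1:
        raise ValueError("models must share gamma_M and t_cyc")
    counts = data["count"].to_numpy(dtype=int)
    kmax_emp = int(counts.max())
    rows = []
    for j, m in enumerate(models):
        pred = predict(m, method="analytic", n_age_nodes=n_age_nodes)
        km = max(kmax_emp, pred.aggregate_pmf.size - 1)
        emp_hist = np.bincount(counts, minlength=km + 1).astype(float)
        emp_pmf = emp_hist / emp_hist.sum()
        model_pmf = np.zeros(km + 1)
        model_pmf[:pred.aggregate_pmf.size] = pred.aggregate_pmf
        keep = model_pmf > 1e-12
        chi2 = float(np.sum((emp_pmf[keep] - model_pmf[keep]) ** 2
                            / model_pmf[keep]))
        row = {"model": j, "chi2": chi2,
               "aggregate_mean_pred": pred.aggregate_mean,
               "aggregate_sd_pred": pred.aggregate_sd,
               "aggregate_mean_emp": float(counts.mean()),
               "aggregate_sd_emp": float(counts.std(ddof=1))}
        for ph in PHASES:
            sel = data["phase"] == ph
            c = data.loc[sel, "count"].to_numpy(dtype=float)
            row[f"{ph}_mean_pred"] = pred.mean[ph]
            row[f"{ph}_sd_pred"] = pred.sd[ph]
            row[f"{ph}_mean_emp"] = float(c.mean()) if c.size else math.nan
            row[f"{ph}_sd_emp"] = float(c.std(ddof=1)) if c.size > 1 else math.nan
        rows.append(row)
    return pd.DataFrame(rows)
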