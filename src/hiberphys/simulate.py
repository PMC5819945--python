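"""Synthetic data generator with programmed ground truth.

Emulates the six input streams of a juvenile-hibernator pre-hibernation /
hibernation experiment: nest-temperature traces (1-min), ambient traces
(30-min), implanted body-temperature traces (0.5 °C resolution), weekly
body-mass/body-length tables, open-flow respirometry records, and
doubly-labelled-water (DLW) isotope samples.  Every stream carries an exact
ground-truth object, so each downstream stage can be validated against known
answers without any external data.

The thermal model of the nest trace is a first-order relaxation toward a
state-dependent target temperature:

* animal in nest, euthermic  → target = T_a + nest elevation,
* animal outside the nest    → target = T_a (fast relaxation, nest cools
  quickly once vacated),
* animal in torpor           → target = euthermic level − programmed depth
  (slow relaxation: a torpid animal cools passively over hours).

The fast-versus-slow cooling contrast between nest exits and torpor entries
is the physical signal the downstream classifier exploits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .trace import TemperatureTrace, align_ambient

MIN_PER_DAY = 1440.0
MIN_PER_WEEK = 7 * MIN_PER_DAY

# per-sample ground-truth labels
IN_NEST_EUTHERMIC = 0
IN_NEST_TORPID = 1
OUTSIDE = 2


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one synthetic experiment.

    All times are minutes unless noted; weeks are consecutive 7-day blocks
    counted from experiment start.  A fixed ``seed`` makes every generator
    output byte-identical across runs.
    """

    seed: int = 0
    n_weeks: int = 2
    sampling_interval_nest: float = 1.0
    sampling_interval_ambient: float = 30.0

    # ambient model: daily sinusoid plus AR(1) noise on the 30-min grid
    ambient_mean: float = 22.5
    ambient_amplitude: float = 4.5
    ambient_ar_phi: float = 0.95
    ambient_ar_sd: float = 0.15

    nest_elevation: float = 6.0
    night_window: tuple[float, float] = (1080.0, 360.0)  # 18:00-06:00 clock
    # daily schedule of nest exits: (start minute-of-day, duration min)
    activity_episodes: tuple[tuple[float, float], ...] = ((1080.0, 720.0),)
    # torpor episodes: (day index, onset minute-of-day, duration min, depth °C)
    torpor_schedule: tuple[tuple[int, float, float, float], ...] = ()

    # nest thermal kinetics (time constants, min)
    tau_exit: float = 10.0
    tau_torpor: float = 90.0
    tau_rewarm: float = 15.0
    noise_sd: float = 0.2

    # winter body-temperature trace
    euthermic_tb: float = 36.5
    hibernation_ta: float = 5.3
    torpid_tb_offset: float = 0.5  # torpid T_b sits this far above T_a
    hibernation_bouts: tuple[tuple[float, float], ...] = (
        (720.0, 30 * 60.0),
        (720.0 + 30 * 60.0 + 240.0, 50 * 60.0),
        (720.0 + 80 * 60.0 + 480.0, 80 * 60.0),
    )
    tau_hib_entry: float = 60.0
    tau_hib_arousal: float = 15.0
    tb_resolution: float = 0.5
    tb_noise_sd: float = 0.1

    # weekly growth series: (intercept, slope per week, breakpoint week, noise SD)
    growth_params: tuple[float, float, float, float] = (38.8, 9.4, 5.0, 2.0)
    length_params: tuple[float, float, float, float] = (10.4, 0.4, 5.0, 0.05)

    # open-flow respirometry
    respiro_flow: float = 40.0          # l/h, dry, STPD
    respiro_fio2: float = 0.2095
    respiro_vo2_day: float = 90.0       # ml O2/h during photophase
    respiro_night_day_ratio: float = 2.0
    respiro_rq: float = 0.85
    respiro_interval: float = 5.0       # min
    respiro_hours: float = 48.0
    respiro_habituation_hours: float = 24.0
    respiro_habituation_factor: float = 1.3
    respiro_feo2_noise: float = 2e-5

    # doubly labelled water
    dlw_pool_g: float = 29.28           # total body water, g
    dlw_body_mass_g: float = 55.0
    dlw_k_o: float = 0.45               # 18O elimination, /day
    dlw_k_d: float = 0.35               # 2H elimination, /day
    dlw_dose_g: float = 0.275           # 5 g per kg body mass
    dlw_dose_enrichment: tuple[float, float] = (0.065, 0.10)   # (2H, 18O) abundance
    dlw_background: tuple[float, float] = (0.00015, 0.002)     # (2H, 18O) abundance
    dlw_sample_times: tuple[float, ...] = (1 / 24, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    dlw_noise_frac: float = 0.01

    # weekly food intake (g fresh cat food): rises to a peak then declines
    food_base_g: float = 45.0
    food_peak_g: float = 62.0
    food_peak_week: float = 4.0
    food_noise_g: float = 3.0

    def __post_init__(self) -> None:
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be >= 1")
        for tau in (self.tau_exit, self.tau_torpor, self.tau_rewarm,
                    self.tau_hib_entry, self.tau_hib_arousal):
            if tau <= 0:
                raise ValueError("time constants must be positive")
        for _, dur in self.activity_episodes:
            if dur <= 0:
                raise ValueError("activity episode durations must be positive")
        for _, _, dur, depth in self.torpor_schedule:
            if dur <= 0 or depth <= 0:
                raise ValueError("torpor durations and depths must be positive")
        times = np.asarray(self.dlw_sample_times)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("DLW sample times must be strictly increasing")

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)

    @property
    def n_days(self) -> int:
        return 7 * self.n_weeks

    @property
    def total_minutes(self) -> float:
        return self.n_days * MIN_PER_DAY


@dataclass(frozen=True)
class TruthBout:
    onset: float
    offset: float
    depth: float = 0.0

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class PrehibernationTruth:
    """Exact per-sample labels and episode lists behind a nest trace."""

    labels: np.ndarray                      # one of the label constants
    torpor_bouts: tuple[TruthBout, ...]
    activity_episodes: tuple[tuple[float, float], ...]  # absolute (start, end)

    def activity_minutes_per_week(self, n_weeks: int, dt: float) -> np.ndarray:
        idx = (np.arange(self.labels.size) * dt // MIN_PER_WEEK).astype(int)
        counts = np.bincount(idx[self.labels == OUTSIDE], minlength=n_weeks)
        return counts[:n_weeks] * dt


@dataclass(frozen=True)
class HibernationTruth:
    bouts: tuple[TruthBout, ...]
    ibe_durations: tuple[float, ...]        # gaps between consecutive bouts, min


@dataclass(frozen=True)
class GrowthTruth:
    mass_slope: float
    mass_plateau: float
    mass_breakpoint: float
    length_slope: float
    length_plateau: float
    length_breakpoint: float


@dataclass(frozen=True)
class RespirometryTruth:
    vo2_true: np.ndarray                    # ml O2/h at each sample
    vo2_day: float
    vo2_night: float


@dataclass(frozen=True)
class DLWTruth:
    pool_g: float
    k_o: float
    k_d: float


def _daily_mask(cfg: ScenarioConfig, episodes, n_min: int, dt: float) -> np.ndarray:
    """Boolean per-sample mask for a daily (start minute-of-day, duration) schedule."""
    t = np.arange(n_min) * dt
    mask = np.zeros(n_min, dtype=bool)
    for day in range(cfg.n_days):
        for start, dur in episodes:
            a = day * MIN_PER_DAY + start
            b = a + dur
            mask |= (t >= a) & (t < b)
    return mask


def simulate_ambient(cfg: ScenarioConfig, rng: np.random.Generator) -> TemperatureTrace:
    """Ambient trace on the 30-min grid: daily sinusoid plus AR(1) noise."""
    step = cfg.sampling_interval_ambient
    times = np.arange(0.0, cfg.total_minutes + step, step)
    # warmest point mid-afternoon (15:00)
    phase = 2 * np.pi * (times / MIN_PER_DAY - 15 * 60 / MIN_PER_DAY)
    base = cfg.ambient_mean + cfg.ambient_amplitude * np.cos(phase)
    ar = np.zeros_like(times)
    innov = rng.normal(0.0, cfg.ambient_ar_sd, size=times.size)
    for i in range(1, times.size):
        ar[i] = cfg.ambient_ar_phi * ar[i - 1] + innov[i]
    return TemperatureTrace(times, base + ar, source="ambient", sampling_interval=step)


def simulate_prehibernation_trace(
    cfg: ScenarioConfig,
) -> tuple[TemperatureTrace, TemperatureTrace, PrehibernationTruth]:
    """Nest + ambient traces with exact labels and torpor-bout list.

    Raises ``ValueError`` if any programmed activity episode overlaps a
    programmed torpor episode.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.sampling_interval_nest
    n_min = int(round(cfg.total_minutes / dt))
    t = np.arange(n_min) * dt

    ambient = simulate_ambient(cfg, rng)
    amb_fine = align_ambient(ambient, t).values

    outside = _daily_mask(cfg, cfg.activity_episodes, n_min, dt)
    torpid = np.zeros(n_min, dtype=bool)
    depth = np.zeros(n_min)
    bouts = []
    for day, onset, dur, dep in cfg.torpor_schedule:
        a = day * MIN_PER_DAY + onset
        b = a + dur
        sel = (t >= a) & (t < b)
        torpid |= sel
        depth[sel] = dep
        bouts.append(TruthBout(onset=a, offset=b, depth=dep))
    if np.any(outside & torpid):
        raise ValueError("activity and torpor episodes overlap")

    labels = np.full(n_min, IN_NEST_EUTHERMIC, dtype=np.int8)
    labels[outside] = OUTSIDE
    labels[torpid] = IN_NEST_TORPID

    euthermic_level = amb_fine + cfg.nest_elevation
    target = euthermic_level.copy()
    target[outside] = amb_fine[outside]
    target[torpid] = euthermic_level[torpid] - depth[torpid]

    temp = np.empty(n_min)
    temp[0] = target[0]
    decay_exit = np.exp(-dt / cfg.tau_exit)
    decay_torpor = np.exp(-dt / cfg.tau_torpor)
    decay_rewarm = np.exp(-dt / cfg.tau_rewarm)
    for i in range(1, n_min):
        tgt = target[i]
        prev = temp[i - 1]
        if prev > tgt:
            decay = decay_torpor if labels[i] == IN_NEST_TORPID else decay_exit
        else:
            decay = decay_rewarm
        temp[i] = tgt + (prev - tgt) * decay
    temp = temp + rng.normal(0.0, cfg.noise_sd, size=n_min)

    # absolute activity episodes for reference
    episodes = []
    for day in range(cfg.n_days):
        for start, dur in cfg.activity_episodes:
            a = day * MIN_PER_DAY + start
            episodes.append((a, a + dur))
    truth = PrehibernationTruth(
        labels=labels,
        torpor_bouts=tuple(sorted(bouts, key=lambda b: b.onset)),
        activity_episodes=tuple(sorted(episodes)),
    )
    nest = TemperatureTrace(t, temp, source="nest", sampling_interval=dt)
    return nest, ambient, truth


def simulate_hibernation_trace(
    cfg: ScenarioConfig,
) -> tuple[TemperatureTrace, HibernationTruth]:
    """Implanted body-temperature trace over winter, quantized to 0.5 °C.

    Multiday torpor bouts sit near ambient (cold-room regime) separated by
    brief euthermic arousals.  Bouts must be disjoint; an arousal cannot be
    longer than the gap that hosts it, so overlapping bouts are rejected.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    bouts = sorted(cfg.hibernation_bouts)
    for (s0, d0), (s1, _) in zip(bouts, bouts[1:]):
        if s0 + d0 >= s1:
            raise ValueError(
                "hibernation bouts overlap: arousal does not fit in its inter-bout gap"
            )
    dt = cfg.sampling_interval_nest
    if bouts:
        total = bouts[-1][0] + bouts[-1][1] + 720.0
    else:
        total = cfg.total_minutes
    n_min = int(round(total / dt))
    t = np.arange(n_min) * dt

    torpid = np.zeros(n_min, dtype=bool)
    for start, dur in bouts:
        torpid |= (t >= start) & (t < start + dur)
    target = np.where(torpid, cfg.hibernation_ta + cfg.torpid_tb_offset, cfg.euthermic_tb)

    temp = np.empty(n_min)
    temp[0] = target[0]
    decay_entry = np.exp(-dt / cfg.tau_hib_entry)
    decay_arousal = np.exp(-dt / cfg.tau_hib_arousal)
    for i in range(1, n_min):
        tgt = target[i]
        prev = temp[i - 1]
        decay = decay_entry if prev > tgt else decay_arousal
        temp[i] = tgt + (prev - tgt) * decay
    temp = temp + rng.normal(0.0, cfg.tb_noise_sd, size=n_min)
    temp = np.round(temp / cfg.tb_resolution) * cfg.tb_resolution

    truth_bouts = tuple(TruthBout(onset=s, offset=s + d) for s, d in bouts)
    ibes = tuple(b1.onset - b0.offset for b0, b1 in zip(truth_bouts, truth_bouts[1:]))
    body = TemperatureTrace(t, temp, source="body", sampling_interval=dt)
    return body, HibernationTruth(bouts=truth_bouts, ibe_durations=ibes)


def _two_phase(t: np.ndarray, intercept: float, slope: float, bp: float) -> np.ndarray:
    return intercept + slope * np.minimum(t, bp)


def simulate_growth_series(cfg: ScenarioConfig):
    """Weekly (t, body_mass, body_length) table plus generating parameters.

    Both responses follow a rise-then-plateau two-phase line with Gaussian
    measurement noise.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed + 2)
    weeks = np.arange(cfg.n_weeks + 1, dtype=float)
    mi, ms, mb, msd = cfg.growth_params
    li, ls, lb, lsd = cfg.length_params
    mass = _two_phase(weeks, mi, ms, mb) + rng.normal(0.0, msd, size=weeks.size)
    length = _two_phase(weeks, li, ls, lb) + rng.normal(0.0, lsd, size=weeks.size)
    table = pd.DataFrame({"week": weeks, "body_mass": mass, "body_length": length})
    truth = GrowthTruth(
        mass_slope=ms, mass_plateau=mi + ms * mb, mass_breakpoint=mb,
        length_slope=ls, length_plateau=li + ls * lb, length_breakpoint=lb,
    )
    return table, truth


def simulate_respirometry(cfg: ScenarioConfig):
    """Open-flow respirometry record with a programmed day/night VO2 profile.

    The excurrent O2 fraction is derived by inverting the open-flow VO2
    equation, so the downstream calculator recovers the programmed profile
    exactly in the noiseless case.  The first habituation day runs at an
    elevated VO2 to make the exclusion rule consequential.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed + 3)
    n = int(round(cfg.respiro_hours * 60 / cfg.respiro_interval))
    t = np.arange(n) * cfg.respiro_interval
    minute_of_day = t % MIN_PER_DAY
    night_start, night_end = cfg.night_window
    night = (minute_of_day >= night_start) | (minute_of_day < night_end)

    vo2_day = cfg.respiro_vo2_day
    vo2_night = vo2_day * cfg.respiro_night_day_ratio
    vo2 = np.where(night, vo2_night, vo2_day).astype(float)
    vo2[t < cfg.respiro_habituation_hours * 60] *= cfg.respiro_habituation_factor

    rq = cfg.respiro_rq
    fio2 = cfg.respiro_fio2
    # invert VO2 = FD*(FiO2-FeO2)/(1-FiO2*(1-RQ)), VO2 in l/h here
    feo2 = fio2 - (vo2 / 1000.0) * (1 - fio2 * (1 - rq)) / cfg.respiro_flow
    feo2 = feo2 + rng.normal(0.0, cfg.respiro_feo2_noise, size=n)

    table = pd.DataFrame({
        "time_min": t,
        "fd_lh": np.full(n, cfg.respiro_flow),
        "fio2": np.full(n, fio2),
        "feo2": feo2,
    })
    truth = RespirometryTruth(vo2_true=vo2, vo2_day=vo2_day, vo2_night=vo2_night)
    return table, truth


def simulate_dlw_samples(cfg: ScenarioConfig):
    """Two-isotope washout sampled at the configured times.

    Initial excess enrichments follow from diluting the dose into the
    isotope-specific dilution space (pool × space factor); post-dose
    enrichments decay exponentially at k_d (2H) and k_o (18O).  Multiplicative
    noise at ``dlw_noise_frac`` is applied to the excess enrichments.
    """
    from .energetics import (DILUTION_SPACE_FACTOR_D, DILUTION_SPACE_FACTOR_O,
                             DLWSampleSet)

    rng = np.random.default_rng(cfg.seed + 4)
    times = np.asarray(cfg.dlw_sample_times, dtype=float)
    bg_d, bg_o = cfg.dlw_background
    enr_d, enr_o = cfg.dlw_dose_enrichment
    n_d = cfg.dlw_pool_g * DILUTION_SPACE_FACTOR_D
    n_o = cfg.dlw_pool_g * DILUTION_SPACE_FACTOR_O
    e0_d = cfg.dlw_dose_g * (enr_d - bg_d) / n_d
    e0_o = cfg.dlw_dose_g * (enr_o - bg_o) / n_o
    # washout runs from the equilibration (plateau) sample at times[0]
    ex_d = e0_d * np.exp(-cfg.dlw_k_d * (times - times[0]))
    ex_o = e0_o * np.exp(-cfg.dlw_k_o * (times - times[0]))
    if cfg.dlw_noise_frac > 0:
        ex_d = ex_d * (1 + rng.normal(0.0, cfg.dlw_noise_frac, size=times.size))
        ex_o = ex_o * (1 + rng.normal(0.0, cfg.dlw_noise_frac, size=times.size))
    samples = DLWSampleSet(
        dose_mass=cfg.dlw_dose_g,
        dose_enrichment_d=enr_d,
        dose_enrichment_o=enr_o,
        background_d=bg_d,
        background_o=bg_o,
        sample_times=times,
        enrichment_d=bg_d + ex_d,
        enrichment_o=bg_o + ex_o,
        body_mass=cfg.dlw_body_mass_g,
    )
    return samples, DLWTruth(pool_g=cfg.dlw_pool_g, k_o=cfg.dlw_k_o, k_d=cfg.dlw_k_d)


def simulate_food_intake(cfg: ScenarioConfig):
    """Weekly fresh-mass food consumption (g): rise to a peak then decline."""
    import pandas as pd

    rng = np.random.default_rng(cfg.seed + 5)
    weeks = np.arange(1, cfg.n_weeks + 1, dtype=float)
    shape = np.exp(-0.5 * ((weeks - cfg.food_peak_week) / max(cfg.n_weeks / 3, 1.0)) ** 2)
    grams = cfg.food_base_g + (cfg.food_peak_g - cfg.food_base_g) * shape
    grams = grams + rng.normal(0.0, cfg.food_noise_g, size=weeks.size)
    return pd.DataFrame({"week": weeks, "food_g": np.clip(grams, 0.0, None)})
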