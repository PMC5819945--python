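"""Activity classification, torpor-bout detection and hibernation metrics.

Pre-hibernation nest traces are classified into in-nest versus outside
samples from the difference D = T_nest − T_a: a 100-sample moving average
smooths D, the mean of the smoothed series acts as the threshold (values at
or above the mean are resting in the nest, values below are activity outside
the nest), and a ±0.5 °C refinement pass catches short nest returns during
the night and short nest exits during the day.  Torpor bouts are detected
inside in-nest episodes from slow, deep declines of T_nest: a nest-exit
cools the vacated nest quickly, a torpor entry cools it over hours, and that
rate contrast separates the two events.

Winter body-temperature traces are reduced to hibernation-pattern metrics:
a sample is torpid when T_b is below the euthermy threshold, bouts lasting
at least 24 h mark hibernation, and inter-bout euthermy (IBE) episodes are
the arousals between consecutive hibernation bouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trace import TemperatureTrace

IN_NEST = 0
OUTSIDE = 1
LABEL_NAMES = {IN_NEST: "in_nest", OUTSIDE: "outside"}

MIN_PER_WEEK = 7 * 1440.0


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable constants of the trace classifiers.

    ``ma_window`` (samples) and ``refine_delta`` (°C) are the smoothing
    window and secondary threshold standard in nest-temperature activity
    scoring; the torpor-specific parameters replace a manual bout-scoring
    step with an auditable rate + depth + recovery criterion.
    """

    ma_window: int = 100
    refine_delta: float = 0.5
    torpor_entry_rate_max: float = 0.15     # °C/min; slower declines are torpor-like
    torpor_depth_delta: float = 2.0         # °C below the episode euthermic baseline
    torpor_min_duration: float = 60.0       # min
    hibernation_bout_threshold: float = 24.0  # h
    euthermy_threshold_body: float = 30.0   # °C, for body traces
    refine_ma_window: int = 15              # light smoothing for the refinement pass
    rate_window: int = 10                   # samples used for local rate estimates
    ref_window: int = 120                   # samples of trailing min/max reference
    baseline_quantile: float = 0.9          # euthermic baseline within an episode
    onset_anchor_delta: float = 1.0         # °C below pre-bout level anchoring onsets
    backwalk_limit: int = 240               # max samples of onset back-walk

    def __post_init__(self) -> None:
        if self.ma_window < 2:
            raise ValueError("ma_window must be >= 2")
        for name in ("refine_delta", "torpor_entry_rate_max", "torpor_depth_delta",
                     "torpor_min_duration", "hibernation_bout_threshold",
                     "euthermy_threshold_body"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.refine_ma_window < 1 or self.rate_window < 1:
            raise ValueError("windows must be >= 1 sample")


@dataclass(frozen=True)
class ActivitySegmentation:
    """Per-sample in-nest/outside labels plus the episode list."""

    timestamps: np.ndarray
    labels: np.ndarray                      # IN_NEST / OUTSIDE per sample
    episodes: tuple[tuple[int, float, float], ...]  # (label, start, end) minutes
    sampling_interval: float
    threshold: float                        # smoothed-difference threshold used

    @property
    def activity_time(self) -> float:
        """Total time outside the nest, minutes."""
        return float((self.labels == OUTSIDE).sum() * self.sampling_interval)

    def activity_by_week(self, n_weeks: int | None = None) -> np.ndarray:
        idx = (self.timestamps // MIN_PER_WEEK).astype(int)
        if n_weeks is None:
            n_weeks = int(idx.max()) + 1
        counts = np.bincount(idx[self.labels == OUTSIDE], minlength=n_weeks)
        return counts[:n_weeks] * self.sampling_interval


@dataclass(frozen=True)
class TorporBout:
    onset: float
    offset: float
    min_temp: float
    kind: str = "daily"                     # "daily" or "hibernation"

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("bout offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class WeeklyTorporSummary:
    week_index: int
    torpor_frequency: int
    total_torpor_duration: float            # min
    mean_torpor_duration: float             # min
    activity_time: float                    # min; NaN when nest data missing


@dataclass(frozen=True)
class HibernationPattern:
    detected: bool
    onset_time: float = float("nan")        # min
    end_time: float = float("nan")
    hibernation_duration: float = float("nan")  # weeks
    arousal_frequency: int = 0
    mean_ibe_duration: float = float("nan")     # h
    mean_torpor_bout_duration: float = float("nan")  # h
    min_tb: float = float("nan")            # °C
    euthermy_threshold: float = float("nan")


def centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with symmetric truncation at the edges.

    Sample i averages indices i − ⌊w/2⌋ … i + (w − 1 − ⌊w/2⌋), clipped to the
    array; a centered window avoids the phase lag that a trailing window
    would add to every onset estimate.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    csum = np.concatenate(([0.0], np.cumsum(x)))
    h1 = window // 2
    h2 = window - 1 - h1
    lo = np.clip(np.arange(n) - h1, 0, None)
    hi = np.clip(np.arange(n) + h2, None, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)


def _runs(labels: np.ndarray):
    """Yield (value, start_index, end_index) maximal runs; end exclusive."""
    n = labels.size
    i = 0
    while i < n:
        j = i + 1
        while j < n and labels[j] == labels[i]:
            j += 1
        yield labels[i], i, j
        i = j


def _fall_rate(lite: np.ndarray, k: int, window: int, dt: float) -> float:
    """Cooling rate (°C/min) over the ``window`` samples before index k."""
    k0 = max(0, k - window)
    if k == k0:
        return float("inf")
    return (lite[k0] - lite[k]) / ((k - k0) * dt)


def _trailing_extrema(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Trailing-window running min and max (monotonic-deque sliding window)."""
    from collections import deque

    n = x.size
    mins = np.empty(n)
    maxs = np.empty(n)
    dq_min: deque[int] = deque()
    dq_max: deque[int] = deque()
    for i in range(n):
        while dq_min and x[dq_min[-1]] >= x[i]:
            dq_min.pop()
        dq_min.append(i)
        while dq_max and x[dq_max[-1]] <= x[i]:
            dq_max.pop()
        dq_max.append(i)
        lo = i - window + 1
        if dq_min[0] < lo:
            dq_min.popleft()
        if dq_max[0] < lo:
            dq_max.popleft()
        mins[i] = x[dq_min[0]]
        maxs[i] = x[dq_max[0]]
    return mins, maxs


def _refine_labels(base: np.ndarray, lite: np.ndarray, p: ClassifierParams,
                   dt: float) -> np.ndarray:
    """±refine_delta refinement over the threshold labels.

    A forward state machine tracks the lightly smoothed difference against
    trailing-window extrema.  While in-nest, a fall of more than refine_delta
    below the recent maximum — or a threshold crossing into an outside run —
    marks a nest exit only if the decline is faster than the torpor-entry
    rate limit; slower declines are torpor entries and the samples stay
    in-nest for bout detection, even where deep torpor pulls the smoothed
    difference below the global threshold.  While outside, a threshold
    crossing back above the mean marks a return, as does a rise of more than
    refine_delta above the recent minimum when the warming is faster than the
    same rate limit (a vacated nest drifts with ambient; only an occupied
    nest rewarms quickly).
    """
    roll_min, roll_max = _trailing_extrema(lite, p.ref_window)
    out = np.empty_like(base)
    state = base[0]
    for i in range(base.size):
        boundary = i > 0 and base[i] != base[i - 1]
        if state == IN_NEST:
            fall = roll_max[i] - lite[i]
            if fall > p.refine_delta or (boundary and base[i] == OUTSIDE):
                if _fall_rate(lite, i, p.rate_window, dt) > p.torpor_entry_rate_max:
                    state = OUTSIDE
        else:
            rise = lite[i] - roll_min[i]
            if boundary and base[i] == IN_NEST:
                state = IN_NEST
            elif (rise > p.refine_delta
                  and -_fall_rate(lite, i, p.rate_window, dt)
                  > p.torpor_entry_rate_max):
                state = IN_NEST
        out[i] = state
    return out


def _episodes_from_labels(timestamps: np.ndarray, labels: np.ndarray,
                          dt: float) -> tuple[tuple[int, float, float], ...]:
    eps = []
    for val, i, j in _runs(labels):
        end = timestamps[j - 1] + dt if j == timestamps.size else timestamps[j]
        eps.append((int(val), float(timestamps[i]), float(end)))
    return tuple(eps)


def classify_activity(nest: TemperatureTrace, ambient_aligned: TemperatureTrace,
                      p: ClassifierParams | None = None) -> ActivitySegmentation:
    """Classify every nest-trace sample as in-nest or outside.

    ``ambient_aligned`` must share the nest grid (see
    :func:`hiberphys.trace.align_ambient`).  A constant difference series is
    degenerate: the tie rule (smoothed value ≥ threshold ⇒ in-nest) puts every
    sample in the nest and a warning is emitted.
    """
    p = p or ClassifierParams()
    if nest.n < p.ma_window:
        raise ValueError(
            f"trace has {nest.n} samples, fewer than ma_window={p.ma_window}")
    if nest.n != ambient_aligned.n or not np.array_equal(
            nest.timestamps, ambient_aligned.timestamps):
        raise ValueError("nest and ambient traces must share one time grid")

    dt = nest.sampling_interval
    diff = nest.values - ambient_aligned.values
    smooth = centered_moving_average(diff, p.ma_window)
    threshold = float(smooth.mean())
    if np.ptp(smooth) == 0.0:
        warnings.warn("constant difference series: tie rule labels all samples in-nest",
                      stacklevel=2)
    base = np.where(smooth >= threshold, IN_NEST, OUTSIDE).astype(np.int8)
    lite = centered_moving_average(diff, p.refine_ma_window)
    labels = _refine_labels(base, lite, p, dt)
    episodes = _episodes_from_labels(nest.timestamps, labels, dt)
    return ActivitySegmentation(
        timestamps=nest.timestamps, labels=labels, episodes=episodes,
        sampling_interval=dt, threshold=threshold,
    )


def detect_torpor_bouts(nest: TemperatureTrace, ambient_aligned: TemperatureTrace,
                        seg: ActivitySegmentation,
                        p: ClassifierParams | None = None) -> list[TorporBout]:
    """Detect torpor bouts inside in-nest episodes of a nest trace.

    Within each in-nest episode the lightly smoothed, ambient-corrected
    temperature D = T_nest − T_a is compared with the episode's euthermic
    baseline (upper quantile); working on D removes the daily ambient swing,
    which would otherwise dwarf the torpor dip.  A bout opens where the
    trace has declined more than ``torpor_depth_delta`` below baseline *and*
    the descent through the refine_delta band was slower than
    ``torpor_entry_rate_max`` (fast descents are nest exits).  The onset is
    then back-extrapolated along the entry tangent to the baseline crossing.
    The bout closes when the trace recovers to within ``torpor_depth_delta``
    of baseline.  Bouts shorter than ``torpor_min_duration`` are discarded;
    returned bouts are disjoint and sorted.
    """
    p = p or ClassifierParams()
    if seg.timestamps.size != nest.n:
        raise ValueError("segmentation was not computed on this trace")
    if ambient_aligned.n != nest.n:
        raise ValueError("ambient trace must share the nest grid")
    dt = nest.sampling_interval
    lite = centered_moving_average(nest.values - ambient_aligned.values,
                                   p.refine_ma_window)
    t = nest.timestamps
    bouts: list[TorporBout] = []

    for label, start, end in seg.episodes:
        if label != IN_NEST:
            continue
        i0 = int(np.searchsorted(t, start, side="left"))
        i1 = int(np.searchsorted(t, end, side="left"))
        if i1 - i0 < max(p.refine_ma_window, 4):
            continue
        vals = lite[i0:i1]
        baseline = float(np.quantile(vals, p.baseline_quantile))
        below = vals < baseline - p.torpor_depth_delta
        prev_offset_idx = 0
        for flag, r0, r1 in _runs(below.astype(np.int8)):
            if not flag:
                continue
            # local euthermic level just before the descent; the episode-wide
            # baseline is biased by ambient-lag asymmetry over the day
            floor = max(prev_offset_idx, r0 - p.backwalk_limit)
            pre_level = (float(np.quantile(vals[floor:r0], 0.75))
                         if r0 > floor else baseline)
            anchor = min(pre_level, baseline) - p.onset_anchor_delta
            # walk back (bounded) to the last sample at or above the anchor
            j = r0
            while j > floor and vals[j] < anchor:
                j -= 1
            if r0 > j:
                entry_rate = (vals[j] - vals[r0]) / ((r0 - j) * dt)
            else:
                entry_rate = float("inf")
            if entry_rate > p.torpor_entry_rate_max:
                continue  # fast decline: a nest exit, not a torpor entry
            # tangent extrapolation from the anchor crossing up to the
            # pre-bout level locates the start of the cooling transient
            k1 = min(j + p.rate_window, r1 - 1)
            local_rate = (vals[j] - vals[k1]) / ((k1 - j) * dt) if k1 > j else 0.0
            onset = t[i0 + j]
            if local_rate > 0:
                onset = max(onset - p.onset_anchor_delta / local_rate,
                            t[i0 + prev_offset_idx], float(start))
            # the bout closes at recovery to within depth_delta of baseline;
            # the physiological offset — the start of the terminal rewarming —
            # is located by extrapolating the rewarming tangent back to the
            # bout-bottom level
            if r1 < vals.size:
                closure = float(t[i0 + r1])
                offset = closure
                rw0 = max(r0, r1 - p.rate_window)
                rise_rate = ((vals[r1] - vals[rw0]) / ((r1 - rw0) * dt)
                             if r1 > rw0 else 0.0)
                tail = vals[max(r0, r1 - 4 * p.rate_window):r1]
                bottom_level = float(np.quantile(tail, 0.25))
                if rise_rate > 0:
                    offset = max(offset - (vals[r1] - bottom_level) / rise_rate,
                                 onset + dt)
            else:
                closure = offset = float(end)
            # the minimum-duration screen rejects noise excursions; it acts on
            # the full excursion (onset to recovery crossing) so a genuine
            # bout exactly at the limit is not lost to boundary estimation
            if closure - onset < p.torpor_min_duration:
                continue
            duration = offset - onset
            a = int(np.searchsorted(t, onset, side="left"))
            b = i0 + r1
            min_temp = float(np.min(nest.values[a:b])) if b > a else float(nest.values[a])
            kind = ("hibernation"
                    if duration >= p.hibernation_bout_threshold * 60.0 else "daily")
            bouts.append(TorporBout(onset=float(onset), offset=float(offset),
                                    min_temp=min_temp, kind=kind))
            prev_offset_idx = r1
    bouts.sort(key=lambda b: b.onset)
    return bouts


def weekly_summaries(bouts: list[TorporBout], seg: ActivitySegmentation,
                     n_weeks: int | None = None) -> list[WeeklyTorporSummary]:
    """Weekly torpor frequency, total/mean torpor duration and activity time.

    Weeks are consecutive 7-day blocks from the trace start; a bout belongs to
    the week containing its onset and contributes its full duration there,
    even when it straddles the boundary.
    """
    activity = seg.activity_by_week(n_weeks)
    n_weeks = activity.size
    freq = np.zeros(n_weeks, dtype=int)
    total = np.zeros(n_weeks)
    t0 = float(seg.timestamps[0])
    for bout in bouts:
        w = int((bout.onset - t0) // MIN_PER_WEEK)
        if 0 <= w < n_weeks:
            freq[w] += 1
            total[w] += bout.duration
    out = []
    for w in range(n_weeks):
        mean = total[w] / freq[w] if freq[w] else 0.0
        out.append(WeeklyTorporSummary(
            week_index=w, torpor_frequency=int(freq[w]),
            total_torpor_duration=float(total[w]), mean_torpor_duration=float(mean),
            activity_time=float(activity[w]),
        ))
    return out


def merge_respirometry_torpor(
    weekly: list[WeeklyTorporSummary],
    respiro_torpor_flags: dict[int, bool],
) -> list[WeeklyTorporSummary]:
    """Fill weeks lacking nest data from respirometry torpor detections.

    During respirometry weeks the nest logger yields no usable record; a
    substantial metabolic-rate reduction still reveals whether torpor was
    used.  For such a week a ``True`` flag records presence (frequency 1,
    durations unknown), a ``False`` flag records absence; activity time is
    missing (NaN) either way.  Weeks already covered by nest data pass through
    unchanged.
    """
    present = {w.week_index for w in weekly}
    merged = list(weekly)
    for week, flag in sorted(respiro_torpor_flags.items()):
        if week in present:
            continue
        if flag:
            merged.append(WeeklyTorporSummary(
                week_index=week, torpor_frequency=1,
                total_torpor_duration=float("nan"),
                mean_torpor_duration=float("nan"), activity_time=float("nan")))
        else:
            merged.append(WeeklyTorporSummary(
                week_index=week, torpor_frequency=0, total_torpor_duration=0.0,
                mean_torpor_duration=0.0, activity_time=float("nan")))
    merged.sort(key=lambda w: w.week_index)
    return merged


def hibernation_metrics(body: TemperatureTrace,
                        p: ClassifierParams | None = None) -> HibernationPattern:
    """Hibernation-pattern metrics from a winter body-temperature trace.

    A sample is torpid iff T_b < ``euthermy_threshold_body``.  Maximal torpid
    runs are bouts; hibernation starts at the onset of the first bout lasting
    at least ``hibernation_bout_threshold`` hours (closed boundary) and ends
    at the offset of the last such bout.  Arousals are the euthermic intervals
    strictly between consecutive hibernation bouts — the terminal rewarming
    ends hibernation and is not counted.  A trace with no qualifying bout
    yields ``detected=False`` rather than an error.
    """
    p = p or ClassifierParams()
    dt = body.sampling_interval
    t = body.timestamps
    torpid = (body.values < p.euthermy_threshold_body).astype(np.int8)
    bouts = []
    for flag, i, j in _runs(torpid):
        if not flag:
            continue
        onset = float(t[i])
        offset = float(t[j]) if j < t.size else float(t[-1] + dt)
        bouts.append((onset, offset))
    thresh_min = p.hibernation_bout_threshold * 60.0
    hib = [(a, b) for a, b in bouts if b - a >= thresh_min]
    if not hib:
        return HibernationPattern(detected=False,
                                  euthermy_threshold=p.euthermy_threshold_body)
    onset = hib[0][0]
    end = hib[-1][1]
    # euthermic time within each inter-bout gap
    ibes = []
    for (a0, b0), (a1, b1) in zip(hib, hib[1:]):
        sel = (t >= b0) & (t < a1) & (torpid == 0)
        ibes.append(float(sel.sum() * dt))
    sel_torpid = (t >= onset) & (t < end) & (torpid == 1)
    min_tb = float(np.min(body.values[sel_torpid]))
    durations = [b - a for a, b in hib]
    return HibernationPattern(
        detected=True, onset_time=onset, end_time=end,
        hibernation_duration=(end - onset) / MIN_PER_WEEK,
        arousal_frequency=len(ibes),
        mean_ibe_duration=float(np.mean(ibes) / 60.0) if ibes else float("nan"),
        mean_torpor_bout_duration=float(np.mean(durations) / 60.0),
        min_tb=min_tb, euthermy_threshold=p.euthermy_threshold_body,
    )
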