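"""Two-segment (broken-stick) trajectory fits and measurement QC.

Weekly time courses of body length, body mass, torpor parameters and
activity time in juvenile hibernators are well described by two joined
linear segments: a rise (or flat phase) followed by a plateau (or a phase of
change).  The breakpoint is estimated by profiling: an exhaustive grid of
candidate breakpoints (observation times plus midpoints), conditional
ordinary least squares at each candidate, and the residual-sum-of-squares
minimizer wins, ties going to the earliest candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

RISE_THEN_PLATEAU = "rise_then_plateau"
FLAT_THEN_CHANGE = "flat_then_change"


@dataclass(frozen=True)
class TrajectorySeries:
    """One animal's weekly response series."""

    t: np.ndarray                 # weeks, strictly increasing
    y: np.ndarray                 # g, cm, min or bouts/week
    response_kind: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t and y must be 1-d arrays of equal length")
        if t.size < 4:
            raise ValueError("segmented fits need at least 4 observations")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")


@dataclass(frozen=True)
class SegmentedFit:
    """Slope / plateau / breakpoint summary of a two-phase trajectory.

    ``rise_then_plateau``: y = a + b·t for t ≤ τ, then constant at the
    plateau a + b·τ (continuity imposed).  ``flat_then_change``: y = c for
    t ≤ τ, then c + b·(t − τ).  ``breakpoint`` is the time of plateau
    (growth-type responses) or the starting time (torpor/activity-type
    responses).
    """

    mode: str
    slope: float
    intercept: float
    breakpoint: float
    plateau: float                # rise_then_plateau only; NaN otherwise
    rss: float
    slope_se: float
    n: int

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.mode == RISE_THEN_PLATEAU:
            return self.intercept + self.slope * np.minimum(t, self.breakpoint)
        return self.intercept + self.slope * np.maximum(t - self.breakpoint, 0.0)


def qc_body_length(measurements, precision: float = 0.05) -> tuple[float, bool]:
    """Outlier rule for triplicate body-length measurements (cm).

    When two of the three readings agree (within reading ``precision``) and
    the third differs from them by 0.5 cm or more, the third is excluded and
    the two concordant readings are averaged; otherwise all three are
    averaged.  Returns ``(mean_length, excluded)``.
    """
    vals = np.asarray(measurements, dtype=float)
    if vals.shape != (3,) or not np.all(np.isfinite(vals)):
        raise ValueError("exactly three finite measurements required")
    pairs = ((0, 1, 2), (0, 2, 1), (1, 2, 0))
    for i, j, k in pairs:
        if abs(vals[i] - vals[j]) <= precision:
            agreed = 0.5 * (vals[i] + vals[j])
            if abs(vals[k] - agreed) >= 0.5:
                return float(agreed), True
    return float(vals.mean()), False


def breakpoint_grid(t: np.ndarray, min_left: int = 2) -> np.ndarray:
    """Candidate breakpoints: observation times plus midpoints.

    A candidate must leave at least ``min_left`` observations at or before
    it; the last observation time is always a candidate, which embeds the
    single-line model in the search (the second segment is then empty).
    """
    t = np.asarray(t, dtype=float)
    mids = 0.5 * (t[:-1] + t[1:])
    cand = np.unique(np.concatenate([t, mids]))
    keep = [tau for tau in cand
            if np.count_nonzero(t <= tau) >= min_left and tau <= t[-1]]
    return np.asarray(keep)


def _design(t: np.ndarray, tau: float, mode: str) -> np.ndarray:
    if mode == RISE_THEN_PLATEAU:
        return np.column_stack([np.ones_like(t), np.minimum(t, tau)])
    if mode == FLAT_THEN_CHANGE:
        return np.column_stack([np.ones_like(t), np.maximum(t - tau, 0.0)])
    raise ValueError(f"unknown mode {mode!r}")


def _conditional_ols(t: np.ndarray, y: np.ndarray, tau: float, mode: str):
    """OLS of the two-parameter model at a fixed breakpoint; returns
    (intercept, slope, rss, slope_se)."""
    X = _design(t, tau, mode)
    if np.ptp(X[:, 1]) == 0.0:
        # second column constant (e.g. flat_then_change with tau at t_max):
        # only the level is identified
        c = float(y.mean())
        rss = float(np.sum((y - c) ** 2))
        return c, 0.0, rss, float("nan")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    n = y.size
    dof = n - 2
    se = float("nan")
    if dof > 0:
        sigma2 = rss / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    return float(beta[0]), float(beta[1]), rss, se


def fit_segmented(series: TrajectorySeries, mode: str = RISE_THEN_PLATEAU,
                  grid: np.ndarray | None = None) -> SegmentedFit:
    """Profile-RSS two-segment linear fit.

    The breakpoint τ is chosen by exhaustive search over ``grid`` (defaults
    to :func:`breakpoint_grid`), with conditional OLS for the linear
    parameters at each candidate; ties in RSS go to the smallest τ.  The
    slope standard error is conditional on the selected τ (breakpoint
    uncertainty is not propagated).  A degenerate series (all y equal)
    returns slope 0 at the first candidate with a warning.
    """
    t, y = series.t, series.y
    if grid is None:
        grid = breakpoint_grid(t)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty breakpoint grid")

    if np.ptp(y) == 0.0:
        warnings.warn("degenerate series: all responses equal", stacklevel=2)
        tau = float(grid[0])
        level = float(y[0])
        plateau = level if mode == RISE_THEN_PLATEAU else float("nan")
        return SegmentedFit(mode=mode, slope=0.0, intercept=level,
                            breakpoint=tau, plateau=plateau, rss=0.0,
                            slope_se=0.0, n=t.size)

    best = None
    for tau in grid:
        a, b, rss, se = _conditional_ols(t, y, float(tau), mode)
        if best is None or rss < best[0] - 1e-12 * max(1.0, abs(best[0])):
            best = (rss, float(tau), a, b, se)
    rss, tau, a, b, se = best
    plateau = a + b * tau if mode == RISE_THEN_PLATEAU else float("nan")
    return SegmentedFit(mode=mode, slope=b, intercept=a, breakpoint=tau,
                        plateau=plateau, rss=rss, slope_se=se, n=t.size)


def compare_groups(fits: dict[str, list[SegmentedFit]],
                   n_boot: int = 2000, seed: int = 0):
    """Group means, pairwise differences and bootstrap CIs for fit parameters.

    ``fits`` maps a group label (e.g. diet × birth-timing cell) to the fitted
    trajectories of its animals.  Differences are reported for every ordered
    pair of groups with 95% percentile bootstrap CIs over animals; a group
    with a single animal yields NaN CIs and is flagged.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    params = ("slope", "plateau", "breakpoint")
    rows = []
    values = {
        g: {p: np.asarray([getattr(f, p) for f in fs], dtype=float)
            for p in params}
        for g, fs in fits.items()
    }
    for g, by_param in values.items():
        for p in params:
            v = by_param[p]
            rows.append({"group": g, "contrast": "", "parameter": p,
                         "estimate": float(np.nanmean(v)), "ci_low": float("nan"),
                         "ci_high": float("nan"), "n": v.size,
                         "flag": "single_animal" if v.size < 2 else ""})
    groups = list(fits)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            for p in params:
                va, vb = values[ga][p], values[gb][p]
                diff = float(np.nanmean(va) - np.nanmean(vb))
                if va.size > 1 and vb.size > 1:
                    boots = np.empty(n_boot)
                    for k in range(n_boot):
                        boots[k] = (np.nanmean(rng.choice(va, va.size))
                                    - np.nanmean(rng.choice(vb, vb.size)))
                    lo, hi = np.percentile(boots, [2.5, 97.5])
                    flag = ""
                else:
                    lo = hi = float("nan")
                    flag = "single_animal"
                rows.append({"group": ga, "contrast": gb, "parameter": p,
                             "estimate": diff, "ci_low": float(lo),
                             "ci_high": float(hi),
                             "n": min(va.size, vb.size), "flag": flag})
    return pd.DataFrame(rows)
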