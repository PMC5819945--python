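"""Naive per-sample reference implementation of the activity classifier.

Written independently of the package internals: window means are computed by
explicit summation per sample, the trailing extrema by per-sample window
scans, and the in-nest/outside state machine as a plain transcription of the
documented rules.  Used as the oracle the production classifier must match
exactly.
"""

import numpy as np

IN_NEST = 0
OUTSIDE = 1


def naive_moving_average(x, window):
    n = len(x)
    h_before = window // 2
    h_after = window - 1 - h_before
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - h_before)
        hi = min(n - 1, i + h_after)
        s = 0.0
        for j in range(lo, hi + 1):
            s += x[j]
        out[i] = s / (hi - lo + 1)
    return out


def naive_classify(nest_values, ambient_values, params, dt):
    """Per-sample labels for a nest trace, following the stated rules:

    1. smooth D = T_nest - T_a with a centered moving average; the mean of
       the smoothed series is the threshold; >= threshold means in-nest;
    2. forward state machine: while in-nest, a fall of more than
       refine_delta below the trailing-window maximum of the lightly
       smoothed D (or a threshold crossing to outside) marks an exit only if
       the recent cooling rate exceeds the torpor-entry limit; while
       outside, a threshold crossing back, or a sufficiently fast rise of
       more than refine_delta above the trailing-window minimum, marks a
       return.
    """
    p = params
    n = len(nest_values)
    d = np.empty(n)
    for i in range(n):
        d[i] = nest_values[i] - ambient_values[i]
    smooth = naive_moving_average(d, p.ma_window)
    total = 0.0
    for i in range(n):
        total += smooth[i]
    threshold = total / n
    base = np.empty(n, dtype=np.int8)
    for i in range(n):
        base[i] = IN_NEST if smooth[i] >= threshold else OUTSIDE
    lite = naive_moving_average(d, p.refine_ma_window)

    labels = np.empty(n, dtype=np.int8)
    state = base[0]
    for i in range(n):
        lo = max(0, i - p.ref_window + 1)
        window_min = lite[lo]
        window_max = lite[lo]
        for j in range(lo + 1, i + 1):
            if lite[j] < window_min:
                window_min = lite[j]
            if lite[j] > window_max:
                window_max = lite[j]
        boundary = i > 0 and base[i] != base[i - 1]
        k0 = max(0, i - p.rate_window)
        if i == k0:
            fall_rate = float("inf")
        else:
            fall_rate = (lite[k0] - lite[i]) / ((i - k0) * dt)
        if state == IN_NEST:
            wants_exit = (window_max - lite[i] > p.refine_delta
                          or (boundary and base[i] == OUTSIDE))
            if wants_exit and fall_rate > p.torpor_entry_rate_max:
                state = OUTSIDE
        else:
            if boundary and base[i] == IN_NEST:
                state = IN_NEST
            elif (lite[i] - window_min > p.refine_delta
                  and -fall_rate > p.torpor_entry_rate_max):
                state = IN_NEST
        labels[i] = state
    return labels
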