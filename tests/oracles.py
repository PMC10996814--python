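"""Independent brute-force oracles for the survival metrics.

These are deliberately written as naive per-term / per-pair enumerations,
sharing no code with the package implementation.
"""

import numpy as np


def km_censoring_oracle(durations, events, t):
    """G(t) by direct product over censoring times <= t (right-continuous)."""
    durations = np.asarray(durations, float)
    events = np.asarray(events, int)
    g = 1.0
    for tc in sorted(set(durations[events == 0])):
        if tc <= t:
            at_risk = np.sum(durations >= tc)
            d = np.sum((durations == tc) & (events == 0))
            g *= 1.0 - d / at_risk
    return g


def km_left_oracle(durations, events, t):
    """Left limit G(t-)."""
    durations = np.asarray(durations, float)
    events = np.asarray(events, int)
    g = 1.0
    for tc in sorted(set(durations[events == 0])):
        if tc < t:
            at_risk = np.sum(durations >= tc)
            d = np.sum((durations == tc) & (events == 0))
            g *= 1.0 - d / at_risk
    return g


def step_survival_oracle(edges, survival_row, t):
    """S(t) for one patient: value of the (left-open, right-closed] bin."""
    if t <= edges[0]:
        return 1.0
    for j in range(len(edges) - 1):
        if edges[j] < t <= edges[j + 1]:
            return survival_row[j]
    return survival_row[-1]


def brier_oracle(edges, survival, durations, events, eval_times, floor=1e-4):
    """Term-by-term IPCW Brier enumeration."""
    n = len(durations)
    out = []
    for t in eval_times:
        total = 0.0
        for i in range(n):
            s = step_survival_oracle(edges, survival[i], t)
            if durations[i] <= t and events[i] == 1:
                g = max(km_left_oracle(durations, events, durations[i]), floor)
                total += s**2 / g
            elif durations[i] > t:
                g = max(km_censoring_oracle(durations, events, t), floor)
                total += (1 - s) ** 2 / g
        out.append(total / n)
    return np.array(out)


def nbll_oracle(edges, survival, durations, events, eval_times, floor=1e-4, clip=1e-7):
    """Term-by-term IPCW negative binomial log-likelihood enumeration."""
    n = len(durations)
    out = []
    for t in eval_times:
        total = 0.0
        for i in range(n):
            s = min(max(step_survival_oracle(edges, survival[i], t), clip), 1 - clip)
            if durations[i] <= t and events[i] == 1:
                g = max(km_left_oracle(durations, events, durations[i]), floor)
                total -= np.log(1 - s) / g
            elif durations[i] > t:
                g = max(km_censoring_oracle(durations, events, t), floor)
                total -= np.log(s) / g
        out.append(total / n)
    return np.array(out)


def concordance_oracle(edges, survival, durations, events):
    """Exhaustive all-pairs event-time concordance."""
    n = len(durations)
    num = 0.0
    pairs = 0
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if durations[j] <= durations[i]:
                continue
            si = round(step_survival_oracle(edges, survival[i], durations[i]), 12)
            sj = round(step_survival_oracle(edges, survival[j], durations[i]), 12)
            if si < sj:
                num += 1.0
            elif si == sj:
                num += 0.5
            pairs += 1
    if pairs == 0:
        raise ValueError("no comparable pairs")
    return num / pairs


def random_instance(rng, n=8, n_bins=5, horizon=100.0):
    """A random small survival-prediction instance for oracle comparisons."""
    edges = np.linspace(0.0, horizon, n_bins + 1)
    hazards = rng.uniform(0.02, 0.6, size=(n, n_bins))
    survival = np.cumprod(1 - hazards, axis=1)
    durations = rng.uniform(1.0, horizon, size=n)
    events = rng.integers(0, 2, size=n)
    return edges, hazards, survival, durations, events
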