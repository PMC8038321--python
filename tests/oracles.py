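"""Independent brute-force reference implementations used only by tests.

Each oracle is a direct transcription of the defining formula or parsing
rule, with no shared code or algorithmic structure with the package
implementations it checks.
"""

from __future__ import annotations

import numpy as np


def sampen_brute(x: np.ndarray, m: int = 2, r_factor: float = 0.15) -> float:
    """O(N^2) sample entropy: explicit pair loops over template matrices."""
    x = np.asarray(x, dtype=float)
    r = r_factor * np.std(x)
    nt = x.size - m
    tm = np.array([x[i : i + m] for i in range(nt)])
    tm1 = np.array([x[i : i + m + 1] for i in range(nt)])
    a = b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            if np.max(np.abs(tm[i] - tm[j])) <= r:
                b += 1
            if np.max(np.abs(tm1[i] - tm1[j])) <= r:
                a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def fuzzyen_brute(
    x: np.ndarray, m: int = 2, r_factor: float = 0.15, grad: float = 2.0
) -> float:
    """O(N^2) fuzzy entropy with np.exp memberships over all template pairs."""
    x = np.asarray(x, dtype=float)
    r = r_factor * np.std(x)
    nt = x.size - m
    phis = []
    for w in (m, m + 1):
        t = np.array([x[i : i + w] for i in range(nt)])
        c = t - t.mean(axis=1, keepdims=True)
        total = 0.0
        for i in range(nt - 1):
            for j in range(i + 1, nt):
                d = np.max(np.abs(c[i] - c[j]))
                total += np.exp(-((d / r) ** grad))
        phis.append(total / (nt * (nt - 1) / 2))
    return -np.log(phis[1] / phis[0])


def lz76_parse(symbols) -> int:
    """LZ76 phrase count by explicit exhaustive parsing.

    Each phrase is the shortest prefix of the remaining sequence that is
    not reproducible as a substring of the previously seen text (copy with
    self-overlap allowed); the final phrase may be reproducible if the
    sequence ends first.
    """
    s = "".join(str(int(v)) for v in symbols)
    n = len(s)
    c = 0
    pos = 0
    while pos < n:
        k = 1
        while pos + k <= n and s.find(s[pos : pos + k], 0, pos + k - 1) != -1:
            k += 1
        c += 1
        pos += k
    return c


def auc_rank_sum(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic divided by n+ * n-."""
    from scipy.stats import mannwhitneyu

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (pos.size * neg.size))


def wilcoxon_enumerate(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    from itertools import product

    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_values = []
    for signs in product([0, 1], repeat=n):
        w_values.append(sum(r for s, r in zip(signs, ranks) if s))
    w_values = np.asarray(w_values)
    p_le = np.mean(w_values <= w_plus + 1e-12)
    p_ge = np.mean(w_values >= w_plus - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def windows_by_interval_arithmetic(
    duration_s: float,
    valid_intervals: list[tuple[float, float]],
    win_s: float,
    step_s: float,
    fs: float,
) -> int:
    """Count admissible windows by direct interval containment checks."""
    count = 0
    n = int(round(duration_s * fs))
    n_win = int(round(win_s * fs))
    step = int(round(step_s * fs))
    pos = 0
    while pos + n_win <= n:
        t0 = pos / fs
        t1 = (pos + n_win - 1) / fs
        inside = any(a <= t0 and t1 < b for a, b in valid_intervals)
        # a window is admissible iff every sample time lies in one interval;
        # intervals are disjoint so containment of the span in one suffices
        if inside:
            count += 1
        pos += step
    return count
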