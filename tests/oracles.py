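"""Independent brute-force oracles used to cross-check the implementations.

Each function here is written from the rule definitions directly —
exhaustive pair search, union-find, grid scan, all-pairs concordance —
and deliberately shares no code with the package.
"""

import numpy as np


def brute_suspicion(antibiotics, cultures):
    """Exhaustive search over all antibiotic/culture pairs."""
    best = None
    for a in antibiotics:
        for c in cultures:
            if (a <= c <= a + 24) or (c <= a <= c + 72):
                t = min(a, c)
                best = t if best is None else min(best, t)
    return best


def brute_sofa_rise(times, scores):
    """Scan records in time order; earliest ≥2-point rise over the prior 24 h."""
    order = np.argsort(times, kind="stable")
    times, scores = np.asarray(times)[order], np.asarray(scores)[order]
    for i in range(len(times)):
        prior = [s for t, s in zip(times, scores)
                 if times[i] - 24 <= t < times[i]]
        if prior and scores[i] - min(prior) >= 2:
            return float(times[i])
    return None


def brute_union(intervals, gap):
    """Union-find over the pairwise 'gap ≤ tolerance' relation."""
    iv = list(intervals)
    parent = list(range(len(iv)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(iv)):
        for j in range(i + 1, len(iv)):
            (s1, e1), (s2, e2) = iv[i], iv[j]
            if max(s1 - e2, s2 - e1) <= gap:
                parent[find(i)] = find(j)
    comps = {}
    for i, (s, e) in enumerate(iv):
        r = find(i)
        cs, ce = comps.get(r, (s, e))
        comps[r] = (min(cs, s), max(ce, e))
    return sorted(comps.values())


def grid_scan_label(enroll, death, episodes, step=0.1):
    """Independent trajectory labeling by scanning a 0.1-h time lattice.

    Label 1 when support is active at hour 48, or when any liberation
    observed inside the window is followed by renewed support within 24 h;
    label 2 otherwise; label 0 on death within the window.
    """
    w_end = enroll + 48.0
    if death is not None and death <= w_end:
        return 0
    grid = np.round(np.arange(enroll, w_end + 24.0 + step, step), 6)
    active = np.zeros(len(grid), dtype=bool)
    for ep in episodes:
        active |= (grid >= ep.start_ts) & (grid < ep.end_ts)
    # liberation = active -> inactive transition at a grid point in the window
    offs = [grid[i] for i in range(1, len(grid))
            if active[i - 1] and not active[i]
            and enroll < grid[i] <= w_end]
    for t_lib in offs:
        after = (grid > t_lib + step / 2) & (grid <= t_lib + 24.0 + step / 2)
        if active[after].any():
            return 1
    if active[np.isclose(grid, w_end)][0]:
        return 1
    return 2


def brute_auroc(scores, labels):
    """All-pairs concordance count with half credit for ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = s[y == 1], s[y == 0]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            conc += 1.0 if p > q else (0.5 if p == q else 0.0)
    return conc / total


def brute_f05_cutoff(scores, labels):
    """Best threshold over the unique-score grid via sklearn's F-beta."""
    from sklearn.metrics import fbeta_score
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    grid = np.unique(s)
    f = np.array([fbeta_score(y, s >= t, beta=0.5, zero_division=0)
                  for t in grid])
    return float(grid[f >= f.max() - 1e-12].max())
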