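"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use the slowest, most literal formulation of each
computation (exhaustive enumeration, O(n^2) pair counting, grid search) and
share no code with the package internals they check.
"""
from __future__ import annotations

import itertools

import numpy as np


def brute_isomir(seq, mirna_refs, max_mm=2, min_prefix=15):
    """Exhaustive 5'-anchored alignment over all references and all shared
    lengths.  Returns (name, deletion, addition, mismatches) or None."""
    candidates = []
    for name, ref in mirna_refs.items():
        for L in range(min_prefix, min(len(seq), len(ref)) + 1):
            mm = sum(1 for a, b in zip(seq[:L], ref[:L]) if a != b)
            if mm <= max_mm:
                candidates.append((mm, -L, name, (name, ref[L:], seq[L:], mm)))
    if not candidates:
        return None
    # keep only each reference's own best, then take the global best
    per_ref = {}
    for mm, negL, name, call in sorted(candidates):
        per_ref.setdefault(name, (mm, negL, name, call))
    return sorted(per_ref.values())[0][3]


def brute_tsrna(seq, trna_refs, max_mm=2):
    """Exhaustive ungapped scan over all references and all offsets.
    Returns (name, start_1based, mismatches) or None."""
    best = None
    for name in sorted(trna_refs):
        ref = trna_refs[name][0]
        for s in range(len(ref) - len(seq) + 1):
            mm = sum(1 for a, b in zip(seq, ref[s : s + len(seq)]) if a != b)
            if mm <= max_mm:
                key = (mm, s + 1, name)
                if best is None or key < best:
                    best = key
    if best is None:
        return None
    mm, start, name = best
    return (name, start, mm)


def auc_pair_counting(scores, labels):
    """AUC as the fraction of case/control pairs ordered correctly, ties
    counting one half — the O(n^2) definition."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def mann_whitney_exact_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments
    (tie-free small samples only)."""
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "tie-free only"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)

    def u_stat(group_ranks):
        r = sum(group_ranks)
        return r - n1 * (n1 + 1) / 2

    observed = u_stat([ranks[v] for v in x])
    mu = n1 * len(y) / 2
    all_ranks = list(ranks.values())
    count = total = 0
    for combo in itertools.combinations(all_ranks, n1):
        total += 1
        if abs(u_stat(combo) - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return count / total


def cox_single_binary_grid(times, events, group, lo=-5.0, hi=5.0, n_grid=20001):
    """Maximize the Efron partial likelihood for one binary covariate by
    dense grid search; returns the maximizing log hazard ratio."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=float)

    def log_pl(beta):
        ll = 0.0
        for t in np.unique(times[events == 1]):
            died = (times == t) & (events == 1)
            at_risk = times >= t
            d = died.sum()
            s_died = group[died].sum()
            risk_sum = np.exp(beta * group[at_risk]).sum()
            died_sum = np.exp(beta * group[died]).sum()
            ll += beta * s_died
            for j in range(d):
                ll -= np.log(risk_sum - j / d * died_sum)
        return ll

    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([log_pl(b) for b in grid])
    return float(grid[np.argmax(vals)])


def km_product_limit(times, events):
    """Hand-rolled product-limit estimator: list of (time, survival)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    out = []
    for t in np.unique(times[events == 1]):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1 - d / at_risk
        out.append((float(t), s))
    return out
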