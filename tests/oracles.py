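"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive — exhaustive enumeration, textbook
formulas, plain dynamic programming — and shares no code with the paths it
verifies.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def milp_activity_optimum(net, states, epsilon: float) -> float:
    """Brute-force optimum of the *integer* activity model.

    Enumerates every binary assignment of the activity indicators (y⁺, y⁻
    for each highly expressed reaction, y⁺ for each lowly expressed one) and
    checks LP feasibility of the flux constraints that assignment implies:
    y⁺ = 1 forces v ≥ ε (R_H) or v = 0 (R_L), y⁻ = 1 forces v ≤ −ε.
    Returns the maximal total number of satisfied indicators; -inf if even
    the all-zero assignment is infeasible.
    """
    order = {rid: j for j, rid in enumerate(net.reaction_ids)}
    rh = sorted(states.R_H, key=order.__getitem__)
    rl = sorted(states.R_L, key=order.__getitem__)
    n = len(net.reactions)
    lb = net.lower_bounds().astype(float)
    ub = net.upper_bounds().astype(float)
    best = -np.inf
    n_bits = 2 * len(rh) + len(rl)
    for bits in itertools.product((0, 1), repeat=n_bits):
        yp_h = bits[: len(rh)]
        ym_h = bits[len(rh) : 2 * len(rh)]
        yp_l = bits[2 * len(rh) :]
        lo, hi = lb.copy(), ub.copy()
        ok = True
        for rid, yp, ym in zip(rh, yp_h, ym_h):
            j = order[rid]
            if yp:
                lo[j] = max(lo[j], epsilon)
            if ym:
                hi[j] = min(hi[j], -epsilon)
            if lo[j] > hi[j]:
                ok = False
        for rid, yp in zip(rl, yp_l):
            j = order[rid]
            if yp:
                lo[j] = max(lo[j], 0.0)
                hi[j] = min(hi[j], 0.0)
            if lo[j] > hi[j]:
                ok = False
        if not ok:
            continue
        res = linprog(
            np.zeros(n),
            A_eq=net.S,
            b_eq=np.zeros(net.S.shape[0]),
            bounds=list(zip(lo, hi)),
            method="highs",
        )
        if res.status == 0:
            best = max(best, float(sum(bits)))
    return best


def brute_force_kernel_knn(
    train_labels: dict[str, np.ndarray],
    sims: dict[str, float],
    k: int,
) -> np.ndarray:
    """Weighted-vote score for one query: explicit sort, explicit sums.

    ``train_labels`` maps training reaction id -> per-drug 0/1 label vector;
    ``sims`` maps training reaction id -> similarity to the query.
    """
    ranked = sorted(sims, key=lambda rid: (-sims[rid], rid))[: min(k, len(sims))]
    denom = sum(sims[r] for r in ranked)
    n_drugs = len(next(iter(train_labels.values())))
    if denom <= 0:
        return np.zeros(n_drugs)
    out = np.zeros(n_drugs)
    for r in ranked:
        out += sims[r] * np.asarray(train_labels[r], dtype=float)
    return out / denom


def pair_count_auc(scores, labels) -> float:
    """AUC by exhaustive positive-negative pair counting (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def smith_waterman_dp(s: str, t: str, match: float, mismatch: float, gap: float) -> float:
    """Textbook local-alignment DP with a linear gap penalty (gap ≥ 0)."""
    n, m = len(s), len(t)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if s[i - 1] == t[j - 1] else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub, H[i - 1, j] - gap, H[i, j - 1] - gap)
    return float(H.max())


def two_sample_t_pvalue(a, b) -> float:
    """Equal-variance two-sample t-test from the textbook formulas."""
    from scipy.stats import t as tdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    tstat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return float(2 * tdist.sf(abs(tstat), na + nb - 2))
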