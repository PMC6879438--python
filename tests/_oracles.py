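"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity along a different algorithmic path from
the package (explicit pair enumeration, literal formula transcription,
hypergeometric bookkeeping, grid search) so that agreement is evidence of
correctness rather than repetition.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_counts_bruteforce(levels: np.ndarray, mask: np.ndarray, direction,
                           n_bins: int, distance: int = 1) -> np.ndarray:
    """All-ordered-pairs co-occurrence count for one direction (symmetrized).

    Enumerates every ordered pair of in-mask voxels and keeps those whose
    coordinate difference equals ``distance * direction``; the symmetrized
    matrix additionally counts the reversed pairs.
    """
    coords = np.argwhere(mask)
    lv = levels[mask]
    d = np.asarray(direction) * distance
    # pairwise coordinate differences, vectorized over all m^2 pairs
    diff = coords[None, :, :] - coords[:, None, :]
    hits = np.all(diff == d, axis=2)
    a_idx, b_idx = np.nonzero(hits)
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    for a, b in zip(a_idx, b_idx):
        counts[lv[a] - 1, lv[b] - 1] += 1
    return counts + counts.T, len(a_idx)


def texture_features_literal(p: np.ndarray, log_base: float = 2.0) -> dict:
    """The 16 co-occurrence features transcribed term by term with loops."""
    G = p.shape[0]

    def log(v):
        return math.log(v) / math.log(log_base)

    px = [sum(p[i][j] for j in range(G)) for i in range(G)]
    py = [sum(p[i][j] for i in range(G)) for j in range(G)]
    mu_x = sum((i + 1) * px[i] for i in range(G))
    mu_y = sum((j + 1) * py[j] for j in range(G))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(G)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(G)))

    p_sum = {k: 0.0 for k in range(2, 2 * G + 1)}
    p_diff = {k: 0.0 for k in range(0, G)}
    for i in range(G):
        for j in range(G):
            p_sum[i + j + 2] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    entropy = -sum(p[i][j] * log(p[i][j]) for i in range(G) for j in range(G)
                   if p[i][j] > 0)
    homogeneity = sum(p[i][j] / (1 + abs(i - j)) for i in range(G) for j in range(G))
    contrast = sum((i - j) ** 2 * p[i][j] for i in range(G) for j in range(G))
    if sig_x > 0 and sig_y > 0:
        correlation = (
            sum((i + 1) * (j + 1) * p[i][j] for i in range(G) for j in range(G))
            - mu_x * mu_y
        ) / (sig_x * sig_y)
    else:
        correlation = 1.0
    asm = sum(p[i][j] ** 2 for i in range(G) for j in range(G))
    diff_ent = -sum(v * log(v) for v in p_diff.values() if v > 0)
    da = sum(k * v for k, v in p_diff.items())
    diff_var = sum((k - da) ** 2 * v for k, v in p_diff.items())
    idm = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G))
    sa = sum(k * v for k, v in p_sum.items())
    se = -sum(v * log(v) for v in p_sum.values() if v > 0)
    sv = sum((k - sa) ** 2 * v for k, v in p_sum.items())
    cp = sum((i + 1 + j + 1 - mu_x - mu_y) ** 4 * p[i][j]
             for i in range(G) for j in range(G))
    cs = sum((i + 1 + j + 1 - mu_x - mu_y) ** 3 * p[i][j]
             for i in range(G) for j in range(G))
    maxp = max(p[i][j] for i in range(G) for j in range(G))
    hx = -sum(v * log(v) for v in px if v > 0)
    hy = -sum(v * log(v) for v in py if v > 0)
    hxy1 = -sum(p[i][j] * log(px[i] * py[j]) for i in range(G) for j in range(G)
                if p[i][j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * log(px[i] * py[j]) for i in range(G)
                for j in range(G) if px[i] * py[j] > 0)
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(1.0 - math.exp(-2.0 * (hxy2 - entropy)), 0.0))
    return {
        "entropy": entropy, "homogeneity": homogeneity, "contrast": contrast,
        "correlation": correlation, "angular_second_moment": asm,
        "difference_entropy": diff_ent, "difference_variance": diff_var,
        "inverse_difference_moment": idm, "sum_average": sa,
        "sum_entropy": se, "sum_variance": sv, "cluster_prominence": cp,
        "cluster_shade": cs, "maximum_probability": maxp,
        "imc1": imc1, "imc2": imc2,
    }


def auc_paircount(values, labels) -> float:
    """AUC as concordant pairs plus half ties over all case/control pairs."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = values[labels]
    neg = values[~labels]
    conc = tied = 0
    for a in pos:
        for b in neg:
            if a > b:
                conc += 1
            elif a == b:
                tied += 1
    return (conc + 0.5 * tied) / (len(pos) * len(neg))


def logrank_oracle(times, events, groups) -> float:
    """Two-group log-rank chi-square via explicit hypergeometric moments."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert labels.size == 2
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def kendall_tau_b_oracle(x, y) -> float:
    """Tau-b from explicit concordant/discordant/tie pair counts."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = tie_x = tie_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tie_x += 1
                tie_y += 1
            elif dx == 0:
                tie_x += 1
            elif dy == 0:
                tie_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / math.sqrt((n0 - tie_x) * (n0 - tie_y))


def logistic_loglik(params, x, y) -> float:
    b0, b1 = params
    lp = b0 + b1 * x
    return float(np.sum(y * lp - np.log1p(np.exp(lp))))


def logistic_gridsearch(x, y, span=6.0, coarse=41, refinements=6):
    """Coarse-to-fine grid maximization of the univariate logistic likelihood."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c0, c1 = 0.0, 0.0
    width = span
    for _ in range(refinements):
        g0 = np.linspace(c0 - width, c0 + width, coarse)
        g1 = np.linspace(c1 - width, c1 + width, coarse)
        best = (-np.inf, c0, c1)
        for b0 in g0:
            lp0 = b0 + np.outer(g1, x)
            ll = (y * lp0 - np.logaddexp(0, lp0)).sum(axis=1)
            k = int(np.argmax(ll))
            if ll[k] > best[0]:
                best = (float(ll[k]), float(b0), float(g1[k]))
        _, c0, c1 = best
        width /= 8.0
    return c0, c1
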