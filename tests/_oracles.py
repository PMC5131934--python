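"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the ordinal oracle
compares each window against every explicitly generated permutation, the
AUC oracle counts pairs, and the EER oracle scans a dense threshold grid.
"""

import itertools
import math

import numpy as np


def naive_ordinal_distribution(series, dimension, lag):
    """Histogram of ordinal patterns by comparing each window to all D!
    permutations (lexicographic order), ties broken by temporal index."""
    perms = list(itertools.permutations(range(dimension)))  # lexicographic
    counts = np.zeros(len(perms))
    n = len(series)
    n_windows = n - (dimension - 1) * lag
    for start in range(n_windows):
        w = [series[start + i * lag] for i in range(dimension)]
        for idx, p in enumerate(perms):
            ok = True
            for a, b in zip(p, p[1:]):
                if not (w[a] < w[b] or (w[a] == w[b] and a < b)):
                    ok = False
                    break
            if ok:
                counts[idx] += 1
                break
    return counts / n_windows


def naive_entropy(p, normalized=True):
    s = -sum(pi * math.log(pi) for pi in p if pi > 0)
    return s / math.log(len(p)) if normalized else s


def naive_complexity(p):
    """Direct transcription of the MPR complexity formulas."""
    n = len(p)
    pe = [1.0 / n] * n
    mid = [(a + b) / 2 for a, b in zip(p, pe)]
    jsd = naive_entropy(mid, False) - 0.5 * naive_entropy(p, False) - 0.5 * naive_entropy(pe, False)
    jmax = -0.5 * (((n + 1) / n) * math.log(n + 1) - 2 * math.log(2 * n) + math.log(n))
    return (jsd / jmax) * naive_entropy(p, True)


def naive_fisher(p):
    total = sum(
        (math.sqrt(b) - math.sqrt(a)) ** 2 for a, b in zip(p, p[1:])
    )
    f0 = 1.0 if (p[0] == 1.0 or p[-1] == 1.0) else 0.5
    return f0 * total


def pair_count_auc(scores_pos, scores_neg):
    """AUC by exhaustive pair counting, ties worth 1/2."""
    wins = 0.0
    for sp in scores_pos:
        for sn in scores_neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(scores_pos) * len(scores_neg))


def grid_search_eer(scores_pos, scores_neg, step=1e-4):
    """EER from a dense threshold grid: at the threshold minimizing
    |FAR - FRR|, report (FAR + FRR) / 2."""
    pos = np.sort(np.asarray(scores_pos, dtype=float))
    neg = np.sort(np.asarray(scores_neg, dtype=float))
    lo = min(pos[0], neg[0]) - step
    hi = max(pos[-1], neg[-1]) + step
    thresholds = np.arange(lo, hi + step, step)
    far = 1.0 - np.searchsorted(neg, thresholds, side="left") / len(neg)
    frr = np.searchsorted(pos, thresholds, side="left") / len(pos)
    best = np.argmin(np.abs(far - frr))
    return (far[best] + frr[best]) / 2.0
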