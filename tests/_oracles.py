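"""Independent oracles used by the tests.

Deliberately naive: enumeration and all-pairs counting, no shared code with
the package's own likelihood or AUC paths.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np


def polya_urn_log_pmf(s, alpha) -> float:
    """DM probability of the count vector ``s`` by brute-force Polya-urn
    path enumeration: sum over all distinct read orderings of the product of
    sequential draw probabilities (alpha_t + prior same-taxon draws) /
    (A + draws so far)."""
    s = [int(x) for x in s]
    alpha = [float(a) for a in alpha]
    a_total = sum(alpha)
    reads = [t for t, c in enumerate(s) for _ in range(c)]
    total = 0.0
    for path in set(permutations(reads)):
        drawn = [0] * len(alpha)
        prob = 1.0
        for i, t in enumerate(path):
            prob *= (alpha[t] + drawn[t]) / (a_total + i)
            drawn[t] += 1
        total += prob
    return math.log(total)


def count_vectors(n_taxa: int, total: int):
    """All non-negative integer vectors of the given length summing to total."""
    if n_taxa == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in count_vectors(n_taxa - 1, total - first):
            yield (first, *rest)


def brute_force_auc(scores, labels) -> float:
    """All-pairs concordance count: ties contribute 0.5 per pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)


def dm_loglik_direct(counts, pi, theta) -> float:
    """Log-likelihood of a count matrix, written out independently from
    log-gamma identities (used to grid-check the fitted optimum)."""
    from scipy.special import gammaln

    counts = np.asarray(counts, dtype=float)
    alpha = np.asarray(pi, dtype=float) * (1.0 - theta) / theta
    a = alpha.sum()
    n = counts.sum(axis=1)
    ll = 0.0
    for i in range(counts.shape[0]):
        ll += gammaln(n[i] + 1) - gammaln(counts[i] + 1).sum()
        ll += gammaln(a) - gammaln(a + n[i])
        ll += (gammaln(alpha + counts[i]) - gammaln(alpha)).sum()
    return float(ll)


def grid_confirms_optimum(counts, fitted_pi, fitted_theta, true_pi=None, n_theta: int = 40) -> bool:
    """True when no point of a (pi, theta) grid beats the fitted likelihood.

    The grid spans theta log-uniformly and tries several composition
    candidates (fitted, pooled-moment, true if given, and local coordinate
    perturbations of the fitted pi).
    """
    counts = np.asarray(counts)
    pooled = counts.sum(axis=0) / counts.sum()
    candidates = [np.asarray(fitted_pi, float), pooled]
    if true_pi is not None:
        candidates.append(np.asarray(true_pi, float))
    for j in range(len(fitted_pi)):
        for eps in (-0.01, 0.01):
            p = np.array(fitted_pi, float)
            if not (0 < p[j] + eps < 1):
                continue
            p[j] += eps
            candidates.append(p / p.sum())
    best = dm_loglik_direct(counts, fitted_pi, fitted_theta)
    thetas = np.concatenate([np.geomspace(1e-6, 0.5, n_theta), [fitted_theta]])
    for pi in candidates:
        pi = np.clip(pi, 1e-12, None)
        pi = pi / pi.sum()
        for th in thetas:
            if dm_loglik_direct(counts, pi, th) > best + 1e-6:
                return False
    return True
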