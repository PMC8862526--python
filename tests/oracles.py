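"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, explicit
loops, closed-form pedigree recursions) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import poisson


def enumerate_paths_logprob(counts: np.ndarray, pi0, A, lam) -> tuple[np.ndarray, np.ndarray]:
    """Log joint probability of every possible state path (K^T rows)."""
    counts = np.asarray(counts)
    K, T = len(pi0), len(counts)
    paths = np.array(list(itertools.product(range(K), repeat=T)), dtype=np.int64)
    with np.errstate(divide="ignore"):
        lp = np.log(pi0)[paths[:, 0]]
        for t in range(1, T):
            lp = lp + np.log(A)[paths[:, t - 1], paths[:, t]]
    emis = poisson.logpmf(counts[None, :], np.asarray(lam)[paths])
    return paths, lp + emis.sum(axis=1)


def best_path_exhaustive(counts, pi0, A, lam) -> tuple[np.ndarray, float, float]:
    """Argmax path over all K^T paths (lexicographically first on exact ties),
    its log probability, and the margin to the second-best distinct value."""
    paths, lp = enumerate_paths_logprob(counts, pi0, A, lam)
    best = int(np.argmax(lp))
    srt = np.sort(lp)
    margin = float(srt[-1] - srt[-2]) if len(lp) > 1 else np.inf
    return paths[best], float(lp[best]), margin


def posterior_exhaustive(counts, pi0, A, lam) -> np.ndarray:
    """State posteriors by direct summation over all paths: (T, K)."""
    paths, lp = enumerate_paths_logprob(counts, pi0, A, lam)
    w = np.exp(lp - lp.max())
    w /= w.sum()
    T, K = len(counts), len(pi0)
    post = np.zeros((T, K))
    for p, wi in zip(paths, w):
        for t in range(T):
            post[t, p[t]] += wi
    return post


def window_tally(positions, values, window_size, chrom_length) -> np.ndarray:
    """Loop-based per-window sum of ``values`` at 1-based ``positions``."""
    n_windows = -(-chrom_length // window_size)
    out = np.zeros(n_windows, dtype=float)
    for pos, v in zip(positions, values):
        out[(pos - 1) // window_size] += v
    return out


def ibs_pair_loop(geno_a, geno_b) -> float:
    """Mean per-site IBS over co-non-missing sites, explicit loop."""
    total, n = 0.0, 0
    for a, b in zip(geno_a, geno_b):
        if a < 0 or b < 0:
            continue
        total += (2 - abs(int(a) - int(b))) / 2
        n += 1
    return total / n if n else float("nan")


def autozygous_fraction_per_bp(individual, spec) -> float:
    """Autozygous fraction via an explicit per-basepair ancestry scan."""
    auto = total = 0
    for ch in spec.chromosomes:
        m = np.empty(ch.length, dtype=np.int64)
        p = np.empty(ch.length, dtype=np.int64)
        for s, e, h in individual.haps[ch.name][0]:
            m[s:e] = h
        for s, e, h in individual.haps[ch.name][1]:
            p[s:e] = h
        auto += int((m == p).sum())
        total += ch.length
    return auto / total


def sib_kinship_recursion(generations: int, outcross_gen: int | None = None,
                          donor_f: float | None = None) -> float:
    """Expected inbreeding coefficient of the final full-sib brood.

    Tracks (F_t, phi_t) = (inbreeding of brood t, kinship between the two
    brood-t sibs): F_{t+1} = phi_t, phi_{t+1} = (1 + F_t)/4 + phi_t/2.
    An outcross at generation g replaces the father with an unrelated
    individual of inbreeding ``donor_f``: the brood-g inbreeding becomes 0
    and the sib kinship restarts at (2 + F_{g-1} + donor_f)/8.
    """
    F, phi = 0.0, 0.25  # founder children: outbred, kinship 1/4
    for g in range(1, generations + 1):
        if outcross_gen is not None and g == outcross_gen:
            mother_f = F  # the brood-(g-1) sister
            F_new = 0.0
            phi = (2 + mother_f + (donor_f or 0.0)) / 8
            F = F_new
            continue
        F, phi = phi, (1 + F) / 4 + phi / 2
    return F


def rank_auc(scores_pos, scores_neg) -> float:
    """Mann-Whitney AUC of positive vs negative scores."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    wins = 0.0
    for s in pos:
        wins += (s > neg).sum() + 0.5 * (s == neg).sum()
    return wins / (len(pos) * len(neg))
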