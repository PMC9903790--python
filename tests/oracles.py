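"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the package's own recursions: posterior decoding
and Viterbi are computed by exhaustive enumeration over all state paths,
the hypergeometric tail by exact combinatorial sums, and association
tables by direct per-cell tabulation.
"""

import itertools
import math

import numpy as np
from scipy.stats import dirichlet_multinomial


def dm_logpmf_oracle(alpha, x):
    """Dirichlet-multinomial log pmf via scipy's closed form."""
    n = int(np.sum(x))
    return float(dirichlet_multinomial.logpmf(np.asarray(x), np.asarray(alpha), n))


def enumerate_hmm(log_emission, transition, initial):
    """Exhaustive posterior/Viterbi over all S^T paths.

    Returns (posteriors (T, S), loglik, viterbi path) where the Viterbi
    path is the lexicographically smallest maximum-probability path.
    """
    T, S = log_emission.shape
    post = np.zeros((T, S))
    total = -np.inf
    best_lp = -np.inf
    best_path = None
    for path in itertools.product(range(S), repeat=T):
        lp = math.log(initial[path[0]]) if initial[path[0]] > 0 else -math.inf
        lp += log_emission[0, path[0]]
        for t in range(1, T):
            a = transition[path[t - 1], path[t]]
            lp += (math.log(a) if a > 0 else -math.inf) + log_emission[t, path[t]]
        if lp == -math.inf:
            continue
        total = np.logaddexp(total, lp)
        if lp > best_lp:
            best_lp = lp
            best_path = path
        for t, s in enumerate(path):
            post[t, s] += math.exp(lp)
    post /= post.sum(axis=1, keepdims=True)
    return post, float(total), np.asarray(best_path)


def hypergeom_upper_tail_oracle(k, n, N, M):
    """P(X >= k) for X ~ Hypergeom(M, n, N) by exact combinatorial sums."""
    denom = math.comb(M, N)
    num = 0
    for j in range(k, min(n, N) + 1):
        if N - j <= M - n:
            num += math.comb(n, j) * math.comb(M - n, N - j)
    return num / denom


def cell_state_tabulation_oracle(state_call, counts_dense):
    """a_ij by direct per-cell loops: fraction of accessible bins per state."""
    n_bins, n_cells = counts_dense.shape
    S = int(state_call.max()) + 1
    a = np.full((S, n_cells), np.nan)
    for j in range(n_cells):
        acc = [i for i in range(n_bins) if counts_dense[i, j] > 0]
        if not acc:
            continue
        for s in range(S):
            a[s, j] = sum(1 for i in acc if state_call[i] == s) / len(acc)
    return a


def state_cluster_tabulation_oracle(state_call, counts_dense):
    """(Pcs, Pb) by direct loops over bins and clusters."""
    n_bins, n_clusters = counts_dense.shape
    S = int(state_call.max()) + 1
    reads = np.zeros((S, n_clusters))
    for i in range(n_bins):
        reads[state_call[i]] += counts_dense[i]
    Pb = reads.sum(axis=0) / reads.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        Pcs = reads / reads.sum(axis=1, keepdims=True)
    return Pcs, Pb


def random_hmm_instance(rng, max_states=4, max_bins=8, max_tracks=5):
    """Random small DM-HMM instance plus a count matrix for enumeration tests."""
    S = int(rng.integers(1, max_states + 1))
    T = int(rng.integers(2, max_bins + 1))
    C = int(rng.integers(1, max_tracks + 1))
    alpha = rng.gamma(2.0, 1.0, size=(S, C)) + 0.05
    trans = rng.dirichlet(np.ones(S) * 2.0, size=S)
    init = rng.dirichlet(np.ones(S) * 2.0)
    counts = rng.poisson(2.0, size=(T, C))
    return alpha, trans, init, counts
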