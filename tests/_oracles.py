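"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from first principles (exhaustive
enumeration, all-pairs transitive closure, direct partial-likelihood sums)
without calling the implementation paths they check.
"""
import itertools

import numpy as np


def enumerate_best_path(emis, log_trans, log_init):
    """Exhaustive maximum-scoring state path.

    ``emis``: (n, S) log emissions; ``log_trans``: list of n-1 (S, S) log
    transition matrices; ``log_init``: (S,) log initial distribution.
    Returns (best_path, best_score); the first path in lexicographic order
    wins ties.
    """
    n, S = emis.shape
    states = np.arange(S)
    grids = np.meshgrid(*([states] * n), indexing="ij")
    paths = np.stack([g.ravel() for g in grids], axis=1)  # (S^n, n), lexicographic
    score = log_init[paths[:, 0]] + emis[0, paths[:, 0]]
    for i in range(1, n):
        score = score + log_trans[i - 1][paths[:, i - 1], paths[:, i]]
        score = score + emis[i, paths[:, i]]
    best = int(np.argmax(score))  # first maximizer = lexicographically smallest
    return paths[best].copy(), float(score[best])


def path_score(path, emis, log_trans, log_init):
    s = log_init[path[0]] + emis[0, path[0]]
    for i in range(1, len(path)):
        s += log_trans[i - 1][path[i - 1], path[i]] + emis[i, path[i]]
    return float(s)


def transitive_closure_components(calls, min_frac):
    """All-pairs overlap graph + Warshall closure; returns frozenset partition.

    Overlap is recomputed here from scratch on 1-based inclusive intervals.
    """
    n = len(calls)
    adj = np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            a, b = calls[i], calls[j]
            if a.chrom != b.chrom or a.cnv_type != b.cnv_type:
                continue
            ov = min(a.end_pos, b.end_pos) - max(a.start_pos, b.start_pos) + 1
            if ov <= 0:
                continue
            shorter = min(a.end_pos - a.start_pos + 1, b.end_pos - b.start_pos + 1)
            if ov / shorter >= min_frac:
                adj[i, j] = True
    for k in range(n):
        adj |= adj[:, k:k + 1] & adj[k:k + 1, :]
    comps = {}
    for i in range(n):
        root = int(np.flatnonzero(adj[i])[0])
        comps.setdefault(root, []).append(i)
    # same-type/chrom components only; key by member set
    return {frozenset(v) for v in comps.values()}


def breslow_loglik(beta, x, entry, exit_, event):
    """Direct delayed-entry partial log-likelihood (valid for tie-free data)."""
    beta = np.atleast_1d(beta)
    X = np.atleast_2d(x)
    if X.shape[0] != len(exit_):
        X = X.T
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for i in np.flatnonzero(event):
        t = exit_[i]
        risk = (entry < t) & (exit_ >= t)
        ll += eta[i] - np.log(w[risk].sum())
    return float(ll)
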