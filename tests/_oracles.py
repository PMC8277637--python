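"""Independent oracles used by unit and acceptance tests.

These deliberately re-derive results through routes different from the
package implementation: exhaustive enumeration, a hand-rolled IRLS, maximal
cliques for letter displays, and Monte-Carlo gene dropping.
"""

from __future__ import annotations

import itertools

import numpy as np

from polypat.panel import distinguishes


def brute_force_minimal_sets(panel, candidates, pool):
    """All minimal-cardinality distinguishing subsets, by full enumeration."""
    for size in range(1, len(pool) + 1):
        hits = [
            list(sub)
            for sub in itertools.combinations(sorted(pool), size)
            if distinguishes(panel, candidates, sub)
        ]
        if hits:
            return hits
    return []


def irls_binomial(X, k, n, maxiter=200, tol=1e-12):
    """Weighted IRLS for a binomial-logit GLM with (possibly fractional)
    success counts k out of totals n. Returns (beta, deviance)."""
    X = np.asarray(X, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    y = np.divide(k, n, out=np.zeros_like(k), where=n > 0)
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n * mu * (1.0 - mu)
        z = eta + (y - mu) / (mu * (1.0 - mu))
        xtw = X.T * w
        beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    term1 = np.zeros_like(k)
    mask = k > 0
    term1[mask] = k[mask] * np.log(y[mask] / mu[mask])
    term2 = np.zeros_like(k)
    mask = (n - k) > 0
    term2[mask] = (n[mask] - k[mask]) * np.log((1 - y[mask]) / (1 - mu[mask]))
    deviance = 2.0 * np.sum(term1 + term2)
    return beta, deviance


def clique_letters(sig):
    """Compact letters as maximal cliques of the non-significance graph.

    Two levels share a letter iff they are not significantly different; an
    edge of the graph always lies in some maximal clique, and non-adjacent
    vertices never share one.
    """
    n = sig.shape[0]
    adj = {i: {j for j in range(n) if j != i and not sig[i, j]} for i in range(n)}

    cliques = []

    def bron_kerbosch(r, p, x):
        if not p and not x:
            cliques.append(frozenset(r))
            return
        pivot = max(p | x, key=lambda v: len(adj[v]))
        for v in list(p - adj[pivot]):
            bron_kerbosch(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    bron_kerbosch(set(), set(range(n)), set())
    letters = {i: set() for i in range(n)}
    for idx, clique in enumerate(sorted(cliques, key=sorted)):
        for i in clique:
            letters[i].add(idx)
    return letters


def gene_drop(
    founder_weights,
    cross_rate,
    generations,
    n_individuals,
    rng,
    null_mode="recessive",
):
    """Monte-Carlo gene dropping with two labelled founder alleles per plant.

    Founders are fully inbred and unrelated, so IBD == same founder label.
    Donor plants are sampled proportional to their expressed pollen weight.
    Returns the realized mean inbreeding coefficient.
    """
    fw = np.asarray(founder_weights, dtype=float)
    n_f = len(fw)
    reps = n_individuals // n_f
    a = np.repeat(np.arange(n_f), reps)
    b = a.copy()
    for _ in range(generations):
        n = len(a)
        if null_mode == "recessive":
            w = np.maximum(fw[a], fw[b])
        else:
            w = np.minimum(fw[a], fw[b])
        p = w / w.sum()
        mothers = rng.integers(n, size=n)
        donors = rng.choice(n, size=n, p=p)
        selfed = rng.random(n) >= cross_rate
        fathers = np.where(selfed, mothers, donors)
        mg = np.where(rng.integers(2, size=n) == 0, a[mothers], b[mothers])
        pg = np.where(rng.integers(2, size=n) == 0, a[fathers], b[fathers])
        a, b = mg, pg
    return float(np.mean(a == b))


def pearson_r_closed_form(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cx = x - x.mean()
    cy = y - y.mean()
    return float((cx @ cy) / np.sqrt((cx @ cx) * (cy @ cy)))
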