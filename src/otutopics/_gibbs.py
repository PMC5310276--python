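"""Numba kernels for the collapsed Gibbs sampler.

The sampler state is kept in flat arrays: ``tokens[i]`` is the taxon index of
token ``i``, ``doc_of[i]`` its document, ``z[i]`` its current topic.  Sweeps
visit tokens in document-major, position-minor order, so a run is bit
reproducible given the seed.  All kernels share numba's global Mersenne
Twister state, seeded once per operation via :func:`seed_rng`.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_rng(seed):  # pragma: no cover - one-liner around numba RNG state
    np.random.seed(seed)


@njit(cache=True)
def init_assignments(tokens, doc_of, K, z, n_dk, n_kw, n_k):
    """Assign every token a uniform random topic and build the count matrices."""
    for i in range(tokens.shape[0]):
        k = np.random.randint(0, K)
        z[i] = k
        n_dk[doc_of[i], k] += 1
        n_kw[k, tokens[i]] += 1
        n_k[k] += 1


@njit(cache=True)
def sweep(tokens, doc_of, z, n_dk, n_kw, n_k, alpha, beta, n_sweeps):
    """Run ``n_sweeps`` full collapsed-Gibbs sweeps in place.

    Each token is removed from the counts, a new topic is drawn from
    p(k) ∝ (n_dk + α)(n_kw + β)/(n_k + Vβ) with the token excluded, and the
    counts are restored.
    """
    K = n_k.shape[0]
    V = n_kw.shape[1]
    vbeta = V * beta
    cum = np.empty(K, dtype=np.float64)
    for _ in range(n_sweeps):
        for i in range(tokens.shape[0]):
            w = tokens[i]
            d = doc_of[i]
            k = z[i]
            n_dk[d, k] -= 1
            n_kw[k, w] -= 1
            n_k[k] -= 1
            total = 0.0
            for kk in range(K):
                total += (n_dk[d, kk] + alpha) * (n_kw[kk, w] + beta) / (n_k[kk] + vbeta)
                cum[kk] = total
            u = np.random.random() * total
            knew = K - 1
            for kk in range(K):
                if u < cum[kk]:
                    knew = kk
                    break
            z[i] = knew
            n_dk[d, knew] += 1
            n_kw[knew, w] += 1
            n_k[knew] += 1


@njit(cache=True)
def sweep_tally(tokens, doc_of, z, n_dk, n_kw, n_k, alpha, beta, n_sweeps, tally):
    """Sweep ``n_sweeps`` times, incrementing ``tally[i, z[i]]`` after each."""
    for _ in range(n_sweeps):
        sweep(tokens, doc_of, z, n_dk, n_kw, n_k, alpha, beta, 1)
        for i in range(tokens.shape[0]):
            tally[i, z[i]] += 1


@njit(cache=True)
def foldin_sweep(tokens, doc_of, z, n_dk, phi, alpha, n_sweeps):
    """Gibbs sweeps over held-out documents with the topic-word matrix fixed:
    p(k) ∝ (n_dk + α) · φ[k, w]."""
    K = n_dk.shape[1]
    cum = np.empty(K, dtype=np.float64)
    for _ in range(n_sweeps):
        for i in range(tokens.shape[0]):
            w = tokens[i]
            d = doc_of[i]
            k = z[i]
            n_dk[d, k] -= 1
            total = 0.0
            for kk in range(K):
                total += (n_dk[d, kk] + alpha) * phi[kk, w]
                cum[kk] = total
            u = np.random.random() * total
            knew = K - 1
            for kk in range(K):
                if u < cum[kk]:
                    knew = kk
                    break
            z[i] = knew
            n_dk[d, knew] += 1
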