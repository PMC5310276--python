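"""Shared brute-force oracles and fixture builders for the test suite."""
from itertools import permutations

import numpy as np
from scipy.special import gammaln

from otutopics import OtuTable


def make_random_table(rng: np.random.Generator, D: int, V: int,
                      max_count: int = 10, zero_frac: float = 0.4) -> OtuTable:
    counts = rng.integers(1, max_count + 1, size=(D, V))
    counts[rng.random((D, V)) < zero_frac] = 0
    # guarantee no all-zero rows/columns so filters at their identity settings
    # really are the identity
    for d in range(D):
        if counts[d].sum() == 0:
            counts[d, rng.integers(V)] = 1
    for w in range(V):
        if counts[:, w].sum() == 0:
            counts[rng.integers(D), w] = 1
    return OtuTable([f"s{d}" for d in range(D)], [f"g{w}" for w in range(V)], counts)


def best_permutation_mean_tv(phi_fit: np.ndarray, phi_true: np.ndarray) -> float:
    """Mean per-topic total-variation distance under the best topic matching."""
    K = phi_true.shape[0]
    return min(float(np.abs(phi_fit[list(p)] - phi_true).sum(axis=1).mean() / 2)
               for p in permutations(range(K)))


def best_permutation(phi_fit: np.ndarray, phi_true: np.ndarray) -> tuple[int, ...]:
    """Topic matching minimising total |phi_fit[p[k]] - phi_true[k]|; p[k] is
    the fitted topic corresponding to true topic k."""
    K = phi_true.shape[0]
    return min(permutations(range(K)),
               key=lambda p: float(np.abs(phi_fit[list(p)] - phi_true).sum()))


def enum_foldin_theta(phi: np.ndarray, doc: np.ndarray, alpha: float) -> np.ndarray:
    """Exact E[(n_dk + alpha)/(n_d + K*alpha)] for one held-out document with
    phi fixed, by enumerating every assignment vector."""
    from itertools import product
    K = phi.shape[0]
    n = len(doc)
    log_post = []
    assigns = []
    for zvec in product(range(K), repeat=n):
        z = np.array(zvec)
        n_k = np.bincount(z, minlength=K)
        lp = gammaln(n_k + alpha).sum() - K * gammaln(alpha)
        lp += float(np.log(phi[z, doc]).sum())
        log_post.append(lp)
        assigns.append(n_k)
    log_post = np.array(log_post)
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    est = np.array([(n_k + alpha) / (n + K * alpha) for n_k in assigns])
    return (w[:, None] * est).sum(axis=0)
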