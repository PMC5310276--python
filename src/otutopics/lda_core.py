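"""Collapsed Gibbs sampling for latent Dirichlet allocation on OTU corpora.

Model
-----
Each sample (document) ``d`` draws a topic mixture θ_d ~ Dirichlet(α); each
topic ``k`` draws a taxon distribution φ_k ~ Dirichlet(β).  Every count unit
(token) ``i`` of sample ``d`` draws a topic ``z_{d,i} ~ Multinomial(θ_d)``
and then a taxon ``w_{d,i} ~ Multinomial(φ_{z_{d,i}})``.  The sampler
integrates θ and φ out analytically and runs MCMC over the token-level topic
assignments; the full conditional for one token is

    p(z = k | z_{-i}, w) ∝ (n_dk + α) · (n_kw + β) / (n_k + Vβ)

with the token itself excluded from all counts.  Point estimates use the
smoothed posterior means θ_dk = (n_dk + α)/(n_d + Kα) and
φ_kw = (n_kw + β)/(n_k + Vβ), averaged over post-burn-in samples.

Runs are bit reproducible: tokens are swept in document-major order and all
randomness flows from one integer seed.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln, logsumexp

from . import _gibbs
from .errors import ConfigError, ValidationError
from .io_otu import Corpus

DEFAULT_BETA = 0.1


def default_alpha(K: int) -> float:
    """Griffiths–Steyvers convention α = 50/K."""
    return 50.0 / K


@dataclass(frozen=True)
class Hyperparams:
    """Symmetric Dirichlet hyperparameters and topic count."""

    K: int
    alpha: float
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigError("alpha and beta must be positive")

    @classmethod
    def with_defaults(cls, K: int, alpha: Optional[float] = None,
                      beta: float = DEFAULT_BETA) -> "Hyperparams":
        return cls(K, default_alpha(K) if alpha is None else alpha, beta)


@dataclass
class GibbsState:
    """Sufficient statistics of the collapsed sampler at one iteration.

    ``z`` is flat over tokens in document-major order; ``doc_lengths`` gives
    the document boundaries.  The count matrices are redundant with ``z`` and
    are kept exactly consistent with it at every iteration.
    """

    tokens: np.ndarray
    doc_of: np.ndarray
    doc_lengths: np.ndarray
    z: np.ndarray
    n_dk: np.ndarray
    n_kw: np.ndarray
    n_k: np.ndarray
    rng_seed: int
    iteration: int = 0

    def doc_offset(self, d: int) -> int:
        return int(self.doc_lengths[:d].sum())

    def assignments(self, d: int) -> np.ndarray:
        """Topic assignments of document ``d``, in token order."""
        off = self.doc_offset(d)
        return self.z[off:off + int(self.doc_lengths[d])]

    def check_consistency(self) -> None:
        """Verify the count matrices against ``z``; raises on any mismatch."""
        K, V = self.n_kw.shape
        n_dk = np.zeros_like(self.n_dk)
        n_kw = np.zeros_like(self.n_kw)
        np.add.at(n_dk, (self.doc_of, self.z), 1)
        np.add.at(n_kw, (self.z, self.tokens), 1)
        if not (np.array_equal(n_dk, self.n_dk) and np.array_equal(n_kw, self.n_kw)
                and np.array_equal(n_kw.sum(axis=1), self.n_k)):
            raise ValidationError("Gibbs count matrices inconsistent with assignments")


@dataclass
class LdaFit:
    """Result of a collapsed-Gibbs LDA fit."""

    hyper: Hyperparams
    state: GibbsState
    theta: np.ndarray          # docs × K posterior-mean mixtures
    phi: np.ndarray            # K × V posterior-mean taxon distributions
    vocab: list[str]
    doc_ids: list[str]
    trace: np.ndarray          # per-iteration collapsed joint log-likelihood
    settings: dict = field(default_factory=dict)


def collapsed_joint_ll(n_dk: np.ndarray, n_kw: np.ndarray,
                       alpha: float, beta: float) -> float:
    """Collapsed joint log P(w, z | α, β) as a sum of Dirichlet-multinomial
    normalisers over documents and topics."""
    D, K = n_dk.shape
    Kv, V = n_kw.shape
    n_d = n_dk.sum(axis=1)
    n_k = n_kw.sum(axis=1)
    doc_part = (D * (gammaln(K * alpha) - K * gammaln(alpha))
                + gammaln(n_dk + alpha).sum() - gammaln(n_d + K * alpha).sum())
    top_part = (Kv * (gammaln(V * beta) - V * gammaln(beta))
                + gammaln(n_kw + beta).sum() - gammaln(n_k + V * beta).sum())
    return float(doc_part + top_part)


def joint_log_likelihood(state: GibbsState, hyper: Hyperparams, V: int) -> float:
    """Collapsed joint log-likelihood of the current state.

    Invariant under any permutation of topic labels.
    """
    if state.n_kw.shape != (hyper.K, V):
        raise ValidationError("state count matrices do not match (K, V)")
    return collapsed_joint_ll(state.n_dk, state.n_kw, hyper.alpha, hyper.beta)


def full_conditional(state: GibbsState, hyper: Hyperparams, d: int, i: int,
                     w: int, V: int) -> np.ndarray:
    """Collapsed full conditional p(z_{d,i} = k | everything else).

    The token's current assignment is excluded from the counts internally;
    the state is not modified.  Returns a length-K probability vector.
    """
    K = hyper.K
    if state.n_kw.shape[0] != K:
        raise ValidationError("state does not match hyperparameters")
    off = state.doc_offset(d) + i
    if state.tokens[off] != w:
        raise ValidationError(f"token ({d},{i}) is {state.tokens[off]}, not {w}")
    k_cur = state.z[off]
    n_dk = state.n_dk[d].astype(float).copy()
    n_kw = state.n_kw[:, w].astype(float).copy()
    n_k = state.n_k.astype(float).copy()
    n_dk[k_cur] -= 1
    n_kw[k_cur] -= 1
    n_k[k_cur] -= 1
    p = (n_dk + hyper.alpha) * (n_kw + hyper.beta) / (n_k + V * hyper.beta)
    if (p < 0).any() or not np.isfinite(p).all():
        raise ValidationError("malformed counts in full conditional")
    return p / p.sum()


def _validate_corpus_for_fit(corpus: Corpus) -> None:
    if corpus.n_docs == 0 or corpus.n_tokens == 0:
        raise ValidationError("corpus is empty")
    if corpus.n_vocab < 2:
        raise ValidationError("vocabulary must contain at least 2 taxa")
    empty = [corpus.doc_ids[d] for d, doc in enumerate(corpus.docs) if len(doc) == 0]
    if empty:
        raise ValidationError(f"documents with no tokens: {empty}")


def fit_lda_gibbs(corpus: Corpus, hyper: Hyperparams, n_iter: int = 2000,
                  burn_in: int = 1000, sample_lag: int = 10,
                  seed: int = 0) -> LdaFit:
    """Fit LDA by collapsed Gibbs sampling.

    Assignments are initialised uniformly at random from ``seed``; each
    iteration sweeps every token once in document-major order.  After
    ``burn_in`` iterations, the smoothed θ and φ estimators are accumulated
    every ``sample_lag`` iterations (the first post-burn-in iteration is
    always retained) and averaged.  ``trace`` records the collapsed joint
    log-likelihood at every iteration.  Identical inputs and seed give bit
    identical output.
    """
    _validate_corpus_for_fit(corpus)
    if not (n_iter > burn_in >= 0):
        raise ConfigError("need n_iter > burn_in >= 0")
    if sample_lag < 1:
        raise ConfigError("sample_lag must be >= 1")
    K, V, D = hyper.K, corpus.n_vocab, corpus.n_docs
    tokens, doc_of = corpus.flatten()
    doc_lens = corpus.doc_lengths()

    z = np.empty(tokens.shape[0], dtype=np.int64)
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    _gibbs.seed_rng(int(seed) & 0x7FFFFFFF)
    _gibbs.init_assignments(tokens, doc_of, K, z, n_dk, n_kw, n_k)

    theta_acc = np.zeros((D, K))
    phi_acc = np.zeros((K, V))
    n_ret = 0
    trace = np.empty(n_iter)
    for it in range(1, n_iter + 1):
        _gibbs.sweep(tokens, doc_of, z, n_dk, n_kw, n_k, hyper.alpha, hyper.beta, 1)
        trace[it - 1] = collapsed_joint_ll(n_dk, n_kw, hyper.alpha, hyper.beta)
        if it > burn_in and (it - burn_in - 1) % sample_lag == 0:
            theta_acc += (n_dk + hyper.alpha) / (doc_lens[:, None] + K * hyper.alpha)
            phi_acc += (n_kw + hyper.beta) / (n_k[:, None] + V * hyper.beta)
            n_ret += 1
    state = GibbsState(tokens, doc_of, doc_lens, z, n_dk, n_kw, n_k,
                       rng_seed=int(seed), iteration=n_iter)
    return LdaFit(hyper, state, theta_acc / n_ret, phi_acc / n_ret,
                  list(corpus.vocab), list(corpus.doc_ids), trace,
                  settings={"n_iter": n_iter, "burn_in": burn_in,
                            "sample_lag": sample_lag, "seed": int(seed)})


def _check_row_stochastic(mat: np.ndarray, name: str, tol: float = 1e-6) -> None:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or not np.allclose(mat.sum(axis=1), 1.0, atol=tol):
        raise ValidationError(f"rows of {name} must sum to 1")
    if (mat < 0).any():
        raise ValidationError(f"{name} has negative entries")


def perplexity(phi: np.ndarray, theta_heldout: np.ndarray, heldout: Corpus) -> float:
    """Held-out perplexity exp(−(1/N) Σ_{d,i} ln Σ_k θ_dk φ_{k,w_{d,i}}).

    Lower is better; a model placing probability one on every observed token
    attains the lower bound 1, and a uniform φ over V taxa scores exactly V.
    """
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta_heldout, dtype=float)
    _check_row_stochastic(phi, "phi")
    _check_row_stochastic(theta, "theta")
    if heldout.n_vocab > phi.shape[1]:
        raise ValidationError("held-out vocabulary larger than phi")
    if heldout.n_tokens == 0:
        raise ValidationError("held-out corpus has no tokens")
    ll = 0.0
    for d, doc in enumerate(heldout.docs):
        if len(doc) == 0:
            continue
        if doc.max() >= phi.shape[1]:
            raise ValidationError(f"held-out token outside vocabulary in doc {d}")
        p = theta[d] @ phi[:, doc]
        ll += float(np.log(p).sum())
    return float(np.exp(-ll / heldout.n_tokens))


def fold_in(phi: np.ndarray, heldout: Corpus, hyper: Hyperparams,
            n_iter: int = 200, seed: int = 0) -> np.ndarray:
    """Estimate θ for held-out documents with φ held fixed.

    Gibbs sampling over the held-out tokens with conditional
    p(k) ∝ (n_dk + α)·φ_{k,w}; the first half of ``n_iter`` is discarded as
    burn-in and the smoothed θ estimator is averaged over the remaining
    sweeps.  Deterministic under a fixed seed.
    """
    phi = np.asarray(phi, dtype=float)
    _check_row_stochastic(phi, "phi")
    _validate_corpus_for_fit(heldout)
    if phi.shape[0] != hyper.K:
        raise ConfigError("phi row count differs from K")
    if n_iter < 2:
        raise ConfigError("n_iter must be >= 2")
    K = hyper.K
    D = heldout.n_docs
    tokens, doc_of = heldout.flatten()
    doc_lens = heldout.doc_lengths()
    z = np.empty(tokens.shape[0], dtype=np.int64)
    n_dk = np.zeros((D, K), dtype=np.int64)
    n_kw = np.zeros((K, phi.shape[1]), dtype=np.int64)  # scratch for init only
    n_k = np.zeros(K, dtype=np.int64)
    _gibbs.seed_rng(int(seed) & 0x7FFFFFFF)
    _gibbs.init_assignments(tokens, doc_of, K, z, n_dk, n_kw, n_k)
    burn = n_iter // 2
    theta_acc = np.zeros((D, K))
    n_ret = 0
    for it in range(1, n_iter + 1):
        _gibbs.foldin_sweep(tokens, doc_of, z, n_dk, phi, hyper.alpha, 1)
        if it > burn:
            theta_acc += (n_dk + hyper.alpha) / (doc_lens[:, None] + K * hyper.alpha)
            n_ret += 1
    return theta_acc / n_ret


def exact_posterior_marginals(corpus: Corpus, hyper: Hyperparams,
                              max_tokens: int = 12) -> np.ndarray:
    """Exact per-token posterior topic marginals by exhaustive enumeration.

    Enumerates all K^N assignment vectors with their collapsed joint
    likelihood; only feasible for tiny corpora (N ≤ ``max_tokens``).  Returns
    an (N × K) matrix in flat (document-major) token order.  Serves as an
    independent ground truth for the Gibbs sampler on small problems.
    """
    _validate_corpus_for_fit(corpus)
    N = corpus.n_tokens
    if N > max_tokens:
        raise ConfigError(f"enumeration over {hyper.K}^{N} assignments refused")
    K, V, D = hyper.K, corpus.n_vocab, corpus.n_docs
    tokens, doc_of = corpus.flatten()
    logw = np.empty(K ** N)
    assigns = np.empty((K ** N, N), dtype=np.int64)
    for idx, zvec in enumerate(itertools.product(range(K), repeat=N)):
        zarr = np.array(zvec, dtype=np.int64)
        n_dk = np.zeros((D, K), dtype=np.int64)
        n_kw = np.zeros((K, V), dtype=np.int64)
        np.add.at(n_dk, (doc_of, zarr), 1)
        np.add.at(n_kw, (zarr, tokens), 1)
        logw[idx] = collapsed_joint_ll(n_dk, n_kw, hyper.alpha, hyper.beta)
        assigns[idx] = zarr
    logw -= logsumexp(logw)
    weights = np.exp(logw)
    marg = np.zeros((N, K))
    for i in range(N):
        for k in range(K):
            marg[i, k] = weights[assigns[:, i] == k].sum()
    return marg
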