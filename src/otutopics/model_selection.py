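"""Choosing the number of topics by cross-validated held-out perplexity.

Samples are the exchangeable unit, so folds partition documents, not tokens.
For every candidate K and fold, the model is fitted on the training documents
(vocabulary unchanged), θ for the test documents is re-estimated by folding
in against the fitted φ, and held-out perplexity / log-likelihood are
recorded.  Per-cell seeds are derived deterministically from the master seed,
so a rerun reproduces every cell bit exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io_otu import Corpus
from .lda_core import Hyperparams, fit_lda_gibbs, fold_in, perplexity


@dataclass(frozen=True)
class FitSettings:
    """Sampler schedule shared by every cross-validation cell.

    ``alpha=None`` resolves to the 50/K default per candidate K.
    """

    n_iter: int = 2000
    burn_in: int = 1000
    sample_lag: int = 10
    alpha: Optional[float] = None
    beta: float = 0.1
    foldin_iter: int = 200


@dataclass(frozen=True)
class CvCell:
    K: int
    fold: int
    heldout_perplexity: float
    heldout_loglik: float
    seed: int


@dataclass
class CvResult:
    """Grid of (K, fold) held-out scores with per-K summaries."""

    k_grid: list[int]
    folds: int
    cells: list[CvCell]
    summary: dict[int, dict[str, float]] = field(default_factory=dict)

    def summarize(self) -> dict[int, dict[str, float]]:
        """Per-K mean/sd of held-out perplexity and mean log-likelihood,
        recomputed from the cells (sd with one delta degree of freedom)."""
        out: dict[int, dict[str, float]] = {}
        for K in self.k_grid:
            perp = np.array([c.heldout_perplexity for c in self.cells if c.K == K])
            ll = np.array([c.heldout_loglik for c in self.cells if c.K == K])
            out[K] = {"mean_perplexity": float(perp.mean()),
                      "sd_perplexity": float(perp.std(ddof=1)) if len(perp) > 1 else 0.0,
                      "mean_loglik": float(ll.mean())}
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.cells])

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"K": K, **stats} for K, stats in sorted(self.summary.items())]
        return pd.DataFrame(rows)


def make_folds(corpus: Corpus, n_folds: int,
               seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Document-level k-fold partition: shuffled indices split into test sets
    whose sizes differ by at most one; train sets are the complements."""
    if n_folds < 2:
        raise ConfigError("n_folds must be >= 2")
    if n_folds > corpus.n_docs:
        raise ConfigError(f"{n_folds} folds but only {corpus.n_docs} documents")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(corpus.n_docs)
    folds = []
    for test in np.array_split(perm, n_folds):
        test = np.sort(test)
        train = np.sort(np.setdiff1d(perm, test))
        folds.append((train, test))
    return folds


def cell_seed(master_seed: int, K: int, fold: int) -> int:
    """Stable per-(K, fold) chain seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(K), int(fold)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def cross_validate_k(corpus: Corpus, k_grid: list[int], n_folds: int,
                     fit_settings: FitSettings = FitSettings(),
                     seed: int = 0) -> CvResult:
    """Held-out perplexity and log-likelihood over a grid of topic counts.

    Test tokens whose taxon never occurs in a training fold are still scored:
    the smoothed φ estimator gives every taxon at least β mass, which keeps
    perplexity finite and comparable across K.
    """
    if not k_grid:
        raise ConfigError("k_grid is empty")
    if any(K < 1 for K in k_grid):
        raise ConfigError("all K must be >= 1")
    folds = make_folds(corpus, n_folds, seed)
    cells: list[CvCell] = []
    for K in k_grid:
        hyper = Hyperparams.with_defaults(K, fit_settings.alpha, fit_settings.beta)
        for f, (train, test) in enumerate(folds):
            s = cell_seed(seed, K, f)
            try:
                fit = fit_lda_gibbs(corpus.subset(train), hyper,
                                    n_iter=fit_settings.n_iter,
                                    burn_in=fit_settings.burn_in,
                                    sample_lag=fit_settings.sample_lag, seed=s)
                test_corpus = corpus.subset(test)
                theta = fold_in(fit.phi, test_corpus, hyper,
                                n_iter=fit_settings.foldin_iter, seed=s + 1)
                perp = perplexity(fit.phi, theta, test_corpus)
            except (ValidationError, ConfigError) as exc:
                raise type(exc)(f"(K={K}, fold={f}): {exc}") from exc
            ll = -float(np.log(perp)) * test_corpus.n_tokens
            cells.append(CvCell(K, f, perp, ll, s))
    cv = CvResult(list(k_grid), n_folds, cells)
    cv.summary = cv.summarize()
    return cv


def select_k(cv: CvResult, rule: str = "min_mean_perplexity") -> int:
    """Pick a topic count from a cross-validation grid.

    ``min_mean_perplexity`` takes the K with the smallest mean held-out
    perplexity, ties to the smaller K.  ``one_sd`` takes the smallest K whose
    mean is within one standard deviation of the minimum (sd at the argmin).
    """
    if not cv.cells:
        raise ValidationError("empty cross-validation result")
    summary = cv.summarize()
    ks = sorted(summary)
    means = {K: summary[K]["mean_perplexity"] for K in ks}
    best = min(ks, key=lambda K: (means[K], K))
    if rule == "min_mean_perplexity":
        return best
    if rule == "one_sd":
        cutoff = means[best] + summary[best]["sd_perplexity"]
        return min(K for K in ks if means[K] <= cutoff)
    raise ConfigError(f"unknown selection rule {rule!r}")
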