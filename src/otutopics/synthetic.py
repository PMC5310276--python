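"""Synthetic OTU tables drawn from the LDA generative model.

The generator draws topic-taxon distributions φ from a symmetric
Dirichlet(β), per-sample topic mixtures θ from Dirichlet(α), and each count
unit through the two-stage topic-then-taxon multinomial, then tallies the
tokens into a sample × taxon table.  All ground truth (φ, θ, per-token topic
assignments, labels and planted associations) is returned alongside, so every
downstream module can be validated against a known answer.

Label-dependent sub-community prevalence is planted by scaling the Dirichlet
concentration of a group's enriched topic before drawing θ — the data stay
inside the model family rather than being edited post hoc.

Two presets mirror common study shapes: ``oral-like`` (≈40 samples × 90
genera) and ``gut-like`` (≈150 samples × 180 genera).  Defaults use
α = 1 (uniform over the mixture simplex), β = 0.1 (moderately concentrated
topics) and 1000 count units per sample, a realistic per-sample sequencing
depth at genus level.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigError
from .io_otu import OtuTable

PRESETS = {
    "oral-like": {"D": 40, "V": 90, "tokens_per_doc": 1000},
    "gut-like": {"D": 150, "V": 180, "tokens_per_doc": 1000},
}

DEFAULT_ALPHA = 1.0
DEFAULT_BETA = 0.1


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated table."""

    phi_true: np.ndarray                 # K × V
    theta_true: np.ndarray               # D × K
    z_true: list[np.ndarray]             # per-doc topic of each drawn token
    labels: Optional[dict[str, str]]
    association: Optional[dict[str, dict[str, float]]]  # group -> {topic, multiplier}
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "phi_true": self.phi_true.tolist(),
            "theta_true": self.theta_true.tolist(),
            "z_true": [z.tolist() for z in self.z_true],
            "labels": self.labels,
            "association": self.association,
            "seed": self.seed,
        })


def _draw_tokens(rng: np.random.Generator, theta_d: np.ndarray,
                 phi: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    K, V = phi.shape
    z = rng.choice(K, size=n, p=theta_d)
    w = np.empty(n, dtype=np.int64)
    for k in range(K):
        idx = np.flatnonzero(z == k)
        if idx.size:
            w[idx] = rng.choice(V, size=idx.size, p=phi[k])
    return z, w


def _validate_dims(K: int, V: int, D: int, tokens_per_doc: int,
                   alpha: float, beta: float) -> None:
    if min(K, V, D, tokens_per_doc) < 1:
        raise ConfigError("all dimensions must be >= 1")
    if alpha <= 0 or beta <= 0:
        raise ConfigError("alpha and beta must be positive")


def _names(D: int, V: int) -> tuple[list[str], list[str]]:
    return ([f"sample_{d + 1}" for d in range(D)],
            [f"genus_{w + 1}" for w in range(V)])


def generate_corpus(K: int, V: int, D: int, tokens_per_doc: int,
                    alpha: float = DEFAULT_ALPHA, beta: float = DEFAULT_BETA,
                    seed: int = 0) -> tuple[OtuTable, SyntheticTruth]:
    """Unlabeled table from the plain generative model; fully determined by
    the seed, with total count D × tokens_per_doc."""
    _validate_dims(K, V, D, tokens_per_doc, alpha, beta)
    rng = np.random.default_rng(seed)
    phi = rng.dirichlet(np.full(V, beta), size=K)
    theta = rng.dirichlet(np.full(K, alpha), size=D)
    counts = np.zeros((D, V), dtype=np.int64)
    z_true = []
    for d in range(D):
        z, w = _draw_tokens(rng, theta[d], phi, tokens_per_doc)
        counts[d] = np.bincount(w, minlength=V)
        z_true.append(z)
    sample_ids, taxon_names = _names(D, V)
    table = OtuTable(sample_ids, taxon_names, counts)
    return table, SyntheticTruth(phi, theta, z_true, None, None, int(seed))


def generate_labeled_corpus(K: int, V: int, D: int, tokens_per_doc: int,
                            groups: Sequence[str],
                            enrich: Mapping[str, tuple[int, float]] | None = None,
                            alpha: float = DEFAULT_ALPHA, beta: float = DEFAULT_BETA,
                            seed: int = 0) -> tuple[OtuTable, SyntheticTruth]:
    """Labeled table with planted label-dependent topic prevalence.

    Samples are assigned to ``groups`` round-robin.  ``enrich`` maps a group
    name to ``(topic index, multiplier)``: that group's θ rows are drawn from
    a Dirichlet whose concentration at the enriched topic is scaled by the
    multiplier, so the topic is over-represented (multiplier > 1) or depleted
    (< 1) in the group while the data remain inside the model family.  With
    all multipliers 1 the output is distributionally identical to
    :func:`generate_corpus`.
    """
    _validate_dims(K, V, D, tokens_per_doc, alpha, beta)
    groups = list(groups)
    if len(groups) < 2:
        raise ConfigError("need at least 2 groups")
    enrich = dict(enrich or {})
    for g, (topic, mult) in enrich.items():
        if g not in groups:
            raise ConfigError(f"enriched group {g!r} not in groups")
        if not 0 <= topic < K:
            raise ConfigError(f"enriched topic {topic} outside [0, {K})")
        if mult <= 0:
            raise ConfigError("multiplier must be positive")
    rng = np.random.default_rng(seed)
    phi = rng.dirichlet(np.full(V, beta), size=K)
    sample_ids, taxon_names = _names(D, V)
    labels = {sample_ids[d]: groups[d % len(groups)] for d in range(D)}
    theta = np.empty((D, K))
    counts = np.zeros((D, V), dtype=np.int64)
    z_true = []
    for d in range(D):
        conc = np.full(K, alpha)
        g = labels[sample_ids[d]]
        if g in enrich:
            topic, mult = enrich[g]
            conc[topic] *= mult
        theta[d] = rng.dirichlet(conc)
        z, w = _draw_tokens(rng, theta[d], phi, tokens_per_doc)
        counts[d] = np.bincount(w, minlength=V)
        z_true.append(z)
    table = OtuTable(sample_ids, taxon_names, counts, dict(labels))
    association = {g: {"topic": int(t), "multiplier": float(m)}
                   for g, (t, m) in enrich.items()}
    return table, SyntheticTruth(phi, theta, z_true, dict(labels), association, int(seed))
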