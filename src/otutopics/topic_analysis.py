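"""Topic summaries, overlap, inter-topic distances and a 2-D MDS map.

A fitted topic is a distribution over taxa.  Its *dominant taxa* are those
with probability strictly above a display threshold (default 0.01, the cutoff
used to display the bacteria-in-topic matrix).  Community interaction between
two topics is summarised as the Jaccard overlap of their dominant-taxon sets,
and as the square root of the Jensen–Shannon divergence (base 2) between the
full distributions — a true metric bounded by [0, 1] — which feeds a
deterministic classical (Torgerson) multidimensional scaling into the plane.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .errors import ConfigError, ValidationError

DEFAULT_PHI_DISPLAY_THRESHOLD = 0.01


@dataclass
class TopicSummary:
    """Per-topic dominant taxa: ``dominant[k]`` is a list of (taxon,
    probability) pairs, sorted by descending probability then taxon name."""

    dominant: list[list[tuple[str, float]]]
    display_threshold: float

    def sets(self) -> list[set[str]]:
        return [{name for name, _ in topic} for topic in self.dominant]


@dataclass
class TopicMap:
    """Inter-topic distance matrix with its 2-D classical-MDS embedding."""

    dist: np.ndarray
    coords: np.ndarray
    eigenvalues: np.ndarray
    warning: str | None = None

    def coords_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"topic": np.arange(1, len(self.coords) + 1),
                             "x": self.coords[:, 0], "y": self.coords[:, 1]})

    def eigs_json(self) -> str:
        return json.dumps({"eigenvalues": self.eigenvalues.tolist(),
                           "warning": self.warning}, indent=2)


def dominant_taxa(phi: np.ndarray, vocab: list[str] | None = None,
                  threshold: float = DEFAULT_PHI_DISPLAY_THRESHOLD) -> TopicSummary:
    """Taxa with φ_kw strictly above the display threshold, per topic."""
    phi = np.asarray(phi, dtype=float)
    if not 0 <= threshold < 1:
        raise ConfigError("threshold must lie in [0, 1)")
    if phi.ndim != 2 or not np.allclose(phi.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("phi rows must sum to 1")
    if vocab is None:
        vocab = [f"taxon_{w + 1}" for w in range(phi.shape[1])]
    dominant = []
    for k in range(phi.shape[0]):
        entries = [(vocab[w], float(phi[k, w]))
                   for w in range(phi.shape[1]) if phi[k, w] > threshold]
        entries.sort(key=lambda e: (-e[1], e[0]))
        dominant.append(entries)
    return TopicSummary(dominant, float(threshold))


def topic_overlap(summary: TopicSummary) -> np.ndarray:
    """Jaccard index between every pair of dominant-taxon sets.

    Two empty sets overlap 0 by convention; the diagonal is 1 for non-empty
    sets.
    """
    sets = summary.sets()
    K = len(sets)
    overlap = np.zeros((K, K))
    for j in range(K):
        for k in range(K):
            union = sets[j] | sets[k]
            overlap[j, k] = len(sets[j] & sets[k]) / len(union) if union else 0.0
    return overlap


def topic_distance(phi: np.ndarray) -> np.ndarray:
    """Square root of the Jensen–Shannon divergence (base 2) between topics.

    Symmetric, zero diagonal, bounded by [0, 1]; 1 is attained exactly for
    topics with disjoint support.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2 or not np.allclose(phi.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("phi rows must sum to 1")
    K = phi.shape[0]
    dist = np.zeros((K, K))
    for j in range(K):
        for k in range(j + 1, K):
            d = jensenshannon(phi[j], phi[k], base=2)
            d = 0.0 if np.isnan(d) else float(d)
            dist[j, k] = dist[k, j] = min(d, 1.0)
    return dist


def mds_topics(dist: np.ndarray, negative_eig_tol: float = 1e-8) -> TopicMap:
    """Classical (Torgerson) MDS of a topic distance matrix into 2-D.

    The squared distances are double-centered, the top two eigenpairs taken,
    and coordinates scaled by the square roots of the eigenvalues.  Axis signs
    are fixed by making the first nonzero loading of each axis positive, so
    the embedding is fully deterministic.  Substantially negative leading
    eigenvalues (non-Euclidean input) are recorded as a warning.
    """
    dist = np.asarray(dist, dtype=float)
    K = dist.shape[0]
    if dist.ndim != 2 or dist.shape != (K, K) or K < 2:
        raise ConfigError("need a square distance matrix with K >= 2")
    if not np.allclose(dist, dist.T, atol=1e-9) or not np.allclose(np.diag(dist), 0, atol=1e-9):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    J = np.eye(K) - np.ones((K, K)) / K
    B = -0.5 * J @ (dist ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    warning = None
    neg = eigvals[eigvals < -negative_eig_tol * max(1.0, abs(eigvals[0]))]
    if neg.size:
        warning = f"{neg.size} negative eigenvalues (min {neg.min():.3g}); distances not exactly Euclidean"
    top = np.clip(eigvals[:2], 0.0, None)
    coords = eigvecs[:, :2] * np.sqrt(top)[None, :]
    for axis in range(2):
        col = coords[:, axis]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return TopicMap(dist, coords, eigvals, warning)
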