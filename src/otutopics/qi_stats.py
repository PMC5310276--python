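"""Quetelet Index: association between sub-communities and disease status.

A topic is "observed" in a sample when its mixture weight θ_dk exceeds a
presence threshold (default 0.05, the same cutoff used to display the
sample-over-topic composition).  For topic k and status group g the Quetelet
Index is the relative change of the observation frequency within the group
against the frequency among all samples,

    QI_kg = f(k present | g) / f(k present | all samples) − 1,

so QI > 0 means the sub-community is over-represented in the group, QI = −1
that it is absent from the group while present elsewhere, and QI = 0 that the
group matches the overall frequency.  Because the group frequencies weighted
by group size average to the overall frequency, the indices within a topic
can never all be strictly positive.

A topic that is present in no sample has an undefined index; such rows are
flagged as missing, never reported as zero.  An optional permutation test
shuffles the status labels jointly across topics to give two-sided p-values.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

DEFAULT_PRESENCE_THRESHOLD = 0.05


@dataclass
class PresenceMatrix:
    """Boolean samples × topics matrix of thresholded topic observations."""

    presence: np.ndarray
    threshold: float
    doc_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.presence.shape[0]

    @property
    def n_topics(self) -> int:
        return self.presence.shape[1]


@dataclass
class QiTable:
    """Topic × group Quetelet indices with the underlying contingency data.

    ``undefined[k]`` marks topics present in no sample; their ``qi`` row is
    NaN and must not be read as zero.
    """

    qi: np.ndarray                      # topics × groups, NaN where undefined
    counts: np.ndarray                  # presence counts within group
    group_sizes: dict[str, int]
    overall_freq: np.ndarray            # per-topic presence fraction
    groups: list[str]
    undefined: np.ndarray               # per-topic bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(self.qi.shape[0]):
            for g, group in enumerate(self.groups):
                rows.append({"topic": k + 1, "group": group,
                             "n_group": self.group_sizes[group],
                             "n_present_in_group": int(self.counts[k, g]),
                             "overall_freq": float(self.overall_freq[k]),
                             "qi": float(self.qi[k, g])})
        return pd.DataFrame(rows)


def topic_presence(theta: np.ndarray, threshold: float = DEFAULT_PRESENCE_THRESHOLD,
                   doc_ids: list[str] | None = None) -> PresenceMatrix:
    """Threshold a row-stochastic θ into a presence matrix.

    A topic counts as observed when θ_dk is strictly greater than the
    threshold — mirroring the display rule that hides points with probability
    no more than the cutoff.
    """
    theta = np.asarray(theta, dtype=float)
    if not 0 < threshold < 1:
        raise ConfigError("threshold must lie in (0, 1)")
    if theta.ndim != 2 or not np.allclose(theta.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("theta rows must sum to 1")
    if doc_ids is None:
        doc_ids = [f"sample_{d + 1}" for d in range(theta.shape[0])]
    return PresenceMatrix(theta > threshold, float(threshold), list(doc_ids))


def _group_arrays(presence: PresenceMatrix,
                  labels: Mapping[str, str]) -> tuple[np.ndarray, list[str]]:
    missing = [s for s in presence.doc_ids if s not in labels]
    if missing:
        raise ValidationError(f"unlabeled samples: {missing}")
    status = np.array([labels[s] for s in presence.doc_ids])
    groups = sorted(set(status))
    return status, groups


def _qi_from_arrays(pres: np.ndarray, status: np.ndarray,
                    groups: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    overall = pres.mean(axis=0)
    counts = np.stack([pres[status == g].sum(axis=0) for g in groups], axis=1)
    sizes = np.array([(status == g).sum() for g in groups])
    with np.errstate(divide="ignore", invalid="ignore"):
        qi = (counts / sizes[None, :]) / overall[:, None] - 1.0
    qi[overall == 0, :] = np.nan
    return qi, counts, overall


def quetelet_index(presence: PresenceMatrix, labels: Mapping[str, str]) -> QiTable:
    """Quetelet Index of every (topic, status group) pair.

    Every sample must be labeled and every group non-empty.  Topics never
    present anywhere get a NaN row flagged in ``undefined``.
    """
    status, groups = _group_arrays(presence, labels)
    if len(groups) < 1:
        raise ValidationError("no status groups")
    qi, counts, overall = _qi_from_arrays(presence.presence, status, groups)
    sizes = {g: int((status == g).sum()) for g in groups}
    if any(v == 0 for v in sizes.values()):
        raise ValidationError("empty status group")
    return QiTable(qi, counts, sizes, overall, groups, undefined=overall == 0)


def qi_permutation_pvalues(presence: PresenceMatrix, labels: Mapping[str, str],
                           n_perm: int = 999, seed: int = 0) -> np.ndarray:
    """Two-sided permutation p-values for every (topic, group) index.

    Labels are shuffled jointly across topics (one permutation re-scores the
    whole matrix), preserving inter-topic correlation;
    p = (1 + #{|QI_perm| ≥ |QI_obs|}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100")
    status, groups = _group_arrays(presence, labels)
    qi_obs, _, _ = _qi_from_arrays(presence.presence, status, groups)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(qi_obs)
    obs_abs = np.abs(qi_obs)
    for _ in range(n_perm):
        qi_perm, _, _ = _qi_from_arrays(presence.presence, rng.permutation(status), groups)
        exceed += np.abs(qi_perm) >= obs_abs - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    p[np.isnan(qi_obs)] = np.nan
    return p
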