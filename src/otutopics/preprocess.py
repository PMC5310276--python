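"""Taxon and sample filtering ahead of topic modeling.

Genus-level OTU tables carry two kinds of noise the topic model should not
see: taxa observed in only a handful of samples (likely sequencing artefacts
or transients) and samples with so few detected taxa that their topic mixture
is unidentifiable.  On top of those, taxa whose mean relative abundance is
negligible everywhere are dropped, and the final modeling vocabulary can be
chosen by tf-idf score — taxa that occur in every sample carry no
discriminative signal (idf = 0), exactly as ubiquitous stop-words do in text.

All filters only drop rows or columns; surviving counts are never modified,
and each filter is idempotent.  The recommended order is sparse samples →
rare taxa → low abundance → vocabulary, which guarantees nonzero sample
totals before any relative-abundance arithmetic.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ValidationError
from .io_otu import OtuTable


@dataclass
class FilterReport:
    """Record of what a filtering step (or pipeline) removed and why.

    Each removed taxon is attributed to the first rule that removed it, so the
    three taxon lists are disjoint and, together with the retained names,
    partition the input taxa.
    """

    taxa_removed_prevalence: list[str] = field(default_factory=list)
    taxa_removed_abundance: list[str] = field(default_factory=list)
    taxa_removed_tfidf: list[str] = field(default_factory=list)
    samples_removed: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def merge(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            self.taxa_removed_prevalence + other.taxa_removed_prevalence,
            self.taxa_removed_abundance + other.taxa_removed_abundance,
            self.taxa_removed_tfidf + other.taxa_removed_tfidf,
            self.samples_removed + other.samples_removed,
            {**self.thresholds, **other.thresholds},
            self.warnings + other.warnings,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def filter_rare_taxa(table: OtuTable, min_prevalence: int) -> tuple[OtuTable, FilterReport]:
    """Drop taxa present (count > 0) in fewer than ``min_prevalence`` samples."""
    if not 1 <= min_prevalence <= table.n_samples:
        raise ValidationError(f"min_prevalence must be in [1, {table.n_samples}]")
    prevalence = (table.counts > 0).sum(axis=0)
    keep = np.flatnonzero(prevalence >= min_prevalence)
    if keep.size == 0:
        raise ValidationError("prevalence filter would remove every taxon")
    removed = [table.taxon_names[j] for j in np.flatnonzero(prevalence < min_prevalence)]
    report = FilterReport(taxa_removed_prevalence=removed,
                          thresholds={"min_prevalence": min_prevalence})
    return table.select_taxa(keep), report


def filter_sparse_samples(table: OtuTable, min_taxa: int) -> tuple[OtuTable, FilterReport]:
    """Drop samples with fewer than ``min_taxa`` taxa at nonzero count."""
    if not 1 <= min_taxa <= table.n_taxa:
        raise ValidationError(f"min_taxa must be in [1, {table.n_taxa}]")
    richness = (table.counts > 0).sum(axis=1)
    keep = np.flatnonzero(richness >= min_taxa)
    if keep.size == 0:
        raise ValidationError("sparsity filter would remove every sample")
    removed = [table.sample_ids[i] for i in np.flatnonzero(richness < min_taxa)]
    report = FilterReport(samples_removed=removed, thresholds={"min_taxa": min_taxa})
    return table.select_samples(keep), report


def filter_low_abundance(table: OtuTable,
                         min_mean_rel_abundance: float) -> tuple[OtuTable, FilterReport]:
    """Drop taxa whose mean per-sample relative abundance is below threshold.

    Relative abundance of taxon ``w`` in sample ``d`` is
    ``counts[d, w] / sum_w counts[d, w]``; the summary is its unweighted mean
    across samples.  Samples with zero total are rejected — run
    :func:`filter_sparse_samples` first.
    """
    if not 0 <= min_mean_rel_abundance < 1:
        raise ValidationError("min_mean_rel_abundance must be in [0, 1)")
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError("sample with zero total count; filter sparse samples first")
    rel = table.counts / totals[:, None]
    mean_rel = rel.mean(axis=0)
    keep = np.flatnonzero(mean_rel >= min_mean_rel_abundance)
    if keep.size == 0:
        raise ValidationError("abundance filter would remove every taxon")
    removed = [table.taxon_names[j] for j in np.flatnonzero(mean_rel < min_mean_rel_abundance)]
    report = FilterReport(taxa_removed_abundance=removed,
                          thresholds={"min_mean_rel_abundance": min_mean_rel_abundance})
    return table.select_taxa(keep), report


def tfidf_scores(table: OtuTable) -> dict[str, float]:
    """Corpus-level tf-idf per taxon: total count × ln(D / document frequency).

    ``df(w)`` counts the samples where the taxon is observed; a taxon present
    in every sample scores exactly 0 (idf = ln 1), and a taxon observed
    nowhere is assigned 0 by convention.
    """
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError("sample with zero total count; filter sparse samples first")
    D = table.n_samples
    tf = table.counts.sum(axis=0).astype(float)
    df = (table.counts > 0).sum(axis=0)
    scores = {}
    for j, name in enumerate(table.taxon_names):
        scores[name] = 0.0 if df[j] == 0 else float(tf[j] * math.log(D / df[j]))
    return scores


def select_vocabulary(table: OtuTable, mode: str,
                      value: float) -> tuple[OtuTable, FilterReport]:
    """Select the modeling vocabulary by tf-idf score.

    ``mode="min_score"`` keeps taxa with score strictly greater than
    ``value``; ``mode="top_n"`` keeps the ``value`` highest-scoring taxa, ties
    broken by taxon name ascending.  Asking for more taxa than exist keeps all
    of them and records a warning in the report.
    """
    scores = tfidf_scores(table)
    warnings: list[str] = []
    if mode == "min_score":
        keep = [j for j, name in enumerate(table.taxon_names) if scores[name] > value]
    elif mode == "top_n":
        n = int(value)
        if n > table.n_taxa:
            warnings.append(f"top_n={n} exceeds {table.n_taxa} taxa; keeping all")
            n = table.n_taxa
        order = sorted(range(table.n_taxa),
                       key=lambda j: (-scores[table.taxon_names[j]], table.taxon_names[j]))
        keep = sorted(order[:n])
    else:
        raise ValidationError(f"unknown vocabulary mode {mode!r}")
    if not keep:
        raise ValidationError("vocabulary selection would remove every taxon")
    kept = set(keep)
    removed = [table.taxon_names[j] for j in range(table.n_taxa) if j not in kept]
    report = FilterReport(taxa_removed_tfidf=removed,
                          thresholds={"vocab_mode": mode, "vocab_value": value},
                          warnings=warnings)
    return table.select_taxa(keep), report


def preprocess_table(table: OtuTable, min_taxa: int = 2, min_prevalence: int = 2,
                     min_mean_rel_abundance: float = 1e-4,
                     vocab_mode: str | None = None,
                     vocab_value: float | None = None) -> tuple[OtuTable, FilterReport]:
    """Standard filtering pipeline: sparse samples → rare taxa → low abundance
    → optional vocabulary selection.  Returns the filtered table and a merged
    report in which every removed name is attributed to the first rule that
    removed it."""
    table, report = filter_sparse_samples(table, min_taxa)
    table, r = filter_rare_taxa(table, min_prevalence)
    report = report.merge(r)
    table, r = filter_low_abundance(table, min_mean_rel_abundance)
    report = report.merge(r)
    if vocab_mode is not None:
        if vocab_value is None:
            raise ValidationError("vocab_mode given without vocab_value")
        table, r = select_vocabulary(table, vocab_mode, vocab_value)
        report = report.merge(r)
    return table, report
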