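import math

import numpy as np
import pytest

from otutopics import (OtuTable, ValidationError, filter_low_abundance,
                       filter_rare_taxa, filter_sparse_samples, preprocess_table,
                       select_vocabulary, tfidf_scores)
from _helpers import make_random_table


def test_rare_taxon_removed_by_prevalence():
    table = OtuTable(["s1", "s2", "s3", "s4"], ["a", "b"],
                     [[1, 3], [0, 2], [0, 1], [0, 4]])
    out, report = filter_rare_taxa(table, min_prevalence=2)
    assert out.taxon_names == ["b"]
    assert report.taxa_removed_prevalence == ["a"]
    assert out.sample_ids == table.sample_ids


def test_prevalence_one_is_identity(rng):
    table = make_random_table(rng, 6, 5)
    out, _ = filter_rare_taxa(table, 1)
    assert np.array_equal(out.counts, table.counts)


def test_prevalence_filter_matches_brute_force(rng):
    table = make_random_table(rng, 20, 10, zero_frac=0.6)
    out, _ = filter_rare_taxa(table, 5)
    expected = [name for j, name in enumerate(table.taxon_names)
                if sum(table.counts[d, j] > 0 for d in range(20)) >= 5]
    assert out.taxon_names == expected


def test_sparse_sample_removed_by_richness():
    table = OtuTable(["s1", "s2"], ["a", "b", "c"], [[4, 0, 0], [1, 2, 3]])
    out, report = filter_sparse_samples(table, min_taxa=2)
    assert out.sample_ids == ["s2"]
    assert report.samples_removed == ["s1"]


def test_richness_filter_matches_brute_force(rng):
    table = make_random_table(rng, 15, 8, zero_frac=0.7)
    out, _ = filter_sparse_samples(table, 3)
    expected = [sid for d, sid in enumerate(table.sample_ids)
                if (table.counts[d] > 0).sum() >= 3]
    assert out.sample_ids == expected


def test_low_abundance_filter_arithmetic():
    counts = np.full((4, 2), 0)
    counts[:, 1] = [99, 100, 100, 100]
    counts[0, 0] = 1  # mean rel abundance (1/100)/4 = 0.0025
    table = OtuTable([f"s{d}" for d in range(4)], ["rare", "common"], counts)
    out, report = filter_low_abundance(table, 0.01)
    assert report.taxa_removed_abundance == ["rare"]
    out2, report2 = filter_low_abundance(table, 0.0)
    assert np.array_equal(out2.counts, table.counts)


def test_low_abundance_matches_brute_force(rng):
    table = make_random_table(rng, 12, 9)
    thr = 0.08
    out, _ = filter_low_abundance(table, thr)
    totals = table.counts.sum(axis=1)
    expected = [name for j, name in enumerate(table.taxon_names)
                if np.mean(table.counts[:, j] / totals) >= thr]
    assert out.taxon_names == expected


def test_low_abundance_rejects_zero_total_sample():
    table = OtuTable(["s1", "s2"], ["a", "b"], [[0, 0], [1, 2]])
    with pytest.raises(ValidationError, match="zero total"):
        filter_low_abundance(table, 0.01)


def test_tfidf_formula_and_homogeneity():
    # taxon "everywhere" present in all 4 samples -> idf 0; "once" has
    # total count 5 in one of four samples -> 5 ln 4
    table = OtuTable([f"s{d}" for d in range(4)], ["everywhere", "once"],
                     [[2, 5], [3, 0], [1, 0], [4, 0]])
    scores = tfidf_scores(table)
    assert scores["everywhere"] == 0.0
    assert scores["once"] == pytest.approx(5 * math.log(4), abs=1e-12)
    doubled = OtuTable(table.sample_ids, table.taxon_names, table.counts * 2)
    assert tfidf_scores(doubled)["once"] == pytest.approx(2 * scores["once"])


def test_min_score_zero_removes_exactly_ubiquitous_taxa(rng):
    table = make_random_table(rng, 10, 8, zero_frac=0.3)
    out, report = select_vocabulary(table, "min_score", 0.0)
    ubiquitous = [name for j, name in enumerate(table.taxon_names)
                  if (table.counts[:, j] > 0).all()]
    assert report.taxa_removed_tfidf == ubiquitous


def test_top_n_matches_sort_oracle(rng):
    table = make_random_table(rng, 10, 12, zero_frac=0.5)
    out, _ = select_vocabulary(table, "top_n", 5)
    scores = tfidf_scores(table)
    ranked = sorted(table.taxon_names, key=lambda n: (-scores[n], n))[:5]
    assert sorted(out.taxon_names) == sorted(ranked)
    assert out.n_taxa == 5


def test_top_n_all_is_identity_and_overflow_warns(rng):
    table = make_random_table(rng, 6, 5)
    out, _ = select_vocabulary(table, "top_n", table.n_taxa)
    assert out.taxon_names == table.taxon_names
    out2, report = select_vocabulary(table, "top_n", 99)
    assert out2.taxon_names == table.taxon_names and report.warnings


@pytest.mark.parametrize("op", [
    lambda t: filter_rare_taxa(t, 3),
    lambda t: filter_sparse_samples(t, 3),
    lambda t: filter_low_abundance(t, 0.05),
    lambda t: select_vocabulary(t, "top_n", 6),
])
def test_filters_idempotent_and_do_not_modify_surviving_counts(rng, op):
    table = make_random_table(rng, 14, 10, zero_frac=0.5)
    once, _ = op(table)
    twice, _ = op(once)
    assert once.sample_ids == twice.sample_ids
    assert once.taxon_names == twice.taxon_names
    assert np.array_equal(once.counts, twice.counts)
    # surviving cells equal the original cells
    rows = [table.sample_ids.index(s) for s in once.sample_ids]
    cols = [table.taxon_names.index(t) for t in once.taxon_names]
    assert np.array_equal(once.counts, table.counts[np.ix_(rows, cols)])


def test_pipeline_report_partitions_input_names(rng):
    table = make_random_table(rng, 20, 12, zero_frac=0.7)
    out, report = preprocess_table(table, min_taxa=2, min_prevalence=3,
                                   min_mean_rel_abundance=0.01,
                                   vocab_mode="top_n", vocab_value=6)
    removed_taxa = (report.taxa_removed_prevalence + report.taxa_removed_abundance
                    + report.taxa_removed_tfidf)
    assert len(set(removed_taxa)) == len(removed_taxa)  # disjoint attribution
    assert sorted(removed_taxa + out.taxon_names) == sorted(table.taxon_names)
    assert sorted(report.samples_removed + out.sample_ids) == sorted(table.sample_ids)
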