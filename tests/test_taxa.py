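"""Partitioning, filtering and overlap counting."""

import numpy as np
import pandas as pd
import pytest

from rarecycle import (
    classify_taxa,
    otu_overlap,
    phylum_aggregate,
    prevalence_filter_top,
    relative_abundance,
    subset_by_class,
)
from rarecycle.tables import OTUTable


def _table(counts: np.ndarray, taxonomy=None) -> OTUTable:
    counts = np.atleast_2d(counts)
    frame = pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(counts.shape[0])],
        columns=[f"o{j}" for j in range(counts.shape[1])],
    )
    return OTUTable(
        counts=frame,
        crop=pd.Series("x", index=frame.index),
        taxonomy=None if taxonomy is None else pd.Series(taxonomy, index=frame.columns),
    )


def test_relative_abundance_simple():
    rel = relative_abundance(_table([[10, 30, 60]]))
    assert np.allclose(rel.to_numpy(), [[0.1, 0.3, 0.6]])


def test_relative_abundance_single_otu():
    rel = relative_abundance(_table([[7], [3]]))
    assert np.allclose(rel.to_numpy(), 1.0)


def test_relative_abundance_rows_sum_to_one():
    rng = np.random.default_rng(0)
    rel = relative_abundance(_table(rng.integers(1, 100, size=(20, 50))))
    assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-12)


def test_zero_sum_sample_named_in_error():
    with pytest.raises(ValueError, match="s1"):
        relative_abundance(_table([[1, 2], [0, 0]]))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "mean_rel,expected",
    [(1e-3, "abundant"), (5e-6, "rare"), (1e-4, "intermediate")],
)
def test_classify_thresholds(mean_rel, expected):
    """0.1% -> abundant, 0.0005% -> rare, 0.01% -> intermediate."""
    depth = 10**7
    other = depth - int(mean_rel * depth)
    table = _table([[int(mean_rel * depth), other]])
    classes = classify_taxa(table)
    assert classes.labels["o0"] == expected


def test_classify_bad_thresholds():
    with pytest.raises(ValueError, match="rare_max"):
        classify_taxa(_table([[1, 2]]), rare_max=0.1, abundant_min=0.01)


def test_classify_invariant_to_sample_rescaling():
    rng = np.random.default_rng(1)
    counts = rng.integers(0, 2000, size=(6, 40))
    counts[:, 0] += 1
    a = classify_taxa(_table(counts))
    b = classify_taxa(_table(counts * np.array([1, 10, 3, 7, 2, 5])[:, None]))
    assert (a.labels == b.labels).all()


def test_class_counts_partition_all_otus():
    rng = np.random.default_rng(2)
    counts = rng.integers(0, 100, size=(5, 30)) + 1
    classes = classify_taxa(_table(counts), rare_max=0.01, abundant_min=0.05)
    assert sum(classes.counts.values()) == 30


# ---------------------------------------------------------------------------
# Subsetting
# ---------------------------------------------------------------------------

def test_subset_by_class_preserves_counts():
    counts = np.array([[980000, 900000, 1, 2, 3], [999999, 950000, 2, 1, 0]])
    table = _table(counts)
    classes = classify_taxa(table)
    rare = subset_by_class(table, classes, "rare")
    assert rare.n_samples == 2
    assert (rare.counts.sum(axis=0) == table.counts[rare.otu_ids].sum(axis=0)).all()


def test_subset_empty_class_errors():
    table = _table([[50, 50]])
    classes = classify_taxa(table)  # both OTUs abundant
    with pytest.raises(ValueError, match="threshold"):
        subset_by_class(table, classes, "rare")


# ---------------------------------------------------------------------------
# Prevalence filter
# ---------------------------------------------------------------------------

def test_filter_top_counts_otus():
    table = _table([np.arange(1, 11)])
    assert prevalence_filter_top(table, 0.8).n_otus == 8


def test_filter_top_identity_at_one():
    rng = np.random.default_rng(3)
    table = _table(rng.integers(1, 50, size=(4, 9)))
    kept = prevalence_filter_top(table, 1.0)
    assert sorted(kept.otu_ids) == sorted(table.otu_ids)


def test_filter_top_rank_oracle():
    """5 OTUs at (5,4,3,2,1)% of a fixed total: ranks 1-4 retained."""
    table = _table([[50, 40, 30, 20, 10]])
    kept = prevalence_filter_top(table, 0.8)
    assert kept.otu_ids == ["o0", "o1", "o2", "o3"]


def test_filter_top_tie_break_lexicographic():
    table = _table([[5, 5, 5, 5]])
    kept = prevalence_filter_top(table, 0.5)
    assert kept.otu_ids == ["o0", "o1"]


# ---------------------------------------------------------------------------
# Phylum aggregation
# ---------------------------------------------------------------------------

def test_phylum_pooling():
    table = _table([[40, 60]], taxonomy=["k__B;p__X", "k__B;p__X"])
    fractions, top, pooled = phylum_aggregate(table)
    assert np.allclose(fractions["X"], 1.0)
    assert top == ["X"]


def test_phylum_fractions_sum_to_one():
    rng = np.random.default_rng(4)
    tax = [f"k__B;p__P{rng.integers(5)}" for _ in range(30)]
    table = _table(rng.integers(1, 100, size=(6, 30)), taxonomy=tax)
    fractions, _, pooled = phylum_aggregate(table)
    assert np.allclose(fractions.sum(axis=1), 1.0, atol=1e-12)
    assert np.allclose(pooled.sum(axis=1), 1.0, atol=1e-12)


def test_twelve_phyla_reports_ten_plus_other():
    tax = [f"k__B;p__P{j:02d}" for j in range(12)]
    table = _table([np.arange(12, 0, -1)], taxonomy=tax)
    _, top, pooled = phylum_aggregate(table)
    assert len(top) == 10
    assert "Other" in pooled.columns


def test_unparseable_taxonomy_is_unclassified():
    table = _table([[10, 10]], taxonomy=["gibberish", "k__B;p__X"])
    fractions, _, _ = phylum_aggregate(table)
    assert "unclassified" in fractions.columns


# ---------------------------------------------------------------------------
# Overlap
# ---------------------------------------------------------------------------

def _group(otus_present, all_otus):
    counts = pd.DataFrame(
        [[1 if o in otus_present else 0 for o in all_otus]],
        index=["s"], columns=all_otus,
    )
    return OTUTable(counts=counts, crop=pd.Series("x", index=["s"]))


def test_overlap_two_groups():
    all_otus = ["o1", "o2", "o3"]
    result = otu_overlap({"A": _group({"o1", "o2"}, all_otus), "B": _group({"o2", "o3"}, all_otus)})
    assert result["unique"] == {"A": 1, "B": 1}
    assert result["shared_all"] == 1


def test_overlap_identical_groups():
    all_otus = ["o1", "o2"]
    result = otu_overlap({"A": _group({"o1", "o2"}, all_otus), "B": _group({"o1", "o2"}, all_otus)})
    assert result["shared_all"] == 2
    assert result["unique"] == {"A": 0, "B": 0}


def test_overlap_needs_two_groups():
    with pytest.raises(ValueError, match="two groups"):
        otu_overlap({"A": _group({"o1"}, ["o1"])})


def test_overlap_matches_set_algebra():
    """Random 4-group fixture vs direct set computation."""
    rng = np.random.default_rng(5)
    all_otus = [f"o{j}" for j in range(40)]
    sets = {g: {o for o in all_otus if rng.random() < 0.4} for g in "ABCD"}
    result = otu_overlap({g: _group(s, all_otus) for g, s in sets.items()})
    # exclusive intersections must sum to the union size
    union = set().union(*sets.values())
    assert sum(result["exclusive_intersections"].values()) == len(union)
    for g in "ABCD":
        others = set().union(*(sets[h] for h in "ABCD" if h != g))
        assert result["unique"][g] == len(sets[g] - others)
    assert result["shared_all"] == len(set.intersection(*sets.values()))
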