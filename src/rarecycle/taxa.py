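"""Rare/abundant taxa partitioning and composition summaries.

The rare-biosphere convention used throughout: an OTU is *abundant* when its
mean relative abundance across all samples exceeds 0.05% and *rare* when it
falls below 0.001%; everything in between is *intermediate* and belongs to
neither sub-community. Thresholds are expressed as fractions (5e-4 / 1e-5)
and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .tables import OTUTable

__all__ = [
    "AbundanceClass",
    "relative_abundance",
    "classify_taxa",
    "subset_by_class",
    "prevalence_filter_top",
    "phylum_aggregate",
    "otu_overlap",
]

RARE_MAX_DEFAULT = 1e-5       # 0.001 %
ABUNDANT_MIN_DEFAULT = 5e-4   # 0.05 %


def relative_abundance(table: OTUTable) -> pd.DataFrame:
    """Per-sample relative abundances; every row sums to one.

    Raises if any sample has zero total count (the fraction is undefined).
    """
    totals = table.counts.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with zero total count: {zero[:5]}")
    return table.counts.div(totals, axis=0)


@dataclass
class AbundanceClass:
    """Per-OTU abundance class labels with the thresholds that produced them."""

    labels: pd.Series            # otu_id -> {"rare", "intermediate", "abundant"}
    mean_rel_abundance: pd.Series
    rare_max: float
    abundant_min: float

    @property
    def counts(self) -> dict[str, int]:
        c = self.labels.value_counts()
        return {k: int(c.get(k, 0)) for k in ("rare", "intermediate", "abundant")}

    def ids(self, which: str) -> list[str]:
        return list(self.labels.index[self.labels == which])


def classify_taxa(
    table: OTUTable,
    rare_max: float = RARE_MAX_DEFAULT,
    abundant_min: float = ABUNDANT_MIN_DEFAULT,
) -> AbundanceClass:
    """Label each OTU rare/intermediate/abundant by mean relative abundance.

    An OTU is abundant iff its mean-across-samples relative abundance is
    strictly above ``abundant_min``, rare iff strictly below ``rare_max``.
    """
    if rare_max >= abundant_min:
        raise ValueError("rare_max must be smaller than abundant_min")
    mean_rel = relative_abundance(table).mean(axis=0)
    labels = pd.Series("intermediate", index=mean_rel.index, dtype=object)
    labels[mean_rel > abundant_min] = "abundant"
    labels[mean_rel < rare_max] = "rare"
    return AbundanceClass(
        labels=labels,
        mean_rel_abundance=mean_rel,
        rare_max=rare_max,
        abundant_min=abundant_min,
    )


def subset_by_class(table: OTUTable, classes: AbundanceClass, which: str) -> OTUTable:
    """Column subset of the table holding one sub-community, counts unmodified."""
    if which not in ("rare", "abundant", "intermediate"):
        raise ValueError(f"unknown class {which!r}")
    ids = classes.ids(which)
    if not ids:
        raise ValueError(
            f"no OTUs classified {which!r}; review thresholds "
            f"(rare_max={classes.rare_max}, abundant_min={classes.abundant_min})"
        )
    return table.subset_otus(ids)


def prevalence_filter_top(table: OTUTable, keep_fraction: float = 0.8) -> OTUTable:
    """Keep the top ``keep_fraction`` of OTU identities by mean relative abundance.

    Retains ceil(keep_fraction * n_otus) OTUs, ranked by mean relative
    abundance descending; ties broken lexicographically on OTU id so the
    selection is deterministic.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    mean_rel = relative_abundance(table).mean(axis=0)
    n_keep = int(np.ceil(keep_fraction * table.n_otus))
    order = sorted(mean_rel.index, key=lambda o: (-mean_rel[o], o))
    return table.subset_otus(order[:n_keep])


def _phylum_of(lineage: str) -> str:
    """Extract the phylum token from a semicolon-delimited lineage string."""
    for rank in str(lineage).split(";"):
        rank = rank.strip()
        if rank.lower().startswith(("p__", "p:")):
            name = rank[3:].strip()
            return name if name else "unclassified"
    ranks = [r.strip() for r in str(lineage).split(";") if r.strip()]
    if len(ranks) >= 2:  # no rank prefixes: take the second field as phylum
        return ranks[1]
    return "unclassified"


def phylum_aggregate(table: OTUTable, top_k: int = 10):
    """Phylum x sample relative-abundance matrix plus the top-k phylum list.

    Returns ``(fractions, top)`` where ``fractions`` sums to one per sample
    and ``top`` lists the ``top_k`` phyla by overall mean abundance; the
    remainder is pooled as ``"Other"`` in the companion ``pooled`` frame.
    """
    rel = relative_abundance(table)
    phyla = table.taxonomy.map(_phylum_of)
    fractions = rel.T.groupby(phyla).sum().T  # samples x phyla
    top = (
        fractions.mean(axis=0)
        .sort_values(ascending=False)
        .head(top_k)
        .index.tolist()
    )
    pooled = fractions[top].copy()
    rest = fractions.drop(columns=top)
    if not rest.empty:
        pooled["Other"] = rest.sum(axis=1)
    return fractions, top, pooled


def otu_overlap(tables: dict[str, OTUTable]) -> dict:
    """Venn/UpSet style presence overlap between named groups of samples.

    An OTU is present in a group when its total count there is positive.
    Returns per-group totals, per-group unique counts, and the size of every
    non-empty combination of groups (exclusive intersections, UpSet style)
    plus the full shared core.
    """
    if len(tables) < 2:
        raise ValueError("otu_overlap needs at least two groups")
    presence = {
        name: set(t.counts.columns[t.counts.sum(axis=0) > 0])
        for name, t in tables.items()
    }
    names = list(presence)
    totals = {n: len(presence[n]) for n in names}
    unique = {
        n: len(presence[n] - set().union(*(presence[m] for m in names if m != n)))
        for n in names
    }
    intersections = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(presence[n] for n in combo))
            outside = set().union(
                *(presence[n] for n in names if n not in combo), set()
            )
            intersections[combo] = len(inside - outside)
    shared_all = len(set.intersection(*presence.values()))
    return {
        "totals": totals,
        "unique": unique,
        "exclusive_intersections": intersections,
        "shared_all": shared_all,
    }
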