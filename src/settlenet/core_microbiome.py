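"""Core-microbiome filtering and set overlaps.

The core microbiome of a settlement category keeps ASVs that are both
prevalent (nonzero in at least 2/3 of the category's samples, rounded
up) and non-negligible (mean relative abundance within the category of
at least 0.01%). Category cores are then recombined — union of retained
ASVs over all of the dataset's samples, raw counts untouched — as the
substrate for network inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .io import CountTable, DataError


@dataclass
class CoreSet:
    category: str
    retained: list[str]
    prevalence_min: float
    abundance_min: float
    abundance_mode: str = "mean"


def relative_abundance(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample total-sum scaling; every column sums to 1."""
    df = table.counts if isinstance(table, CountTable) else table
    totals = df.sum(axis=0)
    zero = totals == 0
    if zero.any():
        raise DataError(f"all-zero sample(s): {list(df.columns[zero])}")
    return df / totals


def core_filter(table: CountTable, category: str, prevalence_min: float = 2 / 3,
                abundance_min: float = 1e-4, abundance_mode: str = "mean") -> CoreSet:
    """Retain ASVs passing joint prevalence and relative-abundance thresholds.

    ``table`` must already be restricted to the category's samples. An ASV is
    retained iff it is nonzero in >= ceil(prevalence_min * n_samples) samples
    and (mode "mean") its mean relative abundance across those samples is
    >= abundance_min, or (mode "any-sample") it reaches abundance_min in at
    least one sample.
    """
    if abundance_mode not in ("mean", "any-sample"):
        raise ValueError(f"unknown abundance_mode {abundance_mode!r}")
    n = table.shape[1]
    if n == 0:
        raise DataError(f"category {category!r} has no samples")
    if n < 3:
        raise DataError(f"category {category!r} has fewer than 3 samples ({n})")
    need = math.ceil(prevalence_min * n)
    prevalence_ok = (table.counts > 0).sum(axis=1) >= need
    rel = relative_abundance(table)
    if abundance_mode == "mean":
        abundance_ok = rel.mean(axis=1) >= abundance_min
    else:
        abundance_ok = (rel >= abundance_min).any(axis=1)
    retained = list(table.counts.index[prevalence_ok & abundance_ok])
    return CoreSet(category, retained, prevalence_min, abundance_min, abundance_mode)


def recombine(cores: list[CoreSet], table: CountTable
              ) -> tuple[CountTable, pd.DataFrame]:
    """Union of category cores over all of the dataset's samples.

    Returns the restricted table (raw counts, all samples) and a membership
    frame tagging each retained ASV with the categories whose core holds it.
    """
    if not cores:
        raise DataError("no core sets to recombine")
    universe = set(table.asv_ids)
    for core in cores:
        stray = set(core.retained) - universe
        if stray:
            raise DataError(
                f"core for {core.category!r} references ASVs outside the table: "
                f"{sorted(stray)[:5]}")
    union = [a for a in table.asv_ids if any(a in set(c.retained) for c in cores)]
    if not union:
        raise DataError("recombined core is empty")
    membership = pd.DataFrame(
        {c.category: [a in set(c.retained) for a in union] for c in cores},
        index=pd.Index(union, name="asv_id"))
    membership["categories"] = membership.apply(
        lambda row: ",".join(col for col in membership.columns[:len(cores)] if row[col]),
        axis=1)
    return table.restrict(asv_ids=union), membership


def set_overlaps(named_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive Venn-cell counts for >= 2 named sets.

    Each key is the tuple of set names whose *exclusive* intersection the
    count describes (members of exactly those sets); cells partition the
    union.
    """
    if len(named_sets) < 2:
        raise DataError("need at least 2 named sets")
    names = list(named_sets)
    cells: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(named_sets[c]) for c in combo))
            outside = set.union(set(), *(set(named_sets[n]) for n in names if n not in combo))
            cells[combo] = len(inside - outside)
    return cells
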