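"""Larval settlement quantification and categorisation.

A tetrapod's settlement success is its share of all larvae that settled
within its tank. Tetrapods are then binned into low / medium / high
settlement categories by fixed fraction intervals (chosen from the
settlement histograms of each conditioning type, supplied as
configuration — the binning itself is not automated). When a pairwise
community test finds two categories indistinguishable they are merged,
and a chi-square test checks whether settlement category covaries with
conditioning time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError

#: Fraction bounds matching the integer-percent bins used for each
#: conditioning type: low 0-32%, medium 33-62%, high 63-100% (aquarium)
#: and low 0-32%, medium 33-55%, high 56-100% (reef).
AQUARIUM_BOUNDS = (0.33, 0.63)
REEF_BOUNDS = (0.33, 0.56)


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered settlement categories over a partition of [0, 1].

    Intervals are half-open [a, b) except the last, which is closed at 1.
    """

    labels: tuple[str, ...] = ("low", "medium", "high")
    bounds: tuple[float, ...] = AQUARIUM_BOUNDS  # interior cut points

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.labels) - 1:
            raise ValueError("need exactly len(labels)-1 interior bounds")
        edges = (0.0, *self.bounds, 1.0)
        if any(later <= earlier for later, earlier in zip(edges[1:], edges[:-1])):
            raise ValueError(f"bounds must be strictly increasing in (0,1): {self.bounds}")

    def assign(self, fraction: float) -> str:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"fraction outside [0,1]: {fraction}")
        for label, hi in zip(self.labels[:-1], self.bounds):
            if fraction < hi:
                return label
        return self.labels[-1]

    def interval(self, label: str) -> tuple[float, float]:
        i = self.labels.index(label)
        edges = (0.0, *self.bounds, 1.0)
        return edges[i], edges[i + 1]


#: Schemes for the two conditioning types.
SCHEMES = {
    "aquarium": CategoryScheme(bounds=AQUARIUM_BOUNDS),
    "reef": CategoryScheme(bounds=REEF_BOUNDS),
}


@dataclass
class SettlementRecord:
    tetrapod_id: str
    tank_id: str
    settled: int
    fraction: float
    category: str | None = None


def settlement_fractions(counts: pd.DataFrame, exclude_controls: bool = False,
                         control_ids: set | None = None) -> list[SettlementRecord]:
    """Per-tetrapod settlement fractions: settled / total settled in the tank.

    ``counts`` has columns tetrapod_id, tank_id, settled. Controls (ids in
    ``control_ids``) are dropped from both numerator and denominator when
    ``exclude_controls`` is set.
    """
    df = counts.copy()
    if exclude_controls:
        control_ids = control_ids or set()
        df = df[~df["tetrapod_id"].isin(control_ids)]
    records: list[SettlementRecord] = []
    for tank, grp in df.groupby("tank_id", sort=False):
        total = int(grp["settled"].sum())
        if total == 0:
            raise DataError(f"tank {tank!r} has zero settled larvae in total")
        for r in grp.itertuples():
            records.append(SettlementRecord(str(r.tetrapod_id), str(tank),
                                            int(r.settled), r.settled / total))
    return records


def categorize(records: list[SettlementRecord], scheme: CategoryScheme) -> list[SettlementRecord]:
    """Label each record with the scheme interval containing its fraction."""
    for rec in records:
        rec.category = scheme.assign(rec.fraction)
    return records


@dataclass
class MergeReport:
    merged_groups: list[tuple[str, ...]]
    label_map: dict[str, str]
    ranges: dict[str, tuple[float, float]]  # merged label -> (min, max) fraction
    warnings: list[str] = field(default_factory=list)


def merge_categories(records: list[SettlementRecord], pairwise_p: dict[frozenset, float],
                     alpha: float = 0.05,
                     category_order: tuple[str, ...] = ("low", "medium", "high"),
                     ) -> tuple[list[SettlementRecord], MergeReport]:
    """Merge categories whose pairwise community test is non-significant.

    ``pairwise_p`` maps frozenset({cat_a, cat_b}) to the (adjusted) p-value of
    the pairwise comparison. Any pair with p > alpha is merged; merges are
    closed transitively (with a warning when transitivity was not already
    present in the pairwise results). The merged group keeps the highest
    constituent label, mirroring how an indistinct medium/high pair is
    reported as high-settlement, and the report carries the min-max fraction
    range of the merged group.
    """
    present = [c for c in category_order if any(r.category == c for r in records)]
    for a in present:
        for b in present:
            if a < b and frozenset((a, b)) not in pairwise_p:
                raise DataError(f"pairwise result missing for categories ({a}, {b})")
    parent = {c: c for c in present}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    nonsig = [(a, b) for a in present for b in present
              if a < b and pairwise_p[frozenset((a, b))] > alpha]
    for a, b in nonsig:
        parent[find(a)] = find(b)

    groups: dict[str, list[str]] = {}
    for c in present:
        groups.setdefault(find(c), []).append(c)
    warnings = []
    for members in groups.values():
        for a in members:
            for b in members:
                if a < b and pairwise_p[frozenset((a, b))] <= alpha:
                    warnings.append(
                        f"categories {a!r} and {b!r} differ (p="
                        f"{pairwise_p[frozenset((a, b))]:.4g}) but are merged transitively")

    label_map: dict[str, str] = {}
    merged_groups: list[tuple[str, ...]] = []
    for members in groups.values():
        members = sorted(members, key=category_order.index)
        label = members[-1]  # highest-settlement constituent names the group
        for m in members:
            label_map[m] = label
        if len(members) > 1:
            merged_groups.append(tuple(members))

    ranges: dict[str, tuple[float, float]] = {}
    for rec in records:
        rec.category = label_map.get(rec.category, rec.category)
    for label in set(label_map.values()):
        fr = [r.fraction for r in records if r.category == label]
        if fr:
            ranges[label] = (min(fr), max(fr))
    return records, MergeReport(merged_groups, label_map, ranges, warnings)


def chi_square(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a category × time table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DataError(f"contingency table must be >=2x2, got shape {obs.shape}")
    if (obs < 0).any():
        raise DataError("contingency table has negative entries")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise DataError("contingency table has a zero marginal row or column")
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def records_to_frame(records: list[SettlementRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.tetrapod_id, r.tank_id, r.settled, r.fraction, r.category) for r in records],
        columns=["tetrapod_id", "tank_id", "settled", "fraction", "category"])
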