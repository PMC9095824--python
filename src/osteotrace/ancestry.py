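"""Regional-ancestry aggregation of called haplogroups.

Haplogroups are mapped to broad maternal-ancestry regions — South Asian,
West Eurasian, East Eurasian — via rule lists of haplogroup labels.  The
default rules encode the standard regional affiliations used for South
Asian cohorts:

* South Asian:   M2-M6, M18, M25, M30-M67, N5, R5-R8, R30-R32, U2a, U2b
* West Eurasian: HV, H, J, K, R0, R1, R2, U1-U5, U7, U8, U9, W, X
* East Eurasian: A, B, C, D, E, F, G, M7-M12, R22, N9

A rule matches a haplogroup when its pattern equals the haplogroup's label
or the label of any of its tree ancestors; among matching rules the most
specific (longest pattern label) wins, so the U2a/U2b carve-out overrides
the broader U1-U5 West Eurasian rule.  Unmatched haplogroups are reported
as Unclassified rather than silently dropped.

Cohort-level enrichment of one region between two cohorts is tested with
Fisher's exact test on the 2x2 focus/non-focus x cohort table; the
two-tailed p-value is the sum of probabilities of all tables (at fixed
margins) no more probable than the observed one.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy import stats

from .haplotree import HaploTree
from .haplocall import EmptyCohortError, HaplogroupCall

SOUTH_ASIAN = "SouthAsian"
WEST_EURASIAN = "WestEurasian"
EAST_EURASIAN = "EastEurasian"
UNCLASSIFIED = "Unclassified"

REGIONS = (SOUTH_ASIAN, WEST_EURASIAN, EAST_EURASIAN, UNCLASSIFIED)

_RANGE_RE = re.compile(r"^([A-Z]+)(\d+)-\1?(\d+)$")


def expand_pattern(pattern: str) -> list[str]:
    """Expand a rule pattern into explicit haplogroup labels.

    ``M30-M67`` -> M30, M31, ..., M67; ``U2a,b`` -> U2a, U2b; a plain
    label passes through.  Lettered sub-clades of a range member are
    covered because matching walks the tree's ancestor path.
    """
    pattern = pattern.strip()
    m = _RANGE_RE.match(pattern)
    if m:
        prefix, lo, hi = m.group(1), int(m.group(2)), int(m.group(3))
        if hi < lo:
            raise ValueError(f"descending range {pattern!r}")
        return [f"{prefix}{i}" for i in range(lo, hi + 1)]
    if "," in pattern:  # "U2a,b" shorthand: shared stem, letter suffixes
        stem_match = re.match(r"^([A-Z]+\d*)([a-z])((?:,[a-z])+)$", pattern)
        if stem_match:
            stem = stem_match.group(1)
            letters = [stem_match.group(2)] + stem_match.group(3).split(",")[1:]
            return [stem + letter for letter in letters]
        return [p.strip() for p in pattern.split(",")]
    return [pattern]


@dataclass
class RegionMap:
    """Ordered rules (haplogroup label -> region), most specific match wins."""

    rules: list[tuple[str, str]]
    _by_label: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_label = {}
        for pattern, region in self.rules:
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r}")
            for label in expand_pattern(pattern):
                self._by_label[label] = region

    @property
    def labels(self) -> dict[str, str]:
        return dict(self._by_label)

    def unresolved_labels(self, tree: HaploTree) -> list[str]:
        """Rule labels that resolve to no tree node (flagged, not fatal)."""
        return sorted(lab for lab in self._by_label if lab not in tree)


DEFAULT_RULES: list[tuple[str, str]] = [
    ("M2-M6", SOUTH_ASIAN), ("M18", SOUTH_ASIAN), ("M25", SOUTH_ASIAN),
    ("M30-M67", SOUTH_ASIAN), ("N5", SOUTH_ASIAN), ("R5-R8", SOUTH_ASIAN),
    ("R30-R32", SOUTH_ASIAN), ("U2a,b", SOUTH_ASIAN),
    ("HV", WEST_EURASIAN), ("H", WEST_EURASIAN), ("J", WEST_EURASIAN),
    ("K", WEST_EURASIAN), ("R0", WEST_EURASIAN), ("R1", WEST_EURASIAN),
    ("R2", WEST_EURASIAN), ("U1-U5", WEST_EURASIAN), ("U7", WEST_EURASIAN),
    ("U8", WEST_EURASIAN), ("U9", WEST_EURASIAN), ("W", WEST_EURASIAN),
    ("X", WEST_EURASIAN),
    # "A-G" is an alphabetic macro-clade list, not a numeric range
    ("A", EAST_EURASIAN), ("B", EAST_EURASIAN), ("C", EAST_EURASIAN),
    ("D", EAST_EURASIAN), ("E", EAST_EURASIAN), ("F", EAST_EURASIAN),
    ("G", EAST_EURASIAN), ("M7-M12", EAST_EURASIAN), ("R22", EAST_EURASIAN),
    ("N9", EAST_EURASIAN),
]


def default_region_map() -> RegionMap:
    return RegionMap(list(DEFAULT_RULES))


@dataclass
class AncestryProportions:
    cohort_id: str
    counts: dict[str, int]
    fractions: dict[str, float]


def assign_region(label: str, region_map: RegionMap, tree: HaploTree) -> str:
    """Region of ``label``: longest matching rule label on its ancestor path."""
    node = tree.node(label)  # raises UnknownHaplogroupError
    rules = region_map.labels
    best_region = UNCLASSIFIED
    best_len = -1
    for ancestor in node.path_from_root():
        region = rules.get(ancestor.label)
        if region is not None and len(ancestor.label) > best_len:
            best_region = region
            best_len = len(ancestor.label)
    return best_region


def ancestry_proportions(
    calls: Sequence[HaplogroupCall],
    region_map: RegionMap,
    tree: HaploTree,
    cohort_id: str = "cohort",
) -> AncestryProportions:
    if not calls:
        raise EmptyCohortError("cannot compute proportions of an empty cohort")
    counts = {r: 0 for r in REGIONS}
    for call in calls:
        counts[assign_region(call.best, region_map, tree)] += 1
    n = len(calls)
    fractions = {r: c / n for r, c in counts.items()}
    return AncestryProportions(cohort_id=cohort_id, counts=counts, fractions=fractions)


def compare_ancestry(
    counts_a: dict[str, int],
    counts_b: dict[str, int],
    focus: str,
) -> float:
    """Two-tailed Fisher's exact p for enrichment of ``focus`` in cohort A vs B."""
    total_a, total_b = sum(counts_a.values()), sum(counts_b.values())
    if total_a == 0 or total_b == 0:
        raise EmptyCohortError("both cohorts must be non-empty")
    fa, fb = counts_a.get(focus, 0), counts_b.get(focus, 0)
    table = [[fa, total_a - fa], [fb, total_b - fb]]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# I/O


def read_region_map_csv(path: str) -> RegionMap:
    """Region map CSV with columns ``pattern,region``."""
    rules: list[tuple[str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rules.append((row["pattern"], row["region"]))
    return RegionMap(rules)


def write_proportions_csv(props: Iterable[AncestryProportions], path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cohort_id", "region", "count", "fraction"])
        for p in props:
            for region in REGIONS:
                writer.writerow(
                    [p.cohort_id, region, p.counts[region],
                     f"{p.fractions[region]:.6f}"]
                )
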