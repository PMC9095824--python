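"""Haplogroup assignment from panel genotypes by Kulczynski scoring.

Each sample's genotype vector over the panel sites is scored against the
expected variant profile of every haplogroup in the tree.  The score is the
Kulczynski similarity — the mean of

* recall:    matched / expected derived states of the haplogroup, and
* precision: matched / observed derived calls of the sample,

both restricted to panel positions with a non-missing call, with the
convention 0/0 = 1.  Missing calls (genotyping dropouts) are excluded from
every term: a dropout is uninformative, not evidence of the reference
state.  Extra derived calls are penalised only through the precision term;
no explicit genotyping-error model is fitted, since panel-scale data are
too sparse for likelihoods.

Ties are broken toward the deeper (more specific) haplogroup, then
lexicographically, so output is deterministic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .haplotree import (
    DEFAULT_MACRO_SET,
    ExpectedProfile,
    HaploTree,
    PanelDefinition,
    expected_profile,
    macro_of,
)

MISSING = None

#: Aliases accepted for a missing call in genotype CSV input.
_MISSING_TOKENS = {"", "N", "NA", ".", "-"}


class NoEvaluablePositionsError(ValueError):
    """A sample has no non-missing call at any panel position."""


class EmptyCohortError(ValueError):
    """A cohort-level operation received zero samples."""


@dataclass
class SampleGenotypes:
    """Per-sample allele calls at panel positions (``None`` = missing)."""

    sample_id: str
    calls: dict[int, str | None]


@dataclass
class HaplogroupCall:
    sample_id: str
    best: str
    score: float
    n_expected: int
    n_matched: int
    n_observed_derived: int
    alternatives: list[tuple[str, float]] = field(default_factory=list)


def _score_counts(
    sample: SampleGenotypes,
    profile: ExpectedProfile,
    panel_positions: frozenset[int],
    reference: Mapping[int, str],
) -> tuple[int, int, int]:
    """(n_expected, n_matched, n_observed_derived) at evaluable positions."""
    n_expected = n_matched = n_observed = 0
    for pos, call in sample.calls.items():
        if call is MISSING or pos not in panel_positions:
            continue
        ref = reference.get(pos)
        if ref is None:
            raise ValueError(
                f"no reference allele known for panel position {pos}; "
                "supply a reference sequence or a tree covering it"
            )
        expected_state = profile.states.get(pos, ref)
        expected_derived = expected_state != ref
        observed_derived = call != ref
        if expected_derived:
            n_expected += 1
            if observed_derived and call == expected_state:
                n_matched += 1
        if observed_derived:
            n_observed += 1
    return n_expected, n_matched, n_observed


def _kulczynski(n_expected: int, n_matched: int, n_observed: int) -> float:
    recall = n_matched / n_expected if n_expected else 1.0
    precision = n_matched / n_observed if n_observed else 1.0
    return 0.5 * (recall + precision)


def score_haplogroup(
    sample: SampleGenotypes,
    label: str,
    tree: HaploTree,
    panel: PanelDefinition,
    reference: Mapping[int, str] | None = None,
) -> float:
    """Kulczynski similarity of ``sample`` to haplogroup ``label`` in [0, 1]."""
    reference = reference if reference is not None else tree.reference_alleles()
    panel_positions = panel.positions
    evaluable = [
        p for p, c in sample.calls.items()
        if c is not MISSING and p in panel_positions
    ]
    if not evaluable:
        raise NoEvaluablePositionsError(
            f"sample {sample.sample_id!r} has no evaluable panel position"
        )
    profile = expected_profile(tree, label)
    return _kulczynski(*_score_counts(sample, profile, panel_positions, reference))


def call_haplogroup(
    sample: SampleGenotypes,
    tree: HaploTree,
    panel: PanelDefinition,
    reference: Mapping[int, str] | None = None,
    k_alternatives: int = 5,
) -> HaplogroupCall:
    """Best haplogroup = argmax score over every tree node.

    The search is exhaustive over all nodes; ties broken by greater path
    depth, then lexicographic label.
    """
    reference = reference if reference is not None else tree.reference_alleles()
    panel_positions = panel.positions
    if not any(
        c is not MISSING and p in panel_positions
        for p, c in sample.calls.items()
    ):
        raise NoEvaluablePositionsError(
            f"sample {sample.sample_id!r} has no evaluable panel position"
        )
    scored: list[tuple[float, int, str, tuple[int, int, int]]] = []
    for node in tree:
        counts = _score_counts(
            sample, expected_profile(tree, node.label), panel_positions, reference
        )
        scored.append((_kulczynski(*counts), node.depth, node.label, counts))
    # sort: score desc, depth desc, label asc
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    best_score, _, best_label, best_counts = scored[0]
    return HaplogroupCall(
        sample_id=sample.sample_id,
        best=best_label,
        score=best_score,
        n_expected=best_counts[0],
        n_matched=best_counts[1],
        n_observed_derived=best_counts[2],
        alternatives=[(lab, sc) for sc, _, lab, _ in scored[1 : 1 + k_alternatives]],
    )


def call_cohort(
    samples: Iterable[SampleGenotypes],
    tree: HaploTree,
    panel: PanelDefinition,
    reference: Mapping[int, str] | None = None,
    macro_set: frozenset[str] = DEFAULT_MACRO_SET,
) -> tuple[list[HaplogroupCall], dict[str, float], dict[str, float]]:
    """Call every sample; return (calls, haplogroup freqs, macrohaplogroup freqs).

    Frequencies are counts / n_samples and sum to 1 over called labels.
    """
    samples = list(samples)
    if not samples:
        raise EmptyCohortError("cohort is empty")
    reference = reference if reference is not None else tree.reference_alleles()
    calls = [call_haplogroup(s, tree, panel, reference) for s in samples]
    n = len(calls)
    freqs: dict[str, float] = {}
    macro_freqs: dict[str, float] = {}
    for c in calls:
        freqs[c.best] = freqs.get(c.best, 0.0) + 1.0 / n
        macro = macro_of(tree, c.best, macro_set)
        macro_freqs[macro] = macro_freqs.get(macro, 0.0) + 1.0 / n
    return calls, freqs, macro_freqs


# ---------------------------------------------------------------------------
# I/O


def read_genotype_csv(path: str) -> list[SampleGenotypes]:
    """Long-format CSV: sample_id, position, allele (missing: empty or "N")."""
    by_sample: dict[str, dict[int, str | None]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            sid = row["sample_id"]
            pos = int(row["position"])
            allele = (row.get("allele") or "").strip().upper()
            call = MISSING if allele in _MISSING_TOKENS else allele
            if call is not MISSING and call not in "ACGT":
                raise ValueError(
                    f"sample {sid}: invalid allele {allele!r} at {pos}"
                )
            by_sample.setdefault(sid, {})[pos] = call
    return [SampleGenotypes(sid, calls) for sid, calls in by_sample.items()]


def read_genotype_vcf(path: str, panel: PanelDefinition) -> list[SampleGenotypes]:
    """Read calls from a VCF; sites outside the panel are ignored.

    Diploid genotypes are collapsed to a haploid call by majority allele
    (ties resolve to the REF allele); uncalled genotypes become missing.
    """
    import pysam

    panel_positions = panel.positions
    with pysam.VariantFile(path) as vcf:
        sample_ids = list(vcf.header.samples)
        calls: dict[str, dict[int, str | None]] = {s: {} for s in sample_ids}
        for rec in vcf:
            if rec.pos not in panel_positions:
                continue
            alleles_at_site = (rec.ref,) + tuple(rec.alts or ())
            for sid in sample_ids:
                gt = rec.samples[sid].get("GT", ())
                observed = [alleles_at_site[a] for a in gt if a is not None]
                observed = [a for a in observed if a in "ACGT"]
                if not observed:
                    calls[sid][rec.pos] = MISSING
                    continue
                tally: dict[str, int] = {}
                for a in observed:
                    tally[a] = tally.get(a, 0) + 1
                top = max(tally.values())
                winners = sorted(a for a, c in tally.items() if c == top)
                call = rec.ref if rec.ref in winners else winners[0]
                calls[sid][rec.pos] = call
    return [SampleGenotypes(sid, c) for sid, c in calls.items()]


def write_calls_csv(calls: Iterable[HaplogroupCall], path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "haplogroup", "score", "n_expected", "n_matched"]
        )
        for c in calls:
            writer.writerow(
                [c.sample_id, c.best, f"{c.score:.6f}", c.n_expected, c.n_matched]
            )
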