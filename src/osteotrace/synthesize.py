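"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Three generators, all driven by one explicit seed through numpy's
``SeedSequence`` spawning (no global random state):

* genotype cohorts — samples drawn from a haplogroup distribution, calls
  equal to the haplogroup's expected panel profile, degraded by
  independent per-call dropout (``missing_rate``) and uniform substitution
  to one of the three alternative bases (``error_rate``), the simplest
  adversarial model for the caller;
* reference frequency tables — populations on a 1-D geographic coordinate
  with a monotone west-Eurasian ancestry cline (linear between two
  endpoint fractions), each population's mass split between a
  west-Eurasian haplogroup pool and regional pools via a Dirichlet draw;
* isotope cohorts — drinking-water values drawn per region (Gaussian),
  pushed through the forward carbonate calibration plus analytical noise;
  carbon values from a C4-fraction distribution through the forward
  end-member mixing model.

Default parameters emulate a mid-19th-century north-Indian cohort of 50
individuals: haplogroup mass concentrated in autochthonous South Asian
M/R clades (M39 0.24, R32 0.14), a minor west-Eurasian component
(HV0e 0.06, U3 0.02, U7 0.02), macro-M totalling 0.70.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .haplocall import SampleGenotypes
from .haplotree import HaploTree, PanelDefinition, expected_profile
from .isotope import IsotopeRecord, drinking_water_to_carbonate
from .popstruct import FrequencyTable

import pandas as pd


class SynthesisConfigError(ValueError):
    """A spec references labels or regions that do not exist."""


#: Haplogroup distribution of the default 50-sample cohort (sums to 1;
#: macro-M mass 0.70, west-Eurasian mass 0.10).
DEFAULT_COHORT_DISTRIBUTION: dict[str, float] = {
    "M39": 0.24, "R32": 0.14, "HV0e": 0.06, "U3": 0.02, "U7": 0.02,
    "M2": 0.10, "M3": 0.08, "M5": 0.06, "M6": 0.06, "M18": 0.04,
    "M25": 0.04, "M30": 0.04, "M33": 0.02, "M65": 0.02,
    "N5": 0.04, "R5": 0.02,
}

#: Haplogroup pools used by the cline generator.
WEST_EURASIAN_POOL = ("HV0e", "U3", "U7", "H", "J", "K", "W", "X", "U5")
SOUTH_ASIAN_POOL = (
    "M39", "R32", "M2", "M3", "M5", "M6", "M18", "M25", "M30",
    "M33", "M65", "N5", "R5", "R6", "U2a",
)
EAST_EURASIAN_POOL = ("A", "D", "M9", "R22")

#: Fig-2-style population codes west -> east along the cline coordinate.
DEFAULT_CLINE_POPULATIONS: tuple[tuple[str, float], ...] = (
    ("Pak", 0.00), ("Pun", 0.05), ("Raj", 0.15), ("Guj", 0.25),
    ("Mah", 0.35), ("Mp", 0.45), ("Up", 0.60), ("Cg", 0.65),
    ("Bih", 0.75), ("Jhk", 0.80), ("WB", 0.90), ("Odi", 0.90),
    ("Ap", 0.95), ("Ker", 1.00),
)

#: Drinking-water d18O (per mil VSMOW) mean/SD per region, matching the
#: packaged water-reference ranges.
DEFAULT_REGION_WATER: dict[str, tuple[float, float]] = {
    "Punjab": (-7.75, 0.5),
    "GangeticPlain": (-5.0, 0.6),
    "CoastalOrissa": (-2.2, 0.5),
}


@dataclass
class CohortSpec:
    n_samples: int = 50
    haplogroup_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_DISTRIBUTION)
    )
    missing_rate: float = 0.1
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.haplogroup_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise SynthesisConfigError(f"probabilities sum to {total}, not 1")
        if not (0 <= self.missing_rate < 1 and 0 <= self.error_rate < 1):
            raise SynthesisConfigError("rates must lie in [0, 1)")


@dataclass
class ClineSpec:
    populations: tuple[tuple[str, float], ...] = DEFAULT_CLINE_POPULATIONS
    west_fraction_at_0: float = 0.45
    west_fraction_at_1: float = 0.03
    west_pool: tuple[str, ...] = WEST_EURASIAN_POOL
    regional_pool: tuple[str, ...] = SOUTH_ASIAN_POOL
    east_pool: tuple[str, ...] = EAST_EURASIAN_POOL
    east_fraction: float = 0.05
    concentration: float = 40.0  # Dirichlet concentration within pools
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.populations) < 2:
            raise SynthesisConfigError("need at least 2 populations")
        if not self.west_pool or not self.regional_pool:
            raise SynthesisConfigError("haplogroup pools must be non-empty")
        for frac in (self.west_fraction_at_0, self.west_fraction_at_1):
            if not 0 <= frac <= 1:
                raise SynthesisConfigError("fractions must lie in [0,1]")

    def west_fraction(self, coordinate: float) -> float:
        f0, f1 = self.west_fraction_at_0, self.west_fraction_at_1
        return f0 + (f1 - f0) * coordinate


@dataclass
class IsotopeSpec:
    region_water: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WATER)
    )
    fraction_c4_mean: float = 0.35
    fraction_c4_sd: float = 0.2
    analytical_sd: float = 0.15  # per mil, on both carbonate and carbon
    c3_enamel_endmember: float = -15.0
    c4_enamel_endmember: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for region, (_, sd) in self.region_water.items():
            if sd < 0:
                raise SynthesisConfigError(f"negative water SD for {region}")
        if self.fraction_c4_sd < 0 or self.analytical_sd < 0:
            raise SynthesisConfigError("SDs must be non-negative")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def simulate_cohort_genotypes(
    spec: CohortSpec,
    tree: HaploTree,
    panel: PanelDefinition,
) -> tuple[list[SampleGenotypes], pd.DataFrame]:
    """Simulate panel genotypes; returns (samples, truth table).

    Each sample's call set equals its haplogroup's expected states at the
    panel sites (reference elsewhere); each call is independently dropped
    with ``missing_rate`` and substituted with ``error_rate``.  The truth
    table has columns ``sample_id, haplogroup``.
    """
    labels = sorted(spec.haplogroup_distribution)
    missing_from_tree = [lab for lab in labels if lab not in tree]
    if missing_from_tree:
        raise SynthesisConfigError(
            f"haplogroups absent from tree: {missing_from_tree}"
        )
    probs = np.array([spec.haplogroup_distribution[lab] for lab in labels])
    reference = tree.reference_alleles()
    positions = sorted(panel.positions)
    profiles = {
        lab: expected_profile(tree, lab).states for lab in labels
    }
    rng = _rng(spec.seed, 0)
    assigned = rng.choice(len(labels), size=spec.n_samples, p=probs)

    alternatives = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    samples: list[SampleGenotypes] = []
    truth_rows = []
    for i, lab_idx in enumerate(assigned):
        label = labels[lab_idx]
        sid = f"S{i:04d}"
        calls: dict[int, str | None] = {}
        for pos in positions:
            base = profiles[label].get(pos, reference[pos])
            if rng.random() < spec.missing_rate:
                calls[pos] = None
            elif spec.error_rate and rng.random() < spec.error_rate:
                calls[pos] = alternatives[base][rng.integers(3)]
            else:
                calls[pos] = base
        samples.append(SampleGenotypes(sid, calls))
        truth_rows.append({"sample_id": sid, "haplogroup": label})
    return samples, pd.DataFrame(truth_rows)


def simulate_reference_frequencies(spec: ClineSpec) -> FrequencyTable:
    """Frequency table for populations along the west-Eurasian cline.

    Each population's west-Eurasian mass follows the linear cline exactly;
    within each pool the mass is split by a Dirichlet draw, so rows sum
    to 1 while pool totals are deterministic by construction.
    """
    rng = _rng(spec.seed, 1)
    haplogroups = sorted(
        set(spec.west_pool) | set(spec.regional_pool) | set(spec.east_pool)
    )
    rows = {}
    for name, coord in spec.populations:
        west = spec.west_fraction(coord)
        east = spec.east_fraction
        regional = max(0.0, 1.0 - west - east)
        freqs = dict.fromkeys(haplogroups, 0.0)
        for pool, mass in (
            (spec.west_pool, west),
            (spec.regional_pool, regional),
            (spec.east_pool, east),
        ):
            if mass <= 0:
                continue
            weights = rng.dirichlet(np.full(len(pool), spec.concentration))
            for lab, w in zip(pool, weights):
                freqs[lab] += mass * w
        rows[name] = freqs
    frame = pd.DataFrame.from_dict(rows, orient="index")[haplogroups]
    frame.index.name = "population"
    return FrequencyTable(frame)


def simulate_isotope_cohort(
    spec: IsotopeSpec, region: str, n: int
) -> list[IsotopeRecord]:
    """Isotope records for ``n`` individuals who grew up in ``region``.

    Carbonate values are generated by the forward calibration from drawn
    drinking-water values plus analytical noise; carbon values from drawn
    C4 fractions through the forward mixing model plus noise.
    """
    if region not in spec.region_water:
        raise SynthesisConfigError(f"unknown region {region!r}")
    mean, sd = spec.region_water[region]
    rng = _rng(spec.seed, 2)
    water = rng.normal(mean, sd, size=n)
    carbonate = drinking_water_to_carbonate(water) + rng.normal(
        0.0, spec.analytical_sd, size=n
    )
    frac = np.clip(
        rng.normal(spec.fraction_c4_mean, spec.fraction_c4_sd, size=n), 0.0, 1.0
    )
    d13c = (
        spec.c3_enamel_endmember
        + frac * (spec.c4_enamel_endmember - spec.c3_enamel_endmember)
        + rng.normal(0.0, spec.analytical_sd, size=n)
    )
    return [
        IsotopeRecord(f"I{i:04d}", float(carbonate[i]), float(d13c[i]))
        for i in range(n)
    ]


def write_synthetic_inputs(
    out_dir,
    seed: int = 0,
    n_samples: int = 50,
    missing_rate: float = 0.1,
    error_rate: float = 0.0,
    isotope_region: str = "GangeticPlain",
    tree: HaploTree | None = None,
    panel: PanelDefinition | None = None,
) -> dict[str, str]:
    """Write a complete synthetic input set as flat CSVs under ``out_dir``.

    Returns the file paths keyed by pipeline config key (``genotypes``,
    ``reference_frequencies``, ``isotopes``) plus ``truth``.
    """
    import csv
    from pathlib import Path

    from . import haplotree as ht
    from . import popstruct as ps

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = tree if tree is not None else ht.load_default_tree()
    panel = panel if panel is not None else ht.load_default_panel()

    spec = CohortSpec(
        n_samples=n_samples, missing_rate=missing_rate,
        error_rate=error_rate, seed=seed,
    )
    samples, truth = simulate_cohort_genotypes(spec, tree, panel)
    geno_path = out / "genotypes.csv"
    with open(geno_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "position", "allele"])
        for s in samples:
            for pos in sorted(s.calls):
                writer.writerow([s.sample_id, pos, s.calls[pos] or ""])
    truth_path = out / "truth.csv"
    truth.to_csv(truth_path, index=False)

    table = simulate_reference_frequencies(ClineSpec(seed=seed))
    ref_path = out / "reference_frequencies.csv"
    ps.write_frequency_csv(table, str(ref_path))

    records = simulate_isotope_cohort(IsotopeSpec(seed=seed), isotope_region, n_samples)
    iso_path = out / "isotopes.csv"
    with open(iso_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "d18O_carbonate_vsmow", "d13C_vpdb"])
        for rec in records:
            writer.writerow(
                [rec.sample_id, f"{rec.d18O_carbonate:.4f}", f"{rec.d13C:.4f}"]
            )
    return {
        "genotypes": str(geno_path),
        "truth": str(truth_path),
        "reference_frequencies": str(ref_path),
        "isotopes": str(iso_path),
    }
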