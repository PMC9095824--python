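"""Stable-isotope provenance and diet classification.

Oxygen: the delta-18-O of tooth-enamel structural carbonate (per mil,
VSMOW) records the drinking water ingested while the tooth mineralised,
through metabolic fractionation summarised by the linear calibration

    d18O_carbonate = 0.77 * d18O_drinking_water + 28.1

which is inverted here to back-calculate drinking-water values.  A sample
is consistent with a region when its drinking-water value falls inside the
region's water range (closed interval) widened by a tolerance (default
0.5 per mil) that acknowledges analytical and seasonal spread; it is
"local" when consistent with the designated local region.

Carbon: the delta-13-C of bioapatite carbonate (per mil, VPDB) reflects
the proportions of C3 plants (wheat, barley, rice, legumes) and C4 plants
(millets, sorghum) in the diet.  Bioapatite is enriched by roughly 9-15
per mil over diet; with the midpoint enrichment of +11.5 and diet
end-members of -26.5 (pure C3) and -12.5 (pure C4) per mil, the default
enamel end-members are -15.0 and -1.0.  The C4 fraction is the linear
mixing coordinate between the end-members, clipped to [0, 1].

Values are kept at full precision internally; rounding to the 1-decimal
reporting precision happens only in the reporting layer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

CARBONATE_SLOPE = 0.77
CARBONATE_INTERCEPT = 28.1  # per mil VSMOW

DEFAULT_C3_ENAMEL = -15.0  # per mil VPDB
DEFAULT_C4_ENAMEL = -1.0
DEFAULT_LOCALITY_TOLERANCE = 0.5  # per mil

# diet classes by C4 fraction; boundaries inclusive on the mixed side
C3_DOMINANT = "C3-dominant"
MIXED = "mixed"
C4_DOMINANT = "C4-dominant"
DIET_LOWER, DIET_UPPER = 0.25, 0.75

# default QC plausibility windows for enamel carbonate measurements
D18O_QC_BOUNDS = (15.0, 35.0)
D13C_QC_BOUNDS = (-25.0, 5.0)


class IsotopeQCError(ValueError):
    """A measurement falls outside its plausibility window."""


class IsotopeConfigError(ValueError):
    """Invalid end-member or region configuration."""


@dataclass(frozen=True)
class IsotopeRecord:
    sample_id: str
    d18O_carbonate: float  # per mil VSMOW
    d13C: float            # per mil VPDB

    def validate(
        self,
        d18o_bounds: tuple[float, float] = D18O_QC_BOUNDS,
        d13c_bounds: tuple[float, float] = D13C_QC_BOUNDS,
    ) -> None:
        if not d18o_bounds[0] <= self.d18O_carbonate <= d18o_bounds[1]:
            raise IsotopeQCError(
                f"sample {self.sample_id}: d18O_carbonate {self.d18O_carbonate} "
                f"outside QC window {d18o_bounds}"
            )
        if not d13c_bounds[0] <= self.d13C <= d13c_bounds[1]:
            raise IsotopeQCError(
                f"sample {self.sample_id}: d13C {self.d13C} "
                f"outside QC window {d13c_bounds}"
            )


@dataclass(frozen=True)
class RegionWaterReference:
    region: str
    d18O_water_min: float
    d18O_water_max: float

    def __post_init__(self) -> None:
        if self.d18O_water_min > self.d18O_water_max:
            raise IsotopeConfigError(
                f"region {self.region}: min above max"
            )


@dataclass
class WaterEstimate:
    sample_id: str
    d18O_drinking_water: float
    consistent_regions: list[str] = field(default_factory=list)
    local_flag: bool = False


@dataclass(frozen=True)
class DietEstimate:
    sample_id: str
    fraction_C4: float
    diet_class: str


def carbonate_to_drinking_water(d18O_carbonate: float) -> float:
    """Invert the carbonate calibration: (x - 28.1) / 0.77, full precision."""
    return (d18O_carbonate - CARBONATE_INTERCEPT) / CARBONATE_SLOPE


def drinking_water_to_carbonate(d18O_drinking_water: float) -> float:
    """Forward calibration, used by the simulator and round-trip checks."""
    return CARBONATE_SLOPE * d18O_drinking_water + CARBONATE_INTERCEPT


def classify_locality(
    sample_id: str,
    d18O_drinking_water: float,
    references: Sequence[RegionWaterReference],
    local_region: str,
    tolerance: float = DEFAULT_LOCALITY_TOLERANCE,
) -> WaterEstimate:
    """All regions whose (tolerance-widened, closed) water interval contains
    the sample's drinking-water value; local iff the local region is among them."""
    if not references:
        raise IsotopeConfigError("no water references supplied")
    region_names = {r.region for r in references}
    if local_region not in region_names:
        raise IsotopeConfigError(
            f"local region {local_region!r} not among references {sorted(region_names)}"
        )
    consistent = [
        r.region
        for r in references
        if r.d18O_water_min - tolerance
        <= d18O_drinking_water
        <= r.d18O_water_max + tolerance
    ]
    return WaterEstimate(
        sample_id=sample_id,
        d18O_drinking_water=d18O_drinking_water,
        consistent_regions=consistent,
        local_flag=local_region in consistent,
    )


def percent_c4(
    d13C: float,
    c3_enamel_endmember: float = DEFAULT_C3_ENAMEL,
    c4_enamel_endmember: float = DEFAULT_C4_ENAMEL,
) -> float:
    """Linear C3/C4 mixing fraction, clipped to [0, 1]."""
    if c3_enamel_endmember == c4_enamel_endmember:
        raise IsotopeConfigError("C3 and C4 end-members must differ")
    fraction = (d13C - c3_enamel_endmember) / (
        c4_enamel_endmember - c3_enamel_endmember
    )
    return min(1.0, max(0.0, fraction))


def classify_diet(fraction_C4: float) -> str:
    if not 0.0 <= fraction_C4 <= 1.0:
        raise ValueError(f"fraction_C4 {fraction_C4} outside [0,1]")
    if fraction_C4 < DIET_LOWER:
        return C3_DOMINANT
    if fraction_C4 <= DIET_UPPER:
        return MIXED
    return C4_DOMINANT


def analyse_cohort(
    records: Sequence[IsotopeRecord],
    references: Sequence[RegionWaterReference],
    local_region: str,
    tolerance: float = DEFAULT_LOCALITY_TOLERANCE,
    c3_endmember: float = DEFAULT_C3_ENAMEL,
    c4_endmember: float = DEFAULT_C4_ENAMEL,
) -> list[tuple[WaterEstimate, DietEstimate]]:
    """QC-check, convert, and classify every record."""
    out = []
    for rec in records:
        rec.validate()
        water = classify_locality(
            rec.sample_id,
            carbonate_to_drinking_water(rec.d18O_carbonate),
            references,
            local_region,
            tolerance,
        )
        frac = percent_c4(rec.d13C, c3_endmember, c4_endmember)
        out.append((water, DietEstimate(rec.sample_id, frac, classify_diet(frac))))
    return out


# ---------------------------------------------------------------------------
# I/O


def read_isotope_csv(path: str) -> list[IsotopeRecord]:
    """CSV columns: sample_id, d18O_carbonate_vsmow, d13C_vpdb."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                IsotopeRecord(
                    sample_id=row["sample_id"],
                    d18O_carbonate=float(row["d18O_carbonate_vsmow"]),
                    d13C=float(row["d13C_vpdb"]),
                )
            )
    return records


def read_water_reference_csv(path: str) -> list[RegionWaterReference]:
    """CSV columns: region, d18O_water_min, d18O_water_max."""
    refs = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            refs.append(
                RegionWaterReference(
                    region=row["region"],
                    d18O_water_min=float(row["d18O_water_min"]),
                    d18O_water_max=float(row["d18O_water_max"]),
                )
            )
    return refs


def write_isotope_report_csv(
    results: Iterable[tuple[WaterEstimate, DietEstimate]], path: str
) -> None:
    """Reporting layer: drinking-water values rounded to 1 decimal."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "d18Odw", "local_flag", "consistent_regions",
             "fraction_C4", "diet_class"]
        )
        for water, diet in results:
            writer.writerow(
                [
                    water.sample_id,
                    f"{water.d18O_drinking_water:.1f}",
                    water.local_flag,
                    ";".join(water.consistent_regions),
                    f"{diet.fraction_C4:.3f}",
                    diet.diet_class,
                ]
            )
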