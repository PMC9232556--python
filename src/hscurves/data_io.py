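"""Data model and CSV I/O for microhabitat samples and taxon trait tables.

Two long-format CSV schemas are supported.

``samples.csv`` — one row per (sample, taxon)::

    sample_id, campaign_id, velocity_m_s, depth_m, substrate, area_m2, taxon, count

The ``area_m2`` column may be omitted entirely; every sample then receives an
area of 1.0 m**2, which turns the availability curve into a sample-frequency
estimate (equal sampling effort per microhabitat).  Rows with ``count`` 0 are
legal and are kept as explicit zeros.  A microhabitat where nothing was caught
is written as a single row with an empty ``taxon`` field and ``count`` 0.

``traits.csv`` — one row per taxon::

    taxon, order, family, gra, shr, gat, ff, pre, par, oth

where the seven integer columns are the 10-point functional-feeding-group
allocation of the taxon; they must sum to exactly 10.

Substrate is recorded as one of six category codes by default (``a`` fine
sand, ``c`` medium sand, ``ae`` fine sand with gravel, ``ce`` medium sand
with gravel, ``e`` gravel, ``f`` silt); the code list is configurable for
reuse on rivers with a different substrate classification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SUBSTRATE_CODES",
    "FFG_LABELS",
    "SAMPLE_COLUMNS",
    "TRAIT_COLUMNS",
    "SchemaError",
    "SampleRecord",
    "TraitRecord",
    "Dataset",
    "read_samples",
    "write_samples",
    "read_traits",
    "write_traits",
    "validate_dataset",
]

#: Default substrate category codes, ordered from fine to coarse with silt last.
SUBSTRATE_CODES: tuple[str, ...] = ("a", "c", "ae", "ce", "e", "f")

#: Functional feeding group labels: grazers/scrapers, shredders, gatherers,
#: filter feeders, predators, parasites, others.
FFG_LABELS: tuple[str, ...] = ("GRA", "SHR", "GAT", "FF", "PRE", "PAR", "OTH")

SAMPLE_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "campaign_id",
    "velocity_m_s",
    "depth_m",
    "substrate",
    "area_m2",
    "taxon",
    "count",
)

TRAIT_COLUMNS: tuple[str, ...] = (
    "taxon",
    "order",
    "family",
    "gra",
    "shr",
    "gat",
    "ff",
    "pre",
    "par",
    "oth",
)


class SchemaError(ValueError):
    """An input table violates the expected schema or a value constraint."""


@dataclass(frozen=True)
class SampleRecord:
    """One microhabitat sample: hydraulics, substrate, sampled area, counts.

    Parameters
    ----------
    sample_id:
        Unique identifier of the microhabitat sample.
    campaign_id:
        Label of the field campaign the sample belongs to (e.g. a year).
    velocity:
        Vertically averaged water flow velocity in m/s, >= 0.
    depth:
        Water depth in m, > 0.
    substrate:
        Substrate category code.
    area:
        Sampled area in m**2, > 0.  Defaults to 1.0 when unmeasured.
    counts:
        Mapping taxon name -> number of individuals (non-negative integers).
    """

    sample_id: str
    campaign_id: str
    velocity: float
    depth: float
    substrate: str
    area: float = 1.0
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.velocity) or self.velocity < 0:
            raise ValueError(
                f"sample {self.sample_id!r}: velocity must be finite and >= 0, "
                f"got {self.velocity}"
            )
        if not math.isfinite(self.depth) or self.depth <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: depth must be finite and > 0, "
                f"got {self.depth}"
            )
        if not math.isfinite(self.area) or self.area <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: area must be finite and > 0, "
                f"got {self.area}"
            )
        clean: dict[str, int] = {}
        for taxon, count in self.counts.items():
            if count != int(count) or count < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: count for {taxon!r} must be a "
                    f"non-negative integer, got {count}"
                )
            clean[str(taxon)] = int(count)
        object.__setattr__(self, "counts", clean)

    @property
    def total_count(self) -> int:
        """Total number of individuals in the sample, across all taxa."""
        return sum(self.counts.values())


@dataclass(frozen=True)
class TraitRecord:
    """Taxonomic placement and 10-point FFG allocation of one taxon.

    The allocation follows the AQEM/STAR convention: 10 points are split
    across feeding mechanisms in proportion to how much a taxon relies on
    each; the points always sum to exactly 10.
    """

    taxon: str
    order: str
    family: str
    allocation: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {label: 0 for label in FFG_LABELS}
        for label, points in self.allocation.items():
            key = str(label).upper()
            if key not in clean:
                raise ValueError(
                    f"trait record for {self.taxon!r}: unknown FFG label {label!r}"
                )
            if points != int(points) or points < 0 or points > 10:
                raise ValueError(
                    f"trait record for {self.taxon!r}: allocation for {label} "
                    f"must be an integer in 0..10, got {points}"
                )
            clean[key] = int(points)
        total = sum(clean.values())
        if total != 10:
            raise ValueError(
                f"FFG allocation for {self.taxon!r} sums to {total}; "
                "it must sum to exactly 10"
            )
        object.__setattr__(self, "allocation", clean)


@dataclass(frozen=True)
class Dataset:
    """A validated pairing of sample records and trait records.

    Construct through :func:`validate_dataset`, which enforces the
    cross-reference invariants (unique sample ids, trait coverage).
    """

    samples: tuple[SampleRecord, ...]
    traits: tuple[TraitRecord, ...]

    @property
    def trait_map(self) -> dict[str, TraitRecord]:
        return {t.taxon: t for t in self.traits}

    @property
    def campaigns(self) -> tuple[str, ...]:
        """Campaign ids present, in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.campaign_id, None)
        return tuple(seen)

    @property
    def taxa(self) -> tuple[str, ...]:
        """Sorted union of taxa occurring in any sample."""
        out: set[str] = set()
        for s in self.samples:
            out.update(s.counts)
        return tuple(sorted(out))


def _check_header(actual: Sequence[str], expected: Sequence[str], path: Path) -> None:
    if tuple(actual) != tuple(expected):
        raise SchemaError(
            f"{path}: expected columns {list(expected)}, found {list(actual)}"
        )


def read_samples(
    path: str | Path,
    substrate_codes: Sequence[str] = SUBSTRATE_CODES,
) -> list[SampleRecord]:
    """Read a long-format samples.csv into a list of :class:`SampleRecord`.

    Rows sharing a ``sample_id`` are merged into one record; their metadata
    (campaign, velocity, depth, substrate, area) must agree exactly.  Records
    are returned sorted by ``sample_id`` so that reading is independent of row
    order in the file.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "campaign_id": str, "substrate": str, "taxon": str},
        float_precision="round_trip",
    )
    has_area = "area_m2" in df.columns
    expected = (
        SAMPLE_COLUMNS
        if has_area
        else tuple(c for c in SAMPLE_COLUMNS if c != "area_m2")
    )
    _check_header(df.columns, expected, path)

    meta: dict[str, tuple[str, float, float, str, float]] = {}
    counts: dict[str, dict[str, int]] = {}
    codes = set(substrate_codes)
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2  # 1-based, after the header line
        sid = str(row["sample_id"])
        substrate = str(row["substrate"])
        if substrate not in codes:
            raise SchemaError(
                f"{path} row {line}: unknown substrate code {substrate!r} "
                f"(expected one of {sorted(codes)})"
            )
        velocity = float(row["velocity_m_s"])
        depth = float(row["depth_m"])
        if not math.isfinite(velocity) or velocity < 0:
            raise SchemaError(f"{path} row {line}: negative or non-finite velocity")
        if not math.isfinite(depth) or depth <= 0:
            raise SchemaError(f"{path} row {line}: non-positive depth")
        area = float(row["area_m2"]) if has_area else 1.0
        if not math.isfinite(area) or area <= 0:
            raise SchemaError(f"{path} row {line}: non-positive area")

        m = (str(row["campaign_id"]), velocity, depth, substrate, area)
        if sid in meta and meta[sid] != m:
            raise SchemaError(
                f"{path} row {line}: sample {sid!r} has inconsistent metadata "
                "across rows"
            )
        meta.setdefault(sid, m)
        counts.setdefault(sid, {})

        taxon = row["taxon"]
        raw = row["count"]
        count = 0 if pd.isna(raw) else float(raw)
        if count != int(count) or count < 0:
            raise SchemaError(
                f"{path} row {line}: count must be a non-negative integer, got {raw}"
            )
        if pd.isna(taxon) or str(taxon) == "":
            # marker row for an empty microhabitat; must carry count 0
            if count != 0:
                raise SchemaError(
                    f"{path} row {line}: empty taxon field with non-zero count"
                )
            continue
        taxon = str(taxon)
        if taxon in counts[sid]:
            raise SchemaError(
                f"{path} row {line}: duplicate (sample_id, taxon) pair "
                f"({sid!r}, {taxon!r})"
            )
        counts[sid][taxon] = int(count)

    records = []
    for sid in sorted(meta):
        campaign, velocity, depth, substrate, area = meta[sid]
        taxa = {t: counts[sid][t] for t in sorted(counts[sid])}
        records.append(
            SampleRecord(
                sample_id=sid,
                campaign_id=campaign,
                velocity=velocity,
                depth=depth,
                substrate=substrate,
                area=area,
                counts=taxa,
            )
        )
    return records


def write_samples(records: Iterable[SampleRecord], path: str | Path) -> None:
    """Write sample records in the canonical long format (sorted rows)."""
    rows = []
    for s in sorted(records, key=lambda r: r.sample_id):
        # repr() preserves float precision exactly (pandas' float formatting
        # can drop the last digit)
        base = {
            "sample_id": s.sample_id,
            "campaign_id": s.campaign_id,
            "velocity_m_s": repr(float(s.velocity)),
            "depth_m": repr(float(s.depth)),
            "substrate": s.substrate,
            "area_m2": repr(float(s.area)),
        }
        if s.counts:
            for taxon in sorted(s.counts):
                rows.append({**base, "taxon": taxon, "count": s.counts[taxon]})
        else:
            rows.append({**base, "taxon": "", "count": 0})
    df = pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))
    df.to_csv(path, index=False)


def read_traits(path: str | Path) -> list[TraitRecord]:
    """Read traits.csv; enforces the sum-to-10 allocation invariant."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"taxon": str, "order": str, "family": str})
    _check_header(df.columns, TRAIT_COLUMNS, path)
    records: list[TraitRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2
        taxon = str(row["taxon"])
        if taxon in seen:
            raise SchemaError(f"{path} row {line}: duplicate taxon {taxon!r}")
        seen.add(taxon)
        allocation = {
            label: int(row[label.lower()]) for label in FFG_LABELS
        }
        records.append(
            TraitRecord(
                taxon=taxon,
                order=str(row["order"]),
                family=str(row["family"]),
                allocation=allocation,
            )
        )
    return records


def write_traits(records: Iterable[TraitRecord], path: str | Path) -> None:
    rows = []
    for t in sorted(records, key=lambda r: r.taxon):
        row = {"taxon": t.taxon, "order": t.order, "family": t.family}
        for label in FFG_LABELS:
            row[label.lower()] = t.allocation[label]
        rows.append(row)
    pd.DataFrame(rows, columns=list(TRAIT_COLUMNS)).to_csv(path, index=False)


def validate_dataset(
    samples: Iterable[SampleRecord], traits: Iterable[TraitRecord]
) -> Dataset:
    """Cross-validate samples against traits and return a sealed Dataset.

    Raises
    ------
    ValueError
        If sample ids repeat, taxa repeat in the trait table, or a taxon
        observed in the samples has no trait record.
    """
    samples = tuple(samples)
    traits = tuple(traits)

    ids = [s.sample_id for s in samples]
    dup_ids = sorted({i for i in ids if ids.count(i) > 1})
    if dup_ids:
        raise ValueError(f"duplicate sample ids: {dup_ids}")

    names = [t.taxon for t in traits]
    dup_taxa = sorted({n for n in names if names.count(n) > 1})
    if dup_taxa:
        raise ValueError(f"duplicate taxa in trait table: {dup_taxa}")

    known = set(names)
    missing: set[str] = set()
    for s in samples:
        missing.update(t for t in s.counts if t not in known)
    if missing:
        raise ValueError(
            f"taxa present in samples but missing from traits: {sorted(missing)}"
        )

    if not samples:
        warnings.warn("dataset contains no samples", stacklevel=2)
    return Dataset(samples=samples, traits=traits)
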