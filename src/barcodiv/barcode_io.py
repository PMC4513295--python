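"""Reading, validation and filtering of barcode datasets.

A dataset is a FASTA of aligned COI barcodes (standard 658-bp frame) plus a
tab-separated metadata table keyed by record id.  Records are retained or
dropped by ungapped length and by a simple geographic rule emulating a
continental survey's inclusion box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO

IUPAC_SYMBOLS = set("ACGTRYSWKMBDHVN-?")

#: Aligned length of the standard animal barcode region.
BARCODE_LENGTH = 658

# Accepted metadata header aliases (BOLD exports vary).
_COLUMN_ALIASES = {
    "processid": "record_id",
    "id": "record_id",
    "species_name": "species",
    "lat": "latitude",
    "lon": "longitude",
    "lng": "longitude",
}


@dataclass(frozen=True)
class BarcodeRecord:
    """One sequenced specimen: the survey's atomic input."""

    record_id: str
    species: str
    family: str
    sequence: str
    latitude: float | None = None
    longitude: float | None = None
    country: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - IUPAC_SYMBOLS
        if bad:
            raise ValueError(
                f"record {self.record_id!r}: non-IUPAC symbols {sorted(bad)}"
            )
        if len(self.sequence) > BARCODE_LENGTH:
            raise ValueError(
                f"record {self.record_id!r}: length {len(self.sequence)} exceeds "
                f"the {BARCODE_LENGTH}-site barcode frame"
            )
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"record {self.record_id!r}: latitude {self.latitude}")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"record {self.record_id!r}: longitude {self.longitude}")

    @property
    def ungapped_length(self) -> int:
        """Number of non-gap, non-missing sites."""
        return sum(1 for c in self.sequence.upper() if c not in "-?")

    @property
    def has_coordinates(self) -> bool:
        return self.latitude is not None and self.longitude is not None


@dataclass
class BarcodeDataset:
    """Ordered collection of records padded to a common alignment frame."""

    records: list[BarcodeRecord]
    alignment_length: int = BARCODE_LENGTH

    def __post_init__(self) -> None:
        seen: set[str] = set()
        padded = []
        for rec in self.records:
            if rec.record_id in seen:
                raise ValueError(f"duplicate record id {rec.record_id!r}")
            seen.add(rec.record_id)
            if not rec.species:
                raise ValueError(f"record {rec.record_id!r} lacks a species name")
            seq = rec.sequence.upper()
            if len(seq) < self.alignment_length:
                seq = seq + "-" * (self.alignment_length - len(seq))
            if len(seq) != self.alignment_length:
                raise ValueError(
                    f"record {rec.record_id!r}: aligned length {len(seq)} != "
                    f"{self.alignment_length}"
                )
            padded.append(replace(rec, sequence=seq))
        self.records = padded

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species(self) -> list[str]:
        """Distinct species names in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for rec in self.records:
            if rec.species not in seen:
                seen.add(rec.species)
                out.append(rec.species)
        return out

    def species_of(self) -> dict[str, str]:
        return {rec.record_id: rec.species for rec in self.records}

    def family_of(self) -> dict[str, str]:
        return {rec.species: rec.family for rec in self.records}

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.record_id}\n{rec.sequence}\n")

    def to_metadata(self, path: str | Path) -> None:
        rows = [
            {
                "record_id": r.record_id,
                "species": r.species,
                "family": r.family,
                "latitude": r.latitude,
                "longitude": r.longitude,
                "country": r.country,
            }
            for r in self.records
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class RegionRule:
    """Inclusion rule for a continental survey window.

    Records are kept when ``longitude <= lon_cap_east`` and, east of
    ``corridor_meridian``, additionally ``latitude >= lat_floor_north``.  The
    defaults encode a European survey whose southeastern limit runs between
    the Black Sea and the Caspian, just north of the Caucasus.
    """

    lon_cap_east: float = 50.0
    lat_floor_north: float = 43.5
    corridor_meridian: float = 40.0

    def keeps(self, latitude: float, longitude: float) -> bool:
        if longitude > self.lon_cap_east:
            return False
        if longitude >= self.corridor_meridian and latitude < self.lat_floor_north:
            return False
        return True


def _parse_float(value, record_id: str, column: str) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    text = str(value).strip()
    if text == "" or text.lower() in {"na", "nan", "none"}:
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ValueError(f"record {record_id!r}: bad {column} value {text!r}") from exc


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated metadata table, normalizing column aliases."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    table.columns = [_COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower())
                     for c in table.columns]
    required = {"record_id", "species", "family"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return table


def read_dataset(fasta_path: str | Path, metadata_path: str | Path,
                 alignment_length: int = BARCODE_LENGTH) -> BarcodeDataset:
    """Load and validate a dataset from FASTA + TSV, matching ids one-to-one."""
    seqs: dict[str, str] = {}
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        if entry.id in seqs:
            raise ValueError(f"duplicate FASTA id {entry.id!r}")
        seqs[entry.id] = str(entry.seq).upper()

    table = read_metadata(metadata_path)
    meta_ids = list(table["record_id"])
    if len(meta_ids) != len(set(meta_ids)):
        dupes = sorted({i for i in meta_ids if meta_ids.count(i) > 1})
        raise ValueError(f"duplicate metadata ids: {dupes}")

    fasta_only = sorted(set(seqs) - set(meta_ids))
    meta_only = sorted(set(meta_ids) - set(seqs))
    if fasta_only or meta_only:
        raise ValueError(
            f"id mismatch between FASTA and metadata: "
            f"FASTA-only={fasta_only[:5]}, metadata-only={meta_only[:5]}"
        )

    records = []
    for row in table.itertuples(index=False):
        row = row._asdict()
        rid = row["record_id"]
        records.append(BarcodeRecord(
            record_id=rid,
            species=str(row["species"]).strip(),
            family=str(row["family"]).strip(),
            sequence=seqs[rid],
            latitude=_parse_float(row.get("latitude"), rid, "latitude"),
            longitude=_parse_float(row.get("longitude"), rid, "longitude"),
            country=(str(row["country"]).strip()
                     if row.get("country") not in (None, "") and
                     not (isinstance(row.get("country"), float) and
                          math.isnan(row["country"])) else None),
        ))
    return BarcodeDataset(records, alignment_length=alignment_length)


def filter_by_length(ds: BarcodeDataset, min_length: int = 401) -> BarcodeDataset:
    """Keep records whose ungapped length is at least ``min_length``.

    The default 401 encodes a "greater than 400 bp" inclusion rule, chosen so
    that 407-bp rescue amplicons pass while anything of 400 sites or less is
    dropped.  Order is preserved; an empty result is allowed.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept = [r for r in ds.records if r.ungapped_length >= min_length]
    return BarcodeDataset(kept, alignment_length=ds.alignment_length)


def filter_by_region(ds: BarcodeDataset, rule: RegionRule | None = None) -> BarcodeDataset:
    """Keep records inside the survey window; coordinate-less records pass."""
    rule = rule or RegionRule()
    kept = [
        r for r in ds.records
        if not r.has_coordinates or rule.keeps(r.latitude, r.longitude)
    ]
    return BarcodeDataset(kept, alignment_length=ds.alignment_length)


def round1(x: float) -> float:
    """Round half away from zero to one decimal (report convention)."""
    return math.floor(abs(x) * 10 + 0.5) / 10 * (1 if x >= 0 else -1)


def dataset_summary(ds: BarcodeDataset) -> dict:
    """Headline counts for a dataset: records, species, sampling depth, families."""
    n_records = len(ds)
    per_species: dict[str, int] = {}
    per_family: dict[str, int] = {}
    n_no_coords = 0
    for rec in ds.records:
        per_species[rec.species] = per_species.get(rec.species, 0) + 1
        per_family[rec.family] = per_family.get(rec.family, 0) + 1
        if not rec.has_coordinates:
            n_no_coords += 1
    n_species = len(per_species)
    mean = n_records / n_species if n_species else 0.0
    n_ge10 = sum(1 for v in per_species.values() if v >= 10)
    return {
        "n_records": n_records,
        "n_species": n_species,
        "mean_records_per_species": round1(mean) if n_species else 0.0,
        "mean_records_per_species_raw": mean,
        "n_species_ge10": n_ge10,
        "pct_species_ge10": round1(100.0 * n_ge10 / n_species) if n_species else 0.0,
        "n_records_without_coordinates": n_no_coords,
        "per_family_records": dict(sorted(per_family.items())),
    }
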