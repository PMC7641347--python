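"""Domain types and delimited-text I/O for the metabarcoding pipeline.

The pipeline starts downstream of read processing: its inputs are denoised
exact sequence variants (ESVs), similarity-search hit tables in the common
tab-separated layout, a ranked lineage table and per-sample metadata from
the water-sampling design (station, depth, filtered volume, DNA yield).
All readers and writers here use plain UTF-8 delimited text so that every
artefact can be inspected, diffed and regenerated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("deepedna")

#: Taxonomic ranks, root to tip, used everywhere in the package.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Water-column positions a sample can come from.
LOCATIONS = ("surface", "deep_scattering_layer", "bottom")


@dataclass(frozen=True)
class Lineage:
    """A ranked taxonomic lineage; missing tip ranks are None.

    Invariant: if a rank is named, every ancestor rank is named too
    (a species cannot have an anonymous genus).
    """

    kingdom: Optional[str] = None
    phylum: Optional[str] = None
    class_: Optional[str] = None
    order: Optional[str] = None
    family: Optional[str] = None
    genus: Optional[str] = None
    species: Optional[str] = None

    def __post_init__(self) -> None:
        names = self.as_tuple()
        seen_gap = False
        for name in names:
            if name is None:
                seen_gap = True
            elif seen_gap:
                raise ValueError(
                    f"lineage has a named rank below an unnamed ancestor: {names}"
                )
            elif name == "":
                raise ValueError("rank names must be non-empty strings")

    def as_tuple(self) -> tuple[Optional[str], ...]:
        return (
            self.kingdom,
            self.phylum,
            self.class_,
            self.order,
            self.family,
            self.genus,
            self.species,
        )

    @classmethod
    def from_mapping(cls, ranks: Mapping[str, Optional[str]]) -> "Lineage":
        kw = {}
        for rank in RANKS:
            val = ranks.get(rank)
            key = "class_" if rank == "class" else rank
            kw[key] = val if val not in (None, "") else None
        return cls(**kw)

    def get(self, rank: str) -> Optional[str]:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        return self.as_tuple()[RANKS.index(rank)]

    def deepest_rank(self) -> Optional[str]:
        """Deepest named rank, or None for an empty lineage."""
        deepest = None
        for rank, name in zip(RANKS, self.as_tuple()):
            if name is not None:
                deepest = rank
        return deepest

    def truncate(self, rank: str) -> "Lineage":
        """Drop all names below `rank`."""
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        cut = RANKS.index(rank)
        names = [n if i <= cut else None for i, n in enumerate(self.as_tuple())]
        return Lineage(*names)

    def contains_name(self, name: str) -> bool:
        return name in [n for n in self.as_tuple() if n is not None]

    def is_empty(self) -> bool:
        return self.kingdom is None


@dataclass(frozen=True)
class HitRecord:
    """One similarity-search hit joined to its subject lineage."""

    query_id: str
    subject_taxon: Lineage
    identity_pct: float
    align_len: int
    query_len: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity_pct {self.identity_pct} outside [0, 100]")
        if self.align_len <= 0 or self.query_len <= 0:
            raise ValueError("align_len and query_len must be positive")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")

    @property
    def overlap_pct(self) -> float:
        """Query coverage as a percent, capped at 100 (gapped alignments
        can make align_len exceed query_len)."""
        return min(100.0, 100.0 * self.align_len / self.query_len)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one filtered water sample (or a field/lab blank)."""

    sample_id: str
    station: str
    transect: str
    year: int
    depth_m: float
    location: str
    volume_l: float
    dna_conc: Optional[float] = None  # pg/uL from fluorometry
    is_control: bool = False

    def __post_init__(self) -> None:
        if not self.depth_m >= 0 or self.depth_m != self.depth_m:
            raise ValueError(f"depth_m must be finite and >= 0, got {self.depth_m}")
        if not self.volume_l > 0:
            raise ValueError(f"volume_l must be > 0, got {self.volume_l}")
        if self.location not in LOCATIONS:
            raise ValueError(
                f"unknown location {self.location!r}; expected one of {LOCATIONS}"
            )
        if self.dna_conc is not None and self.dna_conc < 0:
            raise ValueError("dna_conc must be >= 0")


@dataclass
class ESVTable:
    """Read counts of ESVs across samples for one marker (primer set).

    `counts` is a long-format frame with columns esv_id, sample_id,
    read_count; (esv_id, sample_id) pairs are unique and counts >= 0.
    """

    marker: str
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"esv_id", "sample_id", "read_count"}
        missing = required - set(self.counts.columns)
        if missing:
            raise ValueError(f"ESV table missing columns: {sorted(missing)}")
        if (self.counts["read_count"] < 0).any():
            raise ValueError("read_count must be non-negative")
        if self.counts.duplicated(["esv_id", "sample_id"]).any():
            dup = self.counts[self.counts.duplicated(["esv_id", "sample_id"])]
            raise ValueError(
                f"duplicate (esv_id, sample_id) pairs, e.g. {dup.iloc[0].tolist()[:2]}"
            )

    @property
    def esv_ids(self) -> list[str]:
        return list(dict.fromkeys(self.counts["esv_id"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.counts["sample_id"]))


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> uppercase-sequence map.

    Duplicate ids raise; an empty file returns an empty map with a warning.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        logger.warning("FASTA file %s contains no records", path)
    return out


def read_lineage_table(path: str | Path, sep: str = "\t") -> dict[str, Lineage]:
    """Read a lineage table (taxon_key + the seven ranks) into a dict."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "taxon_key" not in df.columns:
        raise ValueError(f"lineage table {path} lacks a 'taxon_key' column")
    out: dict[str, Lineage] = {}
    for _, row in df.iterrows():
        out[row["taxon_key"]] = Lineage.from_mapping(
            {rank: row.get(rank, "") for rank in RANKS}
        )
    return out


#: Default hit-table column order: the common 12-column tabular output
#: reduced to the fields the selection criterion needs, plus query length.
HIT_COLUMNS = (
    "query_id",
    "taxon_key",
    "identity_pct",
    "align_len",
    "query_len",
    "evalue",
    "bitscore",
)


def read_hit_table(
    path: str | Path,
    lineages: Mapping[str, Lineage],
    evalue_max: float = 0.001,
    columns: Sequence[str] = HIT_COLUMNS,
    sep: str = "\t",
) -> list[HitRecord]:
    """Read a tab-separated hit table, join lineages, filter on e-value.

    Rows with evalue > evalue_max are discarded; rows whose taxon key is
    absent from the lineage table are dropped with a warning; malformed
    rows raise with their line number.
    """
    columns = list(columns)
    for required in HIT_COLUMNS:
        if required not in columns:
            raise ValueError(f"column mapping lacks required field {required!r}")
    records: list[HitRecord] = []
    n_unresolved = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            if len(parts) < len(columns):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(columns)} fields, got {len(parts)}"
                )
            row = dict(zip(columns, parts))
            try:
                identity = float(row["identity_pct"])
                align_len = int(row["align_len"])
                query_len = int(row["query_len"])
                evalue = float(row["evalue"])
                bitscore = float(row["bitscore"])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field: {exc}")
            if evalue > evalue_max:
                continue
            taxon_key = row["taxon_key"]
            if taxon_key not in lineages:
                n_unresolved += 1
                logger.warning(
                    "%s:%d: taxon key %r not in lineage table; row dropped",
                    path,
                    lineno,
                    taxon_key,
                )
                continue
            records.append(
                HitRecord(
                    query_id=row["query_id"],
                    subject_taxon=lineages[taxon_key],
                    identity_pct=identity,
                    align_len=align_len,
                    query_len=query_len,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    if n_unresolved:
        logger.warning("%s: %d rows dropped (unresolvable taxon keys)", path, n_unresolved)
    return records


_META_COLUMNS = [
    "sample_id",
    "station",
    "transect",
    "year",
    "depth_m",
    "location",
    "volume_l",
    "dna_conc",
    "is_control",
]


def read_sample_metadata(path: str | Path, sep: str = "\t") -> list[SampleMeta]:
    """Read sample metadata; invalid depth/volume/location raise."""
    df = pd.read_csv(path, sep=sep)
    required = set(_META_COLUMNS) - {"dna_conc", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        dna = row.get("dna_conc")
        if dna is not None and pd.isna(dna):
            dna = None
        ctrl = row.get("is_control", False)
        if pd.isna(ctrl):
            ctrl = False
        if isinstance(ctrl, str):
            ctrl = ctrl.strip().lower() in ("1", "true", "yes", "y")
        out.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                station=str(row["station"]),
                transect=str(row["transect"]),
                year=int(row["year"]),
                depth_m=float(row["depth_m"]),
                location=str(row["location"]),
                volume_l=float(row["volume_l"]),
                dna_conc=None if dna is None else float(dna),
                is_control=bool(ctrl),
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers above)


def write_sample_metadata(samples: Iterable[SampleMeta], path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "station": s.station,
                "transect": s.transect,
                "year": s.year,
                "depth_m": s.depth_m,
                "location": s.location,
                "volume_l": s.volume_l,
                "dna_conc": s.dna_conc,
                "is_control": s.is_control,
            }
            for s in samples
        ]
    )
    df.to_csv(path, sep=sep, index=False)


def write_lineage_table(lineages: Mapping[str, Lineage], path: str | Path, sep: str = "\t") -> None:
    rows = []
    for key, lin in lineages.items():
        row = {"taxon_key": key}
        row.update({rank: name or "" for rank, name in zip(RANKS, lin.as_tuple())})
        rows.append(row)
    pd.DataFrame(rows, columns=["taxon_key", *RANKS]).to_csv(path, sep=sep, index=False)


def read_esv_table(path: str | Path, marker: str | None = None, sep: str = "\t") -> ESVTable:
    df = pd.read_csv(path, sep=sep, dtype={"esv_id": str, "sample_id": str})
    if marker is None:
        if "marker" not in df.columns:
            raise ValueError("marker not given and no 'marker' column present")
        markers = df["marker"].unique()
        if len(markers) != 1:
            raise ValueError(f"expected one marker per table, got {list(markers)}")
        marker = str(markers[0])
        df = df.drop(columns="marker")
    return ESVTable(marker=marker, counts=df.reset_index(drop=True))


def write_esv_table(table: ESVTable, path: str | Path, sep: str = "\t") -> None:
    df = table.counts.copy()
    df.insert(0, "marker", table.marker)
    df.to_csv(path, sep=sep, index=False)
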