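"""Domain types and readers/writers for the formats the pipeline touches.

A barcoding analysis consumes one aligned FASTA per locus plus a TSV
metadata table keyed by record id; everything downstream (distances, gap
statistics, identification, trees) operates on the :class:`ReferenceLibrary`
built here.  Vernacular-name expectations for market queries live in a
:class:`VernacularLookup`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("barcodekit")

#: Sentinel species label for queries of unknown identity.
UNKNOWN = "UNKNOWN"

#: Valid locus labels.  "combined" marks a concatenated multi-locus alignment.
LOCI = ("rbcLa", "matK", "combined")

#: IUPAC nucleotide codes plus gap; sequences are stored upper-case.
DNA_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

#: Metadata TSV column order.
METADATA_COLUMNS = ("id", "species", "vernacular", "locus", "source", "status")


class BarcodekitError(ValueError):
    """Base class for domain errors raised by this package."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned barcode sequence with its specimen metadata.

    ``source="reference"`` records must carry a species label;
    ``source="query"`` records may be :data:`UNKNOWN`.
    """

    id: str
    species: str
    locus: str
    sequence: str
    source: str = "reference"
    vernacular: str | None = None
    conservation_status: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace(".", "-")
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise BarcodekitError(
                f"record {self.id!r}: invalid sequence characters {sorted(bad)}"
            )
        if self.locus not in LOCI:
            raise BarcodekitError(f"record {self.id!r}: unknown locus {self.locus!r}")
        if self.source not in ("reference", "query"):
            raise BarcodekitError(f"record {self.id!r}: bad source {self.source!r}")
        if self.source == "reference" and (not self.species or self.species == UNKNOWN):
            raise BarcodekitError(
                f"record {self.id!r}: reference records require a species label"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceLibrary:
    """An alignment of records for one locus (or a concatenation).

    ``locus_spans`` records, for combined libraries, the half-open column
    span each constituent locus occupies.
    """

    locus: str
    records: tuple[SequenceRecord, ...]
    locus_spans: Mapping[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise BarcodekitError("library must contain at least one record")
        object.__setattr__(self, "records", tuple(self.records))
        length = len(self.records[0])
        for rec in self.records:
            if len(rec) != length:
                raise BarcodekitError(
                    f"ragged alignment: record {rec.id!r} has length {len(rec)}, "
                    f"expected {length}"
                )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise BarcodekitError(f"duplicate record ids: {dup}")

    @property
    def alignment_length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def species_of(self) -> dict[str, str]:
        """Map record id -> species label."""
        return {r.id: r.species for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, ids: Iterable[str]) -> "ReferenceLibrary":
        keep = set(ids)
        return ReferenceLibrary(
            locus=self.locus,
            records=tuple(r for r in self.records if r.id in keep),
            locus_spans=self.locus_spans,
        )

    def reference_records(self) -> tuple[SequenceRecord, ...]:
        return tuple(r for r in self.records if r.source == "reference")


@dataclass
class VernacularLookup:
    """Many-to-many map from vernacular name to expected scientific name(s).

    A vernacular with no documented scientific name is stored with an empty
    synonym set and rendered as "?"; it is representable, never dropped.
    """

    mapping: dict[str, frozenset[str]] = field(default_factory=dict)

    def add(self, vernacular: str, species: Iterable[str]) -> None:
        known = frozenset(s for s in species if s and s != "?")
        self.mapping[vernacular] = self.mapping.get(vernacular, frozenset()) | known

    def expected(self, vernacular: str) -> frozenset[str] | None:
        """Expected species set, empty frozenset if documented-unknown,
        ``None`` if the vernacular is absent from the lookup entirely."""
        return self.mapping.get(vernacular)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"vernacular": v, "species": ";".join(sorted(s)) or "?"}
            for v, s in sorted(self.mapping.items())
        ]
        pd.DataFrame(rows, columns=["vernacular", "species"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VernacularLookup":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("?")
        lookup = cls()
        for _, row in df.iterrows():
            species = [] if row["species"] == "?" else row["species"].split(";")
            lookup.add(row["vernacular"], species)
        return lookup


# ---------------------------------------------------------------------------
# FASTA + metadata ingest
# ---------------------------------------------------------------------------

def read_alignment(
    path_fasta: str | Path, path_metadata_tsv: str | Path, locus: str
) -> ReferenceLibrary:
    """Read an aligned FASTA plus its metadata TSV into a library.

    FASTA ids must match metadata ids one-to-one; ragged alignments and
    missing metadata rows are rejected with the offending id named.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path_fasta), "fasta")}
    if not seqs:
        raise BarcodekitError(f"empty or unreadable FASTA: {path_fasta}")
    meta = pd.read_csv(path_metadata_tsv, sep="\t", dtype=str)
    if meta.empty:
        raise BarcodekitError(f"empty metadata table: {path_metadata_tsv}")
    meta = meta.where(meta.notna(), None)
    meta_ids = list(meta["id"])
    for rid in seqs:
        if rid not in meta_ids:
            raise BarcodekitError(f"no metadata row for FASTA record {rid!r}")
    records = []
    for _, row in meta.iterrows():
        rid = row["id"]
        if rid not in seqs:
            raise BarcodekitError(f"metadata id {rid!r} missing from FASTA")
        records.append(
            SequenceRecord(
                id=rid,
                species=row["species"] or UNKNOWN,
                vernacular=row.get("vernacular"),
                locus=row.get("locus") or locus,
                sequence=seqs[rid],
                source=row.get("source") or "reference",
                conservation_status=row.get("status"),
            )
        )
    return ReferenceLibrary(locus=locus, records=tuple(records))


def write_alignment(
    lib: ReferenceLibrary, path_fasta: str | Path, path_metadata_tsv: str | Path
) -> None:
    """Write a library back to FASTA (unwrapped lines) + metadata TSV."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in lib.records
    ]
    with open(path_fasta, "w") as fh:
        SeqIO.write(bio, fh, "fasta-2line")
    rows = [
        {
            "id": r.id,
            "species": r.species,
            "vernacular": r.vernacular,
            "locus": r.locus,
            "source": r.source,
            "status": r.conservation_status,
        }
        for r in lib.records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        path_metadata_tsv, sep="\t", index=False
    )


def concatenate(lib_a: ReferenceLibrary, lib_b: ReferenceLibrary) -> ReferenceLibrary:
    """Concatenate two per-locus libraries on their shared record ids.

    Records present in only one locus are dropped (and logged at WARN),
    matching the convention of analysing only specimens sequenced for both
    barcodes.  Order follows the first library's shared-id order.
    """
    by_id_b = {r.id: r for r in lib_b.records}
    shared = [r.id for r in lib_a.records if r.id in by_id_b]
    if not shared:
        raise BarcodekitError("concatenate: libraries share no record ids")
    dropped = (set(lib_a.ids) | set(lib_b.ids)) - set(shared)
    if dropped:
        logger.warning(
            "concatenate: dropping %d record(s) present in only one locus: %s",
            len(dropped),
            sorted(dropped),
        )
    len_a, len_b = lib_a.alignment_length, lib_b.alignment_length
    records = []
    for rid in shared:
        ra = next(r for r in lib_a.records if r.id == rid)
        rb = by_id_b[rid]
        records.append(replace(ra, locus="combined", sequence=ra.sequence + rb.sequence))
    spans = {lib_a.locus: (0, len_a), lib_b.locus: (len_a, len_a + len_b)}
    return ReferenceLibrary(locus="combined", records=tuple(records), locus_spans=spans)
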