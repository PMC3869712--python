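"""Reading, validation and haplotype collapsing of aligned barcode libraries.

A library is an aligned multi-FASTA plus a 4-column metadata TSV
(``seq_id``, ``species``, ``population``, ``locality``).  Sequences are
stored upper-case; ambiguity codes are preserved verbatim.  A translation
screen flags putative nuclear mitochondrial copies (numts) via in-frame
stop codons.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import AlignmentError, BarcodekitError, DuplicateIdError, MetadataError

#: characters accepted in an aligned nucleotide barcode
VALID_CHARS = frozenset("ACGTUNRYSWKMBDHV-")

#: default genetic code: invertebrate mitochondrial
INVERTEBRATE_MITO_TABLE = 5


@dataclass(frozen=True)
class BarcodeRecord:
    """One aligned barcode sequence with its group labels."""

    seq_id: str
    species: str
    sequence: str
    population: str = ""
    locality: str = ""

    def __post_init__(self):
        if not self.seq_id:
            raise MetadataError("seq_id must be non-empty")
        if not self.species:
            raise MetadataError(f"record {self.seq_id!r}: species label must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            raise AlignmentError(
                f"record {self.seq_id!r}: invalid characters {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class Alignment:
    """An ordered, validated collection of equal-length barcode records."""

    records: tuple[BarcodeRecord, ...]
    length: int

    @classmethod
    def from_records(cls, records: Iterable[BarcodeRecord]) -> "Alignment":
        records = tuple(records)
        if not records:
            raise AlignmentError("alignment must contain at least one record")
        length = len(records[0].sequence)
        bad = [r.seq_id for r in records if len(r.sequence) != length]
        if bad:
            raise AlignmentError(
                f"length mismatch (expected {length}) for records: {', '.join(bad)}"
            )
        counts = Counter(r.seq_id for r in records)
        dups = sorted(i for i, c in counts.items() if c > 1)
        if dups:
            raise DuplicateIdError(f"duplicate seq_ids: {', '.join(dups)}")
        return cls(records=records, length=length)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.seq_id for r in self.records)

    def record(self, seq_id: str) -> BarcodeRecord:
        for r in self.records:
            if r.seq_id == seq_id:
                return r
        raise KeyError(seq_id)

    def species_map(self) -> dict[str, str]:
        return {r.seq_id: r.species for r in self.records}

    def population_map(self) -> dict[str, str]:
        return {r.seq_id: r.population for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class Haplotype:
    """A distinct sequence and the record ids carrying it.

    ``hap_id`` is the lexicographically smallest member seq_id.
    """

    hap_id: str
    sequence: str
    members: tuple[str, ...]

    @property
    def multiplicity(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HaplotypeSet:
    """Collapsed haplotypes plus the records they came from."""

    haplotypes: tuple[Haplotype, ...]
    length: int
    records: Mapping[str, BarcodeRecord]

    @property
    def hap_ids(self) -> tuple[str, ...]:
        return tuple(h.hap_id for h in self.haplotypes)

    def haplotype(self, hap_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.hap_id == hap_id:
                return h
        raise KeyError(hap_id)

    def group_labels(self, hap: Haplotype, by: str = "species") -> frozenset[str]:
        """Distinct group labels among a haplotype's members."""
        if by == "species":
            return frozenset(self.records[m].species for m in hap.members)
        if by == "population":
            return frozenset(self.records[m].population for m in hap.members)
        if by == "species_population":
            return frozenset(
                (self.records[m].species, self.records[m].population) for m in hap.members
            )
        raise ValueError(f"unknown grouping {by!r}")

    def __len__(self) -> int:
        return len(self.haplotypes)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain aligned FASTA -> ordered {id: sequence} (upper-cased)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise DuplicateIdError(f"duplicate seq_id in FASTA: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise AlignmentError(f"no sequences found in {path}")
    return seqs


def read_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Metadata TSV with header seq_id/species/population/locality."""
    meta: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"seq_id", "species"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise MetadataError(
                f"metadata {path} must have a header including seq_id and species"
            )
        for row in reader:
            sid = row["seq_id"].strip()
            if sid in meta:
                raise DuplicateIdError(f"duplicate seq_id in metadata: {sid}")
            meta[sid] = {
                "species": row["species"].strip(),
                "population": (row.get("population") or "").strip(),
                "locality": (row.get("locality") or "").strip(),
            }
    return meta


def read_library(fasta_path: str | Path, metadata_path: str | Path) -> Alignment:
    """Read and cross-validate an aligned FASTA + metadata TSV.

    Records keep FASTA order.  Every FASTA id must be present in the
    metadata table; ids present only in the metadata are ignored.
    """
    seqs = read_fasta(fasta_path)
    meta = read_metadata(metadata_path)
    missing = sorted(set(seqs) - set(meta))
    if missing:
        raise MetadataError(
            f"FASTA ids missing from metadata: {', '.join(missing)}"
        )
    records = [
        BarcodeRecord(
            seq_id=sid,
            species=meta[sid]["species"],
            population=meta[sid]["population"],
            locality=meta[sid]["locality"],
            sequence=seq,
        )
        for sid, seq in seqs.items()
    ]
    return Alignment.from_records(records)


def collapse_haplotypes(aln: Alignment) -> HaplotypeSet:
    """Exact-string haplotype collapsing.

    Two records share a haplotype iff their sequences are identical
    character-for-character.  Haplotypes are ordered by representative id.
    """
    by_seq: dict[str, list[str]] = {}
    for rec in aln.records:
        by_seq.setdefault(rec.sequence, []).append(rec.seq_id)
    haps = [
        Haplotype(hap_id=min(members), sequence=seq, members=tuple(sorted(members)))
        for seq, members in by_seq.items()
    ]
    haps.sort(key=lambda h: h.hap_id)
    return HaplotypeSet(
        haplotypes=tuple(haps),
        length=aln.length,
        records={r.seq_id: r for r in aln.records},
    )


@dataclass(frozen=True)
class NumtRecord:
    seq_id: str
    frame: int
    stop_codons: int

    @property
    def flagged(self) -> bool:
        return self.stop_codons > 0


@dataclass(frozen=True)
class NumtReport:
    frame: int
    records: tuple[NumtRecord, ...]

    @property
    def flagged_ids(self) -> tuple[str, ...]:
        return tuple(r.seq_id for r in self.records if r.flagged)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["seq_id", "frame", "stop_codons", "flagged"])
            for r in self.records:
                w.writerow([r.seq_id, r.frame, r.stop_codons, int(r.flagged)])


def _count_stops(sequence: str, frame: int, stop_codons: frozenset[str]) -> int:
    # gap and N columns are dropped before codon assembly; codons containing
    # any other non-ACGT character translate to unknown, never to a stop
    chars = [c for c in sequence if c not in "-N"]
    stops = 0
    for i in range(frame, len(chars) - 2, 3):
        codon = "".join(chars[i : i + 3])
        if codon in stop_codons:
            stops += 1
    return stops


def screen_numts(
    aln: Alignment,
    code_table: int = INVERTEBRATE_MITO_TABLE,
    frame: int | str = "auto",
) -> NumtReport:
    """Translation screen for numt-like sequences.

    With ``frame="auto"`` the single reading frame minimizing the total
    stop-codon count across the whole library is chosen (a library-level
    choice avoids per-record frame shopping that would mask frameshifts),
    then every record with >=1 stop in that frame is flagged.
    """
    if len(aln) == 0:
        raise AlignmentError("cannot screen an empty alignment")
    table = CodonTable.unambiguous_dna_by_id[code_table]
    stop_codons = frozenset(table.stop_codons)
    if frame == "auto":
        totals = {
            f: sum(_count_stops(r.sequence, f, stop_codons) for r in aln.records)
            for f in (0, 1, 2)
        }
        chosen = min((0, 1, 2), key=lambda f: (totals[f], f))
    else:
        chosen = int(frame)
        if chosen not in (0, 1, 2):
            raise BarcodekitError(f"frame must be auto or 0/1/2, got {frame!r}")
    recs = tuple(
        NumtRecord(
            seq_id=r.seq_id,
            frame=chosen,
            stop_codons=_count_stops(r.sequence, chosen, stop_codons),
        )
        for r in aln.records
    )
    return NumtReport(frame=chosen, records=recs)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in aln.records:
            fh.write(f">{r.seq_id}\n{r.sequence}\n")


def write_metadata(aln: Alignment, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["seq_id", "species", "population", "locality"])
        for r in aln.records:
            w.writerow([r.seq_id, r.species, r.population, r.locality])
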