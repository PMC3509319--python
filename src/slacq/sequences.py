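"""Protein sequences, multiple alignments, and coordinate-checked region extraction.

Residue coordinates are 1-based and inclusive on both ends throughout the
public interface (matching the ``K103_K516`` style used to label channel
regions); internal column indices are 0-based half-open and never appear in
reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted on input; 'X' scores as background downstream and counts
#: as a mismatch in identity computations
ALPHABET = frozenset(AMINO_ACIDS + "X")
GAP = "-"


class SequenceError(ValueError):
    """Raised for malformed sequence or alignment input."""


@dataclass(frozen=True)
class ProteinSequence:
    """An ungapped amino-acid sequence with an identifier and optional species tag."""

    id: str
    residues: str
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceError(f"empty sequence record: {self.id!r}")
        if not self.residues.isupper():
            raise SequenceError(f"residues must be uppercase: {self.id!r}")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise SequenceError(
                f"invalid residues {sorted(bad)} in {self.id!r} "
                f"(alphabet is {AMINO_ACIDS} plus X; gaps not allowed)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RegionSpec:
    """A 1-based inclusive residue interval, optionally anchored to expected residues.

    ``start_aa``/``end_aa`` guard against extracting from the wrong isoform or a
    re-annotated proteome release: extraction fails loudly when the residue at
    the stated coordinate is not the stated letter.
    """

    start_pos: int
    end_pos: int
    start_aa: str | None = None
    end_aa: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start_pos <= self.end_pos):
            raise SequenceError(
                f"invalid region: need 1 <= start_pos <= end_pos, "
                f"got {self.start_pos}..{self.end_pos}"
            )

    def __len__(self) -> int:
        return self.end_pos - self.start_pos + 1


def extract_region(seq: ProteinSequence, region: RegionSpec) -> ProteinSequence:
    """Extract ``region`` from ``seq`` (1-based, inclusive), checking anchors.

    Raises :class:`SequenceError` when coordinates run off the sequence or an
    expected anchor residue does not match.
    """
    if region.end_pos > len(seq):
        raise SequenceError(
            f"region {region.start_pos}..{region.end_pos} out of bounds for "
            f"{seq.id!r} (length {len(seq)})"
        )
    if region.start_aa is not None:
        found = seq.residues[region.start_pos - 1]
        if found != region.start_aa:
            raise SequenceError(
                f"{seq.id!r}: expected {region.start_aa} at position "
                f"{region.start_pos}, found {found} (wrong isoform/annotation?)"
            )
    if region.end_aa is not None:
        found = seq.residues[region.end_pos - 1]
        if found != region.end_aa:
            raise SequenceError(
                f"{seq.id!r}: expected {region.end_aa} at position "
                f"{region.end_pos}, found {found} (wrong isoform/annotation?)"
            )
    sub = seq.residues[region.start_pos - 1 : region.end_pos]
    return ProteinSequence(
        id=f"{seq.id}-{region.start_pos}_{region.end_pos}",
        residues=sub,
        species=seq.species,
    )


@dataclass
class MultipleAlignment:
    """An ordered set of equal-length gapped rows over the residue alphabet.

    Rows are ``(id, gapped_row)`` pairs; removing gaps from a row must yield a
    valid :class:`ProteinSequence`.
    """

    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise SequenceError("alignment must contain at least one row")
        ncol = len(self.records[0][1])
        ids = set()
        for rid, row in self.records:
            if len(row) != ncol:
                raise SequenceError(
                    f"row {rid!r} has length {len(row)}, expected {ncol}"
                )
            if rid in ids:
                raise SequenceError(f"duplicate alignment row id: {rid!r}")
            ids.add(rid)
            bad = set(row) - ALPHABET - {GAP}
            if bad:
                raise SequenceError(f"invalid characters {sorted(bad)} in row {rid!r}")
            if not row.replace(GAP, ""):
                raise SequenceError(f"row {rid!r} is all gaps")

    @property
    def ncol(self) -> int:
        return len(self.records[0][1])

    @property
    def nrow(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def row(self, rid: str) -> str:
        for r, row in self.records:
            if r == rid:
                return row
        raise KeyError(rid)

    def ungapped(self, rid: str) -> ProteinSequence:
        return ProteinSequence(id=rid, residues=self.row(rid).replace(GAP, ""))

    def ungapped_all(self) -> list[ProteinSequence]:
        return [self.ungapped(rid) for rid in self.ids]

    def column(self, col: int) -> str:
        """Characters of 0-based column ``col``, one per row."""
        return "".join(row[col] for _, row in self.records)

    def residue_to_column(self, rid: str) -> list[int]:
        """0-based alignment column carrying each residue of the ungapped row."""
        return [i for i, c in enumerate(self.row(rid)) if c != GAP]


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed)

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a protein FASTA file, preserving record order.

    Duplicate ids and empty records raise :class:`SequenceError` naming the
    offending record.
    """
    seqs: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if not residues:
            raise SequenceError(f"empty FASTA record: {rec.id!r}")
        seqs.append(ProteinSequence(id=rec.id, residues=residues))
    return seqs


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_alignment_fasta(path: str | Path) -> MultipleAlignment:
    """Read a gapped FASTA file as a :class:`MultipleAlignment`."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate alignment id: {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    return MultipleAlignment(records=records)


def write_alignment_fasta(aln: MultipleAlignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, row in aln.records:
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a gene→species TSV (columns gene_id, species_id; header optional)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SequenceError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            if lineno == 1 and parts[0].lower() in ("gene_id", "gene", "leaf"):
                continue
            mapping[parts[0]] = parts[1]
    return mapping


def write_species_map(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tspecies_id\n")
        for gene, sp in sorted(mapping.items()):
            fh.write(f"{gene}\t{sp}\n")
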