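"""FASTA input/output and genome-set assembly.

Genomes enter the pipeline as one protein FASTA (``.faa``) per genome,
optionally paired with a nucleotide CDS FASTA (``.fna``), listed in a
tab-separated manifest.  Manifest row order is the canonical genome order:
every downstream matrix, vector table and tree uses it as the determinism
anchor.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio.SeqIO.FastaIO import SimpleFastaParser

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
# non-canonical codes that real annotations contain; accepted at parse time
PROTEIN_EXTENDED = PROTEIN_ALPHABET | frozenset("BJOUXZ*")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

_ALPHABETS = {"protein": PROTEIN_EXTENDED, "nucleotide": NUCLEOTIDE_ALPHABET}

FASTA_WRAP = 60  # fixed column wrap for bit-reproducible output


class FastaError(ValueError):
    """Malformed FASTA content or manifest."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single sequence with its FASTA identity.

    Residues are stored uppercase.  ``molecule_type`` is ``"protein"``
    (20 canonical amino acids plus B/J/O/U/X/Z/*) or ``"nucleotide"``
    (A/C/G/T/N).
    """

    id: str
    residues: str
    molecule_type: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("record id must be a non-empty token")
        if not self.residues:
            raise FastaError(f"record {self.id!r}: empty sequence")
        if self.molecule_type not in _ALPHABETS:
            raise FastaError(f"unknown molecule_type {self.molecule_type!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GenomeProteome:
    """All proteins of one genome, plus (optionally) its CDS set."""

    genome_id: str
    proteins: list[SequenceRecord]
    cds: list[SequenceRecord] | None = None

    def __post_init__(self) -> None:
        if not self.proteins:
            raise FastaError(f"genome {self.genome_id!r}: no proteins")


@dataclass
class GenomeSet:
    """Ordered mapping genome_id -> GenomeProteome (manifest order)."""

    genomes: dict[str, GenomeProteome] = field(default_factory=dict)

    def add(self, genome: GenomeProteome) -> None:
        if genome.genome_id in self.genomes:
            raise FastaError(f"duplicate genome_id {genome.genome_id!r}")
        self.genomes[genome.genome_id] = genome

    def __iter__(self):
        return iter(self.genomes.values())

    def __len__(self) -> int:
        return len(self.genomes)

    def __getitem__(self, genome_id: str) -> GenomeProteome:
        return self.genomes[genome_id]

    @property
    def genome_ids(self) -> list[str]:
        return list(self.genomes)


def _validate_residues(rec_id: str, residues: str, molecule_type: str) -> None:
    alphabet = _ALPHABETS[molecule_type]
    for pos, ch in enumerate(residues):
        if ch not in alphabet:
            raise FastaError(
                f"record {rec_id!r}: illegal {molecule_type} residue "
                f"{ch!r} at position {pos}"
            )


def read_fasta(path: str | os.PathLike, molecule_type: str) -> list[SequenceRecord]:
    """Parse a FASTA file into validated :class:`SequenceRecord` objects.

    Residues are uppercased; record order is preserved.  Raises
    :class:`FastaError` on an empty file, a duplicate id, or a residue
    outside the molecule alphabet (naming record and position).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            header = header.strip()
            rec_id, _, description = header.partition(" ")
            if not rec_id:
                raise FastaError(f"{path}: header with empty id")
            if rec_id in seen:
                raise FastaError(f"{path}: duplicate record id {rec_id!r}")
            seen.add(rec_id)
            residues = "".join(seq.split()).upper()
            if not residues:
                raise FastaError(f"{path}: record {rec_id!r} has no residues")
            _validate_residues(rec_id, residues, molecule_type)
            records.append(
                SequenceRecord(rec_id, residues, molecule_type, description.strip())
            )
    if not records:
        raise FastaError(f"{path}: no records")
    return records


def write_fasta(records: list[SequenceRecord], path: str | os.PathLike) -> None:
    """Write records as FASTA, 60 residues per line, ``>id description``."""
    if not records:
        raise FastaError("write_fasta: no records")
    with open(path, "w") as out:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            out.write(header + "\n")
            for i in range(0, len(rec.residues), FASTA_WRAP):
                out.write(rec.residues[i : i + FASTA_WRAP] + "\n")


def load_genome_set(manifest_path: str | os.PathLike) -> GenomeSet:
    """Build a :class:`GenomeSet` from a TSV manifest.

    The manifest has a header row with columns ``genome_id``,
    ``proteins_path`` and optionally ``cds_path``; relative paths are
    resolved against the manifest's directory.
    """
    base = os.path.dirname(os.path.abspath(manifest_path))
    gs = GenomeSet()
    with open(manifest_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            gid_col = header.index("genome_id")
            prot_col = header.index("proteins_path")
        except ValueError as exc:
            raise FastaError(f"{manifest_path}: missing manifest column: {exc}")
        cds_col = header.index("cds_path") if "cds_path" in header else None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            gid = fields[gid_col]
            prot_path = os.path.join(base, fields[prot_col])
            if not os.path.exists(prot_path):
                raise FastaError(f"genome {gid!r}: missing file {prot_path}")
            proteins = read_fasta(prot_path, "protein")
            cds = None
            if cds_col is not None and len(fields) > cds_col and fields[cds_col]:
                cds_path = os.path.join(base, fields[cds_col])
                if not os.path.exists(cds_path):
                    raise FastaError(f"genome {gid!r}: missing file {cds_path}")
                cds = read_fasta(cds_path, "nucleotide")
            gs.add(GenomeProteome(gid, proteins, cds))
    if len(gs) == 0:
        raise FastaError(f"{manifest_path}: empty manifest")
    return gs
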