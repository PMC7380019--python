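"""Six-frame ORF extraction from genome assemblies.

Candidate proteins are taken as maximal stop-free stretches of the six
translated frames (no start-codon requirement): the downstream motif scan
decides which of them are PPR genes, so demanding ATG initiation would only
discard real repeat tracts on partial scaffolds. Internal coordinates are
0-based half-open; everything reported is 1-based inclusive (GFF3
convention), with reverse-strand spans rendered high->low in tabular
reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeSequence",
    "GenomicInterval",
    "OrfRecord",
    "six_frame_orfs",
    "interval_length",
    "read_genomes",
    "write_orf_fasta",
    "write_orf_gff3",
]

# IUPAC DNA with ambiguity codes; anything else is a hard input error.
_DNA_OK = set("ACGTNRYSWKMBDHVacgtnryswkmbdhv")

_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        bases = "TCAG"
        aas = (
            "FFLLSSSSYY**CC*W"
            "LLLLPPPPHHQQRRRR"
            "IIIMTTTTNNKKSSRR"
            "VVVVAAAADDEEGGGG"
        )
        i = 0
        for b1 in bases:
            for b2 in bases:
                for b3 in bases:
                    _CODON_TABLE[b1 + b2 + b3] = aas[i]
                    i += 1
    return _CODON_TABLE


@dataclass(frozen=True)
class GenomeSequence:
    """A chromosome or scaffold to be scanned."""

    id: str
    residues: str
    source_accession: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """1-based inclusive interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval [{self.start}-{self.end}] on {self.seq_id}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def render_span(self) -> str:
        """Physical position as printed in gene tables: reverse-strand
        features are shown end->start."""
        if self.strand == "-":
            return f"[{self.end}–{self.start}] (REVERSE)"
        return f"[{self.start}–{self.end}] (FORWARD)"


def interval_length(iv: GenomicInterval) -> int:
    """Inclusive length in nucleotides (end - start + 1)."""
    return iv.length


@dataclass(frozen=True)
class OrfRecord:
    """A stop-free translated stretch with its genomic placement."""

    interval: GenomicInterval
    frame: int  # 0..2 offset on the strand read 5'->3'
    aa_seq: str
    nt_seq: str

    def __post_init__(self):
        if len(self.nt_seq) != 3 * len(self.aa_seq):
            raise ValueError("nt_seq must be exactly 3x aa_seq length")

    @property
    def orf_id(self) -> str:
        iv = self.interval
        return f"{iv.seq_id}:{iv.start}-{iv.end}({iv.strand})"


def translate_dna(seq: str) -> str:
    """Translate an in-frame DNA string with the standard code.

    Codons containing anything other than A/C/G/T (N and other ambiguity
    codes) become ``X``; stops are ``*``. Trailing partial codons dropped.
    """
    table = _codon_table()
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        out.append(table.get(seq[i : i + 3], "X"))
    return "".join(out)


def _validate_dna(genome: GenomeSequence) -> None:
    bad = set(genome.residues) - _DNA_OK
    if bad:
        raise ValueError(
            f"sequence {genome.id!r} contains non-DNA characters: "
            f"{sorted(bad)!r}"
        )


def six_frame_orfs(genome: GenomeSequence, min_orf_aa: int = 93) -> list[OrfRecord]:
    """All maximal stop-free ORFs of length >= ``min_orf_aa`` in six frames.

    The length cutoff is inclusive (>= 93 aa keeps 93-aa proteins). Order is
    deterministic: (seq_id, start, strand, frame).
    """
    if min_orf_aa < 1:
        raise ValueError("min_orf_aa must be >= 1")
    if not genome.residues:
        raise ValueError(f"sequence {genome.id!r} is empty")
    _validate_dna(genome)

    seq = genome.residues.upper()
    n = len(seq)
    rc = str(Seq(seq).reverse_complement())
    records: list[OrfRecord] = []
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            aa = translate_dna(s[frame:])
            for m in re.finditer(r"[^*]+", aa):
                if m.end() - m.start() < min_orf_aa:
                    continue
                if set(m.group()) == {"X"}:
                    continue  # fully masked stretch, nothing translatable
                lo = frame + 3 * m.start()  # 0-based on this strand
                hi = frame + 3 * m.end()
                if strand == "+":
                    g_lo, g_hi = lo, hi
                else:
                    g_lo, g_hi = n - hi, n - lo
                iv = GenomicInterval(genome.id, g_lo + 1, g_hi, strand)
                records.append(
                    OrfRecord(iv, frame, m.group(), s[lo:hi])
                )
    records.sort(
        key=lambda r: (r.interval.seq_id, r.interval.start, r.interval.strand, r.frame)
    )
    return records


def extract_nt(genome: GenomeSequence, iv: GenomicInterval) -> str:
    """Strand-aware sequence of an interval (5'->3' on the feature strand)."""
    sub = genome.residues.upper()[iv.start - 1 : iv.end]
    if iv.strand == "-":
        return str(Seq(sub).reverse_complement())
    return sub


def read_genomes(path: str | Path, source_accession: str = "") -> list[GenomeSequence]:
    """Load a multi-FASTA assembly."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(GenomeSequence(rec.id, str(rec.seq), source_accession))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_orf_fasta(orfs: Iterable[OrfRecord], aa_path: str | Path, nt_path: str | Path | None = None) -> None:
    with open(aa_path, "w") as fh:
        for o in orfs:
            fh.write(f">{o.orf_id}\n{o.aa_seq}\n")
    if nt_path is not None:
        with open(nt_path, "w") as fh:
            for o in orfs:
                fh.write(f">{o.orf_id}\n{o.nt_seq}\n")


def write_orf_gff3(orfs: Iterable[OrfRecord], path: str | Path, feature_type: str = "open_reading_frame") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in orfs:
            iv = o.interval
            fh.write(
                "\t".join(
                    [
                        iv.seq_id,
                        "rflscan",
                        feature_type,
                        str(iv.start),
                        str(iv.end),
                        ".",
                        iv.strand,
                        "0",
                        f"ID={o.orf_id};frame={o.frame}",
                    ]
                )
                + "\n"
            )
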