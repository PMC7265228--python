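"""Sequence and annotation I/O on a single 0-based half-open coordinate frame.

All intervals in this package are 0-based half-open on the top strand;
conversion to 1-based (GFF3) happens only at the format boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_TYPES = frozenset({"gene", "rss5", "rss3", "coding", "cluster", "intergenic"})


def normalize_residues(raw: str, context: str = "") -> str:
    """Uppercase, map U->T, demote anything outside {A,C,G,T,N} to N.

    Logs one warning per sequence if any character was demoted.
    """
    s = raw.upper().replace("U", "T")
    if not set(s) <= _VALID:
        n_bad = sum(c not in _VALID for c in s)
        logger.warning(
            "%s: %d non-ACGTN character(s) demoted to N", context or "sequence", n_bad
        )
        s = "".join(c if c in _VALID else "N" for c in s)
    return s


def normalize_gene_name(name: str) -> str:
    """Canonicalize dash typography (en/em dash, minus) to ASCII hyphen."""
    for dash in ("–", "—", "−"):
        name = name.replace(dash, "-")
    return name


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval with strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def shift(self, offset: int) -> "Interval":
        return Interval(self.start + offset, self.end + offset, self.strand)


@dataclass
class NucSequence:
    """A named DNA string over {A,C,G,T,N} with provenance."""

    id: str
    residues: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        if not set(self.residues) <= _VALID:
            raise ValueError(
                f"sequence {self.id!r} contains non-normalized residues; "
                "use NucSequence.from_raw"
            )

    @classmethod
    def from_raw(cls, id: str, raw: str, source: str = "") -> "NucSequence":
        return cls(id=id, residues=normalize_residues(raw, context=id), source=source)

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def extract(seq: NucSequence, iv: Interval) -> NucSequence:
    """Subsequence at *iv*; strand '-' returns the reverse complement."""
    if iv.end > len(seq):
        raise IndexError(
            f"interval [{iv.start}, {iv.end}) out of bounds for {seq.id!r} "
            f"of length {len(seq)}"
        )
    sub = seq.residues[iv.start : iv.end]
    if iv.strand == "-":
        sub = reverse_complement(sub)
    return NucSequence(
        id=f"{seq.id}:{iv.start}-{iv.end}({iv.strand})",
        residues=sub,
        source=seq.source,
    )


@dataclass
class AnnotationRecord:
    name: str
    interval: Interval
    feature_type: str = "gene"
    seq_id: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("annotation name must be nonempty")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature_type {self.feature_type!r}")
        self.name = normalize_gene_name(self.name)


def read_sequences(path: str | Path, format: str = "fasta") -> list[NucSequence]:
    """Read FASTA or GenBank records, normalizing residues.

    Raises OSError for unreadable files and ValueError when no record parses.
    """
    path = Path(path)
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {format!r}")
    if not path.exists():
        raise OSError(f"cannot read sequence file: {path}")
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise ValueError(f"no {format} records found in {path}")
    return [
        NucSequence.from_raw(rec.id, str(rec.seq), source=str(path)) for rec in records
    ]


def write_fasta(seqs: Iterable[NucSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


# --- annotation I/O ---------------------------------------------------------
#
# BED: chrom start end name score strand feature_type  (col 7 carries the
# feature type; columns 1-6 are standard BED6, 0-based half-open).
# GFF3: 1-based inclusive, feature type in column 3, Name attribute.


def write_annotations(
    records: list[AnnotationRecord], path: str | Path, format: str = "bed"
) -> None:
    if format == "bed":
        with open(path, "w") as fh:
            for r in records:
                fh.write(
                    f"{r.seq_id or 'seq'}\t{r.interval.start}\t{r.interval.end}"
                    f"\t{r.name}\t0\t{r.interval.strand}\t{r.feature_type}\n"
                )
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in records:
                fh.write(
                    f"{r.seq_id or 'seq'}\tighdkit\t{r.feature_type}"
                    f"\t{r.interval.start + 1}\t{r.interval.end}\t.\t"
                    f"{r.interval.strand}\t.\tName={r.name}\n"
                )
    else:
        raise ValueError(f"unsupported annotation format {format!r}")


def read_annotations(path: str | Path, format: str = "bed") -> list[AnnotationRecord]:
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if format == "bed":
                seq_id, start, end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
                strand = cols[5] if len(cols) > 5 else "+"
                ftype = cols[6] if len(cols) > 6 else "gene"
            elif format == "gff3":
                seq_id = cols[0]
                ftype = cols[2]
                start, end = int(cols[3]) - 1, int(cols[4])
                strand = cols[6]
                name = ""
                for kv in cols[8].split(";"):
                    if kv.startswith("Name="):
                        name = kv[5:]
            else:
                raise ValueError(f"unsupported annotation format {format!r}")
            records.append(
                AnnotationRecord(
                    name=name,
                    interval=Interval(start, end, strand),
                    feature_type=ftype,
                    seq_id=seq_id,
                )
            )
    return records
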