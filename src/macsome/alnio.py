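"""Read-to-assembly alignment records (PAF and SAM).

A minimal, format-agnostic carrier for long-read alignments.  Query
coordinates always refer to the original, forward-orientation read (the
PAF convention); SAM records on the reverse strand are converted
accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pysam

__all__ = ["AlnRecord", "read_paf", "write_paf", "read_sam"]


@dataclass(frozen=True)
class AlnRecord:
    """One read-to-contig alignment (0-based half-open coordinates)."""

    read_id: str
    contig: str
    rstart: int
    rend: int
    qstart: int
    qend: int
    strand: str  # "+" or "-"
    mapq: int = 60
    is_primary: bool = True
    read_len: int = 0
    contig_len: int = 0
    n_match: int = 0

    def __post_init__(self):
        if self.rstart >= self.rend:
            raise ValueError(f"empty reference interval for read {self.read_id!r}")
        if self.qstart >= self.qend:
            raise ValueError(f"empty query interval for read {self.read_id!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def to_paf_line(self) -> str:
        aln_len = max(self.rend - self.rstart, self.qend - self.qstart)
        n_match = self.n_match or aln_len
        fields = [
            self.read_id,
            self.read_len or self.qend,
            self.qstart,
            self.qend,
            self.strand,
            self.contig,
            self.contig_len or self.rend,
            self.rstart,
            self.rend,
            n_match,
            aln_len,
            self.mapq,
        ]
        line = "\t".join(str(f) for f in fields)
        if not self.is_primary:
            line += "\ttp:A:S"
        return line


def read_paf(path: str | Path) -> list[AlnRecord]:
    """Read a PAF file (12 mandatory columns; tp:A tags honoured)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: PAF line has {len(fields)} < 12 columns")
            try:
                qlen, qstart, qend = int(fields[1]), int(fields[2]), int(fields[3])
                tlen, tstart, tend = int(fields[6]), int(fields[7]), int(fields[8])
                n_match, mapq = int(fields[9]), int(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed PAF numeric field: {exc}") from None
            is_primary = True
            for tag in fields[12:]:
                if tag.startswith("tp:A:") and tag[5] in "SI":
                    is_primary = False
            records.append(
                AlnRecord(
                    read_id=fields[0],
                    contig=fields[5],
                    rstart=tstart,
                    rend=tend,
                    qstart=qstart,
                    qend=qend,
                    strand=fields[4],
                    mapq=mapq,
                    is_primary=is_primary,
                    read_len=qlen,
                    contig_len=tlen,
                    n_match=n_match,
                )
            )
    return records


def write_paf(records: Iterable[AlnRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_paf_line() + "\n")


def read_sam(path: str | Path) -> list[AlnRecord]:
    """Read alignments from SAM/BAM via pysam, converting to PAF-style coords."""
    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        lengths = dict(zip(sam.references or (), sam.lengths or ()))
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            qlen = aln.infer_read_length() or aln.query_length
            qstart = aln.query_alignment_start
            qend = aln.query_alignment_end
            if aln.is_reverse:
                # pysam query coords refer to the stored (revcomp) sequence;
                # flip back onto the original read
                qstart, qend = qlen - qend, qlen - qstart
            records.append(
                AlnRecord(
                    read_id=aln.query_name,
                    contig=aln.reference_name,
                    rstart=aln.reference_start,
                    rend=aln.reference_end,
                    qstart=qstart,
                    qend=qend,
                    strand="-" if aln.is_reverse else "+",
                    mapq=aln.mapping_quality,
                    is_primary=not (aln.is_secondary or aln.is_supplementary),
                    read_len=qlen,
                    contig_len=lengths.get(aln.reference_name, 0),
                )
            )
    return records
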