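"""Genome-architecture statistics for a fragmented MAC genome.

Covers the quantities summarising minichromosomal architecture: the
telomere-bearing read fraction p, the inter-telomere spacing (mean DNA
molecule length) estimated from p and the mean telomere-trimmed read
length, the two-telomere read fraction, nano/mini/chromosomal
classification, SNP heterozygosity arithmetic, AT fraction and intron
length summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .telomere import ReadTeloAnnotation, trimmed_length

__all__ = [
    "TeloFractionStats",
    "SpacingEstimate",
    "ArchitectureCall",
    "telo_fraction",
    "mean_spacing",
    "two_telomere_fraction",
    "expected_two_telomere_fraction",
    "classify_architecture",
    "heterozygosity",
    "at_fraction",
    "gc_fraction",
    "intron_length_summary",
]


@dataclass
class TeloFractionStats:
    """Telomere-bearing read counts and the trimmed mean read length."""

    n_reads: int
    n_telo: int
    mean_read_len: float  # telomere-trimmed

    @property
    def p(self) -> float:
        return self.n_telo / self.n_reads


@dataclass
class SpacingEstimate:
    """Mean inter-telomere distance (mean MAC molecule length), in bp."""

    m_hat: float
    method: str
    ci_lower: float
    ci_upper: float


@dataclass
class ArchitectureCall:
    label: str
    median_molecule_len: float
    mean_genes_per_molecule: float


def telo_fraction(annotations: Sequence[ReadTeloAnnotation]) -> TeloFractionStats:
    """Fraction of telomere-bearing reads and trimmed mean read length."""
    if not annotations:
        raise ValueError("no read annotations supplied")
    n_telo = sum(a.is_telomere_bearing for a in annotations)
    mean_len = float(np.mean([trimmed_length(a) for a in annotations]))
    return TeloFractionStats(n_reads=len(annotations), n_telo=n_telo, mean_read_len=mean_len)


def _spacing_point(p: float, lbar: float, method: str) -> float:
    if method == "linear":
        return 2.0 * lbar / p
    if method == "poisson":
        if p >= 1.0:
            raise ValueError("poisson estimator undefined at p = 1")
        return 2.0 * lbar / (-math.log1p(-p))
    raise ValueError(f"unknown spacing method {method!r}")


def mean_spacing(
    annotations: Sequence[ReadTeloAnnotation],
    method: str = "linear",
    n_boot: int = 200,
    seed: int = 0,
) -> SpacingEstimate:
    """Estimate the mean MAC molecule length from telomere-bearing reads.

    ``linear``: M = 2*Lbar/p — each molecule contributes two telomeres and
    a read of mean (trimmed) length Lbar intercepts each with probability
    Lbar/M.  ``poisson``: M = 2*Lbar/(-ln(1-p)), treating telomere
    interceptions as Poisson and correcting for reads that would span
    multiple telomeres.  The CI is a seeded percentile bootstrap over reads.
    """
    stats = telo_fraction(annotations)
    if stats.p <= 0.0:
        raise ValueError("spacing estimator undefined when no telomere-bearing reads")
    if stats.p >= 1.0 and method == "poisson":
        raise ValueError("poisson estimator undefined at p = 1")
    m_hat = _spacing_point(stats.p, stats.mean_read_len, method)
    telo = np.array([a.is_telomere_bearing for a in annotations], dtype=bool)
    lens = np.array([trimmed_length(a) for a in annotations], dtype=float)
    rng = np.random.default_rng(seed)
    n = len(telo)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        pb = telo[idx].mean()
        if pb <= 0 or (method == "poisson" and pb >= 1):
            continue
        boots.append(_spacing_point(pb, lens[idx].mean(), method))
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        lo, hi = min(lo, m_hat), max(hi, m_hat)
    else:
        lo = hi = m_hat
    return SpacingEstimate(m_hat=m_hat, method=method, ci_lower=float(lo), ci_upper=float(hi))


def two_telomere_fraction(annotations: Sequence[ReadTeloAnnotation]) -> float:
    """Observed fraction of reads bound by telomeres on both ends."""
    if not annotations:
        return 0.0
    return sum(a.cls == "both_ends" for a in annotations) / len(annotations)


def expected_two_telomere_fraction(
    molecule_lens: Sequence[float],
    read_lens: Sequence[float],
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo expectation of the two-telomere read fraction.

    Reads are modelled as fragments of molecules (molecule picked with
    probability proportional to its expected fragment count, fragment
    lengths drawn from ``read_lens``); a read carries both telomeres
    exactly when its molecule is no longer than the drawn read length and
    is therefore recovered whole.
    """
    mol = np.asarray(molecule_lens, dtype=float)
    rl = np.asarray(read_lens, dtype=float)
    if mol.size == 0 or rl.size == 0:
        raise ValueError("molecule and read length samples must be nonempty")
    rng = np.random.default_rng(seed)
    lbar = rl.mean()
    weights = np.maximum(mol / lbar, 1.0)
    weights = weights / weights.sum()
    mi = rng.choice(mol.size, size=n_mc, p=weights)
    ls = rng.choice(rl, size=n_mc, replace=True)
    return float((ls >= mol[mi]).mean())


def classify_architecture(
    median_molecule_len: float,
    mean_genes_per_molecule: float,
    nano_max_len: float = 10_000.0,
    nano_max_genes: float = 2.0,
    chromosomal_min_len: float = 500_000.0,
) -> ArchitectureCall:
    """Classify a MAC genome as nano-, mini- or chromosomal.

    Nanochromosomal genomes (e.g. *Oxytricha*) package single genes on
    molecules of a few kbp; chromosomal MACs (e.g. *Tetrahymena*, 570 kbp
    average) carry hundreds of genes per molecule; minichromosomal
    architectures sit in between (tens to a few hundred genes, ~100 kbp).
    The category boundaries are acknowledged to be rough and overlap.
    """
    if median_molecule_len <= 0 or mean_genes_per_molecule <= 0:
        raise ValueError("inputs must be positive")
    if median_molecule_len <= nano_max_len or mean_genes_per_molecule <= nano_max_genes:
        label = "nanochromosomal"
    elif median_molecule_len >= chromosomal_min_len:
        label = "chromosomal"
    else:
        label = "minichromosomal"
    return ArchitectureCall(
        label=label,
        median_molecule_len=median_molecule_len,
        mean_genes_per_molecule=mean_genes_per_molecule,
    )


def heterozygosity(n_het_snps: int, callable_len: int) -> float:
    """Heterozygous SNPs per callable site."""
    if callable_len <= 0:
        raise ValueError("callable_len must be positive")
    if n_het_snps < 0:
        raise ValueError("n_het_snps must be nonnegative")
    return n_het_snps / callable_len


def _iter_seqs(source) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        for rec in SeqIO.parse(str(source), "fasta"):
            yield str(rec.seq)
    elif isinstance(source, Mapping):
        yield from source.values()
    else:
        yield from source


def at_fraction(source) -> float:
    """A+T fraction over unambiguous bases of a FASTA file / dict / iterable."""
    at = acgt = 0
    for seq in _iter_seqs(source):
        s = seq.upper()
        a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
        at += a + t
        acgt += a + c + g + t
    if acgt == 0:
        raise ValueError("no unambiguous bases found")
    return at / acgt


def gc_fraction(source) -> float:
    return 1.0 - at_fraction(source)


def _gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for kv in attr.strip().split(";"):
        if not kv:
            continue
        if "=" not in kv:
            continue
        k, v = kv.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def intron_length_summary(gff_path: str | Path) -> pd.Series:
    """Intron length histogram from exon features of a GFF3 file.

    Introns are gaps between consecutive exons of the same parent
    transcript; with 1-based inclusive GFF coordinates the intron length
    is ``next_exon_start - prev_exon_end - 1``.  Returns a Series indexed
    by intron length with intron counts as values.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{gff_path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            if fields[2].lower() != "exon":
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(f"{gff_path}:{lineno}: non-integer exon coordinates") from None
            if start > end:
                raise ValueError(f"{gff_path}:{lineno}: exon start > end")
            parent = _gff_attributes(fields[8]).get("Parent")
            if parent is None:
                raise ValueError(f"{gff_path}:{lineno}: exon feature lacks a Parent attribute")
            for p in parent.split(","):
                exons.setdefault(p, []).append((start, end))
    lengths = []
    for parts in exons.values():
        parts.sort()
        for (s1, e1), (s2, e2) in zip(parts, parts[1:]):
            intron = s2 - e1 - 1
            if intron > 0:
                lengths.append(intron)
    counts = pd.Series(lengths, dtype=int).value_counts().sort_index()
    counts.index.name = "intron_length"
    counts.name = "n_introns"
    return counts
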