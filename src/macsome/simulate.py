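"""Synthetic data with known ground truth for every pipeline stage.

Emulated system: a ciliate somatic (MAC) genome of telomere-capped DNA
molecules.  Assembly contigs are consensus sequences; actual molecules
end at the contig ends (always) and at internal alternative telomere
addition sites (ATASs), each used by only a small fraction of molecules.
Long high-accuracy (HiFi-like) reads are fragments of those molecules;
reads covering a molecule end carry a telomeric repeat tract.

Also provided: codon-pair evolution at a planted dN/dS ratio (omega), and
negative-binomial expression count matrices with planted developmental
up-regulation in one target sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alnio import AlnRecord, write_paf
from .dnds import GeneticCode, _codons
from .telomere import DEFAULT_UNIT, revcomp

__all__ = [
    "Junction",
    "SimGenomeTruth",
    "SimReads",
    "SimCodonPairTruth",
    "SimExpr",
    "simulate_mac_genome",
    "simulate_reads",
    "sample_read_layout",
    "simulate_codon_pair",
    "simulate_expression",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Junction:
    """A planted alternative telomere addition site.

    ``side == "left"`` means telomere extends toward decreasing contig
    coordinates: molecules using this junction *start* at ``pos``.
    ``side == "right"``: molecules using it *end* at ``pos``.
    """

    pos: int
    side: str  # "left" | "right"
    usage: float

    def __post_init__(self):
        if not (0.0 < self.usage <= 1.0):
            raise ValueError("junction usage must be in (0, 1]")
        if self.side not in ("left", "right"):
            raise ValueError(f"bad junction side {self.side!r}")


@dataclass
class SimGenomeTruth:
    """A simulated MAC assembly with its planted junction table."""

    contigs: dict[str, str]
    junctions: dict[str, list[Junction]]
    seed: int
    at_frac: float

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def junction_table(self) -> pd.DataFrame:
        rows = [
            {"contig": c, "pos": j.pos, "side": j.side, "usage": j.usage}
            for c, js in self.junctions.items()
            for j in js
        ]
        return pd.DataFrame(rows, columns=["contig", "pos", "side", "usage"])

    def write(self, outdir: str | Path, prefix: str = "genome") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / f"{prefix}.fasta", "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        self.junction_table().to_csv(outdir / f"{prefix}.junctions.tsv", sep="\t", index=False)


def _random_dna(rng: np.random.Generator, n: int, at_frac: float) -> str:
    p_at = at_frac / 2.0
    p_gc = (1.0 - at_frac) / 2.0
    arr = rng.choice(_BASE_BYTES, size=n, p=[p_at, p_gc, p_gc, p_at])
    return arr.tobytes().decode("ascii")


def simulate_mac_genome(
    n_contigs: int = 5,
    contig_length: int | list[int] = 300_000,
    junction_density: float = 200 / 1_500_000,
    usage_range: tuple[float, float] = (0.02, 0.3),
    *,
    n_junctions: int | None = None,
    at_frac: float = 0.66,
    end_margin: int = 1_000,
    min_spacing: int = 100,
    seed: int = 0,
) -> SimGenomeTruth:
    """Simulate an AT-rich MAC assembly with planted one-sided junctions.

    Parameters
    ----------
    junction_density:
        Expected junctions per bp; per-contig counts are Poisson unless
        ``n_junctions`` pins the genome-wide total exactly.
    usage_range:
        Per-junction usage probabilities, drawn uniformly.
    end_margin:
        Junctions are kept this far from contig ends so that planted
        internal sites never collide with contig termini.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if isinstance(contig_length, int):
        lengths = [contig_length] * n_contigs
    else:
        lengths = list(contig_length)
        if len(lengths) != n_contigs:
            raise ValueError("contig_length list must have n_contigs entries")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    if junction_density < 0:
        raise ValueError("junction_density must be >= 0")
    lo, hi = usage_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("usage_range must satisfy 0 < lo <= hi <= 1")

    rng = np.random.default_rng(seed)
    contigs = {}
    counts = []
    for i, length in enumerate(lengths):
        contigs[f"contig_{i + 1}"] = _random_dna(rng, length, at_frac)
        counts.append(rng.poisson(junction_density * length))
    if n_junctions is not None:
        # distribute an exact total proportionally to contig length
        total_len = sum(lengths)
        idx = rng.choice(n_contigs, size=n_junctions, p=[l / total_len for l in lengths])
        counts = [int((idx == i).sum()) for i in range(n_contigs)]

    junctions: dict[str, list[Junction]] = {}
    for (name, seq), want in zip(contigs.items(), counts):
        length = len(seq)
        usable = length - 2 * end_margin
        positions: list[int] = []
        attempts = 0
        while len(positions) < want and attempts < 100 * max(want, 1):
            pos = int(rng.integers(end_margin, length - end_margin)) if usable > 0 else -1
            attempts += 1
            if pos < 0:
                break
            if all(abs(pos - p) >= min_spacing for p in positions):
                positions.append(pos)
        positions.sort()
        junctions[name] = [
            Junction(
                pos=pos,
                side="left" if rng.random() < 0.5 else "right",
                usage=float(rng.uniform(lo, hi)),
            )
            for pos in positions
        ]
    return SimGenomeTruth(contigs=contigs, junctions=junctions, seed=seed, at_frac=at_frac)


@dataclass
class SimReads:
    """Simulated reads with per-read truth and truth-derived alignments."""

    truth: pd.DataFrame
    reads: list[tuple[str, str]] | None  # (read_id, sequence); None in layout-only mode
    alignments: list[AlnRecord]
    seed: int

    def write(self, outdir: str | Path, prefix: str = "reads", qual_char: str = "I") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.reads is not None:
            with open(outdir / f"{prefix}.fastq", "w") as fh:
                for rid, seq in self.reads:
                    fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")
        self.truth.to_csv(outdir / f"{prefix}.truth.tsv", sep="\t", index=False)
        write_paf(self.alignments, outdir / f"{prefix}.truth.paf")


def _draw_read_lengths(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sigma: float,
    lo: int,
    hi: int,
) -> np.ndarray:
    """Truncated lognormal read lengths (HiFi-like)."""
    mu = math.log(mean) - sigma**2 / 2.0
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - filled) + 16)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take].astype(np.int64)
        filled += take
    return out


def _tract(
    rng: np.random.Generator,
    unit: str,
    n_units: int,
    genome_after: str | None = None,
    genome_before: str | None = None,
) -> str:
    """A telomere tract of ``n_units`` complete units at a random phase.

    The phase is drawn uniformly among rotations whose periodic pattern
    does not continue into the adjacent genomic base (``genome_after`` for
    a 5' tract, ``genome_before`` for a 3' tract), so that a scanned
    repeat run always stops exactly at the tract boundary and the truth
    flags computed from tract spans match the scanner.
    """
    k = len(unit)
    offs = list(range(k))
    if genome_after is not None:
        offs = [o for o in offs if unit[(o + n_units * k) % k] != genome_after]
    if genome_before is not None:
        offs = [o for o in offs if unit[(o - 1) % k] != genome_before]
    if not offs:  # unit composed of a single base; phase is irrelevant
        offs = list(range(k))
    off = offs[int(rng.integers(0, len(offs)))]
    s = unit * (n_units + 2)
    return s[off : off + n_units * k]


def simulate_reads(
    truth: SimGenomeTruth,
    n_reads: int = 20_000,
    *,
    read_len_mean: float = 8_000.0,
    read_len_sigma: float = 0.35,
    read_len_range: tuple[int, int] = (1_000, 12_000),
    error_rate: float = 0.0,
    unit: str = DEFAULT_UNIT,
    telo_min_units: int = 3,
    telo_geom_p: float = 0.5,
    end_tol: int = 50,
    seed: int = 0,
    with_sequences: bool = True,
) -> SimReads:
    """Simulate HiFi-like reads from telomere-capped MAC molecules.

    Per read: a genomic anchor picks a contig (length-weighted) and a
    position; the molecule containing the anchor is realised by walking
    outward until a junction fires (independently, with its usage
    probability) or a contig end is reached; telomere tracts of
    ``telo_min_units`` plus a geometric excess of complete units are
    appended at random repeat phase.  The molecule is tiled into fragments
    of the drawn read length at a random offset and one fragment becomes
    the read; molecules shorter than the drawn length are returned whole.
    Under this model the telomere-bearing read fraction converges to
    2*Lbar/M and the linear spacing estimator is unbiased.

    Substitution errors only (HiFi-like), at ``error_rate``.

    ``with_sequences=False`` skips sequence construction (layout, truth
    and alignments only) for estimator-scale simulations.
    """
    if not truth.contigs:
        raise ValueError("empty genome")
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    k = len(unit)
    min_span = telo_min_units * k

    names = list(truth.contigs)
    clens = np.array([len(truth.contigs[c]) for c in names], dtype=np.int64)
    weights = clens / clens.sum()
    contig_idx = rng.choice(len(names), size=n_reads, p=weights)
    anchors = (rng.random(n_reads) * clens[contig_idx]).astype(np.int64)
    lengths = _draw_read_lengths(rng, n_reads, read_len_mean, read_len_sigma, *read_len_range)
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")

    # per-contig junction arrays, split by side
    jleft: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    jright: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in names:
        js = truth.junctions.get(name, [])
        lpos = np.array([j.pos for j in js if j.side == "left"], dtype=np.int64)
        lusage = np.array([j.usage for j in js if j.side == "left"])
        rpos = np.array([j.pos for j in js if j.side == "right"], dtype=np.int64)
        rusage = np.array([j.usage for j in js if j.side == "right"])
        jleft[name] = (lpos, lusage)
        jright[name] = (rpos, rusage)

    rows = []
    reads: list[tuple[str, str]] | None = [] if with_sequences else None
    alignments: list[AlnRecord] = []
    for i in range(n_reads):
        name = names[contig_idx[i]]
        clen = int(clens[contig_idx[i]])
        anchor = int(anchors[i])
        L = int(lengths[i])
        strand = str(strands[i])

        # realise the molecule containing the anchor
        lpos, lusage = jleft[name]
        a = 0
        for idx in range(np.searchsorted(lpos, anchor, side="right") - 1, -1, -1):
            if rng.random() < lusage[idx]:
                a = int(lpos[idx])
                break
        rpos, rusage = jright[name]
        b = clen
        for idx in range(np.searchsorted(rpos, anchor, side="right"), len(rpos)):
            if rng.random() < rusage[idx]:
                b = int(rpos[idx])
                break
        core = b - a
        r5 = telo_min_units + int(rng.geometric(telo_geom_p)) - 1
        r3 = telo_min_units + int(rng.geometric(telo_geom_p)) - 1
        t5 = r5 * k
        t3 = r3 * k
        mtot = t5 + core + t3

        # fragment the molecule; the read is one fragment
        if L >= mtot:
            u, v = 0, mtot
        else:
            c = int(rng.integers(0, L))
            cuts = list(range(c if c > 0 else L, mtot, L))
            bounds = [0] + cuts + [mtot]
            fi = int(rng.integers(0, len(bounds) - 1))
            u, v = bounds[fi], bounds[fi + 1]
        ell = v - u

        # telomeric prefix/suffix spans in molecule orientation
        if u < t5:
            prefix = min(v, t5) - u
        elif u >= t5 + core:
            prefix = ell
        else:
            prefix = 0
        if v > t5 + core:
            suffix = v - max(u, t5 + core)
        elif v <= t5:
            suffix = ell
        else:
            suffix = 0
        # truth flags follow the classifier's terminal-run semantics: a
        # qualifying run counts for a read end when it lies within end_tol
        # of that end (a short end-fragment's single tract can be terminal
        # at both read ends)
        p_run = prefix >= min_span
        s_run = suffix >= min_span
        has5_mol = p_run or (s_run and (ell - suffix) <= end_tol)
        has3_mol = s_run or (p_run and (ell - prefix) <= end_tol)
        n5_mol = prefix // k
        n3_mol = suffix // k

        if strand == "+":
            has5, has3, n5, n3 = has5_mol, has3_mol, n5_mol, n3_mol
            span5, span3 = prefix, suffix
        else:
            has5, has3, n5, n3 = has3_mol, has5_mol, n3_mol, n5_mol
            span5, span3 = suffix, prefix

        rid = f"read_{i + 1}"
        err_positions: np.ndarray | None = None
        if error_rate > 0:
            n_err = rng.binomial(ell, error_rate)
            if n_err:
                err_positions = rng.choice(ell, size=n_err, replace=False)

        if reads is not None:
            contig_seq = truth.contigs[name]
            parts = []
            if u < t5:
                parts.append(
                    _tract(rng, unit, r5, genome_after=contig_seq[a])[u : min(v, t5)]
                )
            gs, ge = max(u, t5), min(v, t5 + core)
            if gs < ge:
                parts.append(contig_seq[a + gs - t5 : a + ge - t5])
            if v > t5 + core:
                parts.append(
                    _tract(rng, unit, r3, genome_before=contig_seq[b - 1])[
                        max(u, t5 + core) - (t5 + core) : v - (t5 + core)
                    ]
                )
            seq = "".join(parts)
            if err_positions is not None:
                sarr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
                for p in err_positions:
                    cur = sarr[p]
                    choices = _BASE_BYTES[_BASE_BYTES != cur]
                    sarr[p] = rng.choice(choices)
                seq = sarr.tobytes().decode("ascii")
            if strand == "-":
                seq = revcomp(seq)
            reads.append((rid, seq))

        # truth-derived alignment of the genomic part of the read
        gs, ge = max(u, t5), min(v, t5 + core)
        if gs < ge:
            rstart, rend = a + gs - t5, a + ge - t5
            qs_f, qe_f = gs - u, ge - u
            if strand == "+":
                qstart, qend = qs_f, qe_f
            else:
                qstart, qend = ell - qe_f, ell - qs_f
            n_err_aln = 0
            if err_positions is not None:
                n_err_aln = int(((err_positions >= qs_f) & (err_positions < qe_f)).sum())
            alignments.append(
                AlnRecord(
                    read_id=rid,
                    contig=name,
                    rstart=rstart,
                    rend=rend,
                    qstart=qstart,
                    qend=qend,
                    strand=strand,
                    mapq=60,
                    is_primary=True,
                    read_len=ell,
                    contig_len=clen,
                    n_match=(ge - gs) - n_err_aln,
                )
            )

        rows.append(
            {
                "read_id": rid,
                "contig": name,
                "mol_start": a,
                "mol_end": b,
                "frag_start": u,
                "frag_end": v,
                "read_len": ell,
                "strand": strand,
                "has_telo_5p": has5,
                "has_telo_3p": has3,
                "n_repeats_5p": n5,
                "n_repeats_3p": n3,
                "telo_5p_span": span5,
                "telo_3p_span": span3,
            }
        )

    truth_df = pd.DataFrame(rows)
    return SimReads(truth=truth_df, reads=reads, alignments=alignments, seed=seed)


def annotations_from_truth(
    truth_df: pd.DataFrame,
    unit_len: int = len(DEFAULT_UNIT),
    min_units: int = 3,
    end_tol: int = 50,
):
    """Reconstruct per-read telomere annotations from a simulation truth table.

    Equivalent to scanning error-free reads: terminal runs are rebuilt from
    the recorded telomeric spans.  Lets estimator-scale analyses run on
    layout-only simulations (no sequences).
    """
    from .telomere import TelomereRun, classify_read

    min_span = min_units * unit_len
    anns = []
    for row in truth_df.itertuples():
        runs = []
        p, s = int(row.telo_5p_span), int(row.telo_3p_span)
        ell = int(row.read_len)
        if p >= min_span:
            runs.append(TelomereRun(qstart=0, qend=p, n_repeats=p // unit_len, orientation="C"))
        if s >= min_span and not (p >= min_span and p == ell):
            runs.append(
                TelomereRun(qstart=ell - s, qend=ell, n_repeats=s // unit_len, orientation="C")
            )
        anns.append(classify_read(row.read_id, ell, runs, end_tol=end_tol))
    return anns


def sample_read_layout(
    truth: SimGenomeTruth,
    n_reads: int,
    seed: int = 0,
    **kwargs,
) -> SimReads:
    """Layout-only read simulation (no sequences); see :func:`simulate_reads`."""
    return simulate_reads(truth, n_reads, seed=seed, with_sequences=False, **kwargs)


@dataclass(frozen=True)
class SimCodonPairTruth:
    omega_true: float
    branch_length_t: float
    n_codons: int
    code_id: str
    seed: int


def _codon_rates(code: GeneticCode, omega_true: float):
    """Per-codon neighbour lists and rates (syn rate 1, nonsyn rate omega)."""
    neighbours: dict[str, tuple[list[str], np.ndarray]] = {}
    for codon in _codons():
        if codon in code.stops:
            continue
        targets, rates = [], []
        for pos in range(3):
            for b in "TCAG":
                if b == codon[pos]:
                    continue
                nb = codon[:pos] + b + codon[pos + 1 :]
                if nb in code.stops:
                    continue
                targets.append(nb)
                rates.append(1.0 if code.translate(nb) == code.translate(codon) else omega_true)
        neighbours[codon] = (targets, np.array(rates))
    return neighbours


def _evolve_codons(
    codons: list[str],
    duration: float,
    neighbours: dict[str, tuple[list[str], np.ndarray]],
    rng: np.random.Generator,
) -> list[str]:
    out = []
    for codon in codons:
        t = 0.0
        cur = codon
        while True:
            targets, rates = neighbours[cur]
            total = rates.sum()
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= duration:
                break
            cur = targets[rng.choice(len(targets), p=rates / total)]
        out.append(cur)
    return out


def simulate_codon_pair(
    omega_true: float,
    t: float,
    n_codons: int,
    code: GeneticCode | str = "standard",
    seed: int = 0,
) -> tuple[str, str, SimCodonPairTruth]:
    """Evolve a codon-sequence pair from a common ancestor at a planted omega.

    A continuous-time Markov codon process: single-nucleotide moves, rate 1
    for synonymous and ``omega_true`` for nonsynonymous changes, moves into
    stop codons forbidden.  Time is scaled so that ``t`` is the expected
    number of substitutions per codon separating the pair (each lineage
    evolves for t/2).
    """
    if omega_true <= 0:
        raise ValueError("omega_true must be > 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    if isinstance(code, str):
        code = GeneticCode.from_name(code)
    rng = np.random.default_rng(seed)
    neighbours = _codon_rates(code, omega_true)
    sense = sorted(neighbours)
    ancestor = [sense[j] for j in rng.integers(0, len(sense), size=n_codons)]
    if t == 0:
        s = "".join(ancestor)
        return s, s, SimCodonPairTruth(omega_true, t, n_codons, code.id, seed)
    mean_rate = float(np.mean([neighbours[c][1].sum() for c in sense]))
    duration = (t / 2.0) / mean_rate
    seq1 = "".join(_evolve_codons(ancestor, duration, neighbours, rng))
    seq2 = "".join(_evolve_codons(ancestor, duration, neighbours, rng))
    return seq1, seq2, SimCodonPairTruth(omega_true, t, n_codons, code.id, seed)


@dataclass
class SimExpr:
    """A simulated developmental expression count matrix with planted truth."""

    counts: pd.DataFrame  # genes x samples
    gene_lengths: pd.Series
    target: str
    baselines: list[str]
    planted: pd.Series  # fold changes indexed by planted gene ids
    dispersion: float
    seed: int


def simulate_expression(
    n_genes: int = 5_000,
    n_planted: int = 50,
    fc_range: tuple[float, float] = (69.0, 825.0),
    dispersion: float = 0.1,
    *,
    target: str = "26h",
    baselines: tuple[str, ...] = ("starved", "gamone", "0h"),
    base_mean_log_mu: float = 3.0,
    base_mean_log_sigma: float = 1.2,
    libsize_sigma: float = 0.15,
    seed: int = 0,
) -> SimExpr:
    """Negative-binomial counts with planted up-regulation in the target sample.

    Planted genes get fold changes log-uniform in ``fc_range`` (default
    spanning the 69x-825x range observed for the top-100 developmental
    genes), applied to the target-sample mean only.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if len(baselines) < 1:
        raise ValueError("need at least one baseline sample")
    if n_planted > n_genes:
        raise ValueError("n_planted cannot exceed n_genes")
    lo, hi = fc_range
    if not (1.0 < lo <= hi):
        raise ValueError("planted fold changes must be > 1")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    samples = list(baselines) + [target]
    base = rng.lognormal(base_mean_log_mu, base_mean_log_sigma, size=n_genes)
    sf = rng.lognormal(0.0, libsize_sigma, size=len(samples))
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False)
    fcs = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_planted))
    fold = np.ones(n_genes)
    fold[planted_idx] = fcs

    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    r = 1.0 / dispersion  # NB size parameter
    for j, s in enumerate(samples):
        mu = base * sf[j] * (fold if s == target else 1.0)
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=genes, columns=samples)
    lengths = pd.Series(rng.integers(500, 5_000, size=n_genes), index=genes, name="length")
    planted = pd.Series(fcs, index=[genes[i] for i in planted_idx], name="planted_fc").sort_index()
    return SimExpr(
        counts=df,
        gene_lengths=lengths,
        target=target,
        baselines=list(baselines),
        planted=planted,
        dispersion=dispersion,
        seed=seed,
    )
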