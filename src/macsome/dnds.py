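"""Pairwise dN/dS estimation (Nei-Gojobori 1986 counting with Jukes-Cantor
correction), for screening paralog/ortholog pairs such as the ciliate
PiggyBac transposase homologs for purifying selection.

Conventions
-----------
* Synonymous/nonsynonymous *sites* per codon position are the fraction of
  single-nucleotide neighbours that are synonymous, with mutations into
  stop codons excluded from the valid neighbour set (mutational-opportunity
  convention).  Each position then contributes exactly one site, so
  N + S = 3 x n_codons.  Site totals are averaged over the two sequences.
* Codon pairs differing at several positions are scored by averaging the
  synonymous/nonsynonymous step counts over all minimal mutational
  pathways that do not pass through a stop codon; if every pathway is
  blocked by a stop, all pathways are used and the codon is flagged.
* Distances: Jukes-Cantor, d = -3/4 ln(1 - 4p/3); p >= 3/4 is reported as
  a saturation flag with a NaN distance.
* omega = dN/dS; 0/0 is NaN ("undefined"), x/0 with x > 0 is +inf.

The *Blepharisma* nuclear genetic code reassigns UGA from stop to
tryptophan; both this code and the standard code are provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations, product
from typing import Mapping

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "CodonAlignment",
    "NGResult",
    "back_align",
    "pair_codon_alignment",
    "ng86",
    "omega",
    "pairwise_matrix",
]

_BASES = "TCAG"


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map with an explicit stop set."""

    id: str
    table: Mapping[str, str]  # 61+ sense codons -> one-letter amino acid
    stops: frozenset[str]

    def __post_init__(self):
        if len(self.table) + len(self.stops) != 64:
            raise ValueError("genetic code must map all 64 codons")

    def translate(self, codon: str) -> str:
        return "*" if codon in self.stops else self.table[codon]

    @staticmethod
    @lru_cache(maxsize=None)
    def standard() -> "GeneticCode":
        bio = CodonTable.unambiguous_dna_by_id[1]
        return GeneticCode(
            id="standard",
            table=dict(bio.forward_table),
            stops=frozenset(bio.stop_codons),
        )

    @staticmethod
    @lru_cache(maxsize=None)
    def uga_trp() -> "GeneticCode":
        """Standard code with UGA reassigned from stop to Trp (Blepharisma)."""
        std = GeneticCode.standard()
        table = dict(std.table)
        table["TGA"] = "W"
        return GeneticCode(
            id="UGA_to_Trp",
            table=table,
            stops=frozenset(std.stops - {"TGA"}),
        )

    @staticmethod
    def from_name(name: str) -> "GeneticCode":
        key = name.lower().replace("-", "_")
        if key == "standard":
            return GeneticCode.standard()
        if key in ("uga_to_trp", "uga_trp"):
            return GeneticCode.uga_trp()
        raise ValueError(f"unknown genetic code {name!r}")


def _codons() -> list[str]:
    return ["".join(c) for c in product(_BASES, repeat=3)]


@lru_cache(maxsize=None)
def _syn_sites(code_id: str) -> dict[str, float]:
    """Synonymous sites per sense codon (stop-excluded neighbour convention)."""
    code = GeneticCode.standard() if code_id == "standard" else GeneticCode.from_name(code_id)
    out = {}
    for codon in _codons():
        if codon in code.stops:
            continue
        aa = code.translate(codon)
        s = 0.0
        for pos in range(3):
            syn = valid = 0
            for b in _BASES:
                if b == codon[pos]:
                    continue
                nb = codon[:pos] + b + codon[pos + 1 :]
                if nb in code.stops:
                    continue
                valid += 1
                if code.translate(nb) == aa:
                    syn += 1
            s += syn / valid if valid else 0.0
        out[codon] = s
    return out


@lru_cache(maxsize=None)
def _pair_diffs(code_id: str, c1: str, c2: str) -> tuple[float, float, bool]:
    """Pathway-averaged (nonsyn, syn) differences between two sense codons.

    Returns (nd, sd, all_paths_blocked).
    """
    code = GeneticCode.from_name(code_id)
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return (0.0, 0.0, False)

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = c1
        nd = sd = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in code.stops:
                return None
            if code.translate(cur) == code.translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return (nd, sd)

    valid, blocked_all = [], []
    for order in permutations(positions):
        res = walk(order)
        if res is not None:
            valid.append(res)
        else:
            # recompute ignoring the stop constraint, for the fallback
            cur = c1
            nd = sd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if code.translate(cur) == code.translate(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            blocked_all.append((nd, sd))
    paths = valid if valid else blocked_all
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    return (nd, sd, not valid)


@dataclass
class CodonAlignment:
    """A gap-free pairwise codon alignment ready for NG86 counting.

    Constructed from two equal-length, in-frame DNA strings; gap columns
    must be whole codons and are removed pairwise (complete deletion).
    Internal stop codons are rejected; a shared terminal stop is stripped.
    """

    codons1: list[str]
    codons2: list[str]
    code: GeneticCode

    @staticmethod
    def from_sequences(seq1: str, seq2: str, code: GeneticCode | None = None) -> "CodonAlignment":
        code = code or GeneticCode.standard()
        seq1, seq2 = seq1.upper().replace("U", "T"), seq2.upper().replace("U", "T")
        if len(seq1) != len(seq2):
            raise ValueError("aligned sequences must have equal length")
        if len(seq1) % 3:
            raise ValueError("alignment length must be divisible by 3")
        c1s, c2s = [], []
        for i in range(0, len(seq1), 3):
            c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
            g1, g2 = "-" in c1, "-" in c2
            if g1 and c1 != "---":
                raise ValueError(f"partial-codon gap at codon {i // 3 + 1} in sequence 1")
            if g2 and c2 != "---":
                raise ValueError(f"partial-codon gap at codon {i // 3 + 1} in sequence 2")
            if g1 or g2:
                continue
            c1s.append(c1)
            c2s.append(c2)
        # strip a shared terminal stop
        if c1s and (c1s[-1] in code.stops or c2s[-1] in code.stops):
            if c1s[-1] in code.stops and c2s[-1] in code.stops:
                c1s.pop()
                c2s.pop()
        for name, cs in (("1", c1s), ("2", c2s)):
            for j, c in enumerate(cs):
                if c in code.stops:
                    raise ValueError(f"internal stop codon {c} at codon {j + 1} in sequence {name}")
                if any(b not in "ACGT" for b in c):
                    raise ValueError(f"non-ACGT codon {c!r} at codon {j + 1} in sequence {name}")
        return CodonAlignment(codons1=c1s, codons2=c2s, code=code)

    @property
    def n_codons(self) -> int:
        return len(self.codons1)


@dataclass
class NGResult:
    """Nei-Gojobori pairwise quantities."""

    n_codons: int
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float  # NaN when saturated
    dS: float  # NaN when saturated
    omega: float  # NaN undefined / inf when dS == 0 < dN
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_codons": self.n_codons,
            "N": self.N,
            "S": self.S,
            "Nd": self.Nd,
            "Sd": self.Sd,
            "pN": self.pN,
            "pS": self.pS,
            "dN": self.dN,
            "dS": self.dS,
            "omega": self.omega,
            "flags": ";".join(self.flags),
        }


def _jc(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return (math.nan, True)
    if p == 0.0:
        return (0.0, False)
    return (-0.75 * math.log(1.0 - 4.0 * p / 3.0), False)


def omega(dN: float, dS: float) -> float:
    """dN/dS with explicit degenerate-case markers."""
    if dN < 0 or dS < 0:
        raise ValueError("dN and dS must be nonnegative")
    if dS > 0:
        return dN / dS
    return math.nan if dN == 0 else math.inf


def ng86(aln: CodonAlignment) -> NGResult:
    """Nei-Gojobori (1986) pairwise counting on a codon alignment."""
    if aln.n_codons == 0:
        raise ValueError("alignment contains zero aligned codons")
    sites = _syn_sites(aln.code.id)
    S1 = sum(sites[c] for c in aln.codons1)
    S2 = sum(sites[c] for c in aln.codons2)
    S = (S1 + S2) / 2.0
    N = 3.0 * aln.n_codons - S
    Nd = Sd = 0.0
    flags: list[str] = []
    blocked = 0
    for c1, c2 in zip(aln.codons1, aln.codons2):
        nd, sd, all_blocked = _pair_diffs(aln.code.id, c1, c2)
        Nd += nd
        Sd += sd
        blocked += all_blocked
    if blocked:
        flags.append(f"stop_blocked_pathways:{blocked}")
    pN = Nd / N if N else 0.0
    pS = Sd / S if S else 0.0
    dN, satN = _jc(pN)
    dS, satS = _jc(pS)
    if satN:
        flags.append("dN_saturated")
    if satS:
        flags.append("dS_saturated")
    w = omega(dN, dS) if not (satN or satS) else math.nan
    return NGResult(aln.n_codons, N, S, Nd, Sd, pN, pS, dN, dS, w, flags)


def back_align(
    protein_aln: Mapping[str, str],
    cds: Mapping[str, str],
    code: GeneticCode | None = None,
) -> dict[str, str]:
    """Thread coding sequences through a gapped protein alignment.

    Each CDS must translate (under ``code``) to the ungapped protein; a
    terminal stop codon is stripped unless the code reads it as an amino
    acid (e.g. terminal TGA under the UGA->Trp code is a Trp residue and
    must be matched by a W in the protein).
    """
    code = code or GeneticCode.standard()
    out = {}
    for pid, prot in protein_aln.items():
        if pid not in cds:
            raise KeyError(f"no CDS for alignment sequence {pid!r}")
        nt = cds[pid].upper().replace("U", "T")
        if len(nt) % 3:
            raise ValueError(f"CDS for {pid!r} has length not divisible by 3")
        ungapped = prot.replace("-", "").upper()
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        if codons and codons[-1] in code.stops and len(codons) == len(ungapped) + 1:
            codons = codons[:-1]
        if len(codons) != len(ungapped):
            raise ValueError(
                f"CDS for {pid!r} has {len(codons)} codons but protein has {len(ungapped)} residues"
            )
        for i, (codon, aa) in enumerate(zip(codons, ungapped)):
            if code.translate(codon) != aa:
                raise ValueError(
                    f"translation mismatch for {pid!r} at residue {i + 1}: "
                    f"codon {codon} -> {code.translate(codon)}, protein has {aa}"
                )
        it = iter(codons)
        out[pid] = "".join("---" if aa == "-" else next(it) for aa in prot)
    return out


def pair_codon_alignment(
    codon_aln: Mapping[str, str],
    id1: str,
    id2: str,
    code: GeneticCode | None = None,
) -> CodonAlignment:
    """Extract a pairwise CodonAlignment from a multi-sequence codon alignment."""
    return CodonAlignment.from_sequences(codon_aln[id1], codon_aln[id2], code)


def pairwise_matrix(
    reference_id: str,
    others: list[str],
    alignments: Mapping[frozenset, CodonAlignment],
) -> pd.DataFrame:
    """NG86 results for a reference against each of ``others``.

    ``alignments`` maps ``frozenset({reference_id, other})`` to a pairwise
    CodonAlignment; missing pairs produce NA rows.  Rows are ordered as
    given in ``others``.
    """
    rows = []
    for other in others:
        key = frozenset({reference_id, other})
        row: dict = {"reference": reference_id, "other": other}
        aln = alignments.get(key)
        if aln is None:
            row.update({k: math.nan for k in ("n_codons", "N", "S", "Nd", "Sd", "pN", "pS", "dN", "dS", "omega")})
            row["flags"] = "missing_alignment"
        else:
            row.update(ng86(aln).to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
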