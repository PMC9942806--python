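"""Domesticated-transposase annotation.

Consumes hmmscan-style per-domain tabular output (domtblout) to build
species x PFAM-domain presence/absence matrices, calls the PiggyBac DDD
catalytic triad from protein multiple sequence alignments (including the
D' case, an aspartate displaced by exactly one alignment column), and
flags C-terminal cysteine-rich domains (CRDs) characteristic of PiggyBac
homologs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DomainHit",
    "PresenceMatrix",
    "TriadCall",
    "CRDHit",
    "DEFAULT_TRANSPOSASE_DOMAINS",
    "read_domain_table",
    "write_domain_table",
    "presence_matrix",
    "call_triad",
    "find_crd",
    "crd_positions_from_spacing",
]

# PFAM transposase domains named for the MAC-encoded domesticated
# transposase survey (PiggyBac's DDE_Tnp_1_7 plus the other cut-and-paste
# families detected as domesticated in Blepharisma); extendable by callers.
DEFAULT_TRANSPOSASE_DOMAINS = (
    "DDE_1",
    "DDE_3",
    "DDE_Tnp_1_7",
    "DDE_Tnp_IS1595",
    "MULE",
)


@dataclass(frozen=True)
class DomainHit:
    """One domain hit on a protein (hmmscan domtblout semantics)."""

    gene_id: str
    domain_name: str
    accession: str
    i_evalue: float
    ali_from: int  # 1-based on the target protein
    ali_to: int

    def __post_init__(self):
        if self.ali_from > self.ali_to:
            raise ValueError("ali_from must be <= ali_to")
        if self.i_evalue < 0:
            raise ValueError("E-value must be nonnegative")


def read_domain_table(path: str | Path, max_evalue: float = 1e-5) -> list[DomainHit]:
    """Parse an hmmscan --domtblout file, applying an i-Evalue filter.

    Column layout follows HMMER3 domtblout: target (domain) name and
    accession in columns 1-2, query (protein) name in column 4, i-Evalue
    in column 13, alignment coordinates in columns 18-19.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(None, 22)
            if len(fields) < 19:
                raise ValueError(f"{path}:{lineno}: domain table line has too few columns")
            try:
                hit = DomainHit(
                    gene_id=fields[3],
                    domain_name=fields[0],
                    accession=fields[1],
                    i_evalue=float(fields[12]),
                    ali_from=int(fields[17]),
                    ali_to=int(fields[18]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed domain table line: {exc}") from None
            if hit.i_evalue <= max_evalue:
                hits.append(hit)
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in a minimal domtblout-compatible layout."""
    with open(path, "w") as fh:
        fh.write("# target_name accession tlen query_name accession qlen "
                 "E-value score bias # of c-Evalue i-Evalue score bias "
                 "hmm_from hmm_to ali_from ali_to env_from env_to acc description\n")
        for h in hits:
            cols = [
                h.domain_name, h.accession, "0", h.gene_id, "-", "0",
                f"{h.i_evalue:g}", "0.0", "0.0", "1", "1",
                f"{h.i_evalue:g}", f"{h.i_evalue:g}", "0.0", "0.0",
                "1", str(h.ali_to - h.ali_from + 1),
                str(h.ali_from), str(h.ali_to),
                str(h.ali_from), str(h.ali_to), "0.00", "-",
            ]
            fh.write(" ".join(cols) + "\n")


@dataclass
class PresenceMatrix:
    """Species x domain presence with per-cell supporting gene counts."""

    presence: pd.DataFrame  # bool
    counts: pd.DataFrame  # int (distinct supporting genes)


def presence_matrix(
    hits_by_species: Mapping[str, Iterable[DomainHit]],
    domains: Iterable[str] = DEFAULT_TRANSPOSASE_DOMAINS,
) -> PresenceMatrix:
    """Presence/absence matrix restricted to a domain whitelist.

    Rows (species) and columns (domains) are ordered lexicographically;
    species with zero hits keep an all-false row.  A cell is present iff
    at least one distinct gene supports it; duplicated hits on the same
    gene do not inflate the count.
    """
    domains = sorted(set(domains))
    if not domains:
        raise ValueError("domain whitelist must be nonempty")
    species = sorted(hits_by_species)
    counts = pd.DataFrame(0, index=species, columns=domains, dtype=int)
    for sp in species:
        seen: dict[str, set[str]] = {}
        for hit in hits_by_species[sp]:
            if hit.domain_name in counts.columns:
                seen.setdefault(hit.domain_name, set()).add(hit.gene_id)
        for dom, genes in seen.items():
            counts.loc[sp, dom] = len(genes)
    return PresenceMatrix(presence=counts > 0, counts=counts)


@dataclass
class TriadCall:
    """Catalytic-triad status of a PiggyBac homolog.

    ``positions`` are 1-based coordinates in the *unaligned* target
    protein of the residue examined (or accepted D' residue) at each triad
    site; None where the target is gapped.
    """

    protein_id: str
    positions: tuple[int | None, int | None, int | None]
    residues: tuple[str, str, str]
    site_status: tuple[str, str, str]  # D | Dprime | missing | gap
    status: str  # complete | offset_Dprime | incomplete | absent


def _unaligned_to_columns(gapped: str, positions_1based: Iterable[int]) -> list[int]:
    cols = []
    wanted = sorted(set(positions_1based))
    res_idx = 0
    found = {}
    for col, ch in enumerate(gapped):
        if ch != "-":
            res_idx += 1
            if res_idx in wanted:
                found[res_idx] = col
    for p in positions_1based:
        if p not in found:
            raise ValueError(f"unaligned position {p} beyond sequence of length {res_idx}")
        cols.append(found[p])
    return cols


def _column_to_unaligned(gapped: str, col: int) -> int:
    return sum(1 for ch in gapped[: col + 1] if ch != "-")


def call_triad(
    alignment: Mapping[str, str],
    reference_id: str,
    reference_triad_positions: tuple[int, int, int],
    target_id: str,
    max_offset: int = 1,
) -> TriadCall:
    """Call the DDD catalytic triad of ``target_id`` against a reference.

    The three reference positions (1-based, unaligned) must hold aspartate
    in the reference; they are mapped to alignment columns and the target
    residues read there.  A non-D target residue with a D within
    ``max_offset`` non-gap columns is scored D' ("1 aa translocation").
    Status aggregation: complete > offset_Dprime > incomplete; absent when
    the target is gapped at all three columns.
    """
    for pid in (reference_id, target_id):
        if pid not in alignment:
            raise KeyError(f"sequence {pid!r} not in alignment")
    ref = alignment[reference_id].upper()
    tgt = alignment[target_id].upper()
    if len(ref) != len(tgt):
        raise ValueError("alignment rows have unequal length")
    cols = _unaligned_to_columns(ref, reference_triad_positions)
    for p, col in zip(reference_triad_positions, cols):
        if ref[col] != "D":
            raise ValueError(
                f"reference residue at position {p} is {ref[col]!r}, expected D"
            )
    site_status: list[str] = []
    residues: list[str] = []
    positions: list[int | None] = []
    for col in cols:
        res = tgt[col]
        if res == "D":
            site_status.append("D")
            residues.append(res)
            positions.append(_column_to_unaligned(tgt, col))
            continue
        # look for an aspartate displaced by up to max_offset columns
        dprime_col = None
        for off in range(1, max_offset + 1):
            for cand in (col - off, col + off):
                if 0 <= cand < len(tgt) and tgt[cand] == "D":
                    dprime_col = cand
                    break
            if dprime_col is not None:
                break
        if res == "-" and dprime_col is None:
            site_status.append("gap")
            residues.append("-")
            positions.append(None)
        elif dprime_col is not None:
            site_status.append("Dprime")
            residues.append("D")
            positions.append(_column_to_unaligned(tgt, dprime_col))
        else:
            site_status.append("missing")
            residues.append(res)
            positions.append(_column_to_unaligned(tgt, col))
    if all(s == "gap" for s in site_status):
        status = "absent"
    elif all(s == "D" for s in site_status):
        status = "complete"
    elif all(s in ("D", "Dprime") for s in site_status):
        status = "offset_Dprime"
    else:
        status = "incomplete"
    return TriadCall(
        protein_id=target_id,
        positions=tuple(positions),
        residues=tuple(residues),
        site_status=tuple(site_status),
        status=status,
    )


@dataclass
class CRDHit:
    """A C-terminal cysteine-rich domain candidate (1-based inclusive)."""

    start: int
    end: int
    n_cys: int
    spacing: str  # e.g. "C-x2-C-x10-C..."


def _spacing_string(cys_positions: list[int]) -> str:
    parts = ["C"]
    for prev, nxt in zip(cys_positions, cys_positions[1:]):
        gap = nxt - prev - 1
        parts.append(f"x{gap}" if gap else "")
        parts.append("C")
    return "-".join(p for p in parts if p != "") if len(cys_positions) > 1 else "C"


def crd_positions_from_spacing(spacing: str, start: int) -> list[int]:
    """Invert a CRD spacing string to 1-based cysteine positions."""
    pos = start
    out = [start]
    for token in spacing.split("-")[1:]:
        if token == "C":
            pos += 1
            out.append(pos)
        else:
            m = re.fullmatch(r"x(\d+)", token)
            if not m:
                raise ValueError(f"bad spacing token {token!r}")
            pos += int(m.group(1))
    return out


def find_crd(
    seq: str,
    min_cys: int = 5,
    window: int = 60,
    cterm_frac: float = 0.35,
) -> list[CRDHit]:
    """Detect cysteine clusters in the C-terminal part of a protein.

    A heuristic: windows of at most ``window`` residues containing at
    least ``min_cys`` cysteines, restricted to the C-terminal
    ``cterm_frac`` of the protein; overlapping qualifying windows are
    merged into maximal hits spanning first to last cysteine.
    """
    seq = seq.upper()
    n = len(seq)
    region_start = int(n * (1.0 - cterm_frac))  # 0-based
    cys = [i for i in range(region_start, n) if seq[i] == "C"]
    if len(cys) < min_cys:
        return []
    # two-pointer over cysteine positions
    spans = []
    j = 0
    for i in range(len(cys)):
        if j < i:
            j = i
        while j + 1 < len(cys) and cys[j + 1] - cys[i] < window:
            j += 1
        if j - i + 1 >= min_cys:
            spans.append((cys[i], cys[j]))
    if not spans:
        return []
    merged = [spans[0]]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    hits = []
    for s, e in merged:
        inside = [p for p in cys if s <= p <= e]
        hits.append(
            CRDHit(
                start=s + 1,
                end=e + 1,
                n_cys=len(inside),
                spacing=_spacing_string([p + 1 for p in inside]),
            )
        )
    return hits
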