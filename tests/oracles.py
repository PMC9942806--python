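"""Independent brute-force oracles for property/acceptance tests.

These deliberately avoid the package's algorithms: telomere runs are
found by testing substrings against the infinite-repeat criterion
character by character, and codon differences are scored by direct
pathway enumeration with Biopython translation.
"""

from __future__ import annotations

from itertools import permutations, product

from Bio.Seq import Seq

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _max_span(seq: str, i: int, unit: str) -> int:
    """Longest m such that seq[i:i+m] is a substring of unit repeated forever."""
    k = len(unit)
    m = 0
    while i + m < len(seq):
        cand = seq[i : i + m + 1]
        tile = unit * ((m + 1) // k + 2)
        if cand not in tile:
            break
        m += 1
    return m


def oracle_find_runs(seq: str, unit: str, min_repeats: int) -> list[tuple[int, int, str]]:
    """Greedy left-to-right maximal telomeric runs, brute-force matching.

    At each position the longer of the C-rich/G-rich spans wins (ties go
    C-rich); a qualifying run (>= min_repeats complete units) is emitted
    and scanning resumes at its end.
    """
    rc = _revcomp(unit)
    k = len(unit)
    out = []
    i = 0
    n = len(seq)
    while i < n:
        span_c = _max_span(seq, i, unit)
        span_g = _max_span(seq, i, rc) if rc not in {unit[j:] + unit[:j] for j in range(k)} else 0
        span, orient = (span_c, "C") if span_c >= span_g else (span_g, "G")
        if span // k >= min_repeats:
            out.append((i, i + span, orient))
            i += span
        else:
            i += 1
    return out


def _translate(codon: str, code_name: str) -> str:
    if code_name == "UGA_to_Trp" and codon == "TGA":
        return "W"
    return str(Seq(codon).translate())


def _is_stop(codon: str, code_name: str) -> bool:
    return _translate(codon, code_name) == "*"


def oracle_ng86_codon(c1: str, c2: str, code_name: str) -> dict:
    """Site and difference counts for one codon pair, by direct enumeration."""
    bases = "ACGT"

    def syn_sites(codon: str) -> float:
        aa = _translate(codon, code_name)
        total = 0.0
        for pos in range(3):
            syn = valid = 0
            for b in bases:
                if b == codon[pos]:
                    continue
                nb = codon[:pos] + b + codon[pos + 1 :]
                if _is_stop(nb, code_name):
                    continue
                valid += 1
                syn += _translate(nb, code_name) == aa
            total += syn / valid if valid else 0.0
        return total

    diffs = [i for i in range(3) if c1[i] != c2[i]]
    paths_ok, paths_all = [], []
    for order in permutations(diffs):
        cur = c1
        nd = sd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _is_stop(nxt, code_name):
                blocked = True
            if _translate(cur, code_name) == _translate(nxt, code_name):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths_all.append((nd, sd))
        if not blocked:
            paths_ok.append((nd, sd))
    use = paths_ok if paths_ok else paths_all
    nd = sum(p[0] for p in use) / len(use) if use else 0.0
    sd = sum(p[1] for p in use) / len(use) if use else 0.0
    return {
        "S1": syn_sites(c1),
        "S2": syn_sites(c2),
        "Nd": nd,
        "Sd": sd,
    }


def sense_codons(code_name: str) -> list[str]:
    return [
        "".join(c)
        for c in product("ACGT", repeat=3)
        if not _is_stop("".join(c), code_name)
    ]
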