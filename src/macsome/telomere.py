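"""Telomeric repeat detection on long reads.

The *Blepharisma stoltei* MAC telomere is a tandem repeat of the 8-mer
CCCTAACA.  Because a sequencing read can enter a telomere tract at any
phase of the repeat, a telomeric run is any maximal substring of a read
that is a substring of the infinite repetition of the unit (equivalently,
of any cyclic rotation of it), on either strand.  A read is called
telomere-bearing when it carries a run of at least ``min_repeats``
complete units (default 3), the same moderately strict definition used
for the 1-in-8 telomere-bearing HiFi read statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "TelomereMotif",
    "TelomereRun",
    "ReadTeloAnnotation",
    "rotations",
    "revcomp",
    "find_runs",
    "classify_read",
    "trim_telomeres",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_UNIT = "CCCTAACA"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rotations(unit: str) -> set[str]:
    """All distinct cyclic rotations of ``unit``.

    >>> sorted(rotations("AAAA"))
    ['AAAA']
    >>> len(rotations("CCCTAACA"))
    8
    """
    if not unit:
        raise ValueError("telomere unit must be non-empty")
    bad = set(unit) - set("ACGT")
    if bad:
        raise ValueError(f"telomere unit contains non-ACGT characters: {sorted(bad)}")
    return {unit[i:] + unit[:i] for i in range(len(unit))}


@dataclass(frozen=True)
class TelomereMotif:
    """A telomeric repeat unit and the matching rules applied to it.

    Parameters
    ----------
    unit:
        The repeat unit on the C-rich strand (default ``CCCTAACA``).
    min_repeats:
        Minimum number of *complete* units for a run to be reported.
    max_mismatches:
        Mismatch budget per run during extension.  0 (the default) means
        exact matching; all headline statistics use exact matching.
    """

    unit: str = DEFAULT_UNIT
    min_repeats: int = 3
    max_mismatches: int = 0

    def __post_init__(self):
        rotations(self.unit)  # validates the alphabet
        if self.min_repeats < 1:
            raise ValueError("min_repeats must be >= 1")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    @property
    def rotations(self) -> set[str]:
        return rotations(self.unit)

    @property
    def rc_unit(self) -> str:
        return revcomp(self.unit)

    @property
    def rc_rotations(self) -> set[str]:
        return rotations(self.rc_unit)


@dataclass(frozen=True)
class TelomereRun:
    """A maximal telomeric match on a read (0-based half-open coords)."""

    qstart: int
    qend: int
    n_repeats: int
    orientation: str  # "C" (matches unit rotations) or "G" (reverse complement)
    read_id: str = ""
    terminal_5p: bool = False
    terminal_3p: bool = False

    @property
    def span(self) -> int:
        return self.qend - self.qstart


@dataclass
class ReadTeloAnnotation:
    """Per-read telomere classification."""

    read_id: str
    read_len: int
    runs: list[TelomereRun] = field(default_factory=list)
    cls: str = "none"  # none | five_prime | three_prime | both_ends | internal_only

    @property
    def is_telomere_bearing(self) -> bool:
        return self.cls != "none"


def _maximal_runs(seq: str, unit: str, orientation: str, max_mismatches: int) -> list[tuple[int, int, str]]:
    """Seed-and-extend search for maximal phase-consistent repeat runs.

    Any run with >= 2 complete units (span >= 2k-1) contains every rotation
    of the unit as a substring, so occurrences of the single string ``unit``
    suffice as seeds for runs that can meet a min_repeats >= 2 threshold
    (min_repeats >= 3 in practice).
    """
    k = len(unit)
    n = len(seq)
    out: list[tuple[int, int, str]] = []
    prev_end = -1
    pos = seq.find(unit)
    while pos != -1:
        if pos + k <= prev_end:
            # seed lies wholly inside the previous run: same run, skip
            pos = seq.find(unit, pos + 1)
            continue
        # phase anchor: seq[pos + j] should equal unit[j % k]
        start = pos
        end = pos + k
        budget = max_mismatches
        if budget == 0:
            while start > 0 and seq[start - 1] == unit[(start - 1 - pos) % k]:
                start -= 1
            while end < n and seq[end] == unit[(end - pos) % k]:
                end += 1
        else:
            # greedy extension with a shared mismatch budget; runs never
            # start or end on a mismatch
            i = start - 1
            last_good = start
            while i >= 0 and budget >= 0:
                if seq[i] == unit[(i - pos) % k]:
                    last_good = i
                else:
                    budget -= 1
                    if budget < 0:
                        break
                i -= 1
            start = last_good
            i = end
            last_good = end
            while i < n and budget >= 0:
                if seq[i] == unit[(i - pos) % k]:
                    last_good = i + 1
                else:
                    budget -= 1
                    if budget < 0:
                        break
                i += 1
            end = last_good
        out.append((start, end, orientation))
        prev_end = end
        pos = seq.find(unit, max(pos + 1, end - k + 1))
    return out


def find_runs(seq: str, motif: TelomereMotif | None = None) -> list[TelomereRun]:
    """Find maximal telomeric repeat runs in ``seq``.

    Runs are maximal substrings of ``seq`` that are substrings of the
    infinite repetition of the unit (C-rich orientation) or of its reverse
    complement (G-rich orientation), carrying at least ``motif.min_repeats``
    complete units.  Reported runs do not overlap; where maximal candidates
    of different phase/orientation overlap, the leftmost (then longest,
    then C-rich) wins and later candidates are truncated to its end.
    """
    if motif is None:
        motif = TelomereMotif()
    seq = seq.upper()
    k = len(motif.unit)
    cands = _maximal_runs(seq, motif.unit, "C", motif.max_mismatches)
    rc = motif.rc_unit
    if rc not in motif.rotations:  # degenerate self-complementary units collapse
        cands += _maximal_runs(seq, rc, "G", motif.max_mismatches)
    cands.sort(key=lambda c: (c[0], -(c[1] - c[0]), 0 if c[2] == "C" else 1))
    runs: list[TelomereRun] = []
    cursor = 0
    for start, end, orient in cands:
        s = max(start, cursor)
        if end <= cursor:
            continue
        if (end - s) // k >= motif.min_repeats:
            runs.append(TelomereRun(qstart=s, qend=end, n_repeats=(end - s) // k, orientation=orient))
            cursor = end
    return runs


def classify_read(
    read_id: str,
    read_len: int,
    runs: list[TelomereRun],
    end_tol: int = 50,
) -> ReadTeloAnnotation:
    """Classify a read from its telomeric runs.

    A run is terminal when it lies within ``end_tol`` bp of the respective
    read end (tolerating adapter remnants / junk at the extremities).
    """
    flagged = []
    for r in runs:
        if not (0 <= r.qstart < r.qend <= read_len):
            raise ValueError(
                f"run coordinates [{r.qstart},{r.qend}) outside read {read_id!r} of length {read_len}"
            )
        flagged.append(
            replace(
                r,
                read_id=read_id,
                terminal_5p=r.qstart <= end_tol,
                terminal_3p=read_len - r.qend <= end_tol,
            )
        )
    has5 = any(r.terminal_5p for r in flagged)
    has3 = any(r.terminal_3p for r in flagged)
    if not flagged:
        cls = "none"
    elif has5 and has3:
        cls = "both_ends"
    elif has5:
        cls = "five_prime"
    elif has3:
        cls = "three_prime"
    else:
        cls = "internal_only"
    return ReadTeloAnnotation(read_id=read_id, read_len=read_len, runs=flagged, cls=cls)


def trim_telomeres(seq: str, ann: ReadTeloAnnotation) -> tuple[str, tuple[int, int]]:
    """Remove terminal telomeric runs (full matched spans, incl. partial units).

    Returns the trimmed sequence and ``(left_cut, right_cut)`` so that
    ``left_cut + len(trimmed) + right_cut == len(seq)``.
    """
    if len(seq) != ann.read_len:
        raise ValueError("sequence length does not match annotation read_len")
    left = max((r.qend for r in ann.runs if r.terminal_5p), default=0)
    right_start = min((r.qstart for r in ann.runs if r.terminal_3p), default=len(seq))
    right_start = max(right_start, left)
    return seq[left:right_start], (left, len(seq) - right_start)


def trimmed_length(ann: ReadTeloAnnotation) -> int:
    """Read length after removing terminal telomeric runs."""
    left = max((r.qend for r in ann.runs if r.terminal_5p), default=0)
    right_start = min((r.qstart for r in ann.runs if r.terminal_3p), default=ann.read_len)
    return max(0, right_start - left)
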