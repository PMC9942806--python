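"""Alternative telomere addition site (ATAS) calling.

An ATAS is an internal assembly position where a minority of mapped reads
carry telomeric repeats: the telomeric tract of such a read abuts its
aligned interval, and the reference boundary of the alignment marks the
junction where a telomere was added on some DNA molecules.  Sites where
most spanning reads are telomere-bearing and which sit at a contig end
are contig termini, not ATASs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .alnio import AlnRecord
from .telomere import ReadTeloAnnotation

__all__ = ["ATASCall", "ATASSummary", "call_atas", "summarize_atas", "atas_table"]


@dataclass
class ATASCall:
    """A telomere-addition junction on the assembly.

    ``pos`` is the 0-based reference offset at which telomeric sequence is
    added; ``side == "left"`` means the telomere extends toward decreasing
    reference coordinates (the supported molecule starts at ``pos``).
    """

    contig: str
    pos: int
    side: str
    n_support: int
    n_cover: int
    is_contig_end: bool = False
    read_ids: list[str] = field(default_factory=list)

    @property
    def telo_frac(self) -> float:
        return self.n_support / self.n_cover if self.n_cover else 0.0

    def is_terminus(self, terminus_frac: float = 0.5) -> bool:
        """Contig-terminus label: majority-telomeric site at a contig end."""
        return self.is_contig_end and self.telo_frac >= terminus_frac


@dataclass
class ATASSummary:
    n_total: int
    n_singleton: int
    singleton_frac: float
    density_per_kbp: dict[str, float] = field(default_factory=dict)


def call_atas(
    annotations: Iterable[ReadTeloAnnotation],
    alignments: Iterable[AlnRecord],
    contig_lengths: Mapping[str, int] | None = None,
    junction_tol: int = 20,
    min_mapq: int = 0,
    end_margin: int = 100,
) -> list[ATASCall]:
    """Call telomere-addition junctions from annotated reads and alignments.

    For each telomere-bearing read whose terminal run abuts its primary
    alignment's query interval within ``junction_tol`` bp, one junction is
    emitted at the strand-appropriate reference boundary:

    * 5'-terminal telomere, ``+`` alignment -> ``(contig, rstart, left)``
    * 5'-terminal telomere, ``-`` alignment -> ``(contig, rend, right)``
    * 3'-terminal telomere, ``+`` alignment -> ``(contig, rend, right)``
    * 3'-terminal telomere, ``-`` alignment -> ``(contig, rstart, left)``

    Identical ``(contig, pos, side)`` junctions are aggregated; coverage is
    the number of qualifying primary alignments spanning ``pos``.
    Secondary/supplementary alignments are ignored entirely: a telomere
    junction must be anchored uniquely.
    """
    if junction_tol < 0 or end_margin < 0:
        raise ValueError("tolerances must be nonnegative")
    ann_by_id = {a.read_id: a for a in annotations}
    primary = []
    for aln in alignments:
        if not aln.is_primary or aln.mapq < min_mapq:
            continue
        if aln.read_id not in ann_by_id:
            import warnings

            warnings.warn(f"alignment for unknown read {aln.read_id!r}; skipped")
            continue
        primary.append(aln)

    support: dict[tuple[str, int, str], list[str]] = defaultdict(list)
    for aln in primary:
        ann = ann_by_id[aln.read_id]
        if not ann.is_telomere_bearing:
            continue
        for run in ann.runs:
            if run.terminal_5p and abs(aln.qstart - run.qend) <= junction_tol:
                if aln.strand == "+":
                    key = (aln.contig, aln.rstart, "left")
                else:
                    key = (aln.contig, aln.rend, "right")
                support[key].append(aln.read_id)
            if run.terminal_3p and abs(run.qstart - aln.qend) <= junction_tol:
                if aln.strand == "+":
                    key = (aln.contig, aln.rend, "right")
                else:
                    key = (aln.contig, aln.rstart, "left")
                support[key].append(aln.read_id)

    # coverage by binary search over per-contig interval bounds
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for contig in {k[0] for k in support}:
        ivs = [(a.rstart, a.rend) for a in primary if a.contig == contig]
        starts[contig] = np.sort(np.array([iv[0] for iv in ivs], dtype=np.int64))
        ends[contig] = np.sort(np.array([iv[1] for iv in ivs], dtype=np.int64))

    calls = []
    for (contig, pos, side), read_ids in sorted(support.items()):
        n_cover = int(
            np.searchsorted(starts[contig], pos, side="right")
            - np.searchsorted(ends[contig], pos, side="left")
        )
        n_support = len(set(read_ids))
        n_cover = max(n_cover, n_support)
        is_end = pos <= end_margin
        if contig_lengths is not None and contig in contig_lengths:
            is_end = is_end or pos >= contig_lengths[contig] - end_margin
        calls.append(
            ATASCall(
                contig=contig,
                pos=pos,
                side=side,
                n_support=n_support,
                n_cover=n_cover,
                is_contig_end=is_end,
                read_ids=sorted(set(read_ids)),
            )
        )
    return calls


def summarize_atas(
    calls: list[ATASCall],
    contig_lengths: Mapping[str, int] | None = None,
    exclude_termini: bool = True,
    terminus_frac: float = 0.5,
) -> ATASSummary:
    """Summary counts over ATAS calls (contig termini excluded by default)."""
    kept = [c for c in calls if not (exclude_termini and c.is_terminus(terminus_frac))]
    n_total = len(kept)
    n_singleton = sum(1 for c in kept if c.n_support == 1)
    density = {}
    if contig_lengths:
        per_contig = defaultdict(int)
        for c in kept:
            per_contig[c.contig] += 1
        density = {
            name: 1_000.0 * per_contig.get(name, 0) / length
            for name, length in contig_lengths.items()
        }
    return ATASSummary(
        n_total=n_total,
        n_singleton=n_singleton,
        singleton_frac=n_singleton / n_total if n_total else 0.0,
        density_per_kbp=density,
    )


def atas_table(calls: list[ATASCall], terminus_frac: float = 0.5) -> pd.DataFrame:
    """Calls as a DataFrame (0-based pos plus a 1-based column for humans)."""
    return pd.DataFrame(
        [
            {
                "contig": c.contig,
                "pos": c.pos,
                "pos_1based": c.pos + 1,
                "side": c.side,
                "n_support": c.n_support,
                "n_cover": c.n_cover,
                "telo_frac": c.telo_frac,
                "is_contig_end": c.is_contig_end,
                "is_terminus": c.is_terminus(terminus_frac),
            }
            for c in calls
        ],
        columns=[
            "contig",
            "pos",
            "pos_1based",
            "side",
            "n_support",
            "n_cover",
            "telo_frac",
            "is_contig_end",
            "is_terminus",
        ],
    )
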