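"""Developmental expression ranking.

The developmental screen is a ranking, not a differential-expression
test: genes are ordered by the fold change of their expression in the
target sample (26 h, when new MACs form) over the mean of three baseline
samples (starved, gamone-treated, 0 h).  A pseudocount keeps ratios
finite for silent baselines; the strongest developmental inductions span 69x-825x
up-regulation and include nine transposase-domain genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .transposase import DEFAULT_TRANSPOSASE_DOMAINS, DomainHit

__all__ = ["FCRecord", "tpm", "fold_change", "annotate_top", "fold_change_frame"]


@dataclass(frozen=True)
class FCRecord:
    gene_id: str
    fc: float
    rank: int  # 1 = highest fold change

    def __post_init__(self):
        if self.fc <= 0:
            raise ValueError("fold change must be positive")


def tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million normalisation (genes x samples).

    Per sample: rate = count/length, value = rate / sum(rate) * 1e6, so
    every column sums to 1e6 and is invariant to scaling the column's
    counts.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def fold_change(
    matrix: pd.DataFrame,
    target: str,
    baselines: Sequence[str],
    pseudocount: float = 0.5,
) -> list[FCRecord]:
    """Rank genes by target-over-baseline-mean fold change.

    fc = (x_target + eps) / (mean over baselines + eps); genes are sorted
    by descending fc with ties broken lexicographically by gene id, and
    ranks are the permutation 1..n.
    """
    if target not in matrix.columns:
        raise ValueError(f"target sample {target!r} not in matrix")
    missing = [b for b in baselines if b not in matrix.columns]
    if missing:
        raise ValueError(f"baseline samples missing from matrix: {missing}")
    if not baselines:
        raise ValueError("at least one baseline sample is required")
    base = matrix[list(baselines)].mean(axis=1)
    fc = (matrix[target] + pseudocount) / (base + pseudocount)
    order = sorted(fc.index, key=lambda g: (-fc[g], g))
    return [FCRecord(gene_id=g, fc=float(fc[g]), rank=i + 1) for i, g in enumerate(order)]


def fold_change_frame(records: Sequence[FCRecord], k: int | None = None) -> pd.DataFrame:
    """Records as a DataFrame ordered by rank, with an in_top_k flag."""
    df = pd.DataFrame(
        [{"gene_id": r.gene_id, "fc": r.fc, "rank": r.rank} for r in records]
    ).sort_values("rank", ignore_index=True)
    if k is not None:
        df["in_top_k"] = df["rank"] <= k
    return df


def annotate_top(
    records: Sequence[FCRecord],
    hits: Iterable[DomainHit] | Mapping[str, Iterable[str]],
    k: int = 100,
    domains: Iterable[str] = DEFAULT_TRANSPOSASE_DOMAINS,
) -> tuple[int, list[str]]:
    """Count top-k genes carrying at least one whitelisted domain hit.

    ``hits`` may be DomainHit objects or a mapping gene_id -> domain names.
    Returns the count and the rank-ordered gene list.
    """
    if k > len(records):
        raise ValueError(f"k={k} exceeds the number of ranked genes ({len(records)})")
    domains = set(domains)
    by_gene: dict[str, set[str]] = {}
    if isinstance(hits, Mapping):
        for gid, doms in hits.items():
            by_gene[gid] = set(doms)
    else:
        for h in hits:
            by_gene.setdefault(h.gene_id, set()).add(h.domain_name)
    top = sorted((r for r in records if r.rank <= k), key=lambda r: r.rank)
    found = [r.gene_id for r in top if by_gene.get(r.gene_id, set()) & domains]
    return len(found), found
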