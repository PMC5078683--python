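"""Chromosome-scale distribution of SSRs relative to genes and TEs.

Windows of a fixed span (1 Mb by default, so window counts read directly
as per-Mb densities) tile each sequence; every feature is assigned to
the window containing its start coordinate.  Per-chromosome Pearson
correlations between the SSR track and the gene / transposable-element
tracks quantify the tendency of microsatellites to co-locate with genes
and avoid TE-rich regions.

Genic context classifies a locus by its start position with precedence
CDS > UTR > intron across all overlapping transcripts; a position inside
a gene span but in no exon is intronic, anything outside gene spans is
intergenic.  5' and 3' UTRs are collapsed into a single UTR class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .repeat_finder import SSRLocus

__all__ = [
    "AnnotationSet",
    "WindowDensity",
    "window_densities",
    "window_table",
    "pearson",
    "chromosome_correlations",
    "classify_genic_context",
    "context_proportions",
]

GENIC_CONTEXTS = ("CDS", "UTR", "intron", "intergenic")


@dataclass
class AnnotationSet:
    """Interval trees per seq_id, all 0-based half-open.

    ``genes`` holds gene spans; ``cds`` and ``utr`` hold the
    corresponding sub-features pooled over isoforms; ``tes`` holds
    transposable-element intervals.
    """

    genes: dict[str, IntervalTree] = field(default_factory=dict)
    cds: dict[str, IntervalTree] = field(default_factory=dict)
    utr: dict[str, IntervalTree] = field(default_factory=dict)
    tes: dict[str, IntervalTree] = field(default_factory=dict)

    @staticmethod
    def _add(trees: dict[str, IntervalTree], seq_id: str, start: int, end: int):
        if end <= start:
            return
        trees.setdefault(seq_id, IntervalTree()).addi(start, end)

    def add_gene(self, seq_id: str, start: int, end: int) -> None:
        self._add(self.genes, seq_id, start, end)

    def add_cds(self, seq_id: str, start: int, end: int) -> None:
        self._add(self.cds, seq_id, start, end)

    def add_utr(self, seq_id: str, start: int, end: int) -> None:
        self._add(self.utr, seq_id, start, end)

    def add_te(self, seq_id: str, start: int, end: int) -> None:
        self._add(self.tes, seq_id, start, end)


@dataclass(frozen=True)
class WindowDensity:
    seq_id: str
    window_index: int
    window_start: int
    window_span: int
    ssr_count: int
    gene_count: int
    te_count: int


def _starts(trees: Mapping[str, IntervalTree], seq_id: str) -> list[int]:
    tree = trees.get(seq_id)
    return [] if tree is None else [iv.begin for iv in tree]


def window_densities(
    loci: Sequence[SSRLocus],
    annotations: AnnotationSet,
    seq_lengths: Mapping[str, int],
    window_size: int = 1_000_000,
) -> list[WindowDensity]:
    """Non-overlapping window counts of SSRs, genes and TEs per sequence.

    Features are binned by start coordinate; the final partial window is
    kept with its true (shorter) span so window spans always sum to the
    sequence length.  Annotations on sequences absent from *seq_lengths*
    are skipped with a warning.
    """
    import logging

    known = set(seq_lengths)
    for trees in (annotations.genes, annotations.tes):
        for seq_id in set(trees) - known:
            logging.getLogger(__name__).warning(
                "annotation on unknown sequence %r skipped", seq_id
            )
    out: list[WindowDensity] = []
    loci_by_seq: dict[str, list[int]] = {}
    for locus in loci:
        loci_by_seq.setdefault(locus.seq_id, []).append(locus.start)
    for seq_id, length in seq_lengths.items():
        n_windows = max(1, -(-length // window_size))
        edges = [w * window_size for w in range(n_windows)] + [length]
        counts = {
            "ssr": np.histogram(loci_by_seq.get(seq_id, []), bins=edges)[0]
            if length
            else np.zeros(n_windows, int),
            "gene": np.histogram(_starts(annotations.genes, seq_id), bins=edges)[0],
            "te": np.histogram(_starts(annotations.tes, seq_id), bins=edges)[0],
        }
        for w in range(n_windows):
            out.append(
                WindowDensity(
                    seq_id=seq_id,
                    window_index=w,
                    window_start=edges[w],
                    window_span=edges[w + 1] - edges[w],
                    ssr_count=int(counts["ssr"][w]),
                    gene_count=int(counts["gene"][w]),
                    te_count=int(counts["te"][w]),
                )
            )
    return out


def window_table(windows: Iterable[WindowDensity]) -> pd.DataFrame:
    return pd.DataFrame([w.__dict__ for w in windows])


def pearson(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Product-moment correlation; None when undefined (constant input)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def chromosome_correlations(windows: Sequence[WindowDensity]) -> pd.DataFrame:
    """Per-sequence Pearson r of SSR counts vs gene and TE counts over windows."""
    df = window_table(windows)
    rows = []
    for seq_id, g in df.groupby("seq_id", sort=True):
        n_mb = g.window_span.sum() / 1e6
        rows.append(
            {
                "seq_id": seq_id,
                "n_windows": len(g),
                "ssr_per_mb": g.ssr_count.sum() / n_mb,
                "gene_per_mb": g.gene_count.sum() / n_mb,
                "te_per_mb": g.te_count.sum() / n_mb,
                "r_ssr_gene": pearson(g.ssr_count, g.gene_count)
                if len(g) >= 3
                else None,
                "r_ssr_te": pearson(g.ssr_count, g.te_count)
                if len(g) >= 3
                else None,
            }
        )
    return pd.DataFrame(rows)


def classify_genic_context(locus: SSRLocus, annotations: AnnotationSet) -> str:
    """CDS / UTR / intron / intergenic by the locus start position."""
    pos = locus.start
    seq_id = locus.seq_id
    if annotations.cds.get(seq_id) and annotations.cds[seq_id][pos]:
        return "CDS"
    if annotations.utr.get(seq_id) and annotations.utr[seq_id][pos]:
        return "UTR"
    if annotations.genes.get(seq_id) and annotations.genes[seq_id][pos]:
        return "intron"
    return "intergenic"


def context_proportions(contexts: Sequence[str]) -> dict[str, float]:
    """Genic vs intergenic split and CDS/UTR/intron shares within genic.

    Returns percentages; the within-genic shares sum to 100 whenever any
    marker is genic.
    """
    if not contexts:
        raise ValueError("no classified markers")
    bad = set(contexts) - set(GENIC_CONTEXTS)
    if bad:
        raise ValueError(f"unknown context labels {sorted(bad)}")
    n = len(contexts)
    n_genic = sum(c != "intergenic" for c in contexts)
    out = {
        "genic_pct": 100.0 * n_genic / n,
        "intergenic_pct": 100.0 * (n - n_genic) / n,
    }
    for label in ("CDS", "UTR", "intron"):
        out[f"{label.lower()}_pct_of_genic"] = (
            100.0 * sum(c == label for c in contexts) / n_genic if n_genic else 0.0
        )
    return out
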