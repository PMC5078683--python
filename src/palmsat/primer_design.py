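"""Primer-pair design for microsatellite loci.

For each SSR locus a single flanking primer pair is sought under fixed
constraint windows: melting temperature 58--62 degC, primer length
18--24 bp, GC content 45--55 %, expected product 100--250 bp.  Primers
must lie entirely in the flanks (never overlapping the repeat itself)
and the product must contain the whole repeat.  Loci for which no
combination of windows satisfies every constraint are reported as
design failures carrying the dominant failing constraint, with "not
enough flanking sequence" kept distinguishable from constraint misses.

Melting temperatures use nearest-neighbor thermodynamics with the
unified parameter set at 50 mM monovalent salt and 50 nM oligo; the
Wallace 2+4 rule is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from Bio.SeqUtils import MeltingTemp as _mt

from .repeat_finder import SSRLocus, reverse_complement

__all__ = [
    "PrimerConstraints",
    "PrimerPair",
    "DesignFailure",
    "gc_content",
    "melting_temp",
    "design_primers",
    "design_all",
]

_ACGT = frozenset("acgtACGT")


def _check_unambiguous(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _ACGT
    if bad:
        raise ValueError(f"ambiguous or invalid bases {sorted(bad)} in {seq!r}")


def gc_content(seq: str) -> float:
    """GC percentage of an unambiguous DNA string."""
    _check_unambiguous(seq)
    s = seq.lower()
    return 100.0 * (s.count("g") + s.count("c")) / len(s)


def melting_temp(
    seq: str,
    method: str = "nn",
    Na: float = 50.0,
    dnac1: float = 50.0,
    dnac2: float = 0.0,
) -> float:
    """Oligo melting temperature in degC.

    ``nn`` (default) is nearest-neighbor thermodynamics with the unified
    parameter set and the entropy salt correction, at *Na* mM monovalent
    cation and *dnac1* nM oligo.  ``wallace`` is the 2(A+T)+4(G+C) rule.
    """
    _check_unambiguous(seq)
    if method == "wallace":
        return float(_mt.Tm_Wallace(seq))
    if method == "nn":
        if len(seq) < 8:
            raise ValueError("nearest-neighbor Tm needs length >= 8")
        selfcomp = seq.lower() == reverse_complement(seq.lower())
        return float(
            _mt.Tm_NN(seq, Na=Na, dnac1=dnac1, dnac2=dnac2, selfcomp=selfcomp)
        )
    raise ValueError(f"unknown Tm method {method!r}")


@dataclass(frozen=True)
class PrimerConstraints:
    """Constraint windows applied to both primers and the product."""

    tm_range: tuple[float, float] = (58.0, 62.0)
    length_range: tuple[int, int] = (18, 24)
    gc_range: tuple[float, float] = (45.0, 55.0)
    product_range: tuple[int, int] = (100, 250)

    def __post_init__(self) -> None:
        for name in ("tm_range", "length_range", "gc_range", "product_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} empty: {lo} > {hi}")


@dataclass(frozen=True)
class PrimerPair:
    """A designed pair; the reverse primer is given 5'->3' on the minus strand."""

    marker_id: str
    forward_seq: str
    reverse_seq: str
    forward_tm: float
    reverse_tm: float
    forward_gc: float
    reverse_gc: float
    forward_start: int  # 0-based start of forward primer on the source sequence
    reverse_end: int  # exclusive end of the reverse-primer site on the source
    source_locus: SSRLocus

    @property
    def expected_product_size(self) -> int:
        return self.reverse_end - self.forward_start


@dataclass(frozen=True)
class DesignFailure:
    """Why no primer pair could be returned for a locus."""

    locus: SSRLocus
    reason: str  # insufficient_flank | gc_out_of_range | tm_out_of_range | product_size
    detail: str = ""


def _candidate_primers(seq, lo, hi, constraints, tm_method, reverse):
    """Constraint-passing primer windows inside seq[lo:hi].

    Returns (candidates, fail_counts); candidates are
    (start, end, primer_seq, tm, gc) with primer_seq 5'->3'.
    """
    lmin, lmax = constraints.length_range
    gmin, gmax = constraints.gc_range
    tmin, tmax = constraints.tm_range
    out = []
    fails = {"gc_out_of_range": 0, "tm_out_of_range": 0}
    for length in range(lmin, lmax + 1):
        for start in range(lo, hi - length + 1):
            window = seq[start : start + length]
            if "n" in window:
                continue
            primer = reverse_complement(window) if reverse else window
            gc = gc_content(primer)
            if not (gmin <= gc <= gmax):
                fails["gc_out_of_range"] += 1
                continue
            tm = melting_temp(primer, method=tm_method)
            if not (tmin <= tm <= tmax):
                fails["tm_out_of_range"] += 1
                continue
            out.append((start, start + length, primer, tm, gc))
    return out, fails


def design_primers(
    seq: str,
    locus: SSRLocus,
    constraints: PrimerConstraints | None = None,
    marker_id: str | None = None,
    tm_method: str = "nn",
) -> PrimerPair | DesignFailure:
    """Best constraint-satisfying primer pair bracketing *locus*, or a failure.

    The search enumerates every forward window ending at or before the
    repeat start and every reverse window starting at or after the
    repeat end, within the product budget.  Among valid combinations the
    pair minimising the summed distances of Tm, GC and product size from
    their range midpoints wins; ties break to the smaller product, then
    the leftmost forward primer, then the shortest primers, so the result
    is deterministic.
    """
    constraints = constraints or PrimerConstraints()
    if locus.start < 0 or locus.end > len(seq):
        raise ValueError(f"locus {locus.start}-{locus.end} outside sequence bounds")
    seq = seq.lower()
    marker_id = marker_id or f"{locus.seq_id}_{locus.start}"
    lmin, _ = constraints.length_range
    pmin, pmax = constraints.product_range

    left_flank = locus.start
    right_flank = len(seq) - locus.end
    if left_flank < lmin or right_flank < lmin:
        return DesignFailure(locus, "insufficient_flank",
                             f"flanks {left_flank}/{right_flank} bp")
    if locus.total_length + 2 * lmin > pmax:
        return DesignFailure(locus, "product_size",
                             "repeat too long for the product window")

    # geometric bounds: product = reverse_end - forward_start must fit pmax
    f_lo = max(0, locus.end + lmin - pmax)
    fwd, f_fail = _candidate_primers(
        seq, f_lo, locus.start, constraints, tm_method, reverse=False
    )
    r_hi = min(len(seq), locus.start - lmin + pmax)
    rev, r_fail = _candidate_primers(
        seq, locus.end, r_hi, constraints, tm_method, reverse=True
    )

    tm_mid = sum(constraints.tm_range) / 2
    gc_mid = sum(constraints.gc_range) / 2
    p_mid = sum(constraints.product_range) / 2

    best = None
    product_misses = 0
    rev_sorted = sorted(rev, key=lambda r: r[1])
    for f_start, f_end, f_seq, f_tm, f_gc in fwd:
        for r_start, r_end, r_seq, r_tm, r_gc in rev_sorted:
            product = r_end - f_start
            if product < pmin or product > pmax:
                product_misses += 1
                continue
            score = (
                abs(f_tm - tm_mid)
                + abs(r_tm - tm_mid)
                + abs(f_gc - gc_mid)
                + abs(r_gc - gc_mid)
                + abs(product - p_mid)
            )
            key = (score, product, f_start, len(f_seq) + len(r_seq))
            if best is None or key < best[0]:
                best = (
                    key,
                    PrimerPair(
                        marker_id=marker_id,
                        forward_seq=f_seq,
                        reverse_seq=r_seq,
                        forward_tm=f_tm,
                        reverse_tm=r_tm,
                        forward_gc=f_gc,
                        reverse_gc=r_gc,
                        forward_start=f_start,
                        reverse_end=r_end,
                        source_locus=locus,
                    ),
                )
    if best is not None:
        return best[1]

    # diagnose: dominant failing constraint over all windows examined
    fails = {
        "gc_out_of_range": f_fail["gc_out_of_range"] + r_fail["gc_out_of_range"],
        "tm_out_of_range": f_fail["tm_out_of_range"] + r_fail["tm_out_of_range"],
        "product_size": product_misses,
    }
    if not fwd and not rev and not any(fails.values()):
        return DesignFailure(locus, "insufficient_flank", "no candidate windows")
    reason = max(fails, key=fails.get)
    return DesignFailure(locus, reason, f"window misses: {fails}")


def design_all(
    genome: Mapping[str, str],
    loci: list[SSRLocus],
    constraints: PrimerConstraints | None = None,
    tm_method: str = "nn",
) -> tuple[list[PrimerPair], list[DesignFailure]]:
    """Design one pair per locus; returns (pairs, failures).

    Marker ids are ``<seq_id>_<start>`` and unique because loci are
    maximal repeats (two loci never share a start and unit length).
    """
    pairs: list[PrimerPair] = []
    failures: list[DesignFailure] = []
    counts: dict[str, int] = {}
    for locus in loci:
        base = f"{locus.seq_id}_{locus.start}"
        n = counts.get(base, 0)
        counts[base] = n + 1
        marker_id = base if n == 0 else f"{base}_{n}"
        result = design_primers(
            genome[locus.seq_id], locus, constraints, marker_id, tm_method
        )
        (pairs if isinstance(result, PrimerPair) else failures).append(result)
    return pairs, failures
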