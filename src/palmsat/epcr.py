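"""Electronic PCR: mismatch-tolerant primer-site search and amplicon calling.

The stringent mode mirrors a conservative marker screen: at most one
mismatch per primer, no gaps, and an amplicon is accepted only when its
size differs from the expected product by strictly less than the size
deviation (100 bp by default).  ``N`` in the template never matches a
primer base.  An optional 3'-protect window forbids mismatches in the
last bases of either primer, where polymerase extension is most
sensitive.

A permissive gapped mode (the classic 2-mismatch/1-gap default of
genome-scale e-PCR screens) is available behind ``max_gaps > 0`` and
uses banded edit distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .primer_design import PrimerPair
from .repeat_finder import reverse_complement

__all__ = [
    "EpcrParams",
    "BindingSite",
    "Amplicon",
    "find_binding_sites",
    "enumerate_amplicons",
    "amplify",
    "classify_copy_number",
]


@dataclass(frozen=True)
class EpcrParams:
    """Matching stringency. Defaults are the stringent screen settings."""

    max_mismatch_per_primer: int = 1
    max_gaps: int = 0
    size_deviation: int = 100  # strict: |size - expected| < size_deviation
    three_prime_protect: int = 0

    def __post_init__(self) -> None:
        if min(
            self.max_mismatch_per_primer,
            self.max_gaps,
            self.size_deviation,
            self.three_prime_protect,
        ) < 0:
            raise ValueError("ePCR parameters must be non-negative")


@dataclass(frozen=True)
class BindingSite:
    seq_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    seq_id: str
    start: int
    end: int
    forward_site: BindingSite
    reverse_site: BindingSite

    @property
    def size(self) -> int:
        return self.end - self.start


def _site_scan(arr: np.ndarray, primer: str, max_mm: int, protect: int,
               protect_at_end: bool) -> tuple[np.ndarray, np.ndarray]:
    """Positions and mismatch counts where *primer* matches *arr* gap-free."""
    m = len(primer)
    if arr.size < m:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    p = np.frombuffer(primer.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    mismatch = (windows != p) | (windows == ord("n"))  # N never matches
    counts = mismatch.sum(axis=1)
    ok = counts <= max_mm
    if protect > 0:
        guarded = mismatch[:, m - protect:] if protect_at_end else mismatch[:, :protect]
        ok &= ~guarded.any(axis=1)
    pos = np.flatnonzero(ok)
    return pos, counts[pos]


def _site_scan_gapped(seq: str, primer: str, budget: int) -> list[tuple[int, int, int]]:
    """(start, end, distance) of best non-overlapping infix matches, edit distance."""
    import edlib

    res = edlib.align(primer, seq.replace("n", "!"), mode="HW", task="locations",
                      k=budget)
    if res["editDistance"] < 0:
        return []
    hits = []
    seen_ends: set[int] = set()
    for start, end in res["locations"]:
        if end in seen_ends:
            continue
        seen_ends.add(end)
        hits.append((start, end + 1, res["editDistance"]))
    return hits


def find_binding_sites(
    seq_id: str,
    seq: str,
    primer: str,
    params: EpcrParams | None = None,
) -> list[BindingSite]:
    """Every site on either strand where the primer binds within tolerance.

    Gap-free (Hamming) matching unless ``params.max_gaps > 0``.  Minus
    strand sites are reported in plus-strand coordinates; their 3' end
    faces the lower coordinate.
    """
    params = params or EpcrParams()
    if len(primer) < 8:
        raise ValueError("primer too short for site search (< 8 bases)")
    primer = primer.lower()
    seq = seq.lower()
    sites: list[BindingSite] = []
    m = len(primer)
    if params.max_gaps > 0:
        budget = params.max_mismatch_per_primer + params.max_gaps
        for strand, probe in (("+", primer), ("-", reverse_complement(primer))):
            for start, end, dist in _site_scan_gapped(seq, probe, budget):
                sites.append(BindingSite(seq_id, strand, start, end, dist))
    else:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        pos, mm = _site_scan(arr, primer, params.max_mismatch_per_primer,
                             params.three_prime_protect, protect_at_end=True)
        sites += [BindingSite(seq_id, "+", int(i), int(i) + m, int(c))
                  for i, c in zip(pos, mm)]
        # on the minus strand the primer's 3' end maps to the window start
        pos, mm = _site_scan(arr, reverse_complement(primer),
                             params.max_mismatch_per_primer,
                             params.three_prime_protect, protect_at_end=False)
        sites += [BindingSite(seq_id, "-", int(i), int(i) + m, int(c))
                  for i, c in zip(pos, mm)]
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def enumerate_amplicons(
    sites_f: Sequence[BindingSite],
    sites_r: Sequence[BindingSite],
    expected_size: int,
    params: EpcrParams | None = None,
) -> list[Amplicon]:
    """All orientation-consistent products within the size window.

    A product needs one primer on the plus strand upstream of the other
    primer's minus-strand site (either primer may take either role), the
    two sites must not overlap, and |size - expected| must be strictly
    below the size deviation.
    """
    params = params or EpcrParams()
    out: list[Amplicon] = []
    for plus_sites, minus_sites in ((sites_f, sites_r), (sites_r, sites_f)):
        for a in plus_sites:
            if a.strand != "+":
                continue
            for b in minus_sites:
                if b.strand != "-" or b.seq_id != a.seq_id:
                    continue
                if b.start < a.end:
                    continue  # overlapping primers cannot form a product
                size = b.end - a.start
                if abs(size - expected_size) < params.size_deviation:
                    out.append(Amplicon(a.seq_id, a.start, b.end, a, b))
    # the two role-assignments can produce duplicate intervals only for
    # identical primers; dedupe on the full site pair
    out = list({(x.seq_id, x.start, x.end, x.forward_site, x.reverse_site): x
                for x in out}.values())
    out.sort(key=lambda x: (x.seq_id, x.start, x.end))
    return out


def amplify(
    genome: Mapping[str, str],
    pair: PrimerPair,
    params: EpcrParams | None = None,
) -> list[Amplicon]:
    """In-silico products of one primer pair over every genome record."""
    params = params or EpcrParams()
    out: list[Amplicon] = []
    for seq_id, seq in genome.items():
        sf = find_binding_sites(seq_id, seq, pair.forward_seq, params)
        sr = find_binding_sites(seq_id, seq, pair.reverse_seq, params)
        out.extend(enumerate_amplicons(sf, sr, pair.expected_product_size, params))
    out.sort(key=lambda x: (x.seq_id, x.start, x.end))
    return out


def classify_copy_number(n_amplicons: int) -> str | None:
    """Copy-number class from the product count: '1', '2', '3', '>3'.

    Zero products means the marker has no class (None): it failed the
    screen rather than landing in a copy-number bin.
    """
    if n_amplicons < 0:
        raise ValueError("negative amplicon count")
    if n_amplicons == 0:
        return None
    if n_amplicons <= 3:
        return str(n_amplicons)
    return ">3"
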