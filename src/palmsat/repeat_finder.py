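"""Detection and summary of perfect microsatellites (SSRs).

A microsatellite here is a maximal perfect tandem run of a primitive
1--6 bp DNA unit.  Mononucleotide runs must reach 12 repeat units; di-
to hexanucleotide runs must reach 4.  Runs are never extended across an
``N`` (an assembly gap cannot be part of a perfect repeat) and scanning
is case-insensitive.

Each locus is labelled with a *motif class*: the unit in the rotational
phase at which the run starts, paired with its reverse complement
(``tc/ga``).  Rotational phases are deliberately kept distinct classes
(``ca/tg`` is not merged with ``ac/gt``), matching how a left-to-right
scanner labels repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MIN_REPEATS",
    "TIER_NAMES",
    "SSRLocus",
    "SummaryTable",
    "reverse_complement",
    "is_primitive",
    "canonicalize_motif",
    "find_ssrs",
    "find_ssrs_in_seq",
    "summarize",
    "density",
    "percentage",
]

#: minimum number of complete repeat units per unit length (1..6)
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 12, 2: 4, 3: 4, 4: 4, 5: 4, 6: 4}

TIER_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}

_COMP = str.maketrans("acgtACGT", "tgcaTGCA")
_VALID = frozenset("acgtnACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMP)[::-1]


def is_primitive(unit: str) -> bool:
    """True iff *unit* is not a whole-number concatenation of a shorter unit.

    ``atat`` is not primitive (it is ``at`` twice), so a run of ``atat``
    is a dinucleotide repeat, never a tetranucleotide one.
    """
    if not unit:
        raise ValueError("empty repeat unit")
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit[:d] * (n // d) == unit:
            return False
    return True


def canonicalize_motif(unit: str) -> str:
    """Motif-class label pairing *unit* with its reverse complement.

    Self-reverse-complementary units (``at``, ``cg``) keep a single-part
    label.  The unit is taken in the phase in which the locus starts;
    rotations are not merged.
    """
    unit = unit.lower()
    if not is_primitive(unit):
        raise ValueError(f"non-primitive unit {unit!r} has no motif class")
    rc = reverse_complement(unit)
    return unit if rc == unit else f"{unit}/{rc}"


@dataclass(frozen=True)
class SSRLocus:
    """One maximal perfect tandem repeat (0-based, half-open coordinates)."""

    seq_id: str
    start: int
    end: int
    unit: str
    repeat_count: int
    motif_class: str

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def total_length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.unit) * self.repeat_count:
            raise ValueError(
                f"locus span {self.end - self.start} != "
                f"{len(self.unit)} x {self.repeat_count}"
            )

    @property
    def sort_key(self):
        return (self.seq_id, self.start, self.unit_length)


def validate_thresholds(thresholds: Mapping[int, int]) -> None:
    if set(thresholds) != set(range(1, 7)):
        raise ValueError("thresholds must have keys exactly 1..6")
    if any(v < 2 for v in thresholds.values()):
        raise ValueError("all repeat-count thresholds must be >= 2")


def _validate_residues(seq_id: str, seq: str) -> None:
    bad = next((i for i, c in enumerate(seq) if c not in _VALID), None)
    if bad is not None:
        raise ValueError(
            f"non-IUPAC character {seq[bad]!r} at position {bad} of {seq_id!r}"
        )


def find_ssrs_in_seq(
    seq_id: str,
    seq: str,
    thresholds: Mapping[int, int] | None = None,
) -> list[SSRLocus]:
    """All maximal perfect SSRs in one sequence, sorted by start.

    Runs containing ``N`` are split at the ``N``.  A run reportable at
    several unit lengths (poly-A as mono or as ``aa``) is reported only
    at its smallest primitive unit; the primitivity check on the unit at
    the locus start enforces this.
    """
    thresholds = dict(DEFAULT_MIN_REPEATS if thresholds is None else thresholds)
    validate_thresholds(thresholds)
    _validate_residues(seq_id, seq)
    lower = seq.lower()
    loci: list[SSRLocus] = []
    # split at N: perfect repeats never span assembly gaps
    offset = 0
    for segment in lower.split("n"):
        if segment:
            loci.extend(_scan_segment(seq_id, segment, offset, thresholds))
        offset += len(segment) + 1
    loci.sort(key=lambda l: l.sort_key)
    return loci


def _scan_segment(
    seq_id: str, segment: str, offset: int, thresholds: Mapping[int, int]
) -> Iterable[SSRLocus]:
    arr = np.frombuffer(segment.encode("ascii"), dtype=np.uint8)
    n = arr.size
    for k in range(1, 7):
        min_len = k * thresholds[k]
        if n < min_len:
            continue
        eq = arr[k:] == arr[:-k]
        # maximal runs of True in eq: each run [a, b) means the region
        # [a, b + k) of the sequence has period k
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = edges[::2], edges[1::2]
        for a, b in zip(starts, ends):
            a = int(a)
            region_len = int(b - a) + k
            count = region_len // k
            if count < thresholds[k]:
                continue
            unit = segment[a : a + k]
            if not is_primitive(unit):
                continue  # reported at a smaller unit length instead
            yield SSRLocus(
                seq_id=seq_id,
                start=offset + a,
                end=offset + a + k * count,
                unit=unit,
                repeat_count=count,
                motif_class=canonicalize_motif(unit),
            )


def find_ssrs(
    genome: Mapping[str, str],
    thresholds: Mapping[int, int] | None = None,
) -> list[SSRLocus]:
    """All maximal perfect SSRs over a genome (mapping seq_id -> residues).

    Loci are sorted by (seq_id, start).
    """
    loci: list[SSRLocus] = []
    for seq_id, seq in genome.items():
        loci.extend(find_ssrs_in_seq(seq_id, seq, thresholds))
    loci.sort(key=lambda l: l.sort_key)
    return loci


def percentage(part: float, total: float) -> float:
    """Percentage of *part* in *total*; 0.0 on an empty total."""
    return 0.0 if total == 0 else 100.0 * part / total


def density(n_loci: int, genome_length: int) -> tuple[float, float | None]:
    """(loci per Mb, kb per locus) for a genome of *genome_length* bases.

    The spacing is undefined (None) when there are no loci.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    per_mb = n_loci / (genome_length / 1e6)
    spacing = None if n_loci == 0 else (genome_length / 1e3) / n_loci
    return per_mb, spacing


@dataclass
class SummaryTable:
    """Per-tier and per-motif-class SSR statistics plus genome-wide density.

    ``table`` rows carry a ``level`` column: one ``total`` row, one
    ``tier`` row per unit length present, and one ``class`` row per motif
    class.  Percentages are reported both against the grand total and
    within the motif-length tier.
    """

    table: pd.DataFrame
    n_loci: int
    genome_length: int
    density_per_mb: float
    kb_per_locus: float | None


_SUMMARY_COLUMNS = [
    "level",
    "tier",
    "motif",
    "count",
    "percent_of_total",
    "percent_of_tier",
    "min_repeats",
    "max_repeats",
    "mean_repeats",
    "total_length_bp",
]


def summarize(loci: Iterable[SSRLocus], genome_length: int) -> SummaryTable:
    """Motif-spectrum summary: counts, repeat-number ranges, lengths.

    Mirrors a per-motif abundance table: for every motif class and every
    unit-length tier the locus count, its share of all loci, the range
    and mean of repeat numbers, and the summed repeat length.
    """
    loci = list(loci)
    per_mb, spacing = density(len(loci), genome_length)
    if not loci:
        table = pd.DataFrame(
            [["total", "", "", 0, 0.0, 0.0, 0, 0, 0.0, 0]],
            columns=_SUMMARY_COLUMNS,
        )
        return SummaryTable(table, 0, genome_length, 0.0, None)

    df = pd.DataFrame(
        {
            "tier": [TIER_NAMES[l.unit_length] for l in loci],
            "unit_length": [l.unit_length for l in loci],
            "motif": [l.motif_class for l in loci],
            "repeats": [l.repeat_count for l in loci],
            "length": [l.total_length for l in loci],
        }
    )
    total = len(df)
    rows: list[list] = [
        [
            "total",
            "",
            "",
            total,
            100.0,
            100.0,
            int(df.repeats.min()),
            int(df.repeats.max()),
            float(df.repeats.mean()),
            int(df.length.sum()),
        ]
    ]
    for ulen in sorted(df.unit_length.unique()):
        tier_df = df[df.unit_length == ulen]
        tier = TIER_NAMES[ulen]
        rows.append(
            [
                "tier",
                tier,
                "",
                len(tier_df),
                percentage(len(tier_df), total),
                100.0,
                int(tier_df.repeats.min()),
                int(tier_df.repeats.max()),
                float(tier_df.repeats.mean()),
                int(tier_df.length.sum()),
            ]
        )
        for motif, cls_df in sorted(tier_df.groupby("motif")):
            rows.append(
                [
                    "class",
                    tier,
                    motif,
                    len(cls_df),
                    percentage(len(cls_df), total),
                    percentage(len(cls_df), len(tier_df)),
                    int(cls_df.repeats.min()),
                    int(cls_df.repeats.max()),
                    float(cls_df.repeats.mean()),
                    int(cls_df.length.sum()),
                ]
            )
    table = pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
    return SummaryTable(table, total, genome_length, per_mb, spacing)
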