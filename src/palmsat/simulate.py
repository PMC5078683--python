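"""Seed-controlled synthetic genomes with known planted features.

The generator stands in for real assemblies at desk scale: an i.i.d.
background of configurable GC content carries planted SSR loci (unit,
repeat count, position) and planted primer-target cassettes (forward
site + filler + reverse-complemented reverse site, at a chosen copy
number).  A truth table records the exact coordinates of everything
planted.  Planted repeats are guarded so the background cannot extend
them: the bases immediately flanking a planted locus are chosen to break
both a full-unit extension and any run through the boundary.

A divergence operator applies per-base substitutions and geometric
indels, emulating the drift between two related genomes, and returns a
mutation ledger so the fate of every planted feature stays computable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .repeat_finder import DEFAULT_MIN_REPEATS, is_primitive, reverse_complement

__all__ = [
    "PlantedSSR",
    "PlantedTarget",
    "SyntheticGenomeSpec",
    "DivergenceSpec",
    "generate_genome",
    "diverge_genome",
]

_BASES = np.frombuffer(b"acgt", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedSSR:
    unit: str
    repeat_count: int
    position: int | None = None  # approximate start; None = place anywhere

    def __post_init__(self):
        if not is_primitive(self.unit.lower()):
            raise ValueError(f"planted unit {self.unit!r} is not primitive")
        if self.repeat_count < 2:
            raise ValueError("repeat_count must be >= 2")


@dataclass(frozen=True)
class PlantedTarget:
    forward_seq: str
    reverse_seq: str
    product_size: int
    copies: int = 1

    def __post_init__(self):
        if self.product_size < len(self.forward_seq) + len(self.reverse_seq):
            raise ValueError("product smaller than the two primer sites")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")


@dataclass
class SyntheticGenomeSpec:
    n_sequences: int = 1
    length: int = 10_000
    gc: float = 0.5
    planted_ssrs: Sequence[PlantedSSR] = field(default_factory=tuple)
    planted_targets: Sequence[PlantedTarget] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must be in [0, 1]")
        if self.n_sequences < 1 or self.length < 1:
            raise ValueError("need at least one sequence of positive length")


def _random_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at, cg = (1 - gc) / 2, gc / 2
    return rng.choice(_BASES, size=n, p=[at, cg, cg, at])


def _place(rng, occupied, length, span, position):
    """A start for a span-bp insert not overlapping occupied intervals (+pad)."""
    pad = 30  # keep planted features out of each other's flanks
    if span + 2 * pad > length:
        raise ValueError("planted feature does not fit in the sequence")
    if position is not None:
        s = min(max(position, pad), length - span - pad)
        for a, b in occupied:
            if s < b + pad and a - pad < s + span:
                raise ValueError(f"planted feature at {position} overlaps another")
        return s
    for _ in range(200):
        s = int(rng.integers(pad, length - span - pad))
        if all(s >= b + pad or s + span <= a - pad for a, b in occupied):
            return s
    raise ValueError("could not pack planted features; genome too small")


def _guard_boundaries(seq: np.ndarray, start: int, end: int, unit: str) -> None:
    """Pick flanking bases that cannot extend the planted repeat."""
    k = len(unit)
    if start > 0:
        forbidden = {unit[k - 1], chr(seq[start])}
        seq[start - 1] = ord(next(b for b in "acgt" if b not in forbidden))
    if end < seq.size:
        forbidden = {unit[0], chr(seq[end - 1])}
        seq[end] = ord(next(b for b in "acgt" if b not in forbidden))


def generate_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Synthetic genome plus a truth table of planted-feature coordinates.

    Deterministic for a given spec (seed included).  The truth table has
    columns seq_id, kind (ssr / target_copy), name, start, end; target
    copies record the full product interval.
    """
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    truth_rows: list[dict] = []
    for s in range(spec.n_sequences):
        seq_id = f"seq{s}"
        seq = _random_background(rng, spec.length, spec.gc)
        occupied: list[tuple[int, int]] = []
        if s == 0:  # planted features go on the first sequence
            for i, ssr in enumerate(spec.planted_ssrs):
                unit = ssr.unit.lower()
                span = len(unit) * ssr.repeat_count
                start = _place(rng, occupied, spec.length, span, ssr.position)
                insert = (unit * ssr.repeat_count).encode("ascii")
                seq[start : start + span] = np.frombuffer(insert, dtype=np.uint8)
                _guard_boundaries(seq, start, start + span, unit)
                occupied.append((start, start + span))
                truth_rows.append(
                    dict(seq_id=seq_id, kind="ssr", name=f"ssr{i}", start=start,
                         end=start + span, unit=unit, repeat_count=ssr.repeat_count)
                )
            for i, tgt in enumerate(spec.planted_targets):
                fwd = tgt.forward_seq.lower()
                rev = tgt.reverse_seq.lower()
                filler = tgt.product_size - len(fwd) - len(rev)
                for c in range(tgt.copies):
                    start = _place(rng, occupied, spec.length, tgt.product_size, None)
                    cassette = (
                        fwd
                        + "".join(map(chr, _random_background(rng, filler, spec.gc)))
                        + reverse_complement(rev)
                    ).encode("ascii")
                    seq[start : start + tgt.product_size] = np.frombuffer(
                        cassette, dtype=np.uint8
                    )
                    occupied.append((start, start + tgt.product_size))
                    truth_rows.append(
                        dict(seq_id=seq_id, kind="target_copy", name=f"target{i}",
                             start=start, end=start + tgt.product_size,
                             unit="", repeat_count=0)
                    )
        genome[seq_id] = seq.tobytes().decode("ascii")
    truth = pd.DataFrame(
        truth_rows,
        columns=["seq_id", "kind", "name", "start", "end", "unit", "repeat_count"],
    )
    return genome, truth


@dataclass
class DivergenceSpec:
    substitution_rate: float = 0.01
    indel_rate: float = 0.0
    mean_indel_length: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.substitution_rate < 1.0):
            raise ValueError("substitution_rate must be in [0, 1)")
        if not (0.0 <= self.indel_rate < 1.0):
            raise ValueError("indel_rate must be in [0, 1)")
        if self.mean_indel_length < 1.0:
            raise ValueError("mean_indel_length must be >= 1")


def diverge_genome(
    genome: dict[str, str], spec: DivergenceSpec
) -> tuple[dict[str, str], pd.DataFrame]:
    """Mutated copy of *genome* plus a per-event mutation ledger.

    Substitutions are i.i.d. per base; at each base an indel starts with
    probability ``indel_rate`` and draws a geometric length (insertions
    and deletions equally likely).  Ledger columns: seq_id, kind
    (sub/ins/del), old_pos (source coordinate), new_pos (coordinate in
    the diverged sequence), length, old, new.
    """
    rng = np.random.default_rng(spec.seed)
    out: dict[str, str] = {}
    rows: list[dict] = []
    p_geom = 1.0 / spec.mean_indel_length
    for seq_id, seq in genome.items():
        arr = np.frombuffer(seq.lower().encode("ascii"), dtype=np.uint8).copy()
        n = arr.size
        # substitutions first (coordinates unchanged)
        sub_pos = np.flatnonzero(rng.random(n) < spec.substitution_rate)
        for pos in sub_pos:
            old = chr(arr[pos])
            if old == "n":
                continue
            choices = [b for b in "acgt" if b != old]
            new = choices[int(rng.integers(3))]
            arr[pos] = ord(new)
            rows.append(dict(seq_id=seq_id, kind="sub", old_pos=int(pos),
                             new_pos=int(pos), length=1, old=old, new=new))
        if spec.indel_rate > 0:
            pieces: list[np.ndarray] = []
            cursor = 0
            new_len = 0
            indel_pos = np.flatnonzero(rng.random(n) < spec.indel_rate)
            for pos in indel_pos:
                if pos < cursor:
                    continue  # swallowed by a previous deletion
                length = int(rng.geometric(p_geom))
                pieces.append(arr[cursor:pos])
                new_len += pos - cursor
                if rng.random() < 0.5:  # insertion before pos
                    ins = _random_background(rng, length, 0.5)
                    pieces.append(ins)
                    rows.append(dict(seq_id=seq_id, kind="ins", old_pos=int(pos),
                                     new_pos=new_len, length=length, old="",
                                     new=ins.tobytes().decode()))
                    new_len += length
                    cursor = pos
                else:  # deletion of [pos, pos+length)
                    length = min(length, n - pos)
                    rows.append(dict(seq_id=seq_id, kind="del", old_pos=int(pos),
                                     new_pos=new_len, length=length,
                                     old=arr[pos : pos + length].tobytes().decode(),
                                     new=""))
                    cursor = pos + length
            pieces.append(arr[cursor:])
            arr = np.concatenate(pieces) if pieces else arr
        out[seq_id] = arr.tobytes().decode("ascii")
    ledger = pd.DataFrame(
        rows, columns=["seq_id", "kind", "old_pos", "new_pos", "length", "old", "new"]
    )
    return out, ledger
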