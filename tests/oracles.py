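"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (per-position scans,
exhaustive enumeration, textbook formulas) and deliberately shares no
code with the package.
"""

from __future__ import annotations

import math

_COMP = {"a": "t", "c": "g", "g": "c", "t": "a"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.lower()))


def brute_primitive(unit: str) -> bool:
    """Primitivity by exhaustive enumeration of all shorter generators."""
    m = len(unit)
    for t_len in range(1, m):
        for i in range(m - t_len + 1):
            t = unit[i : i + t_len]
            if m % t_len == 0 and t * (m // t_len) == unit:
                return False
    return True


def brute_force_ssrs(seq_id: str, seq: str,
                     thresholds: dict[int, int]) -> set[tuple]:
    """Every maximal primitive tandem run meeting its threshold.

    Tests each (position, unit length) pair: a locus starts at ``a`` for
    unit length ``k`` when the period-k match run cannot start earlier,
    then extends right position by position.  ``n`` never matches
    anything, including itself.
    """
    s = seq.lower()
    n = len(s)
    out: set[tuple] = set()

    def match(i: int, j: int) -> bool:
        return s[i] == s[j] and s[i] != "n"

    for k in range(1, 7):
        for a in range(n - k):
            if not match(a, a + k):
                continue
            if a > 0 and match(a - 1, a - 1 + k):
                continue  # run starts earlier
            e = a + k
            while e < n and match(e - k, e):
                e += 1
            count = (e - a) // k
            if count < thresholds[k]:
                continue
            unit = s[a : a + k]
            if "n" in unit or not brute_primitive(unit):
                continue
            out.add((seq_id, a, a + k * count, unit, count))
    return out


def sliding_hamming_sites(seq: str, primer: str, max_mm: int,
                          protect: int = 0) -> set[tuple]:
    """(strand, start, end, mismatches) for both strands, gap-free.

    The 3'-protect window is the last *protect* primer bases: on the
    plus strand these face the window end, on the minus strand the
    window start.
    """
    s = seq.lower()
    out: set[tuple] = set()
    for strand, probe in (("+", primer.lower()), ("-", rc(primer))):
        m = len(probe)
        for i in range(len(s) - m + 1):
            window = s[i : i + m]
            mm_positions = [
                j for j in range(m)
                if window[j] != probe[j] or window[j] == "n"
            ]
            if len(mm_positions) > max_mm:
                continue
            if protect:
                if strand == "+" and any(j >= m - protect for j in mm_positions):
                    continue
                if strand == "-" and any(j < protect for j in mm_positions):
                    continue
            out.add((strand, i, i + m, len(mm_positions)))
    return out


# Unified nearest-neighbor duplex parameters (dH kcal/mol, dS cal/mol/K)
# for the ten unique Watson-Crick stacks, plus terminal initiation terms.
_NN = {
    "aa": (-7.9, -22.2), "at": (-7.2, -20.4), "ta": (-7.2, -21.3),
    "ca": (-8.5, -22.7), "gt": (-8.4, -22.4), "ct": (-7.8, -21.0),
    "ga": (-8.2, -22.2), "cg": (-10.6, -27.2), "gc": (-9.8, -24.4),
    "gg": (-8.0, -19.9),
}
# complete the table via duplex symmetry: XY pairs with rc(XY)
for _k in list(_NN):
    _NN.setdefault(rc(_k), _NN[_k])
_INIT = {"a": (2.3, 4.1), "t": (2.3, 4.1), "g": (0.1, -2.8), "c": (0.1, -2.8)}


def nn_tm(seq: str, Na_mM: float = 50.0, oligo_nM: float = 50.0) -> float:
    """Two-state nearest-neighbor melting temperature, entropy salt correction."""
    s = seq.lower()
    dh, ds = 0.0, 0.0
    for end in (s[0], s[-1]):
        h, sv = _INIT[end]
        dh += h
        ds += sv
    if s == rc(s):
        ds += -1.4
    for i in range(len(s) - 1):
        h, sv = _NN[s[i : i + 2]]
        dh += h
        ds += sv
    ds += 0.368 * (len(s) - 1) * math.log(Na_mM / 1000.0)
    ct = oligo_nM * 1e-9
    if s != rc(s):
        ct = ct  # single excess strand; k = [oligo]
    r = 1.987  # cal/mol/K
    return dh * 1000.0 / (ds + r * math.log(ct)) - 273.15
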