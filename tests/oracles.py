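"""Independent oracles the test suite checks the implementation against.

These deliberately avoid the code paths they validate: the motif oracle
enumerates position tuples exhaustively, the binding oracle solves the
mass-action equilibrium by bisection, and the Welch oracle evaluates the
textbook formulas directly.
"""

from __future__ import annotations

import itertools
import math


def brute_force_scan(sequence: str, anchors, gaps):
    """All anchor-position tuples (1-based) by exhaustive enumeration.

    ``anchors`` is a list of residue-letter sets, ``gaps`` a list of
    (min, max) spacer bounds. O(prod |candidates|) — only for short toys.
    """
    candidate_lists = [
        [i + 1 for i, c in enumerate(sequence) if c in anchor] for anchor in anchors
    ]
    out = []
    for combo in itertools.product(*candidate_lists):
        if any(b <= a for a, b in zip(combo, combo[1:])):
            continue
        ok = True
        for (a, b), (lo, hi) in zip(zip(combo, combo[1:]), gaps):
            if not (lo <= b - a - 1 <= hi):
                ok = False
                break
        if ok:
            out.append(tuple(combo))
    return sorted(out)


def bound_fraction_bisect(Pt: float, La: float, Kd: float, iters: int = 200) -> float:
    """Bound fraction from the mass-action equilibrium by pure bisection.

    Solves (Pt - PL)(La - PL) = Kd * PL for PL in [0, min(Pt, La)].
    """
    def f(PL: float) -> float:
        return (Pt - PL) * (La - PL) - Kd * PL

    lo, hi = 0.0, min(Pt, La)
    if hi == 0.0:
        return 0.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi) / Pt


def welch_from_formulas(a, b):
    """Welch t and Satterthwaite df evaluated from the textbook formulas."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    t = (ma - mb) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    return t, df
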