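"""Cross-species conservation of NMI presence at orthologous promoters.

For a table of pairwise 1:1 orthologues and per-gene NMI-at-TSS booleans,
the conservation score is

    score = n / min(x, y)

where ``n`` counts orthologue pairs with an NMI at both TSSs and ``x``,
``y`` the pairs NMI-positive in each species alone.  Significance is the
hypergeometric upper tail P(X >= n) conditioning on the margins x and y
(one-sided, Fisher-style).  A three-way partition over 1:1:1 orthologues
tallies the eight presence/absence cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import pandas as pd
from scipy import stats


@dataclass
class ConservationResult:
    n: int          # NMI at both TSSs
    x: int          # NMI-positive in species a
    y: int          # NMI-positive in species b
    total: int      # orthologue pairs scored
    dropped: int    # pairs lacking a status entry
    score: float
    p_value: float


def pairwise_conservation(orthologues: pd.DataFrame,
                          status_a: Mapping[str, bool],
                          status_b: Mapping[str, bool]) -> ConservationResult:
    """Score NMI conservation over a two-column 1:1 orthologue table.

    Pairs whose gene id is missing from either status map are dropped and
    counted; the score is defined as 0 when ``min(x, y) == 0``.
    """
    if len(orthologues) == 0:
        raise ValueError("empty orthologue table")
    if orthologues.shape[1] < 2:
        raise ValueError("orthologue table needs >= 2 columns")
    col_a, col_b = orthologues.columns[:2]
    n = x = y = total = dropped = 0
    for ga, gb in zip(orthologues[col_a], orthologues[col_b]):
        if ga not in status_a or gb not in status_b:
            dropped += 1
            continue
        total += 1
        a, b = bool(status_a[ga]), bool(status_b[gb])
        x += a
        y += b
        n += a and b
    score = n / min(x, y) if min(x, y) > 0 else 0.0
    # hypergeometric upper tail: population=total, successes=x, draws=y
    p = float(stats.hypergeom.sf(n - 1, total, x, y)) if total else 1.0
    return ConservationResult(n, x, y, total, dropped, score, p)


def threeway_partition(orthologues: pd.DataFrame,
                       status_a: Mapping[str, bool],
                       status_b: Mapping[str, bool],
                       status_c: Mapping[str, bool]
                       ) -> Dict[Tuple[bool, bool, bool], int]:
    """Counts over the 8 presence/absence cells of a 1:1:1 table
    (mutually exclusive, collectively exhaustive; they sum to the number
    of fully scored triplets)."""
    if orthologues.shape[1] < 3:
        raise ValueError("three-way partition needs a 3-column table")
    ca, cb, cc = orthologues.columns[:3]
    cells: Dict[Tuple[bool, bool, bool], int] = {
        (a, b, c): 0 for a in (False, True) for b in (False, True)
        for c in (False, True)}
    for ga, gb, gc in zip(orthologues[ca], orthologues[cb], orthologues[cc]):
        if ga not in status_a or gb not in status_b or gc not in status_c:
            continue
        cells[(bool(status_a[ga]), bool(status_b[gb]),
               bool(status_c[gc]))] += 1
    return cells
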