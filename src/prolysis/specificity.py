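"""Cleavage-site specificity: amino-acid distributions around scissile bonds.

Windows span five residues on each side of the scissile bond
(P5..P1 | P1'..P5', Schechter-Berger nomenclature).  Positions beyond
the protein termini are padded with '-', which participates in column
normalization as its own category so columns near termini remain
interpretable.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import AMINO_ACIDS, SubstrateProtein
from .cut_frequency import SiteProfile

__all__ = [
    "WINDOW_POSITIONS",
    "extract_window",
    "aa_distribution",
    "consensus",
    "compare_conditions",
]


def window_positions(width: int = 5) -> list[str]:
    """Position labels P<width>..P1, P1'..P<width>'."""
    return [f"P{i}" for i in range(width, 0, -1)] + [
        f"P{i}'" for i in range(1, width + 1)
    ]


WINDOW_POSITIONS = window_positions(5)


def extract_window(p1: int, substrate: SubstrateProtein, width: int = 5) -> str:
    """Residues P<width>..P1,P1'..P<width>' around the bond cut at P1.

    Returned as a string of length 2*width; positions beyond the termini
    are '-'.
    """
    if not 1 <= p1 < substrate.length:
        raise ValueError(f"P1={p1} outside 1..{substrate.length - 1}")
    out = []
    for pos in range(p1 - width + 1, p1 + width + 1):
        if 1 <= pos <= substrate.length:
            out.append(substrate.sequence[pos - 1])
        else:
            out.append("-")
    return "".join(out)


def aa_distribution(
    profiles: Sequence[SiteProfile],
    substrate: SubstrateProtein,
    time_index: int,
    width: int = 5,
    weighting: str = "site",
) -> pd.DataFrame:
    """Percentage of each residue at each window position.

    Considers sites with frequency > 0 at the chosen time point.
    ``weighting="site"`` counts each site once (default);
    ``weighting="frequency"`` weights sites by their relative cut
    frequency at that time point.  Rows are the 20 residues plus the
    terminus padding symbol '-'; every column sums to 100%.
    """
    if weighting not in ("site", "frequency"):
        raise ValueError("weighting must be 'site' or 'frequency'")
    labels = window_positions(width)
    symbols = list(AMINO_ACIDS) + ["-"]
    counts = pd.DataFrame(0.0, index=symbols, columns=labels)
    n_events = 0
    for p in profiles:
        f = float(p.frequencies[time_index])
        if f <= 0:
            continue
        w = f if weighting == "frequency" else 1.0
        n_events += 1
        win = extract_window(p.p1, substrate, width)
        for sym, lab in zip(win, labels):
            counts.loc[sym if sym in counts.index else "-", lab] += w
    total = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = counts.divide(total.where(total > 0), axis=1) * 100.0
    pct = pct.fillna(0.0)
    pct.attrs["n_events"] = n_events
    pct.attrs["weighting"] = weighting
    return pct


def consensus(matrix: pd.DataFrame, floor_percent: float = 10.0) -> pd.DataFrame:
    """Per-position consensus residue of a specificity matrix.

    The argmax residue per position; ties are broken alphabetically and
    flagged; positions whose maximum falls below ``floor_percent`` are
    reported lowercase.
    """
    rows = []
    for lab in matrix.columns:
        col = matrix[lab]
        top = col.max()
        winners = sorted(col.index[col == top])
        sym = winners[0]
        if top < floor_percent:
            sym = sym.lower()
        rows.append(
            {
                "position": lab,
                "consensus": sym,
                "percent": float(top),
                "tie": len(winners) > 1,
            }
        )
    return pd.DataFrame(rows)


def compare_conditions(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-position total-variation distance between two matrices.

    TV = 0.5 * sum |p - q| per position, in percentage points (0..100).
    Also returns the largest single-residue difference per position.
    """
    if list(matrix_a.columns) != list(matrix_b.columns):
        raise ValueError("matrices must cover the same window positions")
    a, b = matrix_a.align(matrix_b, join="outer", fill_value=0.0)
    rows = []
    for lab in a.columns:
        diff = a[lab] - b[lab]
        rows.append(
            {
                "position": lab,
                "tv_distance": float(0.5 * diff.abs().sum()),
                "max_residue_diff": float(diff.abs().max()),
            }
        )
    return pd.DataFrame(rows)
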