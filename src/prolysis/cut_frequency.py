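"""Relative frequency of cuts per P1 site per time point.

The statistic works in two steps.  First, peptides sharing a P1-P1' bond
are grouped (an internal product evidences two bonds: one at its
N-terminal and one at its C-terminal end).  Second, for each peptide the
replicate-average intensity is computed per time point (set to zero when
not significantly above the protease-free control), converted into
ratios referenced to the peptide's first nonzero average, and the
relative frequency of cuts at a P1 site and time point is the sum of the
ratios of all peptides sharing that site.

By default a peptide contributes its ratio to BOTH bounding bonds; a
C-terminal-only mode restricts the contribution to the bond at the
peptide's C-terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import PeptideMeasurement, SubstrateProtein
from .qc_filtering import FilterConfig, timepoint_significance

__all__ = [
    "SiteProfile",
    "average_intensities",
    "intensity_ratios",
    "relative_cut_frequency",
    "classify_sites",
    "cut_histogram",
    "cumulative_site_counts",
    "profiles_to_frame",
    "ANXA1_CLASS_EDGES",
    "MDH_CLASS_EDGES",
]


@dataclass
class SiteProfile:
    """Relative cut frequency of one P1 site across the time course."""

    p1: int
    time_points: np.ndarray
    frequencies: np.ndarray
    peptide_ids: list[str] = field(default_factory=list)

    @property
    def max_frequency(self) -> float:
        return float(np.max(self.frequencies)) if self.frequencies.size else 0.0

    @property
    def onset_time(self) -> float:
        """First time point with frequency > 0 (inf if never)."""
        nz = np.nonzero(self.frequencies > 0)[0]
        return float(self.time_points[nz[0]]) if nz.size else float("inf")


def average_intensities(
    measurement: PeptideMeasurement,
    retained_replicates: Optional[Sequence[int]] = None,
    config: FilterConfig = FilterConfig(),
    significance: Optional[Sequence[bool]] = None,
) -> np.ndarray:
    """Per-time replicate-average intensity of one peptide.

    Non-detections count as measured zeros for the average; the average
    is set to zero at any time point where the digest is not
    significantly enriched over the control (``significance`` overrides
    the built-in Welch test when provided).
    """
    block = measurement.intensities
    if retained_replicates is not None:
        block = block[list(retained_replicates), :]
    filled = np.nan_to_num(block, nan=0.0)
    avgs = filled.mean(axis=0)
    ctrl = measurement.control_intensities
    n_t = avgs.shape[0]
    for j in range(n_t):
        if significance is not None:
            ok = significance[j]
        else:
            ok = timepoint_significance(
                block[:, j],
                None if ctrl is None else ctrl[:, j],
                alpha=config.alpha,
                transform=config.transform,
            )
        if not ok:
            avgs[j] = 0.0
    return avgs


def intensity_ratios(averages: np.ndarray) -> np.ndarray:
    """Ratios referenced to the first nonzero average along the series.

    Zero before the reference point and wherever the average is zero; an
    all-zero series yields all-zero ratios.
    """
    avgs = np.asarray(averages, dtype=float)
    nz = np.nonzero(avgs > 0)[0]
    if nz.size == 0:
        return np.zeros_like(avgs)
    ref_idx = nz[0]
    ratios = np.zeros_like(avgs)
    ratios[ref_idx:] = avgs[ref_idx:] / avgs[ref_idx]
    return ratios


def supported_bonds(
    measurement: PeptideMeasurement,
    substrate_length: int,
    c_terminal_only: bool = False,
) -> list[int]:
    """P1 positions evidenced by one peptide (one or two bounding bonds)."""
    bonds = []
    if not c_terminal_only and measurement.start > 1:
        bonds.append(measurement.start - 1)
    if measurement.end < substrate_length:
        bonds.append(measurement.end)
    return bonds


def relative_cut_frequency(
    measurements: Sequence[PeptideMeasurement],
    substrate: SubstrateProtein,
    time_points: Sequence[float],
    config: FilterConfig = FilterConfig(),
    *,
    retained_replicates: Optional[Sequence[int]] = None,
    c_terminal_only: bool = False,
    ratios_by_peptide: Optional[dict[str, np.ndarray]] = None,
) -> list[SiteProfile]:
    """Compute the per-P1-site relative cut frequency profiles.

    ``ratios_by_peptide`` allows injecting precomputed ratio series
    (e.g. for worked examples); otherwise ratios are derived from the
    measurements via :func:`average_intensities` and
    :func:`intensity_ratios`.  Sites whose profile is all zero are
    omitted.
    """
    tp = np.asarray(time_points, dtype=float)
    acc: dict[int, np.ndarray] = {}
    members: dict[int, list[str]] = {}
    for m in measurements:
        if ratios_by_peptide is not None and m.peptide_id in ratios_by_peptide:
            ratios = np.asarray(ratios_by_peptide[m.peptide_id], float)
        else:
            avgs = average_intensities(m, retained_replicates, config)
            ratios = intensity_ratios(avgs)
        for p1 in supported_bonds(m, substrate.length, c_terminal_only):
            if p1 not in acc:
                acc[p1] = np.zeros(len(tp))
                members[p1] = []
            acc[p1] += ratios
            members[p1].append(m.peptide_id)
    profiles = [
        SiteProfile(p1=p1, time_points=tp, frequencies=freqs, peptide_ids=members[p1])
        for p1, freqs in sorted(acc.items())
        if np.any(freqs > 0)
    ]
    return profiles


#: Class edges (lower bounds of classes 1..3) used for the two study presets.
ANXA1_CLASS_EDGES = (20.0, 11.0, 1.0)
MDH_CLASS_EDGES = (30.0, 21.0, 1.0)


def classify_sites(
    profiles: Sequence[SiteProfile],
    class_edges: Sequence[float] = ANXA1_CLASS_EDGES,
) -> pd.DataFrame:
    """Bin sites into classes by maximum-over-time frequency.

    ``class_edges`` are descending lower bounds: class i (1-based) is
    assigned when max frequency >= edges[i-1]; below the last edge the
    site is "undetected".
    """
    edges = list(class_edges)
    if sorted(edges, reverse=True) != edges:
        raise ValueError("class_edges must be descending lower bounds")
    rows = []
    for p in profiles:
        mf = p.max_frequency
        label = "undetected"
        for i, lo in enumerate(edges, start=1):
            if mf >= lo:
                label = f"class {i}"
                break
        rows.append({"p1": p.p1, "max_frequency": mf, "site_class": label})
    return pd.DataFrame(rows, columns=["p1", "max_frequency", "site_class"])


def cut_histogram(
    profiles: Sequence[SiteProfile],
    time_index: int,
    bin_width: float = 10.0,
) -> pd.DataFrame:
    """Histogram of site frequencies at one time point.

    Bins are [0, w), [w, 2w), ...; sites at exactly zero fall in the
    first bin.
    """
    freqs = np.array([p.frequencies[time_index] for p in profiles])
    if freqs.size == 0:
        return pd.DataFrame(columns=["bin_low", "bin_high", "n_sites"])
    n_bins = int(np.floor(freqs.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(freqs, bins=edges)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "n_sites": counts}
    )


def cumulative_site_counts(profiles: Sequence[SiteProfile]) -> pd.DataFrame:
    """Distinct detected-site count per time point (cumulative).

    A site counts from its onset time onward; the count is non-decreasing
    by construction, mirroring the "Cls" track of fragment overviews.
    """
    if not profiles:
        return pd.DataFrame(columns=["time_s", "n_sites"])
    tp = profiles[0].time_points
    onsets = np.array([p.onset_time for p in profiles])
    counts = [(onsets <= t).sum() for t in tp]
    return pd.DataFrame({"time_s": tp, "n_sites": counts})


def profiles_to_frame(
    profiles: Sequence[SiteProfile],
    substrate: Optional[SubstrateProtein] = None,
    rounded: bool = False,
) -> pd.DataFrame:
    """Site x time frequency matrix (optionally rounded to integers, the
    presentation used in figure-style per-residue tracks)."""
    if not profiles:
        return pd.DataFrame()
    tp = profiles[0].time_points
    data = {f"t{t:g}s": [p.frequencies[j] for p in profiles] for j, t in enumerate(tp)}
    df = pd.DataFrame(data, index=[p.p1 for p in profiles])
    df.index.name = "p1"
    if rounded:
        df = df.round(0).astype(int)
    if substrate is not None:
        df.insert(0, "residue", [substrate.sequence[p - 1] for p in df.index])
        df.insert(1, "native_p1", [substrate.to_native(p) for p in df.index])
    return df
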