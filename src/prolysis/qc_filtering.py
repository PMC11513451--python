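"""Sample QC and peptide-level significance filtering.

Implements the filter stack applied before the cut-frequency statistic:

* replicate QC by mean pairwise Pearson correlation (samples below a
  cutoff are excluded),
* identification-score filtering,
* a homogeneity-of-regression-slopes (ANCOVA interaction) F-test that
  flags peptides whose intensity trend over time differs from the
  protease-free control — the "relevant product" criterion,
* a per-time-point one-sided Welch test against the control, used to
  zero non-significant averages downstream.

Intensities equal to zero are non-detections in label-free MS and are
treated as *missing* for correlations and tests (they are counted as
measured zeros only when averaging, see :mod:`prolysis.cut_frequency`).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("prolysis")

__all__ = [
    "FilterConfig",
    "transform_intensities",
    "replicate_qc",
    "score_filter",
    "slope_homogeneity_test",
    "slope_relevance",
    "timepoint_significance",
]


@dataclass(frozen=True)
class FilterConfig:
    """Filtering thresholds (defaults follow common targeted-proteolysis
    practice: alpha 0.05, minimum identification score 50, replicate
    Pearson cutoff 0.4, log2 intensity transform)."""

    alpha: float = 0.05
    min_score: float = 50.0
    pearson_cutoff: float = 0.4
    transform: str = "log2"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not -1 <= self.pearson_cutoff <= 1:
            raise ValueError("pearson_cutoff must be in [-1, 1]")
        if self.transform not in ("log2", "none"):
            raise ValueError("transform must be 'log2' or 'none'")


def transform_intensities(values: np.ndarray, transform: str = "log2") -> np.ndarray:
    """Transform detected intensities; zeros/NaN become NaN (missing)."""
    v = np.asarray(values, dtype=float).copy()
    v[~(v > 0)] = np.nan
    if transform == "log2":
        with np.errstate(invalid="ignore"):
            v = np.log2(v)
    return v


def replicate_qc(
    sample_matrix: np.ndarray,
    pearson_cutoff: float = 0.4,
    transform: str = "log2",
    sample_names: Optional[Sequence[str]] = None,
) -> list[int]:
    """Retain samples whose mean pairwise Pearson r reaches the cutoff.

    ``sample_matrix`` is (n_samples, n_peptides); correlations are
    computed on jointly detected, transformed intensities.  If exclusion
    would leave fewer than two samples, the best pair is kept with a
    warning.
    Returns the retained sample indices (sorted).
    """
    x = transform_intensities(sample_matrix, transform)
    n = x.shape[0]
    if n < 2:
        raise ValueError("replicate QC needs at least 2 samples")
    if sample_names is None:
        sample_names = [f"sample{i}" for i in range(n)]
    corr = np.full((n, n), np.nan)
    for i, j in itertools.combinations(range(n), 2):
        joint = np.isfinite(x[i]) & np.isfinite(x[j])
        if joint.sum() >= 3 and np.std(x[i, joint]) > 0 and np.std(x[j, joint]) > 0:
            r = float(np.corrcoef(x[i, joint], x[j, joint])[0, 1])
        elif joint.sum() >= 3 and np.array_equal(x[i, joint], x[j, joint]):
            r = 1.0  # identical constant replicates
        else:
            r = np.nan
        corr[i, j] = corr[j, i] = r
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean_r = np.nanmean(corr, axis=1)
    # undefined correlations (too few joint detections) are no evidence
    # against a sample: retain it
    mean_r = np.where(np.isnan(mean_r), 1.0, mean_r)
    retained = [i for i in range(n) if mean_r[i] >= pearson_cutoff]
    removed = [i for i in range(n) if i not in retained]
    if len(retained) < 2:
        best = sorted(np.argsort(mean_r)[-2:])
        logger.warning(
            "replicate QC would leave <2 samples (all mean r < %.2f); "
            "keeping best pair %s",
            pearson_cutoff,
            [sample_names[i] for i in best],
        )
        return [int(i) for i in best]
    for i in removed:
        logger.warning(
            "sample %s removed by replicate QC (mean r = %.3f < %.2f)",
            sample_names[i], mean_r[i], pearson_cutoff,
        )
    return retained


def score_filter(peptides: Sequence, min_score: float = 50.0) -> list:
    """Keep peptides whose identification score is >= min_score."""
    return [p for p in peptides if p.score >= min_score]


def slope_homogeneity_test(
    time_points: Sequence[float],
    digest: np.ndarray,
    control: np.ndarray,
    transform: str = "log2",
) -> float:
    """Homogeneity-of-regression-slopes (ANCOVA interaction) F-test.

    Fits transformed intensity ~ time * group over the pooled digest and
    control observations (replicate x time blocks) and returns the
    p-value of the slope-difference F-test with (1, n - 4) degrees of
    freedom.  Returns NaN when the design is rank-deficient (fewer than
    two distinct time points with observations in either group, or
    fewer than five observations overall).
    """
    tp = np.asarray(time_points, dtype=float)
    rows = []
    for g, block in ((0.0, control), (1.0, digest)):
        b = transform_intensities(np.atleast_2d(block), transform)
        for rep in b:
            for t, y in zip(tp, rep):
                if np.isfinite(y):
                    rows.append((t, g, y))
    if not rows:
        return float("nan")
    t, g, y = map(np.asarray, zip(*rows))
    n = len(y)
    for grp in (0.0, 1.0):
        if len(np.unique(t[g == grp])) < 2:
            return float("nan")
    if n < 5:
        return float("nan")
    X_full = np.column_stack([np.ones(n), t, g, t * g])
    X_red = X_full[:, :3]
    rss_full = _rss(X_full, y)
    rss_red = _rss(X_red, y)
    df_resid = n - 4
    if df_resid <= 0 or rss_full <= 0:
        # saturated or perfect fit: any slope difference is exact
        return 0.0 if rss_red > rss_full else 1.0
    f_stat = (rss_red - rss_full) / (rss_full / df_resid)
    return float(stats.f.sf(f_stat, 1, df_resid))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def slope_relevance(
    time_points: Sequence[float],
    digest: np.ndarray,
    control: np.ndarray,
    alpha: float = 0.05,
    transform: str = "log2",
) -> tuple[bool, float]:
    """Decide whether a peptide is a relevant proteolytic product.

    Relevant iff the slope-homogeneity p-value is < alpha.  When the
    control block carries fewer than two detections the test is
    undefined; the peptide is then called relevant iff it was detected at
    all in the digest (enrichment over a silent control), with p = NaN.
    """
    ctrl = transform_intensities(np.atleast_2d(control), transform)
    if np.isfinite(ctrl).sum() < 2:
        detected = np.nansum(np.atleast_2d(digest)) > 0
        return bool(detected), float("nan")
    p = slope_homogeneity_test(time_points, digest, control, transform)
    if np.isnan(p):
        return False, p
    return bool(p < alpha), p


def timepoint_significance(
    digest_values: np.ndarray,
    control_values: Optional[np.ndarray],
    alpha: float = 0.05,
    transform: str = "log2",
) -> bool:
    """One-sided Welch test: is the digest enriched over the control?

    Operates on transformed detected intensities at one time point.
    Rules for degenerate designs: no digest detection -> False; a silent
    control (fewer than 2 detections) -> True iff anything was detected
    in the digest; a single digest detection against a measured control
    -> False (insufficient evidence); two constant groups -> compare
    means directly.
    """
    d = transform_intensities(np.asarray(digest_values, float), transform)
    d = d[np.isfinite(d)]
    if d.size == 0:
        return False
    if alpha >= 1:
        return True  # limit behaviour: any detection counts
    if control_values is None:
        return True  # degraded mode: no controls measured
    c = transform_intensities(np.asarray(control_values, float), transform)
    c = c[np.isfinite(c)]
    if c.size < 2:
        return True
    if d.size < 2:
        return False
    if np.ptp(d) == 0 and np.ptp(c) == 0:
        return bool(d.mean() > c.mean())
    res = stats.ttest_ind(d, c, equal_var=False, alternative="greater")
    return bool(res.pvalue < alpha)
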