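"""Region-level attention scores and correlation with autopsy pathology.

The AD-specific attention map of a trained model is summarized per
parcellation region as the **sum of voxel attention divided by the region's
voxel count** (aggregation normalized by regional volume), then correlated
across subjects with semi-quantitative histopathology grades — amyloid-beta
deposits, neurofibrillary tangles (NFT) and neuritic plaques (NP), each
scored 0 (none) to 3 (severe) per region. Correlations use Spearman's rank
coefficient with average ranks for ties and a two-sided t-approximation
p-value on n - 2 degrees of freedom; p-values are deliberately left
unadjusted for multiple comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .priors import resample_grid
from .synth import Parcellation, STAINS

__all__ = ["RegionScore", "SpearmanResult", "region_scores", "region_score_table",
           "spearman", "spearman_exact_p", "correlation_table", "permutation_null_rates"]

_AD_CHANNEL = 2  #: class index of AD in the NC/MCI/AD ordering


@dataclass(frozen=True)
class RegionScore:
    region_id: int
    attention_sum: float
    voxel_count: int

    @property
    def score(self) -> float:
        return self.attention_sum / self.voxel_count


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.undefined_reason is None


def region_scores(attention_channel: np.ndarray, parcellation: Parcellation) -> list[RegionScore]:
    """Volume-normalized attention per region (background label 0 excluded).

    The attention channel is resampled trilinearly to the parcellation grid
    if the shapes differ (attention typically lives at feature resolution).
    """
    att = np.asarray(attention_channel, dtype=np.float64)
    if att.shape != parcellation.shape:
        att = resample_grid(att, parcellation.shape)
    labels = parcellation.labels.ravel()
    R = parcellation.n_regions
    sums = np.bincount(labels, weights=att.ravel(), minlength=R + 1)
    counts = np.bincount(labels, minlength=R + 1)
    out = []
    for r in parcellation.region_ids():
        if counts[r] == 0:
            raise ValueError(f"region {r} is empty")
        out.append(RegionScore(r, float(sums[r]), int(counts[r])))
    return out


def region_score_table(attention_by_subject: dict[str, np.ndarray],
                       parcellation: Parcellation) -> pd.DataFrame:
    """Tidy (subject_id, region_id, score) table over a set of subjects."""
    rows = []
    for sid, att in attention_by_subject.items():
        for rs in region_scores(att, parcellation):
            rows.append({"subject_id": sid, "region_id": rs.region_id, "score": rs.score})
    return pd.DataFrame(rows, columns=["subject_id", "region_id", "score"])


def attention_mass_fraction(attention_channel: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of total attention mass falling inside a voxel mask.

    The mask (e.g. the ground-truth disease map) is resampled to the
    attention grid if shapes differ. Scale-invariant: doubling the whole
    attention map leaves the fraction unchanged.
    """
    att = np.asarray(attention_channel, dtype=np.float64)
    m = np.asarray(mask, dtype=np.float64)
    if m.shape != att.shape:
        m = resample_grid(m, att.shape)
    inside = float((att * (m > 0.5)).sum())
    total = float(att.sum())
    if total == 0.0:
        return 0.0
    return inside / total


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Ties receive average ranks. With fewer than 3 pairs, or zero variance in
    either vector, the coefficient is undefined and returned as an explicit
    not-a-value with the reason recorded.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    n = x.size
    if n < 3:
        return SpearmanResult(math.nan, math.nan, n, "fewer than 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return SpearmanResult(math.nan, math.nan, n, "zero variance")
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), n)


def spearman_exact_p(x, y) -> float:
    """Exact two-sided permutation p-value for the Spearman coefficient.

    Enumerates all n! orderings of y; limited to n <= 10. Intended as a
    small-sample cross-check of the t-approximation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    if n > 10:
        raise ValueError("exact permutation p limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def correlation_table(scores: pd.DataFrame, grades: pd.DataFrame,
                      stains: tuple[str, ...] = STAINS) -> pd.DataFrame:
    """One Spearman cell per (region, stain) across shared subjects.

    ``scores`` has columns (subject_id, region_id, score); ``grades`` has
    (subject_id, region_id, stain, grade). A cell with fewer than 3 shared
    subjects, or degenerate variance, is kept in the table and marked
    missing (rho/p = NaN with a reason) rather than dropped.

    Returns a tidy DataFrame: region_id, stain, rho, p, n, missing_reason.
    """
    required = {"subject_id", "region_id", "score"}
    if not required <= set(scores.columns):
        raise ValueError(f"scores table must have columns {sorted(required)}")
    rows = []
    for region_id in sorted(grades["region_id"].unique()):
        sc = scores[scores["region_id"] == region_id].set_index("subject_id")["score"]
        for stain in stains:
            gr = grades[(grades["region_id"] == region_id) & (grades["stain"] == stain)]
            gr = gr.set_index("subject_id")["grade"]
            shared = sc.index.intersection(gr.index)
            if len(shared) < 3:
                rows.append({"region_id": region_id, "stain": stain, "rho": math.nan,
                             "p": math.nan, "n": len(shared),
                             "missing_reason": "fewer than 3 shared subjects"})
                continue
            res = spearman(sc.loc[shared].to_numpy(), gr.loc[shared].to_numpy(dtype=float))
            rows.append({"region_id": region_id, "stain": stain, "rho": res.rho,
                         "p": res.p, "n": res.n, "missing_reason": res.undefined_reason})
    return pd.DataFrame(rows, columns=["region_id", "stain", "rho", "p", "n", "missing_reason"])


def permutation_null_rates(x, y, n_permutations: int = 1000, seed: int = 0,
                           alpha: float = 0.05) -> dict[str, float]:
    """Calibration of the t-approximation under a permuted-grade null.

    Permutes ``y`` relative to ``x`` ``n_permutations`` times and reports
    the mean permuted coefficient and the fraction of permutations rejected
    at the two-sided ``alpha`` level — which should sit near ``alpha`` if
    the p-values are well calibrated.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    rng = np.random.default_rng(seed)
    rhos = np.empty(n_permutations)
    rejections = 0
    for i in range(n_permutations):
        res = spearman(x, rng.permutation(y))
        rhos[i] = res.rho if res.defined else 0.0
        if res.defined and res.p < alpha:
            rejections += 1
    return {"mean_rho": float(np.nanmean(rhos)),
            "rejection_rate": rejections / n_permutations}
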