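"""Local background estimation/subtraction and variance-stabilizing normalization.

Background is computed independently per (array, chromosome) block on
position-sorted probes: for each probe, the nearest-rank 5th percentile of the
window holding the probe and up to 500 probes on each side (1001 values in the
interior, truncated at chromosome ends), then smoothed along the chromosome by
tricube-weighted local linear regression (a single lowess pass) and subtracted.
Negative background-subtracted intensities are kept — the generalized-log
transform downstream is defined on all reals.

Normalization maps each array j through h_j(x) = arsinh((x - a_j) / b_j).
The reference transform's offset/scale are estimated from the pooled sd-vs-mean
relation of the data (robust Theil-Sen line), which is what makes arsinh
variance-stabilizing when sd grows linearly with mean; every other array's
(a_j, b_j) are then calibrated so its transformed median and MAD equal the
reference array's. Because arsinh is monotone the median constraint is exact
and the calibration reduces to a one-dimensional root find in b.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.nonparametric.smoothers_lowess import lowess


def local_background(values: np.ndarray, half_window: int = 500,
                     percentile: float = 5.0) -> np.ndarray:
    """Windowed nearest-rank low-percentile background for one array/chromosome.

    For probe i the window is ``values[max(0, i-half_window) : i+half_window+1]``
    (position-sorted input required); the background is the value at rank
    ``ceil(percentile/100 * m)`` of the sorted window of m values.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("empty chromosome block")
    out = np.empty(n)
    w = half_window
    full = 2 * w + 1

    def rank_index(m: int) -> int:
        return max(math.ceil(percentile / 100.0 * m) - 1, 0)

    if n >= full:
        k = rank_index(full)
        windows = np.lib.stride_tricks.sliding_window_view(values, full)
        out[w:n - w] = np.partition(windows, k, axis=1)[:, k]
    # truncated edges (and the whole vector when n < full)
    for i in range(min(w, n)):
        window = values[: i + w + 1]
        out[i] = np.partition(window, rank_index(len(window)))[rank_index(len(window))]
    for i in range(max(n - w, min(w, n)), n):
        window = values[i - w:]
        out[i] = np.partition(window, rank_index(len(window)))[rank_index(len(window))]
    return out


def smooth_background(positions: np.ndarray, raw_background: np.ndarray,
                      span: float = 0.3) -> np.ndarray:
    """Smooth the raw background along the chromosome with local linear
    regression (tricube weights, single pass).

    With fewer than 3 probes the raw background is returned unchanged.
    """
    positions = np.asarray(positions, dtype=float)
    raw_background = np.asarray(raw_background, dtype=float)
    if len(positions) != len(raw_background):
        raise ValueError("positions and background differ in length")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if len(positions) < 3:
        return raw_background.copy()
    delta = 0.002 * (positions.max() - positions.min())
    smoothed = lowess(raw_background, positions, frac=span, it=0, delta=delta,
                      return_sorted=False)
    return np.asarray(smoothed, dtype=float)


def subtract_background(values: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Elementwise subtraction; negative results are preserved."""
    values = np.asarray(values, dtype=float)
    background = np.asarray(background, dtype=float)
    if values.shape != background.shape:
        raise ValueError("values and background differ in shape")
    return values - background


def background_correct(intensities: pd.DataFrame, probes: pd.DataFrame,
                       half_window: int = 500, percentile: float = 5.0,
                       span: float = 0.3) -> pd.DataFrame:
    """Background-subtract a probes x arrays matrix per (array, chromosome).

    ``probes`` supplies ``probe_id, chrom, start``; row order of the output
    matches the input matrix.
    """
    meta = probes.set_index("probe_id").loc[intensities.index]
    out = intensities.copy().astype(float)
    for chrom in meta["chrom"].unique():
        mask = (meta["chrom"] == chrom).to_numpy()
        order = np.argsort(meta.loc[mask, "start"].to_numpy(), kind="stable")
        pos = meta.loc[mask, "start"].to_numpy(dtype=float)[order]
        block_idx = np.where(mask)[0][order]
        for col in intensities.columns:
            vals = intensities.iloc[block_idx][col].to_numpy(dtype=float)
            raw_bg = local_background(vals, half_window, percentile)
            smooth = smooth_background(pos, raw_bg, span)
            out.iloc[block_idx, out.columns.get_loc(col)] = vals - smooth
    return out


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def _reference_params(matrix: np.ndarray) -> Tuple[float, float]:
    """Offset/scale of the reference arsinh transform from the sd-vs-mean line.

    Fits sd_i ~ c0 + c1 * mean_i over probes (Theil-Sen, subsampled); the
    stabilizing transform for sd(x) = c1*(x + c0/c1) is arsinh about
    a = -c0/c1 with scale b = c0/c1. Falls back to median/MAD standardization
    when the fit is degenerate (non-positive slope or intercept).
    """
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=1)
    scale = _mad(matrix[:, 0])
    if scale == 0:
        raise ValueError("degenerate array: zero MAD")
    idx = np.arange(len(means))
    if len(idx) > 5000:
        idx = idx[:: len(idx) // 5000 + 1]
    slope, intercept, *_ = stats.theilslopes(sds[idx], means[idx])
    if slope > 0 and intercept > 0:
        b = max(intercept / slope, 1e-3 * scale)
        return -b, b
    return float(np.median(matrix[:, 0])), scale


def _calibrate_column(x: np.ndarray, ref_median: float, ref_mad: float,
                      b_init: float) -> Tuple[float, float]:
    """Solve for (a, b) so that arsinh((x-a)/b) has the reference median/MAD.

    The median constraint pins a = median(x) - b*sinh(ref_median); the MAD
    constraint is solved for b by bisection on the log scale.
    """
    med_x = float(np.median(x))
    c1 = math.sinh(ref_median)

    def mad_gap(log_b: float) -> float:
        b = math.exp(log_b)
        a = med_x - b * c1
        return _mad(np.arcsinh((x - a) / b)) - ref_mad

    lo, hi = math.log(b_init) - 20, math.log(b_init) + 20
    flo, fhi = mad_gap(lo), mad_gap(hi)
    if flo * fhi > 0:
        raise ValueError("VSN calibration failed to bracket a scale")
    log_b = optimize.brentq(mad_gap, lo, hi, xtol=1e-12)
    b = math.exp(log_b)
    return med_x - b * c1, b


def vsn_normalize(intensities: pd.DataFrame,
                  params_out: Optional[dict] = None) -> pd.DataFrame:
    """Variance-stabilizing normalization across arrays.

    Each array is mapped through arsinh((x - a_j)/b_j) with the per-array
    offset and scale calibrated so every transformed column shares the
    reference (first) array's median and MAD. Requires >= 2 arrays; raises on
    arrays with zero MAD. ``params_out``, when given, is filled with the
    fitted (a_j, b_j) per array.
    """
    if intensities.shape[1] < 2:
        raise ValueError("need >= 2 arrays for normalization")
    mat = intensities.to_numpy(dtype=float)
    for j, col in enumerate(intensities.columns):
        if _mad(mat[:, j]) == 0:
            raise ValueError(f"degenerate array {col}: zero MAD")
    a0, b0 = _reference_params(mat)
    href = np.arcsinh((mat[:, 0] - a0) / b0)
    ref_median, ref_mad = float(np.median(href)), _mad(href)
    if ref_mad == 0:
        raise ValueError("degenerate reference array: zero MAD after transform")
    out = {}
    for j, col in enumerate(intensities.columns):
        a, b = _calibrate_column(mat[:, j], ref_median, ref_mad, b0)
        out[col] = np.arcsinh((mat[:, j] - a) / b)
        if params_out is not None:
            params_out[col] = (a, b)
    return pd.DataFrame(out, index=intensities.index)


def preprocess(intensities: pd.DataFrame, probes: pd.DataFrame,
               half_window: int = 500, percentile: float = 5.0,
               span: float = 0.3) -> pd.DataFrame:
    """Full preprocessing: background subtraction then VSN, in that order."""
    corrected = background_correct(intensities, probes, half_window, percentile, span)
    return vsn_normalize(corrected)
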