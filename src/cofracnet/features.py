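"""Pairwise co-elution features for co-complex classification.

For every unordered protein pair, six features summarize how similarly
the two proteins elute in one replicate of one channel:

- ``r_raw``: Pearson correlation of the raw chromatograms;
- ``p_r``: its two-tailed p-value (t-transform);
- ``d_raw``: Euclidean distance between the raw chromatograms;
- ``r_smooth``: Pearson correlation of the smoothed chromatograms;
- ``delta_peak``: fractions separating the two chromatogram maxima;
- ``d_gauss``: smallest Euclidean distance between fitted Gaussian
  components, in (center, amplitude) coordinates.

Everything is computed over pairwise-complete fractions and needs at
least three of them, otherwise the feature is missing.  Features from
all replicates of one channel are concatenated column-wise (six features
x three replicates = eighteen classifier inputs per channel).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .matrix import ChromatogramMatrix
from .modern import MIN_OVERLAP, _masked_parts, _pearson_from_sums
from .preprocess import GaussianMixtureFit

FEATURE_NAMES = ("r_raw", "p_r", "d_raw", "r_smooth", "delta_peak", "d_gauss")


def _pairwise_pearson(matrix: ChromatogramMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(r, n) for all protein pairs, pairwise-complete; NaN where < 3 points."""
    a, m = _masked_parts(matrix)
    n = m @ m.T
    sx = a @ m.T        # row i, col j: sum of x_i over fractions common to (i, j)
    sxx = (a**2) @ m.T
    sxy = a @ a.T
    r = _pearson_from_sums(n, sx, sx.T, sxx, sxx.T, sxy)
    return r, n


def _pearson_pvalue(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-tailed p from t = r sqrt((n-2)/(1-r^2))."""
    with np.errstate(invalid="ignore", divide="ignore"):
        df = n - 2
        t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * t_dist.sf(np.abs(t), np.maximum(df, 1))
    p = np.where(np.isfinite(r) & (np.abs(r) >= 1.0), 0.0, p)
    p = np.where(np.isfinite(r), p, np.nan)
    return np.where(df >= 1, p, np.nan)


def _pairwise_euclidean(matrix: ChromatogramMatrix) -> np.ndarray:
    a, m = _masked_parts(matrix)
    n = m @ m.T
    sxx = (a**2) @ m.T
    sxy = a @ a.T
    with np.errstate(invalid="ignore"):
        d2 = sxx + sxx.T - 2.0 * sxy
        d = np.sqrt(np.clip(d2, 0.0, None))
    return np.where(n >= MIN_OVERLAP, d, np.nan)


def _peak_locations(matrix: ChromatogramMatrix) -> np.ndarray:
    """1-based argmax of each raw profile; ties break to the lowest fraction."""
    values = matrix.values
    out = np.full(len(values), np.nan)
    for i, row in enumerate(values):
        if np.isfinite(row).any():
            out[i] = np.nanargmax(row) + 1
    return out


def _gaussian_min_distance(
    proteins: list[str], fits: dict[str, GaussianMixtureFit], max_components: int = 5
) -> np.ndarray:
    """Min over component pairs of Euclidean distance in (center, amplitude)."""
    n = len(proteins)
    mu = np.full((n, max_components), np.nan)
    amp = np.full((n, max_components), np.nan)
    for i, p in enumerate(proteins):
        fit = fits.get(p)
        if fit is None:
            continue
        for k, comp in enumerate(fit.components[:max_components]):
            mu[i, k] = comp.center
            amp[i, k] = comp.amplitude
    dmu = mu[:, None, :, None] - mu[None, :, None, :]
    damp = amp[:, None, :, None] - amp[None, :, None, :]
    with np.errstate(invalid="ignore"):
        dist = np.sqrt(dmu**2 + damp**2)
        out = np.full((n, n), np.nan)
        flat = dist.reshape(n, n, -1)
        any_finite = np.isfinite(flat).any(axis=2)
        out[any_finite] = np.nanmin(flat[any_finite], axis=-1)
    return out


def compute_pair_features(
    raw: ChromatogramMatrix,
    smoothed: ChromatogramMatrix,
    fits: dict[str, GaussianMixtureFit],
) -> pd.DataFrame:
    """Six-feature table for one replicate/channel.

    Index: MultiIndex of sorted (protein_a, protein_b) pairs; missing
    features stay NaN and propagate to the classifier, which skips them.
    """
    if list(raw.proteins) != list(smoothed.proteins):
        raise ValueError("raw and smoothed matrices must share the protein set")
    proteins = raw.proteins
    r_raw, n_raw = _pairwise_pearson(raw)
    p_r = _pearson_pvalue(r_raw, n_raw)
    d_raw = _pairwise_euclidean(raw)
    r_smooth, _ = _pairwise_pearson(smoothed)
    peaks = _peak_locations(raw)
    delta_peak = np.abs(peaks[:, None] - peaks[None, :])
    d_gauss = _gaussian_min_distance(proteins, fits)

    ii, jj = np.triu_indices(len(proteins), k=1)
    pa = np.asarray(proteins)[ii]
    pb = np.asarray(proteins)[jj]
    swap = pa > pb  # canonical lexicographic pair order, stable across replicates
    pa, pb = np.where(swap, pb, pa), np.where(swap, pa, pb)
    index = pd.MultiIndex.from_arrays([pa, pb], names=["protein_a", "protein_b"])
    return pd.DataFrame(
        {
            "r_raw": r_raw[ii, jj],
            "p_r": p_r[ii, jj],
            "d_raw": d_raw[ii, jj],
            "r_smooth": r_smooth[ii, jj],
            "delta_peak": delta_peak[ii, jj],
            "d_gauss": d_gauss[ii, jj],
        },
        index=index,
    )


def assemble_feature_table(per_replicate: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-replicate feature frames column-wise on the pair union.

    Columns are renamed ``rep{r}_{feature}``; pairs absent from a
    replicate get NaN features there.
    """
    frames = []
    for rep, frame in sorted(per_replicate.items()):
        frames.append(frame.rename(columns={c: f"rep{rep}_{c}" for c in frame.columns}))
    out = pd.concat(frames, axis=1, join="outer")
    out.index.names = ["protein_a", "protein_b"]
    return out


def pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.reset_index().to_csv(path, sep="\t", index=False, na_rep="")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(["protein_a", "protein_b"])


def all_pairs(proteins: list[str]):
    return itertools.combinations(sorted(proteins), 2)
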