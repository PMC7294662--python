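"""MODERN: single-point quantitation-error detection for chromatograms.

A SILAC ratio mis-quantified in one fraction can globally rewire a
protein's apparent correlations with every other protein.  MODERN
exploits this: the *interaction profile* of a protein is its vector of
Pearson correlations to all other proteins; removing each observed
chromatogram point in turn and correlating the recomputed profile with
the original one yields a per-point *autocorrelation*.  Genuine points
barely move the profile (autocorrelation near 1); a high-magnitude error
drags it down.  Autocorrelations are Fisher-transformed and
standardized to z-scores (robustly within each protein by default, or
pooled over the whole matrix) and points are flagged when z falls below
the lower-tail normal quantile at ``(fwer / 2) / N``, a
Bonferroni-style two-tailed family-wise error rate of ``fwer`` over the
``N`` observed points.

All Pearson correlations use pairwise-complete fractions and require at
least ``MIN_OVERLAP`` of them; quantities below that support are treated
as missing, never as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .matrix import ChromatogramMatrix

MIN_OVERLAP = 3


@dataclass(frozen=True)
class OutlierReport:
    """Per-point autocorrelations, z-scores, and the flagged set.

    ``flagged`` holds (protein, fraction) with 1-based fractions;
    ``autocorrelations`` and ``z_scores`` are proteins x fractions frames
    (NaN where unobserved or undefined); ``z_crit`` is the flagging
    threshold and ``n_points`` the number of observed points defining the
    family.
    """

    flagged: frozenset
    autocorrelations: pd.DataFrame
    z_scores: pd.DataFrame
    z_crit: float
    n_points: int


def _masked_parts(matrix: ChromatogramMatrix):
    x = matrix.values
    mask = np.isfinite(x)
    a = np.where(mask, x, 0.0)
    return a, mask.astype(float)


def _pearson_from_sums(n, sx, sy, sxx, syy, sxy):
    """Pearson r from accumulated sums; NaN where undefined (< MIN_OVERLAP
    points or zero variance)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        denom = np.sqrt(vx * vy)
        r = cov / denom
    bad = (n < MIN_OVERLAP) | (vx <= 0) | (vy <= 0)
    return np.where(bad, np.nan, np.clip(r, -1.0, 1.0))


def interaction_profile(
    matrix: ChromatogramMatrix,
    protein: str,
    exclude_fraction: int | None = None,
) -> pd.Series:
    """Correlations of ``protein`` to every other protein (pairwise-complete).

    ``exclude_fraction`` (1-based) drops that fraction from both profiles
    of every pair before correlating.  Entries supported by fewer than
    three overlapping observations are NaN.
    """
    a, m = _masked_parts(matrix)
    idx = matrix.proteins.index(protein)
    if exclude_fraction is not None:
        a = a.copy()
        m = m.copy()
        a[:, exclude_fraction - 1] = 0.0
        m[:, exclude_fraction - 1] = 0.0
    a_i, m_i = a[idx], m[idx]
    n = m @ m_i
    sx = m @ a_i
    sy = a @ m_i
    sxx = m @ (a_i**2)
    syy = (a**2) @ m_i
    sxy = a @ a_i
    r = _pearson_from_sums(n, sx, sy, sxx, syy, sxy)
    others = [p for p in matrix.proteins if p != protein]
    keep = np.array([i for i in range(len(matrix.proteins)) if i != idx])
    return pd.Series(r[keep], index=others, name=protein)


def leave_one_out_autocorrelation(
    matrix: ChromatogramMatrix, protein: str, fraction: int
) -> float | None:
    """Correlation between the interaction profile with and without one point.

    Returns None (undefined) when fewer than three profile entries are
    defined in both versions; such points are exempt from flagging.
    """
    base = interaction_profile(matrix, protein).to_numpy()
    loo = interaction_profile(matrix, protein, exclude_fraction=fraction).to_numpy()
    ok = np.isfinite(base) & np.isfinite(loo)
    if ok.sum() < MIN_OVERLAP:
        return None
    b, l = base[ok], loo[ok]
    if np.array_equal(b, l):
        return 1.0  # removal left the interaction profile unchanged
    if b.std() == 0 or l.std() == 0:
        return None
    return float(np.corrcoef(b, l)[0, 1])


def _autocorrelation_matrix(matrix: ChromatogramMatrix) -> np.ndarray:
    """All leave-one-out autocorrelations, vectorized per protein.

    For each protein the pairwise Pearson sums over all partners are
    accumulated once and then down-dated by each fraction's contribution,
    giving every leave-one-out interaction profile in O(fractions x
    proteins) per protein.
    """
    a, m = _masked_parts(matrix)
    n_prot, n_frac = a.shape
    out = np.full((n_prot, n_frac), np.nan)
    a2 = a**2
    for i in range(n_prot):
        a_i, m_i = a[i], m[i]
        obs_i = m_i > 0
        if obs_i.sum() == 0:
            continue
        n = m @ m_i
        sx = m @ a_i
        sy = a @ m_i
        sxx = m @ (a_i**2)
        syy = a2 @ m_i
        sxy = a @ a_i
        base = _pearson_from_sums(n, sx, sy, sxx, syy, sxy)
        base[i] = np.nan  # self-correlation excluded from the profile

        # down-date every pair sum by each fraction's contribution
        mt = m.T  # fractions x proteins
        at = a.T
        n_l = n[None, :] - m_i[:, None] * mt
        sx_l = sx[None, :] - a_i[:, None] * mt
        sy_l = sy[None, :] - m_i[:, None] * at
        sxx_l = sxx[None, :] - (a_i**2)[:, None] * mt
        syy_l = syy[None, :] - m_i[:, None] * a2.T
        sxy_l = sxy[None, :] - a_i[:, None] * at
        loo = _pearson_from_sums(n_l, sx_l, sy_l, sxx_l, syy_l, sxy_l)
        loo[:, i] = np.nan

        valid = np.isfinite(base)[None, :] & np.isfinite(loo)
        cnt = valid.sum(axis=1)
        b = np.where(valid, base[None, :], 0.0)
        l = np.where(valid, loo, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sb, sl = b.sum(axis=1), l.sum(axis=1)
            r = _pearson_from_sums(
                cnt, sb, sl, (b**2).sum(axis=1), (l**2).sum(axis=1),
                (b * l).sum(axis=1),
            )
        # removal that leaves every defined profile entry unchanged is a
        # perfect autocorrelation even when the entries are constant
        unchanged = (np.abs(b - l).max(axis=1) == 0) & (cnt >= MIN_OVERLAP)
        r[unchanged] = 1.0
        r[~obs_i] = np.nan
        r[cnt < MIN_OVERLAP] = np.nan
        out[i] = r
    return out


def detect_outliers(
    matrix: ChromatogramMatrix, fwer: float = 0.05, standardize: str = "protein"
) -> OutlierReport:
    """Flag observed points whose removal maximally rewires the profile.

    Single pass.  Autocorrelations are Fisher-transformed (``atanh``),
    which symmetrizes their one-inflated distribution, then standardized
    to z-scores; a point is flagged when its z falls below the normal
    quantile at ``(fwer / 2) / N``, where ``N`` counts all observed
    points, giving a two-tailed family-wise error rate of ``fwer`` under
    an exchangeable null.

    ``standardize="protein"`` (default) centers and scales each
    protein's transformed autocorrelations by their median and MAD, so a
    genuine single-point error — which a robust scale cannot absorb —
    stands out against that protein's own removal sensitivity.
    ``standardize="pooled"`` uses the mean and standard deviation of the
    pooled values of the whole matrix instead.
    """
    if standardize not in ("protein", "pooled"):
        raise ValueError("standardize must be 'protein' or 'pooled'")
    ac = _autocorrelation_matrix(matrix)
    n_points = matrix.n_observed
    index, columns = matrix.data.index, matrix.data.columns
    ac_df = pd.DataFrame(ac, index=index, columns=columns)

    w = np.arctanh(np.clip(ac, -1.0 + 1e-15, 1.0 - 1e-15))
    vals = w[np.isfinite(w)]
    z = np.full_like(ac, np.nan)
    z_crit = float(norm.ppf((fwer / 2.0) / max(n_points, 1)))
    flagged: set[tuple[str, int]] = set()
    if vals.size == 0 or vals.std() == 0:
        if vals.size:
            warnings.warn(
                "degenerate autocorrelation distribution (zero spread); "
                "no points flagged",
                stacklevel=2,
            )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if standardize == "protein":
                center = np.nanmedian(w, axis=1, keepdims=True)
                scale = 1.4826 * np.nanmedian(
                    np.abs(w - center), axis=1, keepdims=True
                )
                scale[scale == 0] = np.nan  # degenerate protein: exempt
            else:
                center, scale = vals.mean(), vals.std()
            z = (w - center) / scale
        for i, j in np.argwhere(z < z_crit):
            flagged.add((str(index[i]), int(j) + 1))
    z_df = pd.DataFrame(z, index=index, columns=columns)
    return OutlierReport(frozenset(flagged), ac_df, z_df, z_crit, n_points)


def remove_outliers(
    matrix: ChromatogramMatrix, report: OutlierReport
) -> ChromatogramMatrix:
    """Blank every flagged point; all other values are untouched."""
    values = matrix.values.copy()
    pos = {p: i for i, p in enumerate(matrix.proteins)}
    for protein, fraction in report.flagged:
        values[pos[protein], fraction - 1] = np.nan
    return matrix.with_values(values)
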