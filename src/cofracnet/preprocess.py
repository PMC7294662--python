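"""Chromatogram cleaning, smoothing, and Gaussian mixture deconvolution.

The cleaning rules follow the standard co-fractionation recipe: single
missing values flanked by two observed neighbors are imputed as their
mean; proteins quantified in fewer than five fractions are dropped; a
centered sliding average of width five smooths each profile.  Each
smoothed chromatogram is then deconvolved into a mixture of one to five
Gaussian elution peaks by nonlinear least squares, with the number of
components chosen by the bias-corrected Akaike information criterion
(AICc); chromatograms no mixture can fit are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import argrelmax

from .matrix import ChromatogramMatrix

#: default fit bounds: centers may sit a little outside the gradient
CENTER_PAD = 5.0
SIGMA_MIN = 0.5
SIGMA_INIT = 2.0
MAX_ITER = 500
SSE_RTOL = 1e-8


@dataclass(frozen=True)
class GaussianComponent:
    amplitude: float
    center: float
    width: float


@dataclass(frozen=True)
class GaussianMixtureFit:
    """Selected mixture for one chromatogram.

    ``model_score`` is the AICc of the selected model, which minimizes the
    score among all component counts that converged.
    """

    components: tuple[GaussianComponent, ...]
    model_score: float
    converged: bool = True

    @property
    def n_components(self) -> int:
        return len(self.components)

    def predict(self, fractions: np.ndarray) -> np.ndarray:
        fractions = np.asarray(fractions, dtype=float)
        out = np.zeros_like(fractions)
        for comp in self.components:
            out += comp.amplitude * np.exp(
                -((fractions - comp.center) ** 2) / (2.0 * comp.width**2)
            )
        return out


def impute_single_missing(profile: np.ndarray) -> np.ndarray:
    """Fill isolated missing points with the mean of their two neighbors.

    Runs of two or more consecutive missing values, and missing endpoints,
    are left untouched.  Observed values never change.
    """
    x = np.asarray(profile, dtype=float).copy()
    n = len(x)
    miss = ~np.isfinite(x)
    for i in range(1, n - 1):
        if miss[i] and not miss[i - 1] and not miss[i + 1]:
            x[i] = 0.5 * (profile[i - 1] + profile[i + 1])
    return x


def impute_matrix(matrix: ChromatogramMatrix) -> ChromatogramMatrix:
    values = matrix.values
    return matrix.with_values(
        np.vstack([impute_single_missing(row) for row in values])
    )


def filter_min_observations(
    matrix: ChromatogramMatrix, min_obs: int = 5
) -> ChromatogramMatrix:
    """Keep proteins observed in at least ``min_obs`` fractions (order kept)."""
    counts = np.isfinite(matrix.values).sum(axis=1)
    keep = matrix.data.index[counts >= min_obs]
    return ChromatogramMatrix(
        matrix.data.loc[keep],
        replicate=matrix.replicate,
        channel=matrix.channel,
        condition=matrix.condition,
    )


def smooth_profile(profile: np.ndarray, width: int = 5) -> np.ndarray:
    """Centered sliding average over observed points; width must be odd.

    Windows truncate at the profile ends; missing points stay missing.
    """
    if width % 2 == 0 or width < 1:
        raise ValueError("smoothing width must be a positive odd integer")
    x = np.asarray(profile, dtype=float)
    n = len(x)
    half = width // 2
    obs = np.isfinite(x)
    filled = np.where(obs, x, 0.0)
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        m = obs[lo:hi]
        if obs[i] and m.any():
            out[i] = filled[lo:hi][m].mean()
    return out


def smooth_matrix(matrix: ChromatogramMatrix, width: int = 5) -> ChromatogramMatrix:
    return matrix.with_values(
        np.vstack([smooth_profile(row, width) for row in matrix.values])
    )


def _mixture_residuals(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    k = len(params) // 3
    amps, centers, widths = params[:k], params[k : 2 * k], params[2 * k :]
    pred = np.sum(
        amps[:, None] * np.exp(-((x[None, :] - centers[:, None]) ** 2)
                               / (2.0 * widths[:, None] ** 2)),
        axis=0,
    )
    return pred - y


def _mixture_jacobian(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    k = len(params) // 3
    amps, centers, widths = params[:k], params[k : 2 * k], params[2 * k :]
    dx = x[None, :] - centers[:, None]
    g = np.exp(-(dx**2) / (2.0 * widths[:, None] ** 2))  # k x n
    d_amp = g
    d_center = amps[:, None] * g * dx / widths[:, None] ** 2
    d_width = amps[:, None] * g * dx**2 / widths[:, None] ** 3
    return np.concatenate([d_amp, d_center, d_width], axis=0).T


def _initial_centers(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Candidate peak centers: the k largest local maxima, padded by the
    largest remaining values, then by quantile-spaced positions."""
    idx = list(argrelmax(y, order=1)[0])
    idx.sort(key=lambda i: -y[i])
    if len(idx) < k:
        rest = [i for i in np.argsort(-y) if i not in idx]
        idx.extend(rest[: k - len(idx)])
    centers = [x[i] for i in idx[:k]]
    q = 1
    while len(centers) < k:
        centers.append(np.quantile(x, q / (k + 1)))
        q += 1
    return np.asarray(centers[:k])


def _aicc(sse: float, n: int, p: int, scale: float) -> float:
    # floor the mean squared residual so machine-epsilon-perfect fits of
    # different orders are compared by their parameter penalty alone
    floor = (1e-6 * max(scale, 1e-300)) ** 2
    msr = max(sse / n, floor)
    return n * np.log(msr) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def fit_gaussian_mixture(
    profile: np.ndarray, max_components: int = 5
) -> GaussianMixtureFit | None:
    """Fit mixtures of 1..``max_components`` Gaussians; pick by AICc.

    Fits are least-squares over observed points only, with fractions
    numbered 1-based.  Returns ``None`` when the chromatogram is discarded:
    no candidate converged, the profile carries no signal, or every
    candidate has too few points for the AICc correction term
    (``n - 3k - 1 <= 0``).
    """
    y_all = np.asarray(profile, dtype=float)
    x_all = np.arange(1, len(y_all) + 1, dtype=float)
    obs = np.isfinite(y_all)
    x, y = x_all[obs], y_all[obs]
    n = len(y)
    scale = y.max(initial=0.0)
    if n == 0 or scale <= 0:
        return None

    nfr = len(y_all)
    best: GaussianMixtureFit | None = None
    worse_streak = 0
    for k in range(1, max_components + 1):
        p = 3 * k
        if n - p - 1 <= 0:
            continue
        centers0 = _initial_centers(x, y, k)
        amps0 = np.interp(centers0, x, y).clip(min=1e-3 * scale)
        params0 = np.concatenate([amps0, centers0, np.full(k, SIGMA_INIT)])
        lower = np.concatenate(
            [np.full(k, 0.0), np.full(k, 1.0 - CENTER_PAD), np.full(k, SIGMA_MIN)]
        )
        upper = np.concatenate(
            [np.full(k, 10.0 * scale), np.full(k, nfr + CENTER_PAD), np.full(k, float(nfr))]
        )
        try:
            res = least_squares(
                _mixture_residuals,
                np.clip(params0, lower + 1e-9, upper - 1e-9),
                jac=_mixture_jacobian,
                bounds=(lower, upper),
                args=(x, y),
                ftol=SSE_RTOL,
                xtol=1e-10,
                max_nfev=MAX_ITER,
            )
        except Exception:
            continue
        if not res.success:
            continue
        sse = float(2.0 * res.cost)
        score = _aicc(sse, n, p, scale)
        if best is None or score < best.model_score:
            comps = tuple(
                GaussianComponent(float(a), float(c), float(w))
                for a, c, w in zip(res.x[:k], res.x[k : 2 * k], res.x[2 * k :])
            )
            best = GaussianMixtureFit(comps, score)
            worse_streak = 0
        else:
            # adding components stopped helping twice in a row: larger
            # mixtures only add penalty, so stop early
            worse_streak += 1
            if worse_streak >= 2:
                break
    return best


def fit_matrix(
    matrix: ChromatogramMatrix, max_components: int = 5
) -> tuple[dict[str, GaussianMixtureFit], list[str]]:
    """Fit every profile; return {protein: fit} plus the discarded ids."""
    fits: dict[str, GaussianMixtureFit] = {}
    discarded: list[str] = []
    for protein, row in zip(matrix.proteins, matrix.values):
        fit = fit_gaussian_mixture(row, max_components=max_components)
        if fit is None:
            discarded.append(protein)
        else:
            fits[protein] = fit
    return fits, discarded


def write_fits_tsv(fits: dict[str, GaussianMixtureFit], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tcomponent\tamplitude\tcenter\twidth\taicc\n")
        for protein, fit in fits.items():
            for i, comp in enumerate(fit.components, start=1):
                fh.write(
                    f"{protein}\t{i}\t{comp.amplitude:.6g}\t{comp.center:.6g}\t"
                    f"{comp.width:.6g}\t{fit.model_score:.6g}\n"
                )


def read_fits_tsv(path) -> dict[str, GaussianMixtureFit]:
    rows: dict[str, list[tuple[GaussianComponent, float]]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            protein, _i, a, c, w, score = line.rstrip("\n").split("\t")
            rows.setdefault(protein, []).append(
                (GaussianComponent(float(a), float(c), float(w)), float(score))
            )
    return {
        protein: GaussianMixtureFit(tuple(c for c, _ in comps), comps[0][1])
        for protein, comps in rows.items()
    }


def clean_matrix(matrix: ChromatogramMatrix, min_obs: int = 5) -> ChromatogramMatrix:
    """Imputation followed by the minimum-observation filter."""
    return filter_min_observations(impute_matrix(matrix), min_obs=min_obs)
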