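"""Spectral preprocessing: baseline correction, replicate averaging,
vector normalization, and analysis-window truncation.

The pipeline order is fixed by the analysis protocol: baseline-correct
each scan, average a specimen's replicate scans, vector-normalize the
averaged spectrum. Window truncation (default 400-1800 cm^-1) is applied
at analysis time, not here, because the acquisition range (250-1950
cm^-1) and the chemometric analysis window differ.

Baseline model
--------------
Urine spectra ride on a broad fluorescence background. The default
corrector fits a low-order polynomial with an *asymmetric, clipped*
quadratic cost, iteratively reweighted:

* residuals at or below the baseline (signal < fit) are penalized
  quadratically — the baseline must not cut below the background;
* small positive residuals (noise above the fit) are penalized
  quadratically as well;
* large positive residuals — Raman peaks — have their penalty clipped
  beyond a scale threshold ``s``, so peaks do not drag the fit upward.

``s`` is re-tuned every iteration from a residual quantile so that the
fraction of strongly positive (clipped) channels approaches the
configured ``peak_fraction`` plus a tail allowance. An ordinary asymmetric
least-squares polynomial fit (constant small weight on all positive
residuals) is available via ``method="als"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    ConfigError,
    DegenerateSpectrumError,
    UnderdeterminedFitError,
    WindowError,
)
from .spectra_io import RamanSpectrum, SpectrumSet

#: Analysis window used by the chemometric and distance statistics.
DEFAULT_WINDOW = (400.0, 1800.0)


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    poly_order
        Degree of the baseline polynomial. 7 tracks the curvature of a
        typical fluorescence background without chasing peak clusters.
    peak_fraction
        Fraction of channels assumed to carry peak signal, in (0, 1).
        Controls the clipping threshold of the asymmetric cost.
    max_iter, tol
        Iteration cap and relative convergence tolerance on the baseline
        polynomial coefficients.
    window
        [low, high] analysis window in cm^-1 for truncate_window.
    normalize
        Whether the pipeline applies vector normalization.
    method
        "goldindec" (asymmetric clipped cost, default) or "als"
        (ordinary asymmetric least squares with asymmetry ``als_p``).
    norm
        "l2" Euclidean (default) or "l1" area normalization.
    """

    poly_order: int = 7
    peak_fraction: float = 0.5
    max_iter: int = 100
    tol: float = 1e-6
    window: tuple[float, float] = DEFAULT_WINDOW
    normalize: bool = True
    method: str = "goldindec"
    norm: str = "l2"
    als_p: float = 0.01

    def __post_init__(self) -> None:
        if self.poly_order < 1:
            raise ConfigError("poly_order must be >= 1")
        if not 0.0 < self.peak_fraction < 1.0:
            raise ConfigError("peak_fraction must be in (0, 1)")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ConfigError("tol must be > 0")
        low, high = self.window
        if not low < high:
            raise ConfigError("window must satisfy low < high")
        if self.method not in ("goldindec", "als"):
            raise ConfigError(f"unknown baseline method {self.method!r}")
        if self.norm not in ("l2", "l1"):
            raise ConfigError(f"unknown norm {self.norm!r}")
        if not 0.0 < self.als_p < 1.0:
            raise ConfigError("als_p must be in (0, 1)")


def _design_matrix(shifts: np.ndarray, order: int) -> np.ndarray:
    # Legendre basis on shifts scaled to [-1, 1]: orthogonal-ish columns
    # keep the normal equations well conditioned up to high degree.
    lo, hi = shifts[0], shifts[-1]
    x = 2.0 * (shifts - lo) / (hi - lo) - 1.0
    return np.polynomial.legendre.legvander(x, order)


def _baseline_matrix(
    Y: np.ndarray, shifts: np.ndarray, config: PreprocessConfig
) -> np.ndarray:
    """Fit baselines for every row of Y at once (batched IRLS)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n_spec, n_chan = Y.shape
    if n_chan < config.poly_order + 1:
        raise UnderdeterminedFitError(
            f"{n_chan} channels cannot determine a degree-{config.poly_order} "
            "baseline"
        )
    V = _design_matrix(shifts, config.poly_order)  # (n_chan, d)
    W = np.ones_like(Y)
    coef = np.zeros((n_spec, V.shape[1]))
    scale = np.maximum(np.ptp(Y, axis=1, keepdims=True), 1e-300)
    for _ in range(config.max_iter):
        # weighted normal equations, one small solve per spectrum
        A = np.einsum("ci,nc,cj->nij", V, W, V, optimize=True)
        b = np.einsum("ci,nc->ni", V, W * Y, optimize=True)
        new_coef = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        B = new_coef @ V.T
        R = Y - B
        if config.method == "goldindec":
            # The clipping threshold masks twice the nominal peak
            # fraction (capped at 60% of channels): Lorentzian tails
            # reach well beyond the FWHM footprint and would otherwise
            # bias the fit upward.
            q = 1.0 - min(2.0 * config.peak_fraction, 0.6)
            s = np.quantile(R, q, axis=1, keepdims=True)
            s = np.maximum(s, 1e-9 * scale)
            W = np.where(R <= s, 1.0, 0.0)
        else:  # als
            W = np.where(R <= 0.0, 1.0 - config.als_p, config.als_p)
        delta = np.max(np.abs(new_coef - coef))
        coef = new_coef
        if delta <= config.tol * (1.0 + np.max(np.abs(coef))):
            break
    return coef @ V.T


def fit_baseline(
    spectrum: RamanSpectrum, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Fitted baseline on the spectrum's own grid."""
    config = config or PreprocessConfig()
    return _baseline_matrix(
        spectrum.intensities[None, :], spectrum.shifts, config
    )[0]


def correct_baseline(
    spectrum: RamanSpectrum, config: PreprocessConfig | None = None
) -> RamanSpectrum:
    """Subtract the fitted baseline. Small negative values are retained:
    clipping would bias the subsequent vector normalization."""
    config = config or PreprocessConfig()
    baseline = fit_baseline(spectrum, config)
    return replace(spectrum, intensities=spectrum.intensities - baseline)


def correct_baseline_set(
    spectra: SpectrumSet, config: PreprocessConfig | None = None
) -> SpectrumSet:
    """Baseline-correct every row of a SpectrumSet (batched)."""
    config = config or PreprocessConfig()
    B = _baseline_matrix(spectra.matrix, spectra.grid, config)
    return SpectrumSet(
        grid=spectra.grid,
        matrix=spectra.matrix - B,
        specimen_ids=list(spectra.specimen_ids),
        scan_indices=(
            None
            if spectra.scan_indices is None
            else list(spectra.scan_indices)
        ),
    )


def average_replicates(spectra: SpectrumSet) -> SpectrumSet:
    """Per-channel mean over each specimen's replicate scans.

    Output has one row per distinct specimen, in order of first
    appearance; ``scan_indices`` is dropped.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(spectra.specimen_ids):
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(i)
    scan = spectra.scan_indices

    def _group_rows(sid: str) -> list[int]:
        # summing in scan-index order makes the mean exactly invariant
        # to the order scans arrive in
        idx = groups[sid]
        return sorted(idx, key=lambda i: scan[i]) if scan is not None else idx

    rows = np.vstack(
        [spectra.matrix[_group_rows(sid)].mean(axis=0) for sid in order]
    )
    return SpectrumSet(
        grid=spectra.grid, matrix=rows, specimen_ids=order, scan_indices=None
    )


def vector_normalize(spectra: SpectrumSet, norm: str = "l2") -> SpectrumSet:
    """Scale every row to unit Euclidean (or L1) norm."""
    if norm == "l2":
        norms = np.linalg.norm(spectra.matrix, axis=1)
    elif norm == "l1":
        norms = np.abs(spectra.matrix).sum(axis=1)
    else:
        raise ConfigError(f"unknown norm {norm!r}")
    zero = norms == 0.0
    if zero.any():
        sid = spectra.specimen_ids[int(np.flatnonzero(zero)[0])]
        raise DegenerateSpectrumError(
            f"specimen {sid!r} has a zero-norm spectrum and cannot be normalized"
        )
    return SpectrumSet(
        grid=spectra.grid,
        matrix=spectra.matrix / norms[:, None],
        specimen_ids=list(spectra.specimen_ids),
        scan_indices=(
            None
            if spectra.scan_indices is None
            else list(spectra.scan_indices)
        ),
    )


def truncate_window(
    spectra: SpectrumSet, window: tuple[float, float] = DEFAULT_WINDOW
) -> SpectrumSet:
    """Keep channels with low <= shift <= high (closed interval)."""
    low, high = window
    mask = (spectra.grid >= low) & (spectra.grid <= high)
    if not mask.any():
        raise WindowError(
            f"window [{low}, {high}] contains no grid channels "
            f"(grid spans [{spectra.grid[0]}, {spectra.grid[-1]}])"
        )
    return SpectrumSet(
        grid=spectra.grid[mask],
        matrix=spectra.matrix[:, mask],
        specimen_ids=list(spectra.specimen_ids),
        scan_indices=(
            None
            if spectra.scan_indices is None
            else list(spectra.scan_indices)
        ),
    )


def preprocess_set(
    scans: SpectrumSet, config: PreprocessConfig | None = None
) -> SpectrumSet:
    """Full chain on raw scans: baseline (per scan) -> average (per
    specimen) -> vector normalize. Truncation is left to analysis code."""
    config = config or PreprocessConfig()
    out = correct_baseline_set(scans, config)
    out = average_replicates(out)
    if config.normalize:
        out = vector_normalize(out, config.norm)
    return out
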