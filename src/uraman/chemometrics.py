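"""PCA of preprocessed spectra and discriminant analysis of principal
components (DAPC).

PCA here is the plain mean-centered singular value decomposition, with
no per-channel standardization (spectra are already vector normalized;
standardizing would inflate noise-only channels). Component sign is
fixed so each loading's largest-magnitude channel is positive, making
stored models bit-reproducible.

DAPC fits a Gaussian linear discriminant — per-class means and a single
pooled within-class covariance — on the leading PC scores rather than
on raw channels. The number of components is usually chosen by a
cumulative explained-variance tier (90/95/99/99.9%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .errors import (
    ClassSizeError,
    ConditioningError,
    CoverageError,
    DimensionError,
    InsufficientDataError,
)
from .spectra_io import SpectrumSet


@dataclass
class PCAModel:
    """Mean-centered PCA of a SpectrumSet.

    loadings has one orthonormal channel-space direction per row;
    scores[i, j] is specimen i's coordinate on component j;
    variance_fraction[j] is component j's share of total variance.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (k, p)
    scores: np.ndarray  # (n, k)
    variance_fraction: np.ndarray  # (k,)
    grid: np.ndarray
    specimen_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def project(self, X: np.ndarray, n_pcs: int | None = None) -> np.ndarray:
        """Center rows of X by the model mean and project onto loadings."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean_spectrum.size:
            raise DimensionError(
                f"{X.shape[1]} channels but PCA was fit on "
                f"{self.mean_spectrum.size}"
            )
        k = self.n_components if n_pcs is None else int(n_pcs)
        return (X - self.mean_spectrum) @ self.loadings[:k].T


@dataclass
class DAPCModel:
    """Linear discriminant on the first ``n_pcs`` PCA score coordinates."""

    pca: PCAModel
    n_pcs: int
    classes: list[str]
    class_means: np.ndarray  # (k_classes, n_pcs)
    pooled_covariance: np.ndarray  # (n_pcs, n_pcs)
    priors: np.ndarray  # (k_classes,)


def summarize_spectra(spectra: SpectrumSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and sample standard deviation (n-1 denominator),
    the summary behind mean +/- 1 and 2 s.d. envelope plots."""
    if spectra.n_rows < 2:
        raise InsufficientDataError("need >= 2 rows to summarize")
    return spectra.matrix.mean(axis=0), spectra.matrix.std(axis=0, ddof=1)


def fit_pca(spectra: SpectrumSet) -> PCAModel:
    """Mean-centered PCA by SVD; deterministic up to the sign convention."""
    if spectra.n_rows < 2:
        raise InsufficientDataError("need >= 2 rows for PCA")
    if spectra.n_channels < 2:
        raise InsufficientDataError("need >= 2 channels for PCA")
    X = spectra.matrix
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: each loading's largest-|.| channel is positive
    anchor = np.argmax(np.abs(Vt), axis=1)
    signs = np.sign(Vt[np.arange(Vt.shape[0]), anchor])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    scores = (U * S) * signs[None, :]
    total = np.sum(S**2)
    variance_fraction = (
        S**2 / total if total > 0 else np.zeros_like(S)
    )
    return PCAModel(
        mean_spectrum=mean,
        loadings=Vt,
        scores=scores,
        variance_fraction=variance_fraction,
        grid=spectra.grid.copy(),
        specimen_ids=list(spectra.specimen_ids),
    )


def select_n_pcs(variance_fraction: np.ndarray, target: float) -> int:
    """Smallest k whose cumulative variance fraction reaches ``target``."""
    if not 0.0 < target <= 1.0:
        raise ValueError("target must be in (0, 1]")
    cum = np.cumsum(np.asarray(variance_fraction, dtype=float))
    reach = cum >= target - 1e-9
    if not reach.any():
        raise CoverageError(
            f"cumulative variance {cum[-1]:.6f} cannot reach target {target}"
        )
    return int(np.argmax(reach)) + 1


@dataclass
class LoadingAttribution:
    """Raman-shift attribution of dataset variance.

    per_component ranks channels by |loading| within each component;
    combined ranks channels by sum_j variance_fraction_j * |loading_jc|
    over the first n_pcs components (invariant to component sign flips).
    """

    per_component: pd.DataFrame
    combined: pd.DataFrame


def loading_attribution(model: PCAModel, n_pcs: int) -> LoadingAttribution:
    if n_pcs > model.n_components:
        raise DimensionError(
            f"n_pcs {n_pcs} exceeds available components {model.n_components}"
        )
    rows = []
    for j in range(n_pcs):
        w = np.abs(model.loadings[j])
        order = np.argsort(-w)
        for rank, c in enumerate(order, start=1):
            rows.append(
                {
                    "component": j + 1,
                    "rank": rank,
                    "shift": float(model.grid[c]),
                    "weight": float(w[c]),
                }
            )
    per_component = pd.DataFrame(rows)
    combined_w = (
        model.variance_fraction[:n_pcs, None] * np.abs(model.loadings[:n_pcs])
    ).sum(axis=0)
    order = np.argsort(-combined_w)
    combined = pd.DataFrame(
        {
            "rank": np.arange(1, order.size + 1),
            "shift": model.grid[order],
            "weight": combined_w[order],
        }
    )
    return LoadingAttribution(per_component=per_component, combined=combined)


def _align_labels(labels, specimen_ids: list[str]) -> np.ndarray:
    """Labels pair to rows by specimen_id, never by position, when given
    as a mapping/Series; a plain sequence is taken as already aligned."""
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    if isinstance(labels, dict):
        missing = [s for s in specimen_ids if s not in labels]
        if missing:
            raise KeyError(f"no label for specimens {missing[:5]}")
        return np.asarray([str(labels[s]) for s in specimen_ids])
    arr = np.asarray([str(v) for v in labels])
    if arr.size != len(specimen_ids):
        raise DimensionError(
            f"{arr.size} labels for {len(specimen_ids)} specimens"
        )
    return arr


def fit_dapc(
    pca: PCAModel,
    labels,
    n_pcs: int,
    priors: str = "frequency",
    ridge: float = 1e-8,
) -> DAPCModel:
    """Fit the discriminant on the first ``n_pcs`` score coordinates.

    The pooled within-class covariance is regularized by adding
    ``ridge * trace/dim`` to the diagonal — deliberately minimal, so the
    near-singular behaviour of very high variance tiers stays observable.
    """
    if not 1 <= n_pcs <= pca.n_components:
        raise DimensionError(
            f"n_pcs must be in [1, {pca.n_components}], got {n_pcs}"
        )
    y = _align_labels(labels, pca.specimen_ids)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ClassSizeError("DAPC needs >= 2 classes")
    S = pca.scores[:, :n_pcs]
    n, _ = S.shape
    means = np.zeros((len(classes), n_pcs))
    pooled = np.zeros((n_pcs, n_pcs))
    counts = np.zeros(len(classes))
    for i, cls in enumerate(classes):
        rows = S[y == cls]
        if rows.shape[0] < 2:
            raise ClassSizeError(
                f"class {cls!r} has {rows.shape[0]} member(s); need >= 2"
            )
        counts[i] = rows.shape[0]
        means[i] = rows.mean(axis=0)
        dev = rows - means[i]
        pooled += dev.T @ dev
    pooled /= n - len(classes)
    pooled = pooled + ridge * (np.trace(pooled) / n_pcs) * np.eye(n_pcs)
    try:
        sla.cho_factor(pooled)
    except sla.LinAlgError as exc:
        raise ConditioningError(
            "pooled covariance singular after regularization"
        ) from exc
    if priors == "frequency":
        prior = counts / counts.sum()
    elif priors == "uniform":
        prior = np.full(len(classes), 1.0 / len(classes))
    else:
        raise ValueError(f"unknown priors {priors!r}")
    return DAPCModel(
        pca=pca,
        n_pcs=n_pcs,
        classes=classes,
        class_means=means,
        pooled_covariance=pooled,
        priors=prior,
    )


def predict_dapc(
    model: DAPCModel, X: np.ndarray, is_scores: bool | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Classify spectra or score vectors.

    X with ``n_pcs`` columns is taken as PC scores; with the PCA's
    channel count, rows are projected first. Returns (labels,
    posteriors); posteriors rows sum to 1. Ties at equal posterior go to
    the first class in lexicographic order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if is_scores is None:
        if X.shape[1] == model.n_pcs:
            is_scores = True
        elif X.shape[1] == model.pca.mean_spectrum.size:
            is_scores = False
        else:
            raise DimensionError(
                f"input has {X.shape[1]} columns; expected {model.n_pcs} "
                f"scores or {model.pca.mean_spectrum.size} channels"
            )
    S = X if is_scores else model.pca.project(X, model.n_pcs)
    if S.shape[1] != model.n_pcs:
        raise DimensionError(
            f"{S.shape[1]} score columns but model uses {model.n_pcs}"
        )
    cho = sla.cho_factor(model.pooled_covariance)
    log_post = np.empty((S.shape[0], len(model.classes)))
    for i, mu in enumerate(model.class_means):
        diff = S - mu
        maha = np.sum(diff * sla.cho_solve(cho, diff.T).T, axis=1)
        log_post[:, i] = -0.5 * maha + np.log(model.priors[i])
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    labels = np.asarray(model.classes)[np.argmax(post, axis=1)]
    return labels, post


# --- model persistence (CSV/JSON files in a directory) -------------------

def save_pca_model(model: PCAModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"raman_shift_cm-1": model.grid, "mean": model.mean_spectrum}
    ).to_csv(out / "mean.csv", index=False)
    k = model.n_components
    pc_cols = [f"PC{j + 1}" for j in range(k)]
    pd.DataFrame(model.loadings.T, columns=pc_cols).assign(
        **{"raman_shift_cm-1": model.grid}
    )[["raman_shift_cm-1"] + pc_cols].to_csv(out / "loadings.csv", index=False)
    pd.DataFrame(model.scores, columns=pc_cols).assign(
        specimen_id=model.specimen_ids
    )[["specimen_id"] + pc_cols].to_csv(out / "scores.csv", index=False)
    pd.DataFrame(
        {"component": pc_cols, "variance_fraction": model.variance_fraction}
    ).to_csv(out / "variance.csv", index=False)


def load_pca_model(model_dir: str | Path) -> PCAModel:
    d = Path(model_dir)
    mean = pd.read_csv(d / "mean.csv")
    loadings = pd.read_csv(d / "loadings.csv")
    scores = pd.read_csv(d / "scores.csv")
    variance = pd.read_csv(d / "variance.csv")
    pc_cols = [c for c in loadings.columns if c.startswith("PC")]
    return PCAModel(
        mean_spectrum=mean["mean"].to_numpy(),
        loadings=loadings[pc_cols].to_numpy().T,
        scores=scores[pc_cols].to_numpy(),
        variance_fraction=variance["variance_fraction"].to_numpy(),
        grid=mean["raman_shift_cm-1"].to_numpy(),
        specimen_ids=[str(s) for s in scores["specimen_id"]],
    )


def save_dapc_model(model: DAPCModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_pca_model(model.pca, out / "pca")
    cols = [f"PC{j + 1}" for j in range(model.n_pcs)]
    pd.DataFrame(model.class_means, columns=cols).assign(
        **{"class": model.classes}
    )[["class"] + cols].to_csv(out / "class_means.csv", index=False)
    pd.DataFrame(model.pooled_covariance, columns=cols).to_csv(
        out / "pooled_covariance.csv", index=False
    )
    with open(out / "params.json", "w") as fh:
        json.dump(
            {
                "n_pcs": model.n_pcs,
                "classes": model.classes,
                "priors": model.priors.tolist(),
            },
            fh,
            indent=2,
        )


def load_dapc_model(model_dir: str | Path) -> DAPCModel:
    d = Path(model_dir)
    pca = load_pca_model(d / "pca")
    with open(d / "params.json") as fh:
        params = json.load(fh)
    cols = [f"PC{j + 1}" for j in range(params["n_pcs"])]
    means = pd.read_csv(d / "class_means.csv")
    cov = pd.read_csv(d / "pooled_covariance.csv")
    return DAPCModel(
        pca=pca,
        n_pcs=int(params["n_pcs"]),
        classes=[str(c) for c in params["classes"]],
        class_means=means[cols].to_numpy(),
        pooled_covariance=cov[cols].to_numpy(),
        priors=np.asarray(params["priors"], dtype=float),
    )
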