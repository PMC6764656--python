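"""Blind leave-one-out build/test validation of DAPC models.

For every specimen, the PCA *and* the discriminant are refit on the
remaining n-1 spectra — the held-out spectrum never influences
centering, loadings or discriminant parameters — and the held-out
spectrum is projected through the fold's model and classified. Accuracy,
sensitivity (true-positive rate) and specificity (true-negative rate)
are computed from the collected predictions: binary when a positive
class is named, one-vs-rest per class otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import (
    PCAModel,
    fit_dapc,
    fit_pca,
    predict_dapc,
    select_n_pcs,
    _align_labels,
)
from .errors import FoldDegeneracyError, InsufficientDataError, ValidationError
from .spectra_io import SpectrumSet


@dataclass
class ConfusionMetrics:
    """Binary confusion counts with derived rates (fractions in [0, 1])."""

    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be >= 0")
        total = self.tp + self.fn + self.tn + self.fp
        if total == 0:
            raise InsufficientDataError("empty confusion matrix")
        self.accuracy = (self.tp + self.tn) / total
        pos, neg = self.tp + self.fn, self.tn + self.fp
        self.sensitivity = self.tp / pos if pos > 0 else float("nan")
        self.specificity = self.tn / neg if neg > 0 else float("nan")


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> ConfusionMetrics:
    return ConfusionMetrics(tp=tp, fn=fn, tn=tn, fp=fp)


def render_percent(fraction: float) -> str:
    """Whole-percent rendering, rounding half away from zero."""
    if np.isnan(fraction):
        return "n/a"
    pct = fraction * 100.0
    return f"{int(np.floor(pct + 0.5)) if pct >= 0 else -int(np.floor(-pct + 0.5))}%"


def one_vs_rest_metrics(true_labels, predicted_labels, cls) -> ConfusionMetrics:
    """Binarize with ``cls`` positive, all other labels pooled negative."""
    t = np.asarray([str(v) for v in true_labels])
    p = np.asarray([str(v) for v in predicted_labels])
    if t.size != p.size:
        raise ValidationError("label arrays differ in length")
    cls = str(cls)
    if cls not in t:
        raise ValidationError(f"class {cls!r} absent from true labels")
    tpos, ppos = t == cls, p == cls
    return confusion_metrics(
        tp=int(np.sum(tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fp=int(np.sum(~tpos & ppos)),
    )


@dataclass
class LOOResult:
    """One row per specimen plus summary metrics of the LOO routine."""

    predictions: pd.DataFrame  # specimen_id, true, predicted, posterior, fold_n_pcs
    metrics: ConfusionMetrics | dict[str, ConfusionMetrics]
    accuracy: float
    n_pcs_mode: int
    tier: float | None
    positive_class: str | None

    def per_class(self) -> dict[str, ConfusionMetrics]:
        if isinstance(self.metrics, dict):
            return self.metrics
        return {self.positive_class: self.metrics}


def loo_validate(
    spectra: SpectrumSet,
    labels,
    positive_class: str | None = None,
    tier_or_npcs: float | int = 0.99,
    refit_pca: bool = True,
    priors: str = "frequency",
) -> LOOResult:
    """Leave-one-out build/test over every specimen row.

    ``tier_or_npcs``: an int >= 1 fixes the PC count in every fold; a
    float in (0, 1] selects per fold the smallest count reaching that
    cumulative variance tier (counts may then differ across folds).
    ``refit_pca=False`` reuses one PCA fit on all rows (a deliberately
    leaky comparison mode; the default is the strict blind reading).
    """
    if spectra.scan_indices is not None:
        raise ValidationError(
            "loo_validate expects one row per specimen; average replicates first"
        )
    y = _align_labels(labels, spectra.specimen_ids)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise FoldDegeneracyError("need >= 2 classes for LOO validation")
    small = classes[counts < 3]
    if small.size:
        raise FoldDegeneracyError(
            f"classes {list(small)} have < 3 members; a fold would leave "
            "< 2 for the discriminant fit"
        )
    if isinstance(tier_or_npcs, (int, np.integer)) and not isinstance(
        tier_or_npcs, bool
    ):
        fixed_n, tier = int(tier_or_npcs), None
        if fixed_n < 1:
            raise ValidationError("explicit PC count must be >= 1")
    else:
        fixed_n, tier = None, float(tier_or_npcs)
        if not 0.0 < tier <= 1.0:
            raise ValidationError("variance tier must be in (0, 1]")

    n = spectra.n_rows
    full_pca: PCAModel | None = None
    if not refit_pca:
        full_pca = fit_pca(spectra)
    rows = []
    for i in range(n):
        keep = np.arange(n) != i
        train = spectra.subset(keep)
        pca = fit_pca(train) if refit_pca else full_pca
        if fixed_n is not None:
            k = min(fixed_n, pca.n_components)
        else:
            k = select_n_pcs(pca.variance_fraction, tier)
        if refit_pca:
            model = fit_dapc(pca, {s: l for s, l in zip(train.specimen_ids, y[keep])},
                             n_pcs=k, priors=priors)
        else:
            # discriminant refit on training scores only
            sub_pca = PCAModel(
                mean_spectrum=pca.mean_spectrum,
                loadings=pca.loadings,
                scores=pca.scores[keep],
                variance_fraction=pca.variance_fraction,
                grid=pca.grid,
                specimen_ids=[spectra.specimen_ids[j] for j in np.flatnonzero(keep)],
            )
            model = fit_dapc(
                sub_pca,
                {s: l for s, l in zip(sub_pca.specimen_ids, y[keep])},
                n_pcs=k,
                priors=priors,
            )
        pred, post = predict_dapc(model, spectra.matrix[i][None, :], is_scores=False)
        j = model.classes.index(pred[0])
        rows.append(
            {
                "specimen_id": spectra.specimen_ids[i],
                "true": y[i],
                "predicted": pred[0],
                "posterior": float(post[0, j]),
                "fold_n_pcs": k,
            }
        )
    predictions = pd.DataFrame(rows)
    accuracy = float(np.mean(predictions["true"] == predictions["predicted"]))
    n_pcs_mode = int(predictions["fold_n_pcs"].mode().iloc[0])
    if positive_class is not None:
        if str(positive_class) not in classes:
            raise ValidationError(
                f"positive class {positive_class!r} absent from labels"
            )
        metrics: ConfusionMetrics | dict[str, ConfusionMetrics] = (
            one_vs_rest_metrics(
                predictions["true"], predictions["predicted"], positive_class
            )
        )
    else:
        metrics = {
            str(c): one_vs_rest_metrics(
                predictions["true"], predictions["predicted"], c
            )
            for c in classes
        }
    return LOOResult(
        predictions=predictions,
        metrics=metrics,
        accuracy=accuracy,
        n_pcs_mode=n_pcs_mode,
        tier=tier,
        positive_class=None if positive_class is None else str(positive_class),
    )
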