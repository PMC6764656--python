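"""Distance statistics against the control standard and their analysis.

A preprocessed specimen spectrum is reduced to a single number in two
ways:

* **TPD** (total principal component distance) — Euclidean distance
  between the specimen's first ``n_pcs`` PC scores (4 by default) and
  those of the synthetic-urine control:
  ``TPD = sqrt( sum_{i=1..n} (P_u,i - P_control,i)^2 )``.
* **TSD** (total spectral distance) — Euclidean distance between the
  full normalized spectra of specimen and control over the analysis
  window.

TPD values are then analyzed by 2-way ANOVA (factors such as sex and
birth year, both categorical) and by Tukey's honestly significant
difference test for pairwise group comparisons. The ANOVA follows the
two-step protocol: fit with the interaction, drop it if non-significant
and refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .chemometrics import PCAModel
from .errors import (
    ClassSizeError,
    DimensionError,
    MissingControlError,
    ValidationError,
)
from .spectra_io import SpectrumSet

#: Distances use the first four principal components by default.
DEFAULT_TPD_PCS = 4


def control_scores(pca: PCAModel, control_ids) -> np.ndarray:
    """Mean PC-score vector of the control rows (replicates averaged in
    score space). The control rows must have been part of the PCA fit."""
    wanted = {str(c) for c in control_ids}
    idx = [i for i, s in enumerate(pca.specimen_ids) if s in wanted]
    if not idx:
        raise MissingControlError("no control rows found in the PCA fit")
    return pca.scores[idx].mean(axis=0)


def tpd(
    scores_u: np.ndarray,
    scores_control: np.ndarray,
    n_pcs: int = DEFAULT_TPD_PCS,
) -> float:
    """Euclidean distance over the first ``n_pcs`` PC coordinates."""
    u = np.asarray(scores_u, dtype=float).ravel()
    c = np.asarray(scores_control, dtype=float).ravel()
    if u.size < n_pcs or c.size < n_pcs:
        raise DimensionError(
            f"n_pcs={n_pcs} exceeds available components "
            f"({u.size} and {c.size})"
        )
    d = u[:n_pcs] - c[:n_pcs]
    return float(np.sqrt(np.sum(d * d)))


def tsd(spectrum_u: np.ndarray, spectrum_control: np.ndarray) -> float:
    """Euclidean distance over all channels of the analysis window."""
    u = np.asarray(spectrum_u, dtype=float).ravel()
    c = np.asarray(spectrum_control, dtype=float).ravel()
    if u.size != c.size:
        raise DimensionError(
            f"channel mismatch: {u.size} vs {c.size}"
        )
    return float(np.linalg.norm(u - c))


def distance_table(
    spectra: SpectrumSet,
    pca: PCAModel,
    control_ids,
    n_pcs: int = DEFAULT_TPD_PCS,
) -> pd.DataFrame:
    """TPD and TSD for every non-control specimen.

    ``spectra`` must be the same preprocessed set the PCA was fit on
    (one row per specimen, control rows included).
    """
    ctrl = control_scores(pca, control_ids)
    wanted = {str(c) for c in control_ids}
    ctrl_rows = [i for i, s in enumerate(spectra.specimen_ids) if s in wanted]
    ctrl_spectrum = spectra.matrix[ctrl_rows].mean(axis=0)
    rows = []
    for i, sid in enumerate(spectra.specimen_ids):
        if sid in wanted:
            continue
        rows.append(
            {
                "specimen_id": sid,
                "tpd": tpd(pca.scores[i], ctrl, n_pcs),
                "tsd": tsd(spectra.matrix[i], ctrl_spectrum),
                "n_pcs_used": n_pcs,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnovaTable:
    """2-way ANOVA decomposition with bookkeeping of the fit."""

    table: pd.DataFrame  # source, sum_sq, df, mean_sq, F, p
    factors: tuple[str, str]
    ss_type: str
    include_interaction: bool
    n_used: int

    def p_value(self, source: str) -> float:
        row = self.table[self.table["source"] == source]
        if row.empty:
            raise KeyError(source)
        return float(row["p"].iloc[0])

    def format_p(self, source: str) -> str:
        p = self.p_value(source)
        if np.isnan(p):
            return "n/a"
        return "<1e-12" if p < 1e-12 else f"{p:.3g}"


def two_way_anova(
    y,
    factor_a,
    factor_b,
    include_interaction: bool = False,
    ss_type: str | None = None,
    factor_names: tuple[str, str] = ("factor_a", "factor_b"),
) -> AnovaTable:
    """2-way ANOVA with both factors categorical.

    Default sum-of-squares type: II without the interaction, III with it
    (unbalanced designs). F and p come from the error mean square.
    """
    y = np.asarray(y, dtype=float)
    a = pd.Categorical([str(v) for v in factor_a])
    b = pd.Categorical([str(v) for v in factor_b])
    if y.size != len(a) or y.size != len(b):
        raise ValidationError("response and factor lengths differ")
    if len(a.categories) < 2 or len(b.categories) < 2:
        raise ValidationError("each factor needs >= 2 levels")
    if ss_type is None:
        ss_type = "III" if include_interaction else "II"
    if ss_type not in ("I", "II", "III"):
        raise ValueError(f"ss_type must be I, II or III, got {ss_type!r}")
    df = pd.DataFrame({"y": y, "A": a, "B": b})
    contrast = "Sum" if ss_type == "III" else "Treatment"
    formula = (
        f"y ~ C(A, {contrast}) + C(B, {contrast})"
        + (f" + C(A, {contrast}):C(B, {contrast})" if include_interaction else "")
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance designs emit RuntimeWarnings
        fit = ols(formula, data=df).fit()
        anova = sm.stats.anova_lm(fit, typ={"I": 1, "II": 2, "III": 3}[ss_type])
    rename = {}
    for idx in anova.index:
        name = str(idx)
        if ":" in name:
            rename[idx] = f"{factor_names[0]}:{factor_names[1]}"
        elif "C(A" in name:
            rename[idx] = factor_names[0]
        elif "C(B" in name:
            rename[idx] = factor_names[1]
        elif name == "Residual":
            rename[idx] = "error"
        else:
            rename[idx] = name.lower()
    anova = anova.rename(index=rename)
    if "intercept" in anova.index:
        anova = anova.drop(index="intercept")
    total_ss = float(np.sum((y - y.mean()) ** 2))
    # constant response: every SS is roundoff; F and p are undefined
    degenerate = total_ss <= 1e-20 * max(1.0, float(np.sum(y**2)))
    out_rows = []
    for source, row in anova.iterrows():
        ss = float(row["sum_sq"])
        dof = float(row["df"])
        out_rows.append(
            {
                "source": source,
                "sum_sq": 0.0 if degenerate else ss,
                "df": int(dof),
                "mean_sq": ss / dof if dof > 0 and not degenerate else float("nan"),
                "F": float("nan") if degenerate else float(row.get("F", float("nan"))),
                "p": float("nan") if degenerate else float(row.get("PR(>F)", float("nan"))),
            }
        )
    out_rows.append(
        {
            "source": "total",
            "sum_sq": total_ss,
            "df": y.size - 1,
            "mean_sq": float("nan"),
            "F": float("nan"),
            "p": float("nan"),
        }
    )
    return AnovaTable(
        table=pd.DataFrame(out_rows),
        factors=factor_names,
        ss_type=ss_type,
        include_interaction=include_interaction,
        n_used=int(y.size),
    )


def anova_two_step(
    y,
    factor_a,
    factor_b,
    alpha: float = 0.05,
    factor_names: tuple[str, str] = ("factor_a", "factor_b"),
) -> tuple[float, AnovaTable]:
    """The two-step protocol: fit with the interaction first; if its p
    exceeds ``alpha`` refit without it. Returns (interaction_p, final)."""
    with_int = two_way_anova(
        y, factor_a, factor_b, include_interaction=True,
        factor_names=factor_names,
    )
    p_int = with_int.p_value(f"{factor_names[0]}:{factor_names[1]}")
    if not np.isnan(p_int) and p_int < alpha:
        return p_int, with_int
    final = two_way_anova(
        y, factor_a, factor_b, include_interaction=False,
        factor_names=factor_names,
    )
    return p_int, final


def tukey_hsd(y, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (Tukey-Kramer for unbalanced
    groups), using the one-way error mean square."""
    y = np.asarray(y, dtype=float)
    g = np.asarray([str(v) for v in groups])
    if y.size != g.size:
        raise ValidationError("response and group lengths differ")
    levels, counts = np.unique(g, return_counts=True)
    if levels.size < 2:
        raise ClassSizeError("Tukey HSD needs >= 2 groups")
    small = levels[counts < 2]
    if small.size:
        raise ClassSizeError(f"groups {list(small)} have < 2 members")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pairwise_tukeyhsd(endog=y, groups=g, alpha=alpha)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    out = pd.DataFrame(
        {
            "group_i": frame["group1"].astype(str),
            "group_j": frame["group2"].astype(str),
            "mean_diff": frame["meandiff"].astype(float),
            "adjusted_p": np.asarray(res.pvalues, dtype=float),
            "significant": np.asarray(res.reject, dtype=bool),
        }
    )
    return out


def tpd_summary(distances: pd.DataFrame, group_by) -> pd.DataFrame:
    """Per-group mean, sample s.d., min and max of TPD, with the
    rendered "mean ± sd" / "min − max" strings used in reports.

    ``distances`` needs columns specimen_id and tpd; ``group_by`` maps
    specimen_id -> group (mapping or Series) or is an aligned sequence.
    """
    if "tpd" not in distances.columns:
        raise ValidationError("distances frame lacks a 'tpd' column")
    if isinstance(group_by, pd.Series):
        group_by = group_by.to_dict()
    if isinstance(group_by, dict):
        groups = [group_by[s] for s in distances["specimen_id"]]
    else:
        groups = list(group_by)
        if len(groups) != len(distances):
            raise ValidationError("group_by length mismatch")
    df = distances.assign(_group=[str(v) for v in groups])
    rows = []
    for grp, sub in df.groupby("_group", sort=True):
        vals = sub["tpd"].to_numpy()
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
        lo, hi = float(vals.min()), float(vals.max())
        rows.append(
            {
                "group": grp,
                "n": int(vals.size),
                "mean": mean,
                "sd": sd,
                "min": lo,
                "max": hi,
                "mean_sd": (
                    f"{mean:.3g} ± {sd:.3g}" if vals.size > 1 else f"{mean:.3g} ± n/a"
                ),
                "range": f"{lo:.3g} − {hi:.3g}",
            }
        )
    return pd.DataFrame(rows)
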