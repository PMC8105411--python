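"""Classical statistics for the validation assays.

Covers the linear-model and test layer used downstream of the screen:

* ANCOVA of log2-transformed immunoblot densitometry with a
  loading-control covariate (signal ~ log2(loading) + genotype *
  treatment), reported as a sequential (Type I) ANOVA table in the order
  covariate, genotype, treatment, interaction, plus fold-change
  contrasts against a reference condition;
* immunofluorescence foci summaries: percent of focus-positive nuclei
  at per-marker count thresholds, and directional co-localization
  percentages between two markers;
* two-sample t-tests (Student or Welch) and Tukey's HSD.

Densitometry enters on the log2 scale, so treatment differences exponentiate
to fold-changes; densities must be strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AncovaResult",
    "ancova_blot",
    "DEFAULT_FOCI_THRESHOLDS",
    "foci_positive",
    "colocalization",
    "two_sample_tests",
    "tukey_hsd",
]

#: Minimum foci per nucleus for a cell to count as focus-positive,
#: per marker (gamma-H2AX 5, 53BP1 3, RNF168 3, FK2 10).
DEFAULT_FOCI_THRESHOLDS: dict[str, int] = {
    "gH2AX": 5,
    "53BP1": 3,
    "RNF168": 3,
    "FK2": 10,
}


@dataclass
class AncovaResult:
    anova_table: pd.DataFrame  # Df, Sum Sq, Mean Sq, F, Pr(>F)
    coefficients: pd.Series
    contrasts: pd.DataFrame  # fold-changes vs reference with CIs
    residual_ss: float
    model: object  # fitted statsmodels results


def ancova_blot(
    table: pd.DataFrame,
    signal_col: str = "signal",
    loading_col: str = "loading",
    genotype_col: str = "genotype",
    treatment_col: str = "treatment",
    reference: tuple[str, str] | None = None,
    ci_level: float = 0.95,
) -> AncovaResult:
    """Loading-control-adjusted ANCOVA of densitometry on the log2 scale.

    Fits log2(signal) ~ log2(loading) + C(genotype) * C(treatment) by
    least squares under the equal-slopes assumption and returns the
    sequential ANOVA table (covariate first, then genotype, treatment,
    interaction) plus per-condition fold-change contrasts relative to
    ``reference`` (default: alphabetically first genotype and treatment,
    intended to be the wild-type vehicle cell).
    """
    for col in (signal_col, loading_col, genotype_col, treatment_col):
        if col not in table.columns:
            raise ValueError(f"blot table missing column {col!r}")
    if (table[signal_col] <= 0).any() or (table[loading_col] <= 0).any():
        raise ValueError("densities must be strictly positive for the log2 transform")
    df = table.copy()
    df["_y"] = np.log2(df[signal_col])
    df["_load"] = np.log2(df[loading_col])
    if reference is None:
        reference = (
            _default_level(df[genotype_col], ("WT", "wildtype", "wild-type", "+/+")),
            _default_level(df[treatment_col], ("vehicle",)),
        )
    ref_g, ref_t = reference
    g_term = f"C({genotype_col}, Treatment('{ref_g}'))"
    t_term = f"C({treatment_col}, Treatment('{ref_t}'))"
    formula = f"_y ~ _load + {g_term} * {t_term}"
    fit = smf.ols(formula, data=df).fit()
    if fit.df_resid <= 0:
        raise ValueError("no residual degrees of freedom; design is saturated")
    rank_expected = fit.model.exog.shape[1]
    if np.linalg.matrix_rank(fit.model.exog) < rank_expected:
        raise ValueError("rank-deficient design: some genotype x treatment cells alias")
    anova = _sequential_anova(
        df,
        terms=[
            ("log2_loading", "_load"),
            (genotype_col, g_term),
            (treatment_col, t_term),
            (f"{genotype_col}:{treatment_col}", f"{g_term}:{t_term}"),
        ],
        full_fit=fit,
    )

    # cell-mean contrasts vs the reference cell at the mean loading
    params = fit.params
    ci = fit.conf_int(alpha=1 - ci_level)
    rows = []
    for name in params.index:
        if name in ("Intercept", "_load"):
            continue
        rows.append(
            {
                "term": name,
                "log2_difference": params[name],
                "fold_change": 2.0 ** params[name],
                "fold_ci_lower": 2.0 ** ci.loc[name, 0],
                "fold_ci_upper": 2.0 ** ci.loc[name, 1],
            }
        )
    contrasts = pd.DataFrame(rows)
    return AncovaResult(
        anova_table=anova,
        coefficients=params,
        contrasts=contrasts,
        residual_ss=float(fit.ssr),
        model=fit,
    )


def _default_level(column: pd.Series, preferred: tuple[str, ...]) -> str:
    """Reference level: a conventional control name if present, else first."""
    levels = sorted(column.unique())
    for cand in preferred:
        for lvl in levels:
            if str(lvl).lower() == cand.lower():
                return lvl
    return levels[0]


def _sequential_anova(
    df: pd.DataFrame, terms: list[tuple[str, str]], full_fit
) -> pd.DataFrame:
    """Type I (sequential) ANOVA table in the given term order.

    Each term's SS is the drop in residual SS when it is added to the
    preceding terms; F compares the term mean square to the full-model
    residual mean square.  statsmodels' anova_lm reorders terms, so the
    decomposition is built here from nested fits to keep the covariate
    first.
    """
    rows = []
    rhs_parts: list[str] = []
    prev = smf.ols("_y ~ 1", data=df).fit()
    for label, term in terms:
        rhs_parts.append(term)
        cur = smf.ols("_y ~ " + " + ".join(rhs_parts), data=df).fit()
        ss = prev.ssr - cur.ssr
        dof = prev.df_resid - cur.df_resid
        ms = ss / dof if dof > 0 else np.nan
        f = ms / full_fit.mse_resid if dof > 0 else np.nan
        p = stats.f.sf(f, dof, full_fit.df_resid) if dof > 0 else np.nan
        rows.append((label, dof, ss, ms, f, p))
        prev = cur
    rows.append(
        ("Residual", full_fit.df_resid, full_fit.ssr, full_fit.mse_resid, np.nan, np.nan)
    )
    return pd.DataFrame(
        rows, columns=["term", "Df", "Sum Sq", "Mean Sq", "F", "Pr(>F)"]
    ).set_index("term")


def foci_positive(
    table: pd.DataFrame, thresholds: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Percent focus-positive cells per condition and marker.

    ``table`` columns: ``cell``, ``marker``, ``foci_count``,
    ``condition``.  A cell is positive when its count is >= the marker's
    threshold (defaults: :data:`DEFAULT_FOCI_THRESHOLDS`).
    """
    thresholds = dict(DEFAULT_FOCI_THRESHOLDS if thresholds is None else thresholds)
    markers = set(table["marker"].unique())
    missing = markers - set(thresholds)
    if missing:
        raise KeyError(f"no positivity threshold for marker(s) {sorted(missing)}")
    rows = []
    for (cond, marker), sub in table.groupby(["condition", "marker"]):
        thr = thresholds[marker]
        pos = (sub["foci_count"] >= thr).sum()
        rows.append(
            {
                "condition": cond,
                "marker": marker,
                "threshold": thr,
                "n_cells": len(sub),
                "percent_positive": 100.0 * pos / len(sub),
            }
        )
    return pd.DataFrame(rows)


def colocalization(
    table: pd.DataFrame, marker_a: str, marker_b: str
) -> pd.DataFrame:
    """Directional focus co-localization between two markers.

    Rows with ``marker == marker_a`` give, per cell, the percent of A
    foci that are B-positive (100 x overlap_count / foci_count) and vice
    versa; per-cell percentages are averaged within condition.  The two
    directions are not symmetric.
    """
    if (table["overlap_count"] > table["foci_count"]).any():
        raise ValueError("overlap_count exceeds foci_count for some cell")
    rows = []
    for direction, marker in ((f"{marker_a}+{marker_b}", marker_a),
                              (f"{marker_b}+{marker_a}", marker_b)):
        sub = table[(table["marker"] == marker) & (table["foci_count"] > 0)]
        for cond, cells in sub.groupby("condition"):
            pct = 100.0 * cells["overlap_count"] / cells["foci_count"]
            rows.append(
                {
                    "condition": cond,
                    "direction": direction,
                    "n_cells": len(cells),
                    "percent_overlap": float(pct.mean()),
                }
            )
    return pd.DataFrame(rows)


def two_sample_tests(
    x: Sequence[float], y: Sequence[float], mode: str = "student"
) -> tuple[float, float]:
    """Two-tailed unpaired t-test; ``mode`` selects Student or Welch.

    Welch uses the Welch-Satterthwaite degrees of freedom.  When both
    samples are constant with equal means, (0.0, 1.0) is returned by
    convention; constant samples with different means are degenerate and
    raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >=2 observations per sample")
    if mode not in ("student", "welch"):
        raise ValueError("mode must be 'student' or 'welch'")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both samples with unequal means")
    t, p = stats.ttest_ind(x, y, equal_var=(mode == "student"))
    return float(t), float(p)


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey HSD over all pairwise group comparisons.

    Uses the studentized-range distribution with the pooled within-group
    variance; returns one row per pair with the mean difference and the
    family-wise adjusted p-value.
    """
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    labels = []
    values = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has <2 observations")
        labels.extend([name] * len(vals))
        values.extend(vals.tolist())
    res = pairwise_tukeyhsd(np.asarray(values), np.asarray(labels))
    frame = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    frame = frame.rename(
        columns={"group1": "group_a", "group2": "group_b", "p-adj": "p_adjusted",
                 "meandiff": "mean_difference"}
    )
    frame["p_adjusted"] = res.pvalues
    return frame[["group_a", "group_b", "mean_difference", "lower", "upper",
                  "p_adjusted", "reject"]]
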