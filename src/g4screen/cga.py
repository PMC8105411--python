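"""Blocked-bootstrap inference for competitive growth assays (CGA).

A CGA co-cultures fluorescently marked, sgRNA-transduced cells with
unmarked cells and reads out fitness as the proportion of marked (DRX2+)
cells after drug or vehicle treatment.  Experiments have a two-level
structure: independent assays (outer blocks), each with technical
replicates (inner blocks).  Inference resamples that structure: assays
are drawn with replacement, then replicates within each drawn assay are
drawn with replacement.  Per bootstrap replicate, proportions are
averaged on the logit ("logistic") scale, back-transformed, and the
drug - vehicle difference recorded; percentile confidence intervals are
read from the resulting distribution.

Family-wise error over a batch of contrasts is controlled by Bonferroni:
a contrast is called significant when the confidence interval at level
1 - family_alpha / n_comparisons excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "CgaExperiment",
    "BootstrapResult",
    "clamp_proportions",
    "fold_change",
    "blocked_bootstrap",
    "fwer_call",
    "DEFAULT_CI_LEVELS",
]

#: CI levels reported by default: 95%, 99%, 99.9% and 99.99%.
DEFAULT_CI_LEVELS = (0.95, 0.99, 0.999, 0.9999)


@dataclass
class CgaExperiment:
    """Tidy table of DRX2+ proportions: assay x replicate x condition.

    ``data`` columns: ``assay`` (int), ``replicate`` (int), ``condition``
    (str, one of them ``vehicle``), ``proportion`` (float in (0, 1));
    an optional ``sgrna`` column labels the target.
    """

    data: pd.DataFrame
    vehicle: str = "vehicle"

    def __post_init__(self) -> None:
        required = {"assay", "replicate", "condition", "proportion"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CGA table missing columns {sorted(missing)}")
        if self.vehicle not in set(self.data["condition"]):
            raise ValueError(f"no {self.vehicle!r} condition present")
        p = self.data["proportion"].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("proportions must lie in [0, 1]")

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.data["condition"]))

    def arm(self, condition: str) -> np.ndarray:
        """Proportions as an (n_assays, n_replicates) array.

        Requires a balanced layout (same replicate count in every assay
        for the condition); assays and replicates are ordered by label.
        """
        sub = self.data[self.data["condition"] == condition]
        if sub.empty:
            raise KeyError(f"condition {condition!r} not present")
        wide = sub.pivot_table(
            index="assay", columns="replicate", values="proportion", aggfunc="first"
        ).sort_index()
        if wide.isna().any().any():
            raise ValueError(
                f"unbalanced assay x replicate layout for condition {condition!r}"
            )
        return wide.to_numpy(dtype=float)


@dataclass
class BootstrapResult:
    """Blocked-bootstrap summary for one drug-vs-vehicle contrast."""

    condition: str
    point_difference: float  # drug - vehicle, proportion scale
    B: int
    seed: int | None
    ci: dict[float, tuple[float, float]]
    boot_mean: float
    boot_sd: float
    sgrna: str | None = None
    significant: dict[float, bool] = field(default_factory=dict)

    def interval(self, level: float) -> tuple[float, float]:
        """CI at ``level``, or the tightest stored level above it."""
        if level in self.ci:
            return self.ci[level]
        above = sorted(l for l in self.ci if l >= level)
        if not above:
            raise KeyError(f"no stored CI at level >= {level}")
        return self.ci[above[0]]


def clamp_proportions(
    p: np.ndarray | pd.Series, counts: np.ndarray | None = None, eps: float = 1e-4
) -> np.ndarray:
    """Continuity-correct proportions of exactly 0 or 1.

    With raw cell counts available the correction is (x + 0.5)/(n + 1);
    otherwise values are clamped to [eps, 1 - eps].  The logit transform
    downstream requires proportions strictly inside (0, 1).
    """
    p = np.asarray(p, dtype=float)
    if counts is not None:
        counts = np.asarray(counts, dtype=float)
        x = p * counts
        return (x + 0.5) / (counts + 1.0)
    return np.clip(p, eps, 1.0 - eps)


def fold_change(exp: CgaExperiment, condition: str) -> float:
    """Ratio of mean drug-arm to mean vehicle-arm DRX2+ percentage.

    The grand mean is taken over all assay x replicate observations of
    each arm on the raw proportion scale.
    """
    drug = exp.data.loc[exp.data["condition"] == condition, "proportion"]
    veh = exp.data.loc[exp.data["condition"] == exp.vehicle, "proportion"]
    if drug.empty:
        raise KeyError(f"condition {condition!r} not present")
    vmean = veh.mean()
    if vmean == 0:
        raise ZeroDivisionError("vehicle mean proportion is zero")
    return float(drug.mean() / vmean)


def _logit_mean_diff(drug: np.ndarray, veh: np.ndarray) -> float:
    return float(expit(logit(drug).mean()) - expit(logit(veh).mean()))


def blocked_bootstrap(
    exp: CgaExperiment,
    condition: str,
    B: int = 400_000,
    seed: int | None = None,
    levels: tuple[float, ...] = DEFAULT_CI_LEVELS,
    independent_arms: bool = False,
    batch_size: int = 100_000,
) -> BootstrapResult:
    """Two-level blocked bootstrap of the drug - vehicle difference.

    Each of the ``B`` replicates draws ``N_a`` assay indices with
    replacement (outer block), then within each drawn assay draws
    ``N_r`` replicate indices with replacement (inner block), yielding a
    dataset of the original shape.  Per replicate, each arm's
    proportions are averaged in logit space and back-transformed before
    differencing.  By default the same resampled assay/replicate indices
    are applied to both arms (paired resampling, mirroring that assays
    contain both conditions); ``independent_arms=True`` resamples the
    arms separately.

    Percentile CIs at ``levels`` are read from the B differences.
    """
    if B < 1000:
        raise ValueError("B >= 1000 required for CI reporting")
    drug = exp.arm(condition)
    veh = exp.arm(exp.vehicle)
    if drug.shape != veh.shape:
        raise ValueError("drug and vehicle arms must share assay/replicate layout")
    for name, arr in (("drug", drug), (exp.vehicle, veh)):
        if np.any((arr <= 0) | (arr >= 1)):
            raise ValueError(
                f"{name} arm contains proportions of exactly 0 or 1; "
                "apply clamp_proportions first"
            )
    n_assays, n_reps = drug.shape
    point = _logit_mean_diff(drug, veh)

    rng = np.random.default_rng(seed)
    ldrug = logit(drug)
    lveh = logit(veh)
    diffs = np.empty(B)
    done = 0
    while done < B:
        nb = min(batch_size, B - done)
        a_idx = rng.integers(0, n_assays, size=(nb, n_assays))
        r_idx = rng.integers(0, n_reps, size=(nb, n_assays, n_reps))
        md = expit(ldrug[a_idx[..., None], r_idx].mean(axis=(1, 2)))
        if independent_arms:
            a_idx = rng.integers(0, n_assays, size=(nb, n_assays))
            r_idx = rng.integers(0, n_reps, size=(nb, n_assays, n_reps))
        mv = expit(lveh[a_idx[..., None], r_idx].mean(axis=(1, 2)))
        diffs[done : done + nb] = md - mv
        done += nb

    ci = {}
    for level in sorted(levels):
        alpha = 1.0 - level
        lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
        ci[level] = (float(lo), float(hi))
    sgrna = None
    if "sgrna" in exp.data.columns:
        vals = exp.data["sgrna"].unique()
        sgrna = str(vals[0]) if len(vals) == 1 else None
    return BootstrapResult(
        condition=condition,
        point_difference=point,
        B=B,
        seed=seed,
        ci=_nest_monotone(ci),
        boot_mean=float(diffs.mean()),
        boot_sd=float(diffs.std(ddof=1)),
        sgrna=sgrna,
    )


def _nest_monotone(ci: dict[float, tuple[float, float]]) -> dict:
    """Enforce CI nesting across levels (guards against quantile ties)."""
    out: dict[float, tuple[float, float]] = {}
    lo_prev, hi_prev = np.inf, -np.inf
    for level in sorted(ci):
        lo, hi = ci[level]
        lo = min(lo, lo_prev)
        hi = max(hi, hi_prev)
        out[level] = (lo, hi)
        lo_prev, hi_prev = lo, hi
    return out


def fwer_call(
    results: list[BootstrapResult],
    n_comparisons: int = 50,
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Bonferroni-adjusted significance calls over a family of contrasts.

    The per-comparison alpha is family_alpha / n_comparisons and a
    contrast is significant when the CI at level 1 - adjusted alpha
    (or the tightest stored level above it) excludes zero.
    """
    alpha_adj = family_alpha / n_comparisons
    level_req = 1.0 - alpha_adj
    rows = []
    for res in results:
        if res.B * alpha_adj < 20:
            warnings.warn(
                f"B={res.B} resolves the adjusted tail alpha={alpha_adj:g} poorly "
                f"(B x alpha = {res.B * alpha_adj:.1f} < 20)",
                stacklevel=2,
            )
        lo, hi = res.interval(level_req)
        sig = lo > 0 or hi < 0
        res.significant[family_alpha] = sig
        rows.append(
            {
                "sgrna": res.sgrna,
                "condition": res.condition,
                "difference": res.point_difference,
                "ci_lower": lo,
                "ci_upper": hi,
                "family_alpha": family_alpha,
                "adjusted_alpha": alpha_adj,
                "significant": sig,
            }
        )
    return pd.DataFrame(rows)
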