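"""Dose-response and drug-combination pharmacology.

Three layers:

* four-parameter logistic (4PL, "variable slope") dose-response fitting
  with a profile-likelihood confidence interval for the IC50;
* many-to-one IC50 comparison (one-way ANOVA with pooled variance,
  followed by Dunnett's multiple-comparison test);
* Bliss-independence synergy analysis of two-drug checkerboards,
  summarized as synergy/antagonism volumes over the dose grid.

The 4PL model is fitted on the log10-dose axis::

    y(d) = bottom + (top - bottom) / (1 + (d / ic50) ** hill)

with responses expressed as viability relative to vehicle, so bottom is
constrained to be non-negative.

For a checkerboard, each well's fractional inhibition is
1 - response / untreated mean.  The Bliss-expected inhibition of a
combination is fx + fy - fx*fy from the monotherapy means; the per-cell
deviation (observed - expected, in %) is tested with a t-interval at a
Bonferroni-adjusted level, and significant deviations are accumulated
into volumes weighted by each cell's dose-interval area (units
dose_x x dose_y x %), following the MacSynergyII style of summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FourPLParams",
    "FourPLFit",
    "four_pl",
    "fit_4pl",
    "NonIdentifiableError",
    "compare_ic50_anova_dunnett",
    "bliss_expected",
    "Checkerboard",
    "SynergyResult",
    "synergy_volumes",
    "equipotency_design",
    "NSC697923_DOSES_NM",
    "CX5461_DOSES_NM",
]

#: Checkerboard monotherapy dose ladders used in the UBE2N-inhibitor
#: combination study: NSC697923 at five doses (IC50 = 166.1 nM scaled
#: x0.25..x4) and CX-5461 at nine (IC50 = 7.4 nM scaled x0.03125..x8).
NSC697923_DOSES_NM = (41.53, 83.05, 166.1, 332.2, 664.4)
CX5461_DOSES_NM = (0.23, 0.46, 0.93, 1.85, 3.7, 7.4, 14.8, 29.6, 59.2)


class NonIdentifiableError(RuntimeError):
    """Raised when the dose-response carries no information about IC50."""


class FourPLParams(NamedTuple):
    bottom: float
    top: float
    ic50: float
    hill: float


@dataclass(frozen=True)
class FourPLFit:
    params: FourPLParams
    residual_ss: float
    n_obs: int
    ic50_ci: tuple[float, float]

    @property
    def ic50(self) -> float:
        return self.params.ic50

    def predict(self, dose: np.ndarray) -> np.ndarray:
        return four_pl(dose, *self.params)


def four_pl(
    dose: np.ndarray | float, bottom: float, top: float, ic50: float, hill: float
) -> np.ndarray | float:
    """Four-parameter logistic response at the given dose(s)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def _4pl_logspace(logd, bottom, top, logic50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - logic50)))


def fit_4pl(
    data: pd.DataFrame,
    dose_col: str = "dose",
    response_col: str = "response",
    ci_level: float = 0.95,
) -> FourPLFit:
    """Least-squares 4PL fit of a single dose-response arm.

    ``data`` needs a positive ``dose`` column and a ``response`` column
    (viability relative to vehicle).  The fit runs in log10-dose space
    with multi-start initialization over hill slopes and IC50 positions;
    the IC50 CI comes from the profile likelihood (F-ratio threshold).

    Raises :class:`NonIdentifiableError` for flat responses and
    ``RuntimeError`` when no start converges.
    """
    doses = data[dose_col].to_numpy(dtype=float)
    y = data[response_col].to_numpy(dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive (vehicle is the normalizer)")
    if len(np.unique(doses)) < 4:
        raise ValueError("need >=4 distinct doses to fit four parameters")
    span = y.max() - y.min()
    scale = max(abs(y).max(), 1.0)
    if span < 1e-6 * scale:
        raise NonIdentifiableError(
            "response is flat (top ~= bottom); IC50 is not identifiable"
        )
    logd = np.log10(doses)
    lo_bounds = [0.0, y.min() - span, logd.min() - 3, 0.01]
    hi_bounds = [y.min() + span, y.max() + span, logd.max() + 3, 20.0]

    best = None
    for hill0 in (0.5, 1.0, 1.5, 3.0):
        for logic0 in np.quantile(logd, [0.25, 0.5, 0.75]):
            p0 = [max(y.min(), 0.0), y.max(), logic0, hill0]
            try:
                popt, _ = optimize.curve_fit(
                    _4pl_logspace,
                    logd,
                    y,
                    p0=p0,
                    bounds=(lo_bounds, hi_bounds),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((y - _4pl_logspace(logd, *popt)) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        raise RuntimeError(
            f"4PL fit failed to converge on {len(y)} points "
            f"(dose range {doses.min():g}..{doses.max():g})"
        )
    popt, rss = best
    params = FourPLParams(
        bottom=float(popt[0]),
        top=float(popt[1]),
        ic50=float(10.0 ** popt[2]),
        hill=float(popt[3]),
    )
    ci = _profile_ic50_ci(logd, y, popt, rss, lo_bounds, hi_bounds, ci_level)
    return FourPLFit(params=params, residual_ss=rss, n_obs=len(y), ic50_ci=ci)


def _profile_ic50_ci(logd, y, popt, rss_min, lo_b, hi_b, level):
    """Profile-likelihood CI for log-IC50 via the F-ratio threshold."""
    n, p = len(y), 4
    if n <= p or rss_min <= 0:
        return (float("nan"), float("nan"))
    fcrit = stats.f.ppf(level, 1, n - p)
    threshold = rss_min * (1.0 + fcrit / (n - p))

    def profile_rss(logic50):
        def model(ld, bottom, top, hill):
            return _4pl_logspace(ld, bottom, top, logic50, hill)

        p0 = [popt[0], popt[1], popt[3]]
        bounds = ([lo_b[0], lo_b[1], lo_b[3]], [hi_b[0], hi_b[1], hi_b[3]])
        try:
            q, _ = optimize.curve_fit(model, logd, y, p0=p0, bounds=bounds, maxfev=10000)
        except (RuntimeError, ValueError):
            return np.inf
        return float(np.sum((y - model(logd, *q)) ** 2))

    def edge(direction):
        step = 0.05 * direction
        x_in = popt[2]
        x_out = x_in + step
        for _ in range(200):
            if profile_rss(x_out) > threshold:
                break
            x_in, x_out = x_out, x_out + step
        else:
            return float("nan")
        for _ in range(40):  # bisection
            mid = 0.5 * (x_in + x_out)
            if profile_rss(mid) > threshold:
                x_out = mid
            else:
                x_in = mid
            if abs(x_out - x_in) < 1e-4:
                break
        return 10.0 ** (0.5 * (x_in + x_out))

    return (edge(-1.0), edge(+1.0))


# ---------------------------------------------------------------------------
# IC50 comparison


def compare_ic50_anova_dunnett(
    ic50_by_group: Mapping[str, Sequence[float]], control: str, seed: int = 0
) -> pd.DataFrame:
    """One-way pooled-variance ANOVA plus Dunnett's many-to-one test.

    ``ic50_by_group`` maps group labels to per-replicate IC50 estimates;
    ``control`` names the reference group.  Adjusted two-sided p-values
    come from the multivariate-t null of the max-|t| statistic
    (randomized quasi-Monte-Carlo integration, fixed by ``seed``).
    Returns a table with one row per non-control group and the ANOVA F/p
    in attrs.
    """
    if control not in ic50_by_group:
        raise KeyError(f"control group {control!r} missing")
    if len(ic50_by_group) < 2:
        raise ValueError("need >=2 groups")
    for g, vals in ic50_by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has <2 replicates")
    groups = [g for g in ic50_by_group if g != control]
    samples = [np.asarray(ic50_by_group[g], dtype=float) for g in groups]
    ctrl = np.asarray(ic50_by_group[control], dtype=float)

    fstat, fp = stats.f_oneway(ctrl, *samples)
    res = stats.dunnett(
        *samples,
        control=ctrl,
        alternative="two-sided",
        rng=np.random.default_rng(seed),
    )
    out = pd.DataFrame(
        {
            "group": groups,
            "mean_ic50": [s.mean() for s in samples],
            "control_mean_ic50": ctrl.mean(),
            "statistic": res.statistic,
            "p_adjusted": res.pvalue,
        }
    )
    out.attrs["anova_F"] = float(fstat)
    out.attrs["anova_p"] = float(fp)
    return out


# ---------------------------------------------------------------------------
# Bliss synergy


def bliss_expected(fx: float | np.ndarray, fy: float | np.ndarray) -> float | np.ndarray:
    """Bliss-independent combined inhibition fraction: fx + fy - fx*fy."""
    fx = np.asarray(fx, dtype=float)
    fy = np.asarray(fy, dtype=float)
    if np.any((fx < 0) | (fx > 1)) or np.any((fy < 0) | (fy > 1)):
        raise ValueError("inhibition fractions must lie in [0, 1]")
    out = fx + fy - fx * fy
    return float(out) if out.ndim == 0 else out


@dataclass
class Checkerboard:
    """Replicate responses over a two-drug dose grid.

    ``data`` columns: ``dose_x``, ``dose_y`` (0 encodes drug absent),
    ``replicate``, ``response`` (surviving fraction / viability signal).
    A complete board holds untreated wells (0, 0), both monotherapy
    ladders (d, 0) and (0, d), and every combination (dx, dy).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"dose_x", "dose_y", "replicate", "response"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"checkerboard missing columns {sorted(missing)}")
        if not ((self.data["dose_x"] == 0) & (self.data["dose_y"] == 0)).any():
            raise ValueError("untreated wells (dose_x=0, dose_y=0) are required")
        for axis, doses in (("x", self.doses_x), ("y", self.doses_y)):
            if len(doses) == 0:
                raise ValueError(f"no monotherapy doses for drug {axis}")
        combos = self.data[(self.data["dose_x"] > 0) & (self.data["dose_y"] > 0)]
        expected = {(x, y) for x in self.doses_x for y in self.doses_y}
        observed = set(zip(combos["dose_x"], combos["dose_y"]))
        if observed != expected:
            raise ValueError(
                f"incomplete dose grid: {len(observed)}/{len(expected)} combinations"
            )

    @property
    def doses_x(self) -> np.ndarray:
        d = self.data.loc[self.data["dose_x"] > 0, "dose_x"].unique()
        return np.sort(d)

    @property
    def doses_y(self) -> np.ndarray:
        d = self.data.loc[self.data["dose_y"] > 0, "dose_y"].unique()
        return np.sort(d)

    @property
    def n_combinations(self) -> int:
        return len(self.doses_x) * len(self.doses_y)


@dataclass
class SynergyResult:
    deviation: pd.DataFrame  # mean observed - expected inhibition (%), x as rows
    ci_lower: pd.DataFrame
    ci_upper: pd.DataFrame
    synergy_volume: float
    antagonism_volume: float
    log_synergy_volume: float
    log_antagonism_volume: float
    raw_synergy_volume: float
    raw_antagonism_volume: float
    confidence: float
    bonferroni: int


def _interval_weights(doses: np.ndarray, scale: str) -> np.ndarray:
    """Dose-interval width attributed to each grid point (trapezoid split)."""
    if scale == "unit":
        return np.ones_like(doses, dtype=float)
    vals = np.log10(doses) if scale == "log10" else np.asarray(doses, dtype=float)
    if len(vals) == 1:
        return np.ones(1)
    w = np.empty_like(vals)
    w[0] = (vals[1] - vals[0]) / 2
    w[-1] = (vals[-1] - vals[-2]) / 2
    if len(vals) > 2:
        w[1:-1] = (vals[2:] - vals[:-2]) / 2
    return w


def synergy_volumes(
    board: Checkerboard,
    confidence: float = 0.95,
    bonferroni: int | None = None,
    dose_scale: str = "linear",
) -> SynergyResult:
    """Bliss deviation surface and CI-thresholded synergy volumes.

    Per combination cell: deviation = observed inhibition% - Bliss
    expectation from the monotherapy mean inhibitions; a two-sided
    t-interval at per-cell level 1 - (1 - confidence)/bonferroni
    (default bonferroni = number of combinations) decides significance.
    The interval's standard error propagates both the combination-well
    replicate variance and the variance of the Bliss-expected surface
    through the monotherapy means (delta method), with
    Welch-Satterthwaite degrees of freedom.
    Synergy volume sums max(0, CI lower bound) x cell weight; antagonism
    volume sums min(0, CI upper bound) x cell weight, so antagonism <= 0
    <= synergy always.  Weights are products of per-axis dose-interval
    widths on ``dose_scale`` ("linear", "log10", or "unit" for weight 1);
    ``log_*`` volumes always use log10 widths.  ``raw_*`` volumes sum
    the unthresholded deviations for reference.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    data = board.data
    dx, dy = board.doses_x, board.doses_y
    if bonferroni is None:
        bonferroni = board.n_combinations
    untreated = data.loc[(data["dose_x"] == 0) & (data["dose_y"] == 0), "response"]
    u = untreated.mean()
    if u <= 0:
        raise ValueError("untreated mean response must be positive")

    def inh(sub: pd.DataFrame) -> pd.Series:
        return 100.0 * (1.0 - sub["response"] / u)

    def mono_stats(axis: str, doses: np.ndarray):
        other = "dose_y" if axis == "dose_x" else "dose_x"
        means, variances, ns = [], [], []
        for d in doses:
            vals = inh(data[(data[axis] == d) & (data[other] == 0)]).to_numpy()
            if vals.size == 0:
                raise ValueError(f"missing monotherapy wells for {axis}={d}")
            means.append(vals.mean())
            variances.append(vals.var(ddof=1) if vals.size > 1 else 0.0)
            ns.append(vals.size)
        return np.array(means), np.array(variances), np.array(ns)

    mono_x, var_x, n_x = mono_stats("dose_x", dx)
    mono_y, var_y, n_y = mono_stats("dose_y", dy)
    fx = np.clip(mono_x / 100.0, 0.0, 1.0)
    fy = np.clip(mono_y / 100.0, 0.0, 1.0)
    expected = 100.0 * bliss_expected(fx[:, None], fy[None, :])

    alpha_cell = (1.0 - confidence) / bonferroni
    mean_dev = np.full((len(dx), len(dy)), np.nan)
    lo = np.full_like(mean_dev, np.nan)
    hi = np.full_like(mean_dev, np.nan)
    for i, dxi in enumerate(dx):
        for j, dyj in enumerate(dy):
            obs = inh(data[(data["dose_x"] == dxi) & (data["dose_y"] == dyj)])
            vals = obs.to_numpy()
            m = vals.mean() - expected[i, j]
            mean_dev[i, j] = m
            # delta-method variance: combo replicates plus the expected
            # surface's dependence on the two monotherapy means
            comps = []
            if len(vals) >= 2:
                comps.append((vals.var(ddof=1) / len(vals), len(vals) - 1))
            comps.append(
                ((1.0 - fy[j]) ** 2 * var_x[i] / n_x[i], max(n_x[i] - 1, 1))
            )
            comps.append(
                ((1.0 - fx[i]) ** 2 * var_y[j] / n_y[j], max(n_y[j] - 1, 1))
            )
            se2 = sum(c for c, _ in comps)
            if se2 > 0:
                df = se2**2 / sum(c**2 / d for c, d in comps if c > 0)
                tcrit = stats.t.ppf(1 - alpha_cell / 2, df)
                half = tcrit * np.sqrt(se2)
            else:
                half = 0.0
            lo[i, j], hi[i, j] = m - half, m + half

    def volumes(wx, wy):
        w = wx[:, None] * wy[None, :]
        syn = float(np.sum(np.maximum(lo, 0.0) * w))
        ant = float(np.sum(np.minimum(hi, 0.0) * w))
        return syn, ant

    syn, ant = volumes(_interval_weights(dx, dose_scale), _interval_weights(dy, dose_scale))
    lsyn, lant = volumes(_interval_weights(dx, "log10"), _interval_weights(dy, "log10"))
    wx = _interval_weights(dx, dose_scale)
    wy = _interval_weights(dy, dose_scale)
    w = wx[:, None] * wy[None, :]
    raw_syn = float(np.sum(np.maximum(mean_dev, 0.0) * w))
    raw_ant = float(np.sum(np.minimum(mean_dev, 0.0) * w))

    idx = pd.Index(dx, name="dose_x")
    cols = pd.Index(dy, name="dose_y")
    return SynergyResult(
        deviation=pd.DataFrame(mean_dev, index=idx, columns=cols),
        ci_lower=pd.DataFrame(lo, index=idx, columns=cols),
        ci_upper=pd.DataFrame(hi, index=idx, columns=cols),
        synergy_volume=syn,
        antagonism_volume=ant,
        log_synergy_volume=lsyn,
        log_antagonism_volume=lant,
        raw_synergy_volume=raw_syn,
        raw_antagonism_volume=raw_ant,
        confidence=confidence,
        bonferroni=bonferroni,
    )


def equipotency_design(
    ic50_x: float,
    ic50_y: float,
    factors_x: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0),
    factors_y: Sequence[float] = (0.03125, 0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Equipotency-ratio dose ladders for a two-drug checkerboard.

    Scales each drug's IC50 by the given fold-factors (defaults give the
    5 x 9 = 45-combination design) so the two drugs contribute equal
    potency at matching rungs.
    """
    if ic50_x <= 0 or ic50_y <= 0:
        raise ValueError("IC50s must be positive")
    return (
        ic50_x * np.asarray(sorted(factors_x), dtype=float),
        ic50_y * np.asarray(sorted(factors_y), dtype=float),
    )
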