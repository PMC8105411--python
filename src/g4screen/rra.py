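"""Gene-level negative-selection scoring by alpha-truncated robust rank
aggregation (alpha-RRA).

The pipeline mirrors the standard pooled-screen workflow: normalized
guide counts are compared between treatment and control arms with a
negative-binomial test whose variance comes from a mean-variance trend
fitted on the control replicates; guides are ranked by depletion
evidence into percentiles; each gene's guide percentiles are aggregated
into a score

    rho = min over qualifying guides i of BetaCDF(p_(i); i, k - i + 1)

where p_(1) <= ... <= p_(k) are the gene's sorted guide percentiles and
only guides with p_(i) < alpha qualify (rho = 1 when none do).  Under
the null the p_(i) are order statistics of uniforms, whose marginal law
is Beta(i, k - i + 1); the truncation at alpha makes the score robust to
inert guides.  Gene p-values come from a permutation null that redraws
guide percentiles uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .screen_counts import CountMatrix, GuideLibrary, median_ratio_normalize

__all__ = [
    "VarianceModel",
    "fit_variance_model",
    "sgrna_nb_test",
    "rra_score",
    "null_rho_distribution",
    "permutation_pvalue",
    "score_screen",
]


@dataclass(frozen=True)
class VarianceModel:
    """Log-linear mean-variance trend, floored at the Poisson variance.

    var(mean) = max(mean, exp(intercept + slope * log(mean))).
    """

    intercept: float
    slope: float

    def __call__(self, mean: np.ndarray) -> np.ndarray:
        mean = np.asarray(mean, dtype=float)
        with np.errstate(divide="ignore"):
            trend = np.exp(self.intercept + self.slope * np.log(mean))
        return np.maximum(mean, np.where(mean > 0, trend, 0.0))


#: Variance model pinned to the Poisson relation var = mean.
POISSON_VARIANCE = VarianceModel(intercept=-np.inf, slope=0.0)


def fit_variance_model(control: pd.DataFrame) -> VarianceModel:
    """Fit the mean-variance trend on control-arm replicates.

    ``control`` is guides x replicate samples of normalized counts.
    Regresses log sample variance on log mean over guides with positive
    mean and variance; with <2 replicates or too few usable guides the
    model degrades to the Poisson floor.
    """
    if control.shape[1] < 2:
        return POISSON_VARIANCE
    mean = control.mean(axis=1).to_numpy()
    var = control.var(axis=1, ddof=1).to_numpy()
    ok = (mean > 0) & (var > 0)
    if ok.sum() < 10:
        return POISSON_VARIANCE
    x = np.log(mean[ok])
    yv = np.log(var[ok])
    slope, intercept = np.polyfit(x, yv, 1)
    return VarianceModel(intercept=float(intercept), slope=float(slope))


def sgrna_nb_test(
    treatment: pd.DataFrame,
    control: pd.DataFrame,
    variance_model: VarianceModel | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-guide depletion/enrichment test of treatment vs control means.

    Both arms are guides x samples of normalized counts over the same
    guide universe.  The control mean parametrizes a negative-binomial
    null (variance from ``variance_model``, floored at Poisson; exactly
    Poisson when variance <= mean) and the rounded treatment mean is
    compared against its tails.  Returns a table with ``log2_fold_change``,
    one-sided ``p_depletion``, two-sided ``p_value``, and the depletion
    ``percentile`` rank/(n+1) (ties broken by sgrna_id for determinism).
    """
    if not treatment.index.equals(control.index):
        missing = treatment.index.symmetric_difference(control.index)
        raise ValueError(
            f"guide universes differ between arms ({len(missing)} mismatched ids)"
        )
    if variance_model is None:
        variance_model = fit_variance_model(control)
    mu = control.mean(axis=1).to_numpy(dtype=float)
    t_obs = treatment.mean(axis=1).to_numpy(dtype=float)
    var = variance_model(np.maximum(mu, 1e-8))
    mu_safe = np.maximum(mu, 1e-8)

    t_round = np.round(t_obs).astype(np.int64)
    p_dep = np.empty(len(mu))
    p_enr = np.empty(len(mu))
    nb_mask = var > mu_safe * (1 + 1e-9)
    if nb_mask.any():
        m = mu_safe[nb_mask]
        v = var[nb_mask]
        size = m**2 / (v - m)
        prob = size / (size + m)
        p_dep[nb_mask] = stats.nbinom.cdf(t_round[nb_mask], size, prob)
        p_enr[nb_mask] = stats.nbinom.sf(t_round[nb_mask] - 1, size, prob)
    po = ~nb_mask
    if po.any():
        p_dep[po] = stats.poisson.cdf(t_round[po], mu_safe[po])
        p_enr[po] = stats.poisson.sf(t_round[po] - 1, mu_safe[po])
    p_two = np.minimum(1.0, 2.0 * np.minimum(p_dep, p_enr))

    lfc = np.log2((t_obs + pseudocount) / (mu + pseudocount))
    out = pd.DataFrame(
        {
            "sgrna_id": treatment.index,
            "log2_fold_change": lfc,
            "p_depletion": p_dep,
            "p_value": p_two,
        }
    )
    order = np.lexsort((out["sgrna_id"].to_numpy(), out["p_depletion"].to_numpy()))
    ranks = np.empty(len(out), dtype=float)
    ranks[order] = np.arange(1, len(out) + 1)
    out["percentile"] = ranks / (len(out) + 1)
    return out


def rra_score(
    percentiles: np.ndarray | list[float], alpha: float = 0.05
) -> float:
    """Alpha-truncated RRA score of one gene's sorted guide percentiles.

    rho = min over i with p_(i) < alpha of BetaCDF(p_(i); i, k - i + 1);
    1.0 when no percentile falls below alpha.
    """
    p = np.asarray(percentiles, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("percentiles must be a non-empty 1-d array")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("percentiles must lie strictly in (0, 1)")
    if np.any(np.diff(p) < 0):
        raise ValueError("percentiles must be sorted ascending")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    k = len(p)
    i = np.arange(1, k + 1)
    qualify = p < alpha
    if not qualify.any():
        return 1.0
    vals = stats.beta.cdf(p[qualify], i[qualify], k - i[qualify] + 1)
    return float(vals.min())


def _rho_of_sorted(u_sorted: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized rho over rows of sorted uniforms (n_draws, k)."""
    n, k = u_sorted.shape
    i = np.arange(1, k + 1)
    beta_vals = stats.beta.cdf(u_sorted, i[None, :], (k - i + 1)[None, :])
    beta_vals = np.where(u_sorted < alpha, beta_vals, np.inf)
    rho = beta_vals.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def null_rho_distribution(
    k: int, alpha: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Sorted null rho draws for a gene with k guides."""
    if k <= 0:
        raise ValueError("k must be positive")
    u = np.sort(rng.random((n_perm, k)), axis=1)
    return np.sort(_rho_of_sorted(u, alpha))


def permutation_pvalue(
    rho_observed: float,
    k: int,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    null: np.ndarray | None = None,
) -> float:
    """Permutation p-value of an observed rho with the add-one convention.

    p = (1 + #{rho* <= rho_obs}) / (n_perm + 1) over ``n_perm`` draws of
    k uniform percentiles.  A precomputed sorted ``null`` (from
    :func:`null_rho_distribution`) may be supplied to share draws across
    genes with the same guide count.
    """
    if n_perm < 100:
        raise ValueError("n_perm >= 100 required")
    if null is None:
        null = null_rho_distribution(k, alpha, n_perm, np.random.default_rng(seed))
    n_le = int(np.searchsorted(null, rho_observed, side="right"))
    return (1 + n_le) / (len(null) + 1)


def score_screen(
    counts: CountMatrix,
    library: GuideLibrary,
    treatment_samples: list[str],
    control_samples: list[str],
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    nt_pseudogene_size: int | None = None,
) -> pd.DataFrame:
    """Full gene-ranking pipeline for one contrast (e.g. drug vs vehicle).

    Normalizes the matrix by median ratios, fits the control-arm
    variance trend, tests every guide, aggregates per-gene percentiles
    into alpha-RRA scores, and attaches permutation p-values (null draws
    shared across genes with equal guide counts) and dense ranks.
    Non-targeting guides are grouped into pseudo-genes of
    ``nt_pseudogene_size`` guides (default: the modal real-gene guide
    count) and scored identically, flagged via ``is_nt``.
    """
    for s in treatment_samples + control_samples:
        if s not in counts.counts.columns:
            raise KeyError(f"sample {s!r} not in count matrix")
    normalized, _ = median_ratio_normalize(counts)
    treat = normalized[treatment_samples]
    ctrl = normalized[control_samples]
    vm = fit_variance_model(ctrl)
    guide_res = sgrna_nb_test(treat, ctrl, vm)
    gene_of = library.gene_of().reindex(guide_res["sgrna_id"])
    is_nt = library.entries.set_index("sgrna_id")["is_nt"].reindex(
        guide_res["sgrna_id"]
    )

    # group NT guides into pseudo-genes for calibration
    real_sizes = library.entries.loc[~library.entries["is_nt"]].groupby("gene").size()
    if nt_pseudogene_size is None:
        nt_pseudogene_size = int(real_sizes.mode().iloc[0]) if len(real_sizes) else 6
    labels = gene_of.to_numpy(dtype=object).copy()
    nt_ids = np.flatnonzero(is_nt.to_numpy())
    for j, idx in enumerate(nt_ids):
        labels[idx] = f"NT_pseudo_{j // nt_pseudogene_size + 1:03d}"

    guide_res = guide_res.assign(gene=labels, is_nt=is_nt.to_numpy())
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for gene, sub in guide_res.groupby("gene", sort=True):
        perc = np.sort(sub["percentile"].to_numpy())
        k = len(perc)
        rho = rra_score(perc, alpha=alpha)
        if k not in null_cache:
            null_cache[k] = null_rho_distribution(k, alpha, n_perm, rng)
        p = permutation_pvalue(rho, k, alpha, n_perm, null=null_cache[k])
        rows.append(
            {
                "gene": gene,
                "rra_score": rho,
                "p_value": p,
                "n_guides": k,
                "n_guides_below_alpha": int((perc < alpha).sum()),
                "is_nt": bool(sub["is_nt"].all()),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["rra_score", "p_value", "gene"], kind="mergesort"
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)
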