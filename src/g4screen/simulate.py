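"""Synthetic data generators for every pipeline stage.

Each generator reproduces the statistical structure its downstream
consumer assumes, so the whole toolkit is exercisable without any
external dataset:

* :func:`simulate_screen` — negative-binomial sgRNA counts over a
  guide library (default 480 genes x 6 guides + 50 non-targeting =
  2930 guides) with planted essential and drug-interacting genes whose
  abundance decays by a chosen log2 fold-change per cell passage;
* :func:`simulate_cga` — DRX2+ proportions with Gaussian assay- and
  replicate-level variation on the logit scale and additive logit drug
  effects;
* :func:`simulate_checkerboard` — two-drug response surfaces that are
  exactly Bliss-consistent from two 4PL monotherapies, with optional
  planted synergy/antagonism bumps;
* :func:`simulate_doseresponse` — 4PL viability curves with
  multiplicative log-normal noise;
* :func:`simulate_blot` — densitometry tied to a loading-control
  covariate through a linear model on the log2 scale;
* :func:`simulate_foci` — per-cell focus counts from a two-component
  Poisson mixture with a focus-positive subpopulation.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cga import CgaExperiment
from .pharm import Checkerboard, FourPLParams, four_pl
from .screen_counts import CountMatrix, GuideLibrary

__all__ = [
    "ScreenSimConfig",
    "CgaSimConfig",
    "ScreenData",
    "simulate_library",
    "simulate_screen",
    "simulate_cga",
    "simulate_checkerboard",
    "simulate_doseresponse",
    "simulate_blot",
    "simulate_foci",
    "write_synthetic_fastq",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions for the dropout-screen generator.

    The library composition defaults to the screen's: 480 genes with 6
    guides each plus 50 non-targeting controls.  ``dispersion`` is the
    negative-binomial size parameter (larger = closer to Poisson);
    ``depth`` is the mean read count per guide.  ``essential_lfc`` and
    the per-entry lfc of ``interacting_genes`` are log2 fold-changes
    per passage; cells are passaged on ``passage_days`` (the screen's
    schedule of days 4, 7, 10, 13, 16 by default, harvest on day 19).
    ``abundance_sigma`` is the SD of log-normal guide representation in
    the plasmid pool.
    """

    n_genes: int = 480
    guides_per_gene: int = 6
    n_nontargeting: int = 50
    dispersion: float = 20.0
    depth: float = 500.0
    essential_fraction: float = 0.05
    essential_lfc: float = -1.0
    interacting_genes: tuple[tuple[str, str, float], ...] = ()
    timepoints: tuple[int, ...] = (1, 19)
    replicates: int = 3
    passage_days: tuple[int, ...] = (4, 7, 10, 13, 16)
    abundance_sigma: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0 or self.depth <= 0:
            raise ValueError("dispersion and depth must be positive")
        if not 0 <= self.essential_fraction <= 1:
            raise ValueError("essential_fraction must be in [0, 1]")
        if self.replicates < 1 or self.n_genes < 1 or self.guides_per_gene < 1:
            raise ValueError("counts must be positive")

    @property
    def n_guides_total(self) -> int:
        return self.n_genes * self.guides_per_gene + self.n_nontargeting

    def passages_by(self, day: int) -> int:
        return sum(1 for d in self.passage_days if d <= day)


@dataclass(frozen=True)
class CgaSimConfig:
    """Study conditions for the competitive-growth-assay generator.

    ``baseline_logit`` is the logit of the transduced (DRX2+) fraction
    in the vehicle arm; ``assay_sd`` and ``replicate_sd`` are Gaussian
    SDs on the logit scale at the two blocking levels (assay effects
    are shared across conditions within an assay, mirroring that each
    assay contains every treatment arm).  ``drug_effects`` maps drug
    condition labels to additive logit shifts.
    """

    n_assays: int = 3
    n_replicates: int = 3
    baseline_logit: float = 0.0
    assay_sd: float = 0.3
    replicate_sd: float = 0.15
    drug_effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assay_sd < 0 or self.replicate_sd < 0:
            raise ValueError("SDs must be non-negative")
        baseline = expit(self.baseline_logit)
        if not 0 < baseline < 1:
            raise ValueError("baseline proportion must lie strictly in (0, 1)")
        if self.n_assays < 1 or self.n_replicates < 1:
            raise ValueError("need >=1 assay and replicate")


@dataclass
class ScreenData:
    """A simulated screen: library, counts, and the planted truth."""

    library: GuideLibrary
    counts: CountMatrix
    essential_genes: list[str]
    interacting: dict[tuple[str, str], float]  # (gene, drug) -> lfc per passage


def _random_spacers(n: int, length: int, rng: np.random.Generator) -> list[str]:
    seen: set[str] = set()
    while len(seen) < n:
        block = rng.integers(0, 4, size=(n - len(seen), length))
        for row in block:
            seen.add("".join(_BASES[row]))
    return sorted(seen)[:n]  # sorted for determinism independent of set order


def simulate_library(config: ScreenSimConfig) -> GuideLibrary:
    """Deterministic guide library matching ``config`` composition."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB1B]))
    spacers = _random_spacers(config.n_guides_total, 20, rng)
    rows = []
    k = 0
    for g in range(1, config.n_genes + 1):
        gene = f"GENE{g:04d}"
        for j in range(1, config.guides_per_gene + 1):
            rows.append((f"{gene}_g{j}", gene, spacers[k], False))
            k += 1
    for j in range(1, config.n_nontargeting + 1):
        rows.append((f"NT_{j:03d}", "NT", spacers[k], True))
        k += 1
    return GuideLibrary(
        pd.DataFrame(rows, columns=["sgrna_id", "gene", "spacer", "is_nt"])
    )


def simulate_screen(config: ScreenSimConfig) -> ScreenData:
    """Negative-binomial dropout-screen counts with planted effects.

    Guide abundance starts from a log-normal plasmid representation and
    evolves multiplicatively: an essential gene's guides decay by
    ``essential_lfc`` log2 units per passage in every arm, and a
    drug-interacting gene's guides additionally decay by its listed lfc
    per passage in the matching drug arm only.  Abundances are
    renormalized per sample (sequencing reports relative composition at
    fixed depth) and counts drawn NB(size=dispersion, mean=depth-scaled
    abundance).  Samples span timepoints x replicates x conditions
    (vehicle plus one arm per distinct drug in ``interacting_genes``).
    """
    library = simulate_library(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    genes = [f"GENE{g:04d}" for g in range(1, config.n_genes + 1)]
    n_ess = round(config.essential_fraction * config.n_genes)
    essential = sorted(rng.choice(genes, size=n_ess, replace=False).tolist())
    interacting = {(g, d): lfc for g, d, lfc in config.interacting_genes}
    for gene, _ in interacting:
        if gene not in genes:
            raise ValueError(f"interacting gene {gene!r} not in simulated library")

    gene_col = library.entries["gene"].to_numpy()
    ess_mask = np.isin(gene_col, essential)
    baseline = rng.lognormal(mean=0.0, sigma=config.abundance_sigma,
                             size=config.n_guides_total)

    conditions = ["vehicle"] + sorted({d for _, d in interacting})
    total_reads = config.depth * config.n_guides_total
    col_counts = {}
    meta_rows = []
    for day in config.timepoints:
        passages = config.passages_by(day)
        for cond in conditions:
            lfc = np.where(ess_mask, config.essential_lfc * passages, 0.0)
            for (gene, drug), dlfc in interacting.items():
                if drug == cond:
                    lfc = lfc + np.where(gene_col == gene, dlfc * passages, 0.0)
            rel = baseline * np.exp2(lfc)
            mean = total_reads * rel / rel.sum()
            p = config.dispersion / (config.dispersion + mean)
            for rep in range(1, config.replicates + 1):
                sample = f"{cond}_d{day}_r{rep}"
                col_counts[sample] = rng.negative_binomial(config.dispersion, p)
                meta_rows.append((sample, cond, day, rep))
    counts = pd.DataFrame(col_counts, index=library.sgrna_ids)
    samples = pd.DataFrame(
        meta_rows, columns=["sample", "condition", "day", "replicate"]
    ).set_index("sample")
    return ScreenData(
        library=library,
        counts=CountMatrix(counts, samples),
        essential_genes=essential,
        interacting=interacting,
    )


def simulate_cga(config: CgaSimConfig, sgrna: str | None = None) -> CgaExperiment:
    """Logit-normal DRX2+ proportions for vehicle plus drug conditions.

    logit(p) = baseline + assay effect + drug effect + replicate noise,
    with assay effects shared across conditions within an assay.
    """
    rng = np.random.default_rng(config.seed)
    conditions = ["vehicle"] + sorted(config.drug_effects)
    assay_eff = rng.normal(0.0, config.assay_sd, size=config.n_assays)
    rows = []
    for a in range(config.n_assays):
        for cond in conditions:
            shift = config.drug_effects.get(cond, 0.0)
            noise = rng.normal(0.0, config.replicate_sd, size=config.n_replicates)
            logits = config.baseline_logit + assay_eff[a] + shift + noise
            for r, l in enumerate(logits, start=1):
                rows.append((a + 1, r, cond, float(expit(l))))
    df = pd.DataFrame(rows, columns=["assay", "replicate", "condition", "proportion"])
    if sgrna is not None:
        df.insert(0, "sgrna", sgrna)
    return CgaExperiment(df)


def simulate_checkerboard(
    doses_x: Sequence[float],
    doses_y: Sequence[float],
    monotherapy_params: tuple[FourPLParams, FourPLParams],
    synergy_bump: Mapping[tuple[int, int], float] | None = None,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> Checkerboard:
    """Bliss-consistent checkerboard with optional planted deviations.

    Monotherapy responses follow the two 4PL curves (surviving-fraction
    scale; use top=1 so untreated wells read 1).  Combination survival
    is the Bliss product of the two normalized monotherapy survivals,
    minus ``synergy_bump[(i, j)]`` (a planted inhibition excess, as a
    fraction, at dose indices i of x and j of y).  Additive Gaussian
    noise of SD ``noise_sd`` is applied to every well.
    """
    doses_x = np.asarray(sorted(doses_x), dtype=float)
    doses_y = np.asarray(sorted(doses_y), dtype=float)
    if len(doses_x) == 0 or len(doses_y) == 0 or (doses_x <= 0).any() or (doses_y <= 0).any():
        raise ValueError("dose lists must be non-empty and strictly positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    px, py = monotherapy_params
    bump = dict(synergy_bump or {})
    rng = np.random.default_rng(seed)

    untreated = 0.5 * (px.top + py.top)
    vx = np.asarray(four_pl(doses_x, *px), dtype=float)
    vy = np.asarray(four_pl(doses_y, *py), dtype=float)
    rows = []

    def add(dx, dy, value):
        for rep in range(1, replicates + 1):
            noisy = value + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append((dx, dy, rep, noisy))

    add(0.0, 0.0, untreated)
    for i, d in enumerate(doses_x):
        add(d, 0.0, vx[i])
    for j, d in enumerate(doses_y):
        add(0.0, d, vy[j])
    for i, dx in enumerate(doses_x):
        for j, dy in enumerate(doses_y):
            survival = untreated * (vx[i] / untreated) * (vy[j] / untreated)
            survival -= untreated * bump.get((i, j), 0.0)
            add(dx, dy, survival)
    return Checkerboard(
        pd.DataFrame(rows, columns=["dose_x", "dose_y", "replicate", "response"])
    )


def simulate_doseresponse(
    params_by_group: Mapping[str, FourPLParams],
    doses: Sequence[float],
    replicates: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """4PL viability tables with multiplicative log-normal noise.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    error; 0 gives the exact curve.  Returns a tidy frame with columns
    group, dose, replicate, response.
    """
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise ValueError("doses must be strictly positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    for group, p in params_by_group.items():
        clean = np.asarray(four_pl(doses, *p), dtype=float)
        for rep in range(1, replicates + 1):
            mult = rng.lognormal(-(sigma**2) / 2, sigma, size=len(doses)) if sigma > 0 else 1.0
            for d, v in zip(doses, clean * mult):
                rows.append((group, d, rep, v))
    return pd.DataFrame(rows, columns=["group", "dose", "replicate", "response"])


def simulate_blot(
    genotypes: Sequence[str] = ("WT", "KO"),
    treatments: Sequence[str] = ("vehicle", "drug"),
    lanes_per_cell: int = 2,
    intercept: float = 2.0,
    beta_load: float = 1.0,
    genotype_effects: Mapping[str, float] | None = None,
    treatment_effects: Mapping[str, float] | None = None,
    interaction_effects: Mapping[tuple[str, str], float] | None = None,
    loading_log2_mean: float = 10.0,
    loading_log2_sd: float = 0.5,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Densitometry tables from the ANCOVA generative model.

    log2(signal) = intercept + beta_load * log2(loading) + genotype +
    treatment + interaction + N(0, noise_sd); loading densities are
    log-normal.  Effect maps default to zero for unlisted levels.
    Returns columns lane, signal, loading, genotype, treatment.
    """
    if noise_sd < 0 or loading_log2_sd < 0:
        raise ValueError("SDs must be non-negative")
    g_eff = dict(genotype_effects or {})
    t_eff = dict(treatment_effects or {})
    gt_eff = dict(interaction_effects or {})
    rng = np.random.default_rng(seed)
    rows = []
    lane = 0
    for g in genotypes:
        for t in treatments:
            for _ in range(lanes_per_cell):
                lane += 1
                log2_load = rng.normal(loading_log2_mean, loading_log2_sd)
                log2_sig = (
                    intercept
                    + beta_load * log2_load
                    + g_eff.get(g, 0.0)
                    + t_eff.get(t, 0.0)
                    + gt_eff.get((g, t), 0.0)
                    + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                )
                rows.append((f"lane{lane:02d}", 2.0**log2_sig, 2.0**log2_load, g, t))
    return pd.DataFrame(
        rows, columns=["lane", "signal", "loading", "genotype", "treatment"]
    )


def simulate_foci(
    n_cells: int,
    positive_fraction: float,
    mu_positive: float,
    mu_background: float = 0.5,
    overlap_p: float = 0.0,
    marker: str = "FK2",
    condition: str = "drug",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell focus counts from a two-component Poisson mixture.

    A ``positive_fraction`` of cells draws counts from
    Poisson(mu_positive) (the focus-forming subpopulation), the rest
    from Poisson(mu_background).  Overlap counts with a secondary
    marker are Binomial(count, overlap_p).  Returns columns cell,
    marker, foci_count, overlap_count, condition.
    """
    if not 0 <= positive_fraction <= 1:
        raise ValueError("positive_fraction must be in [0, 1]")
    if mu_positive < 0 or mu_background < 0 or not 0 <= overlap_p <= 1:
        raise ValueError("invalid mixture parameters")
    rng = np.random.default_rng(seed)
    is_pos = rng.random(n_cells) < positive_fraction
    counts = np.where(
        is_pos,
        rng.poisson(mu_positive, size=n_cells),
        rng.poisson(mu_background, size=n_cells),
    )
    overlap = rng.binomial(counts, overlap_p)
    return pd.DataFrame(
        {
            "cell": [f"cell{i:05d}" for i in range(1, n_cells + 1)],
            "marker": marker,
            "foci_count": counts,
            "overlap_count": overlap,
            "condition": condition,
        }
    )


def write_synthetic_fastq(
    path: str | Path,
    library: GuideLibrary,
    reads_per_guide: Mapping[str, int],
    anchor: str,
    staggers: Sequence[str] = ("", "ACT", "GATCGA"),
    read_length: int = 75,
    seed: int = 0,
) -> int:
    """Emit synthetic 4-line FASTQ records embedding library spacers.

    Each read is stagger prefix + anchor + spacer + random filler,
    padded/truncated to ``read_length``; staggers cycle through the
    given prefixes, emulating the staggered forward primers of the
    sequencing design.  Returns the number of reads written.
    """
    rng = np.random.default_rng(seed)
    spacer_of = dict(zip(library.entries["sgrna_id"], library.entries["spacer"]))
    n = 0
    with open(path, "w") as out:
        for sgrna, count in reads_per_guide.items():
            spacer = spacer_of[sgrna]
            for _ in range(count):
                stagger = staggers[n % len(staggers)]
                core = stagger + anchor + spacer
                fill = "".join(rng.choice(_BASES, size=max(0, read_length - len(core))))
                seq = (core + fill)[:read_length]
                out.write(f"@read{n}\n{seq}\n+\n{'I' * len(seq)}\n")
                n += 1
    return n
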