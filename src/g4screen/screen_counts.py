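"""Guide libraries, sgRNA count matrices, and screen bookkeeping.

This module holds the data containers shared by the whole pipeline
(:class:`GuideLibrary`, :class:`CountMatrix`), readers/writers for their
plain-text formats, exact-match spacer counting from FASTQ, median-ratio
normalization, and the small arithmetic helpers used when planning a
screen (per-guide sequencing coverage, lentiviral titer).

Counting is deliberately strict: a read contributes to a guide's count
only when the 20-base spacer following the anchor sequence matches a
library spacer exactly.  Reads without the anchor, or with any mismatch
in the spacer, are tallied as unmapped.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GuideLibrary",
    "CountMatrix",
    "LibraryQcReport",
    "LibraryFormatError",
    "read_library",
    "write_library",
    "read_counts",
    "write_counts",
    "extract_counts",
    "median_ratio_normalize",
    "library_qc",
    "coverage_per_guide",
    "viral_titer",
]

_VALID_BASES = frozenset("ACGT")


class LibraryFormatError(ValueError):
    """Raised for malformed guide-library or count tables."""


@dataclass(frozen=True)
class GuideLibrary:
    """Mapping of sgRNA ids to genes and 20-mer spacer sequences.

    Non-targeting controls carry ``is_nt=True`` and, by convention, the
    gene label ``"NT"``.
    """

    entries: pd.DataFrame  # columns: sgrna_id, gene, spacer, is_nt

    def __post_init__(self) -> None:
        df = self.entries
        required = ["sgrna_id", "gene", "spacer", "is_nt"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise LibraryFormatError(f"library table missing columns {missing}")
        if df["sgrna_id"].duplicated().any():
            dups = df.loc[df["sgrna_id"].duplicated(), "sgrna_id"].tolist()
            raise LibraryFormatError(f"duplicate sgrna_id(s): {dups[:5]}")
        lengths = df["spacer"].str.len().unique()
        if len(lengths) > 1:
            raise LibraryFormatError(
                f"spacers must share one length, found {sorted(lengths)}"
            )
        bad = ~df["spacer"].map(lambda s: set(s) <= _VALID_BASES)
        if bad.any():
            first = df.loc[bad].index[0]
            raise LibraryFormatError(
                f"non-ACGT spacer at row {first}: {df.loc[first, 'spacer']!r}"
            )

    @property
    def sgrna_ids(self) -> pd.Index:
        return pd.Index(self.entries["sgrna_id"])

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.entries.loc[~self.entries["is_nt"], "gene"].unique())

    @property
    def spacer_length(self) -> int:
        return int(self.entries["spacer"].str.len().iloc[0])

    def __len__(self) -> int:
        return len(self.entries)

    def spacer_index(self) -> dict[str, str]:
        """spacer -> sgrna_id lookup for exact-match counting."""
        return dict(zip(self.entries["spacer"], self.entries["sgrna_id"]))

    def gene_of(self) -> pd.Series:
        return self.entries.set_index("sgrna_id")["gene"]


@dataclass
class CountMatrix:
    """sgRNA x sample counts plus per-sample metadata.

    ``counts`` is indexed by sgrna_id with one column per sample id;
    ``samples`` is indexed by sample id with columns ``condition``,
    ``day`` and ``replicate``.  ``unmapped`` records, per sample, reads
    that could not be assigned to any library spacer.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    unmapped: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(pd.Index(self.samples.index)):
            raise LibraryFormatError(
                "count columns and sample metadata index do not match"
            )
        if (self.counts.to_numpy() < 0).any():
            raise LibraryFormatError("counts must be non-negative")
        for col in ("condition", "day", "replicate"):
            if col not in self.samples.columns:
                raise LibraryFormatError(f"sample metadata missing {col!r}")
        if self.unmapped is None:
            self.unmapped = pd.Series(0, index=self.samples.index)

    @property
    def n_guides(self) -> int:
        return self.counts.shape[0]

    def select(self, **criteria) -> list[str]:
        """Sample ids whose metadata match all given column=value pairs."""
        mask = pd.Series(True, index=self.samples.index)
        for col, val in criteria.items():
            mask &= self.samples[col] == val
        return list(self.samples.index[mask])


@dataclass(frozen=True)
class LibraryQcReport:
    percent_detected: float
    quantile_fold_difference: float
    zero_count_guides: list[str] = field(default_factory=list)
    central_mass: float = 0.80

    def to_json(self) -> str:
        return json.dumps(
            {
                "percent_detected": self.percent_detected,
                "quantile_fold_difference": self.quantile_fold_difference,
                "zero_count_guides": self.zero_count_guides,
                "central_mass": self.central_mass,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_library(path: str | Path) -> GuideLibrary:
    """Read a tab-separated guide library (sgrna_id, gene, spacer, is_nt).

    The ``is_nt`` column is optional; when absent, entries with gene
    label ``NT`` are flagged as non-targeting.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sgrna_id": str, "gene": str, "spacer": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise LibraryFormatError(f"cannot parse {path}: {exc}") from exc
    for col in ("sgrna_id", "gene", "spacer"):
        if col not in df.columns:
            raise LibraryFormatError(f"{path}: missing column {col!r}")
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 2  # 1-based incl. header
            raise LibraryFormatError(f"{path}: empty {col!r} at line {row}")
    df["spacer"] = df["spacer"].str.upper()
    if "is_nt" not in df.columns:
        df["is_nt"] = df["gene"].str.upper() == "NT"
    else:
        df["is_nt"] = df["is_nt"].astype(bool)
    return GuideLibrary(df.reset_index(drop=True))


def write_library(library: GuideLibrary, path: str | Path) -> None:
    library.entries.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count TSV with three metadata header rows.

    Layout: row 1 ``condition``, row 2 ``day``, row 3 ``replicate``,
    then one row per sgRNA.  First column is the sgrna_id.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=[0, 1, 2, 3], index_col=0)
    sample_ids = [t[0] for t in raw.columns]
    samples = pd.DataFrame(
        {
            "condition": [t[1] for t in raw.columns],
            "day": [int(t[2]) for t in raw.columns],
            "replicate": [int(t[3]) for t in raw.columns],
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    counts = raw.copy()
    counts.columns = samples.index
    return CountMatrix(counts, samples)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    out.columns = pd.MultiIndex.from_arrays(
        [
            cm.samples.index,
            cm.samples["condition"],
            cm.samples["day"].astype(str),
            cm.samples["replicate"].astype(str),
        ],
        names=["sample", "condition", "day", "replicate"],
    )
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# FASTQ spacer extraction


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def extract_counts(
    fastq_path: str | Path,
    library: GuideLibrary,
    anchor: str,
    sample_id: str = "sample",
    condition: str = "na",
    day: int = 0,
    replicate: int = 1,
) -> CountMatrix:
    """Count exact spacer matches in a FASTQ file for a single sample.

    Each read is scanned for ``anchor`` (the invariant vector sequence
    immediately 5' of the spacer) at any offset, which accommodates the
    staggered forward primers used to diversify the flow cell.  The
    ``spacer_length`` bases following the first anchor occurrence are
    looked up in the library with no mismatches allowed; anything else
    increments the unmapped tally.
    """
    anchor = anchor.upper()
    if not anchor or not set(anchor) <= _VALID_BASES:
        raise ValueError(f"anchor must be a non-empty ACGT string, got {anchor!r}")
    lookup = library.spacer_index()
    k = library.spacer_length
    counts: dict[str, int] = dict.fromkeys(library.sgrna_ids, 0)
    unmapped = 0
    path = Path(fastq_path)
    if not path.exists():
        raise IOError(f"FASTQ not found: {path}")
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fastq"):
            seq = str(record.seq).upper()
            pos = seq.find(anchor)
            if pos < 0:
                unmapped += 1
                continue
            spacer = seq[pos + len(anchor) : pos + len(anchor) + k]
            sgrna = lookup.get(spacer)
            if sgrna is None:
                unmapped += 1
            else:
                counts[sgrna] += 1
    counts_df = pd.DataFrame(
        {sample_id: pd.Series(counts, dtype=int)}
    ).reindex(library.sgrna_ids)
    samples = pd.DataFrame(
        {"condition": [condition], "day": [day], "replicate": [replicate]},
        index=pd.Index([sample_id], name="sample"),
    )
    return CountMatrix(
        counts_df, samples, unmapped=pd.Series([unmapped], index=samples.index)
    )


# ---------------------------------------------------------------------------
# normalization and QC


def median_ratio_normalize(
    cm: CountMatrix, min_eligible: int = 100
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization across samples.

    The size factor of a sample is the median, over guides with a
    nonzero geometric mean across samples, of count / geometric mean.
    When fewer than ``min_eligible`` guides qualify the procedure falls
    back to total-count scaling.  Returns (normalized counts, size
    factors); normalized values are real-valued.
    """
    counts = cm.counts
    if counts.shape[1] < 2:
        raise ValueError(
            "median-ratio normalization needs >=2 samples; "
            "scale by total counts for a single sample"
        )
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_geo = np.log(arr).mean(axis=1)
    eligible = np.isfinite(log_geo)
    if eligible.sum() < min_eligible:
        factors = totals / totals.mean()
    else:
        ratios = arr[eligible] / np.exp(log_geo[eligible])[:, None]
        factors = pd.Series(np.median(ratios, axis=0), index=counts.columns)
    factors.name = "size_factor"
    normalized = counts / factors
    return normalized, factors


def library_qc(
    cm: CountMatrix,
    library: GuideLibrary | None = None,
    central_mass: float = 0.80,
    sample: str | None = None,
) -> LibraryQcReport:
    """Representation QC of a (plasmid-pool) sample.

    ``percent_detected`` is the percentage of guides with nonzero count;
    ``quantile_fold_difference`` is the ratio of the upper to the lower
    quantile bracketing the central ``central_mass`` of detected guide
    counts (90th/10th percentile at the default 0.80).
    """
    if not 0 < central_mass < 1:
        raise ValueError("central_mass must be in (0, 1)")
    if cm.counts.empty:
        raise ValueError("empty count matrix")
    col = sample if sample is not None else cm.counts.columns[0]
    counts = cm.counts[col]
    if library is not None:
        counts = counts.reindex(library.sgrna_ids).fillna(0)
    detected = counts > 0
    percent_detected = 100.0 * detected.sum() / len(counts)
    nonzero = counts[detected].to_numpy(dtype=float)
    if nonzero.size == 0:
        fold = float("nan")
    else:
        lo = np.quantile(nonzero, 0.5 - central_mass / 2)
        hi = np.quantile(nonzero, 0.5 + central_mass / 2)
        fold = float(hi / lo)
    return LibraryQcReport(
        percent_detected=float(percent_detected),
        quantile_fold_difference=fold,
        zero_count_guides=list(counts.index[~detected]),
        central_mass=central_mass,
    )


# ---------------------------------------------------------------------------
# planning arithmetic


def coverage_per_guide(
    dna_mass_ug: float, n_guides: int, pg_per_cell: float = 7.5
) -> float:
    """Fold sequencing coverage per guide from a genomic DNA input.

    Assumes ``pg_per_cell`` picograms of genomic DNA per diploid cell
    (default 7.5 pg), so coverage = cells represented / guides =
    (mass in pg / pg per cell) / n_guides.
    """
    if dna_mass_ug <= 0 or n_guides <= 0 or pg_per_cell <= 0:
        raise ValueError("mass, guide count and pg/cell must be positive")
    return dna_mass_ug * 1e6 / pg_per_cell / n_guides


def viral_titer(
    survival_fraction: float, cells_per_well: float, virus_volume_ul: float
) -> float:
    """Transducing units per mL from a puromycin-survival titration.

    titer = survival fraction x cells per well x 1000 / virus volume (uL).
    """
    if not 0 <= survival_fraction <= 1:
        raise ValueError("survival_fraction must be in [0, 1]")
    if virus_volume_ul <= 0:
        raise ValueError("virus volume must be positive")
    if cells_per_well <= 0:
        raise ValueError("cells per well must be positive")
    return survival_fraction * cells_per_well * 1000.0 / virus_volume_ul
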