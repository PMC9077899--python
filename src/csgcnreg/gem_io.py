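"""Gene expression matrix (GEM) I/O, merging, normalization and QC screening.

A GEM is a genes x samples table of RNA abundance (FPKM on the linear
scale, or log2 FPKM after normalization).  Missing values are carried as
NaN and excluded from every downstream statistic; they are never imputed.

The normalization recipe is the standard bulk RNA-seq one: log2 transform
(zeros become missing, i.e. log2 of raw FPKM with no pseudocount),
quantile normalization of each sample against the mean sorted profile,
and a Kolmogorov-Smirnov screen that flags samples whose expression
distribution drifts from the pooled remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GEM",
    "SampleAnnotation",
    "load_gem",
    "write_gem",
    "load_annotation",
    "write_annotation",
    "merge_gems",
    "log2_quantile_normalize",
    "ks_outlier_detect",
]

LINEAR = "linear"
LOG2 = "log2"


@dataclass
class GEM:
    """Genes x samples expression matrix.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and sample ids as columns.
        NaN marks a missing measurement.
    scale
        ``"linear"`` (FPKM-like) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"unknown scale marker: {self.scale!r}")
        self.values = self.values.astype(float)
        self.values.index.name = "gene"
        self.values.columns.name = None

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True where the measurement is missing."""
        return self.values.isna()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "GEM":
        return GEM(self.values.loc[:, list(sample_ids)].copy(), scale=self.scale)

    def subset_genes(self, gene_ids: Sequence[str]) -> "GEM":
        return GEM(self.values.loc[list(gene_ids), :].copy(), scale=self.scale)


@dataclass
class SampleAnnotation:
    """Maps each sample to a categorical condition label plus optional
    real-valued covariates (e.g. age, tumor stage score)."""

    condition: pd.Series  # sample id -> condition label
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.condition.index.has_duplicates:
            raise ValueError("duplicate sample ids in annotation")
        self.condition = self.condition.astype(str)
        if self.covariates.empty:
            self.covariates = pd.DataFrame(index=self.condition.index)

    @property
    def sample_ids(self) -> pd.Index:
        return self.condition.index

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels, in first-appearance order."""
        return list(dict.fromkeys(self.condition))

    def samples_of(self, condition: str) -> pd.Index:
        return self.condition.index[self.condition == condition]

    def validate_against(self, gem: GEM) -> None:
        missing = self.condition.index.difference(gem.sample_ids)
        if len(missing) > 0:
            raise ValueError(
                f"annotated samples absent from GEM: {sorted(missing)[:10]}"
            )

    def subset(self, sample_ids: Sequence[str]) -> "SampleAnnotation":
        ids = list(sample_ids)
        return SampleAnnotation(
            self.condition.loc[ids].copy(), self.covariates.loc[ids].copy()
        )


# ---------------------------------------------------------------------------
# TSV dialect: tab separated, UTF-8, first header cell empty or "gene",
# "NA" (or empty) for missing.
# ---------------------------------------------------------------------------


def load_gem(path: str | Path, scale: str = LINEAR) -> GEM:
    """Read a GEM from a tab-delimited file.

    First row is the sample header, first column the gene ids.  ``NA`` or
    empty cells become missing.  Duplicate gene or sample ids and ragged
    rows are hard errors.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_fields = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() == "":
                continue
            if len(line.rstrip("\n").split("\t")) != n_fields:
                raise ValueError(f"ragged row at line {lineno} of {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in {path}: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in {path}: {dups}")
    return GEM(df, scale=scale)


def write_gem(gem: GEM, path: str | Path) -> None:
    """Write a GEM in the TSV dialect (repr-round-trip floats, NA for missing)."""
    df = gem.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", na_rep="NA", float_format=lambda x: repr(float(x)))


def load_annotation(path: str | Path) -> SampleAnnotation:
    """Read an annotation TSV with columns ``sample``, ``condition`` and
    optional numeric covariate columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str})
    for col in ("sample", "condition"):
        if col not in df.columns:
            raise ValueError(f"annotation file {path} lacks required column {col!r}")
    df = df.set_index("sample")
    covars = df.drop(columns=["condition"]).apply(pd.to_numeric)
    return SampleAnnotation(df["condition"], covars)


def write_annotation(annot: SampleAnnotation, path: str | Path) -> None:
    df = annot.covariates.copy()
    df.insert(0, "condition", annot.condition)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def merge_gems(
    gems: Sequence[GEM], annotations: Sequence[SampleAnnotation]
) -> tuple[GEM, SampleAnnotation]:
    """Column-concatenate GEMs measured on the same gene set.

    Gene order follows the first input; the other inputs are row-aligned
    to it.  Sample ids must be globally unique.
    """
    if len(gems) != len(annotations):
        raise ValueError("one annotation per GEM required")
    if not gems:
        raise ValueError("no GEMs to merge")
    ref_genes = gems[0].gene_ids
    for i, g in enumerate(gems[1:], start=1):
        if set(g.gene_ids) != set(ref_genes):
            diff = sorted(set(g.gene_ids).symmetric_difference(ref_genes))
            raise ValueError(f"gene sets differ (input 0 vs {i}): {diff[:20]}")
    scales = {g.scale for g in gems}
    if len(scales) > 1:
        raise ValueError(f"cannot merge GEMs on different scales: {scales}")
    frames = [g.values.reindex(ref_genes) for g in gems]
    all_samples = pd.Index(np.concatenate([f.columns for f in frames]))
    if all_samples.has_duplicates:
        dups = all_samples[all_samples.duplicated()].unique().tolist()
        raise ValueError(f"sample id collision across inputs: {dups}")
    merged = pd.concat(frames, axis=1)
    cond = pd.concat([a.condition for a in annotations])
    covars = pd.concat([a.covariates for a in annotations])
    merged_annot = SampleAnnotation(cond.loc[merged.columns], covars.loc[merged.columns])
    gem = GEM(merged, scale=gems[0].scale)
    merged_annot.validate_against(gem)
    return gem, merged_annot


def log2_quantile_normalize(gem: GEM) -> GEM:
    """log2-transform a linear-scale GEM and quantile-normalize samples.

    Zeros map to missing (log2 FPKM without a pseudocount).  Each sample's
    non-missing values are then replaced by the mean sorted profile across
    samples, interpolated at the sample's own quantile ranks; ties share
    the average of their ranks' reference values, so permuted columns
    normalize to identical columns.
    """
    if gem.scale != LINEAR:
        raise ValueError("input GEM must be on the linear scale")
    vals = gem.values.to_numpy(copy=True)
    if np.nanmin(vals) < 0:
        raise ValueError("negative expression value: input is not linear-scale FPKM")
    vals[vals == 0] = np.nan
    logged = np.log2(vals)

    # Reference profile: mean of per-sample sorted vectors.  Columns may
    # hold different numbers of non-missing values, so each sorted column
    # is mapped onto a common quantile grid first.
    n_genes, n_samples = logged.shape
    grid = np.linspace(0.0, 1.0, n_genes)
    sorted_cols = np.full((n_genes, n_samples), np.nan)
    for j in range(n_samples):
        col = logged[:, j]
        obs = np.sort(col[~np.isnan(col)])
        if obs.size == 0:
            continue
        if obs.size == 1:
            sorted_cols[:, j] = obs[0]
        else:
            q = np.linspace(0.0, 1.0, obs.size)
            sorted_cols[:, j] = np.interp(grid, q, obs)
    reference = np.nanmean(sorted_cols, axis=1)

    out = np.full_like(logged, np.nan)
    for j in range(n_samples):
        col = logged[:, j]
        ok = ~np.isnan(col)
        n_ok = int(ok.sum())
        if n_ok == 0:
            continue
        # average ranks for ties, mapped to reference quantiles
        ranks = stats.rankdata(col[ok], method="average")
        q = (ranks - 1) / max(n_ok - 1, 1)
        out[ok, j] = np.interp(q, grid, reference)
    df = pd.DataFrame(out, index=gem.gene_ids, columns=gem.sample_ids)
    return GEM(df, scale=LOG2)


def ks_outlier_detect(
    gem: GEM, threshold: float = 0.15
) -> tuple[list[str], list[str]]:
    """Flag distributional outlier samples by a two-sample KS screen.

    For each sample, the KS statistic D is computed between that sample's
    non-missing values and the pooled values of all other samples; the
    sample is flagged iff D > ``threshold``.  Flagging only — removing
    flagged samples is the caller's decision.

    Returns ``(flagged, undefined)`` where ``undefined`` lists samples
    with fewer than two non-missing values (D cannot be computed).
    """
    vals = gem.values.to_numpy()
    flagged: list[str] = []
    undefined: list[str] = []
    col_data = [v[~np.isnan(v)] for v in vals.T]
    for j, sample in enumerate(gem.sample_ids):
        own = col_data[j]
        if own.size < 2:
            undefined.append(sample)
            continue
        others = np.concatenate([col_data[k] for k in range(len(col_data)) if k != j])
        if others.size == 0:
            undefined.append(sample)
            continue
        d = stats.ks_2samp(own, others, method="asymp").statistic
        if d > threshold:
            flagged.append(sample)
    return flagged, undefined
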