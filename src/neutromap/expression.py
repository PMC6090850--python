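"""Uniform-gene FPKM normalization and expression-matrix manipulation.

Cross-dataset comparison of RNA-seq expression requires putting FPKM
matrices produced by different labs on a common scale.  The strategy used
here anchors each sample on its "uniform genes" -- genes whose expression
falls between the 50th and 90th percentile in *every* sample -- and rescales
each sample so the geometric mean of those genes matches a reference group
of samples.  Downstream steps (log10 transform with a floor for zero
counts, two-stage geometric-mean replicate averaging with equal lab
weighting, homolog and gene-type restriction) live here as well.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "UniformGeneSet",
    "ScalingFactors",
    "HomologMap",
    "identify_uniform_genes",
    "compute_scaling_factors",
    "normalize",
    "log_transform",
    "average_replicates",
    "restrict_to_homologs",
    "filter_gene_type",
]

#: Sample-metadata columns every ExpressionMatrix must carry.
META_COLUMNS = ("species", "lab", "condition", "replicate", "day")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample.  On the
        ``"linear"`` scale values are FPKM-like and must be nonnegative;
        on the ``"log10"`` scale values may be negative (floored logs).
    sample_meta
        DataFrame indexed by sample name with columns ``species``, ``lab``,
        ``condition``, ``replicate``, ``day`` and optionally a boolean
        ``reference_group`` flag marking the samples whose mean scaling
        factor anchors normalization.
    scale
        ``"linear"`` (FPKM) or ``"log10"``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and (vals < 0).any():
            raise ValueError("FPKM-scale expression values must be nonnegative")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in META_COLUMNS:
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta missing column {col!r}")
        if "reference_group" not in self.sample_meta.columns:
            self.sample_meta = self.sample_meta.assign(reference_group=False)

    # -- convenience -------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def meta_for(self, sample: str) -> pd.Series:
        return self.sample_meta.loc[sample]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        meta = self.sample_meta.loc[list(values.columns)]
        return ExpressionMatrix(values, meta, scale or self.scale)


@dataclass(frozen=True)
class UniformGeneSet:
    """Genes lying within the per-sample percentile band in every sample."""

    gene_ids: tuple
    lower_percentile: float
    upper_percentile: float
    bounds: pd.DataFrame = field(repr=False)  # per-sample lower/upper values

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class ScalingFactors:
    """Per-sample geometric-mean factors plus the reference-group mean."""

    factors: pd.Series
    reference_mean: float
    reference_samples: tuple

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("scaling factors must be positive")
        if self.reference_mean <= 0:
            raise ValueError("reference mean factor must be positive")


class HomologMap:
    """Pairs of homologous gene ids between two species.

    A thin wrapper over a two-column table; duplicate pairs are dropped and
    the multiplicity of each gene on either side is tracked so one-to-many
    mappings can be filtered.
    """

    def __init__(self, pairs: pd.DataFrame | Iterable[tuple]):
        if not isinstance(pairs, pd.DataFrame):
            pairs = pd.DataFrame(list(pairs), columns=["gene_a", "gene_b"])
        if pairs.shape[1] != 2:
            raise ValueError("homolog map requires exactly two columns")
        pairs = pairs.copy()
        pairs.columns = ["gene_a", "gene_b"]
        self.pairs = pairs.drop_duplicates(ignore_index=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def one_to_one(self) -> pd.DataFrame:
        """Pairs where both genes map uniquely."""
        p = self.pairs
        uniq_a = p["gene_a"].map(p["gene_a"].value_counts()) == 1
        uniq_b = p["gene_b"].map(p["gene_b"].value_counts()) == 1
        return p[uniq_a & uniq_b].reset_index(drop=True)

    def first_listed(self) -> pd.DataFrame:
        """One pair per gene, keeping the first listed partner."""
        p = self.pairs.drop_duplicates(subset="gene_a", keep="first")
        return p.drop_duplicates(subset="gene_b", keep="first").reset_index(drop=True)


# ---------------------------------------------------------------------------
# operations


def identify_uniform_genes(
    matrix: ExpressionMatrix,
    lower: float = 50.0,
    upper: float = 90.0,
) -> UniformGeneSet:
    """Find genes within the [lower, upper] expression percentile in all samples.

    Percentiles are computed per sample over all genes (zeros included) with
    linear interpolation; band membership is inclusive at both bounds.  When
    a sample's lower bound is 0 the membership additionally requires a
    strictly positive value so geometric means stay defined downstream.
    """
    if matrix.n_samples < 1 or matrix.n_genes < 10:
        raise ValueError("need at least 1 sample and 10 genes")
    if matrix.scale != "linear":
        raise ValueError("uniform genes are identified on the linear (FPKM) scale")
    vals = matrix.values
    lo = vals.quantile(lower / 100.0, axis=0, interpolation="linear")
    hi = vals.quantile(upper / 100.0, axis=0, interpolation="linear")
    member = (vals.ge(lo, axis=1) & vals.le(hi, axis=1)).all(axis=1)
    # guard the degenerate case P50 == 0: require positivity everywhere
    if (lo == 0).any():
        member &= (vals > 0).all(axis=1)
    genes = tuple(vals.index[member])
    if not genes:
        warnings.warn("uniform gene set is empty", stacklevel=2)
    bounds = pd.DataFrame({"lower": lo, "upper": hi})
    return UniformGeneSet(genes, lower, upper, bounds)


def compute_scaling_factors(
    matrix: ExpressionMatrix,
    uniform: UniformGeneSet,
    reference_samples: Sequence[str] | None = None,
    reference_stat: str = "arithmetic",
) -> ScalingFactors:
    """Per-sample geometric mean of the uniform genes, plus the reference mean.

    The per-sample factor is ``exp(mean(log(v)))`` over the uniform genes;
    the reference mean is the arithmetic (default) or geometric mean of the
    factors over the reference samples.  Reference samples default to those
    flagged ``reference_group`` in the metadata, or all samples if none are
    flagged.
    """
    if len(uniform) == 0:
        raise ValueError("uniform gene set is empty")
    sub = matrix.values.loc[list(uniform.gene_ids)]
    zero_mask = sub <= 0
    if zero_mask.to_numpy().any():
        gene = sub.index[zero_mask.any(axis=1)][0]
        sample = sub.columns[zero_mask.any(axis=0)][0]
        raise ValueError(
            f"uniform gene {gene!r} has nonpositive value in sample {sample!r}"
        )
    factors = np.exp(np.log(sub).mean(axis=0))
    factors.name = "scaling_factor"
    if reference_samples is None:
        flagged = matrix.sample_meta["reference_group"].astype(bool)
        reference_samples = list(flagged.index[flagged])
        if not reference_samples:
            reference_samples = list(matrix.samples)
    ref = factors.loc[list(reference_samples)]
    if reference_stat == "arithmetic":
        ref_mean = float(ref.mean())
    elif reference_stat == "geometric":
        ref_mean = float(np.exp(np.log(ref).mean()))
    else:
        raise ValueError(f"unknown reference_stat {reference_stat!r}")
    return ScalingFactors(factors, ref_mean, tuple(reference_samples))


def normalize(matrix: ExpressionMatrix, factors: ScalingFactors) -> ExpressionMatrix:
    """Divide each sample by its factor and multiply by the reference mean."""
    missing = set(matrix.samples) - set(factors.factors.index)
    if missing:
        raise ValueError(f"samples without scaling factor: {sorted(missing)}")
    scaled = matrix.values.div(factors.factors[matrix.samples], axis=1) * factors.reference_mean
    return matrix.with_values(scaled)


def log_transform(
    matrix: ExpressionMatrix,
    zero_value: float = -4.0,
    floor: float = -4.0,
) -> ExpressionMatrix:
    """log10-transform FPKM values; zeros map to ``zero_value``.

    Positive values below ``10**floor`` are floored to ``floor`` so the
    codomain is bounded below by ``min(zero_value, floor)``.
    """
    if matrix.scale != "linear":
        raise ValueError("input must be on the linear (FPKM) scale")
    vals = matrix.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative expression values")
    out = np.full_like(vals, zero_value)
    pos = vals > 0
    out[pos] = np.maximum(np.log10(vals[pos]), floor)
    logged = pd.DataFrame(out, index=matrix.genes, columns=matrix.samples)
    return matrix.with_values(logged, scale="log10")


def average_replicates(
    matrix: ExpressionMatrix,
    groups: Mapping[str, str] | pd.Series | None = None,
) -> ExpressionMatrix:
    """Two-stage replicate averaging on the log scale with equal lab weight.

    Arithmetic means of log10 values are geometric means of the raw values.
    Within each final group, samples are first averaged within each lab, then
    the per-lab means are averaged with equal weight so no lab dominates by
    replicate count.

    Parameters
    ----------
    groups
        Mapping from sample name to final group label.  Defaults to the
        ``condition`` metadata column.
    """
    if matrix.scale != "log10":
        raise ValueError("replicate averaging operates on the log10 scale")
    if groups is None:
        groups = matrix.sample_meta["condition"]
    groups = pd.Series(groups)
    missing = set(matrix.samples) - set(groups.index)
    if missing:
        raise ValueError(f"samples without group assignment: {sorted(missing)}")
    labs = matrix.sample_meta["lab"]
    out = {}
    meta_rows = {}
    for grp in pd.unique(groups[matrix.samples]):
        cols = [s for s in matrix.samples if groups[s] == grp]
        if not cols:
            raise ValueError(f"group {grp!r} has no samples")
        lab_means = []
        for lab in pd.unique(labs[cols]):
            lab_cols = [s for s in cols if labs[s] == lab]
            lab_means.append(matrix.values[lab_cols].mean(axis=1))
        out[grp] = pd.concat(lab_means, axis=1).mean(axis=1)
        first = matrix.sample_meta.loc[cols[0]]
        meta_rows[grp] = {
            "species": first["species"],
            "lab": "pooled" if labs[cols].nunique() > 1 else first["lab"],
            "condition": grp,
            "replicate": 0,
            "day": first["day"],
            "reference_group": bool(matrix.sample_meta.loc[cols, "reference_group"].any()),
        }
    values = pd.DataFrame(out)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    return ExpressionMatrix(values, meta, scale="log10")


def restrict_to_homologs(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    homologs: HomologMap,
    policy: str = "one_to_one",
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two matrices to homologous gene pairs, row-aligned.

    ``policy="one_to_one"`` (default) drops multi-mapped genes;
    ``policy="first_listed"`` keeps the first listed partner of each gene.
    Rows are sorted by the species-A gene id for determinism.
    """
    if len(homologs) == 0:
        raise ValueError("homolog map is empty")
    if policy == "one_to_one":
        pairs = homologs.one_to_one()
    elif policy == "first_listed":
        pairs = homologs.first_listed()
    else:
        raise ValueError(f"unknown policy {policy!r}")
    keep = pairs[
        pairs["gene_a"].isin(matrix_a.genes) & pairs["gene_b"].isin(matrix_b.genes)
    ].sort_values("gene_a", kind="stable")
    if keep.empty:
        raise ValueError("no homolog pairs overlap both matrices")
    a = matrix_a.with_values(matrix_a.values.loc[keep["gene_a"]])
    b = matrix_b.with_values(matrix_b.values.loc[keep["gene_b"]])
    return a, b


def filter_gene_type(
    matrix: ExpressionMatrix,
    annotation: Mapping[str, str] | pd.Series,
    keep: str = "protein-coding",
) -> ExpressionMatrix:
    """Keep only genes annotated with the given type (e.g. protein-coding)."""
    annotation = pd.Series(annotation)
    types = annotation.reindex(matrix.genes)
    n_unannotated = int(types.isna().sum())
    if n_unannotated:
        logger.info("dropping %d unannotated genes", n_unannotated)
    mask = (types == keep).to_numpy()
    if not mask.any():
        warnings.warn(f"no genes of type {keep!r} retained", stacklevel=2)
    return matrix.with_values(matrix.values.loc[mask])
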