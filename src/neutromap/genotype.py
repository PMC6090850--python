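"""Sample-identity testing from genotype calls.

Cell-line authentication from RNA-seq variant calls: loci are filtered on
per-sample read depth and site quality, then every pair of samples is
scored by the fraction of loci at which their unphased genotypes are
identical.  Replicates and sub-lines of the same line score 1.0; unrelated
donors fall well below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeTable",
    "ConcordanceMatrix",
    "normalize_genotype",
    "filter_loci",
    "pairwise_identity",
]


def normalize_genotype(gt: str) -> tuple:
    """Canonical unphased representation of a genotype call.

    ``"1/0"``, ``"0/1"`` and ``"0|1"`` all normalize to ``("0", "1")``:
    identity is defined on allele multisets, so phase is ignored.
    """
    alleles = gt.replace("|", "/").split("/")
    return tuple(sorted(alleles))


@dataclass
class GenotypeTable:
    """Loci x samples genotype calls with depths and site quality.

    Parameters
    ----------
    loci
        DataFrame with columns ``chrom``, ``pos``, ``ref``, ``alt``,
        ``qual``; one row per locus, positions unique per chromosome.
    genotypes
        DataFrame (same index as ``loci``) of genotype strings like
        ``"0/1"``, one column per sample.
    depths
        DataFrame of per-sample read depths, aligned with ``genotypes``.
    """

    loci: pd.DataFrame
    genotypes: pd.DataFrame
    depths: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("chrom", "pos", "ref", "alt", "qual"):
            if col not in self.loci.columns:
                raise ValueError(f"loci table missing column {col!r}")
        if self.loci.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) loci")
        if not (self.loci.index.equals(self.genotypes.index) and
                self.loci.index.equals(self.depths.index)):
            raise ValueError("loci, genotypes and depths must share an index")
        if list(self.genotypes.columns) != list(self.depths.columns):
            raise ValueError("genotypes and depths must share sample columns")
        if (self.depths.to_numpy() < 0).any():
            raise ValueError("read depths must be nonnegative")

    @property
    def samples(self) -> list:
        return list(self.genotypes.columns)

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class ConcordanceMatrix:
    """Pairwise fractions of loci with identical genotypes."""

    fractions: pd.DataFrame
    n_loci: int


def filter_loci(
    table: GenotypeTable,
    min_depth: int = 10,
    min_qual: float = 100.0,
) -> GenotypeTable:
    """Keep loci with depth >= min_depth in every sample and quality > min_qual.

    The depth bound is inclusive and must hold in all samples; the quality
    bound is strict.  Raises if no locus survives.
    """
    if table.n_loci == 0:
        raise ValueError("empty genotype table")
    depth_ok = (table.depths >= min_depth).all(axis=1)
    qual_ok = table.loci["qual"] > min_qual
    keep = depth_ok & qual_ok
    n_kept = int(keep.sum())
    logger.info("filter_loci retained %d of %d loci", n_kept, table.n_loci)
    if n_kept == 0:
        raise ValueError(
            "no loci pass the depth/quality filter; consider relaxing "
            f"min_depth={min_depth} or min_qual={min_qual}"
        )
    return GenotypeTable(
        table.loci[keep], table.genotypes[keep], table.depths[keep]
    )


def pairwise_identity(table: GenotypeTable) -> ConcordanceMatrix:
    """Fraction of loci with identical unphased genotypes for each sample pair."""
    if table.n_loci == 0:
        raise ValueError("no loci")
    samples = table.samples
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    canon = table.genotypes.map(normalize_genotype)
    n = len(samples)
    frac = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            same = (canon[samples[i]] == canon[samples[j]]).mean()
            frac[i, j] = frac[j, i] = same
    fractions = pd.DataFrame(frac, index=samples, columns=samples)
    return ConcordanceMatrix(fractions, table.n_loci)
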