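"""Plain-text readers and writers for the pipeline's tabular formats.

Formats are deliberately simple, uncompressed text:

* expression: TSV with genes as rows (first column ``gene_id``) plus a
  companion sample-metadata TSV;
* homolog maps: two-column TSV;
* cell tracks: CSV with ``cell_id, frame, time_s, x_um, y_um``;
* genotypes: TSV with ``chrom, pos, ref, alt, qual`` then per-sample
  ``GT:DP`` fields;
* correlation / concordance matrices: TSV;
* gene sets: one id per line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .chemotaxis import TrackSet
from .expression import ExpressionMatrix, HomologMap
from .genotype import GenotypeTable

__all__ = [
    "write_expression",
    "read_expression",
    "read_homolog_map",
    "write_tracks",
    "read_tracks",
    "write_genotypes",
    "read_genotypes",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_gene_set",
    "read_gene_set",
]

_LOCUS_COLS = ["chrom", "pos", "ref", "alt", "qual"]


def write_expression(matrix: ExpressionMatrix, values_path, meta_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="gene_id")
    matrix.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_expression(values_path, meta_path, scale: str = "linear") -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
    values.index.name = None
    meta.index.name = None
    return ExpressionMatrix(values, meta, scale=scale)


def read_homolog_map(path) -> HomologMap:
    pairs = pd.read_csv(path, sep="\t", header=0, dtype=str)
    return HomologMap(pairs)


def write_tracks(ts: TrackSet, path, config_path=None) -> None:
    """Write the track table as CSV; source/stimulus go to a key=value file."""
    ts.tracks.to_csv(path, index=False)
    if config_path is not None:
        Path(config_path).write_text(
            f"source_x={ts.source[0]}\nsource_y={ts.source[1]}\n"
            f"stimulus_time={ts.stimulus_time}\n"
        )


def read_tracks(path, config_path=None, source=None, stimulus_time=None) -> TrackSet:
    tracks = pd.read_csv(path)
    if config_path is not None:
        config = dict(
            line.split("=", 1)
            for line in Path(config_path).read_text().splitlines()
            if "=" in line
        )
        source = (float(config["source_x"]), float(config["source_y"]))
        stimulus_time = float(config["stimulus_time"])
    if source is None or stimulus_time is None:
        raise ValueError("source and stimulus_time required (directly or via config)")
    return TrackSet(tracks, tuple(source), float(stimulus_time))


def write_genotypes(table: GenotypeTable, path) -> None:
    """TSV with locus columns followed by per-sample ``GT:DP`` fields."""
    out = table.loci[_LOCUS_COLS].copy()
    for sample in table.samples:
        out[sample] = table.genotypes[sample] + ":" + table.depths[sample].astype(str)
    out.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeTable:
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sample_cols = [c for c in raw.columns if c not in _LOCUS_COLS]
    if not sample_cols:
        raise ValueError("no sample columns found")
    loci = raw[_LOCUS_COLS]
    split = {s: raw[s].str.split(":", expand=True) for s in sample_cols}
    genotypes = pd.DataFrame({s: v[0] for s, v in split.items()})
    depths = pd.DataFrame({s: v[1].astype(int) for s, v in split.items()})
    return GenotypeTable(loci, genotypes, depths)


def write_matrix_tsv(matrix: pd.DataFrame, path, index_label: str = "sample") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path, index_label: str = "sample") -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t", index_col=index_label)
    out.index.name = None
    return out


def write_gene_set(genes: Iterable, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_set(path) -> list:
    return [line for line in Path(path).read_text().splitlines() if line]
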