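"""Merged, queryable expression catalog across cell states and species.

Averaged log10 expression per cell state (undifferentiated, DMSO, DMSO +
Nutridoma, primary human, primary mouse, ...) is joined into one table
keyed by gene id, optionally decorated with gene symbols, cross-species
homolog links and protein-domain labels, and queried by gene or domain
with stable per-column sorting -- a static counterpart of a searchable
web expression database.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .expression import ExpressionMatrix, HomologMap

__all__ = ["CatalogTable", "build_catalog", "query"]

#: sentinel written to CSV for groups where a gene was not measured
MISSING_TOKEN = "NA"


@dataclass
class CatalogTable:
    """Merged averaged expression keyed by gene id."""

    table: pd.DataFrame                   # index gene_id; one column per group
    expression_columns: tuple             # the group (expression) columns
    domains: pd.DataFrame | None = None   # columns: gene_id, domain

    def to_csv(self, path) -> None:
        self.table.to_csv(path, na_rep=MISSING_TOKEN, index_label="gene_id")


def _as_series(obj, name: str) -> pd.Series:
    if isinstance(obj, ExpressionMatrix):
        if obj.n_samples != 1:
            raise ValueError(
                f"group {name!r}: expected an averaged single-column matrix, "
                f"got {obj.n_samples} columns"
            )
        s = obj.values.iloc[:, 0]
    elif isinstance(obj, pd.DataFrame):
        if obj.shape[1] != 1:
            raise ValueError(f"group {name!r}: expected a single column")
        s = obj.iloc[:, 0]
    else:
        s = pd.Series(obj)
    if not s.index.is_unique:
        dupes = s.index[s.index.duplicated()].unique()
        raise ValueError(f"group {name!r} has duplicate gene ids: {list(dupes[:5])}")
    return s.rename(name)


def build_catalog(
    groups: Mapping[str, "pd.Series | pd.DataFrame | ExpressionMatrix"],
    symbols: Mapping[str, str] | pd.Series | None = None,
    homologs: HomologMap | None = None,
    domains: pd.DataFrame | None = None,
) -> CatalogTable:
    """Outer-join averaged per-group expression into one catalog.

    Parameters
    ----------
    groups
        Mapping from group label (cell state / species) to averaged log10
        expression keyed by gene id.  Genes absent from a group get NaN
        (rendered as an explicit token on export), never a filled-in floor.
    symbols
        Optional gene id -> symbol mapping.
    homologs
        Optional cross-species homolog map; the partner id of each gene is
        recorded in a ``homolog`` column.
    domains
        Optional two-column (gene_id, domain) table; a gene may carry any
        number of domain labels.
    """
    if not groups:
        raise ValueError("no groups supplied")
    series = [_as_series(obj, name) for name, obj in groups.items()]
    table = pd.concat(series, axis=1, join="outer").sort_index()
    expr_cols = tuple(table.columns)
    if symbols is not None:
        table.insert(0, "symbol", pd.Series(symbols).reindex(table.index))
    if homologs is not None:
        partner = homologs.one_to_one().set_index("gene_a")["gene_b"]
        table["homolog"] = partner.reindex(table.index)
    dom = None
    if domains is not None:
        dom = domains.copy()
        dom.columns = ["gene_id", "domain"]
    return CatalogTable(table, expr_cols, dom)


def query(
    catalog: CatalogTable,
    gene: str | None = None,
    symbol: str | None = None,
    domain: str | None = None,
    sort_by: str | None = None,
    descending: bool = True,
    top: int | None = None,
) -> pd.DataFrame:
    """Filter the catalog by gene id, symbol or domain; sort; truncate.

    Filters are exact-match.  Sorting is stable (ties keep catalog order)
    and NaN expression sorts last.  A domain absent from the mapping gives
    an empty result, not an error.  The catalog itself is never mutated.
    """
    table = catalog.table
    if gene is not None:
        table = table[table.index == gene]
    if symbol is not None:
        if "symbol" not in table.columns:
            raise ValueError("catalog has no symbol column")
        table = table[table["symbol"] == symbol]
    if domain is not None:
        if catalog.domains is None:
            raise ValueError("catalog has no domain annotations")
        ids = catalog.domains.loc[catalog.domains["domain"] == domain, "gene_id"]
        table = table[table.index.isin(set(ids))]
    if sort_by is not None:
        if sort_by not in table.columns:
            raise ValueError(f"unknown sort column {sort_by!r}")
        table = table.sort_values(
            sort_by, ascending=not descending, kind="stable", na_position="last"
        )
    if top is not None:
        table = table.head(top)
    return table.copy()
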