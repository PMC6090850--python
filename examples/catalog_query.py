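"""Building and querying the merged expression catalog.

Joins averaged log10 expression for three cell states into one table keyed
by gene id, attaches symbols and protein-domain labels, and answers the
kind of question the catalog exists for: the top kinase-domain genes
ranked by expression in primary neutrophils.
"""

import pandas as pd

from neutromap.catalog import build_catalog, query

groups = {
    "undifferentiated": pd.Series(
        {"g01": 0.2, "g02": 1.1, "g03": -0.5, "g04": 0.9, "g05": 2.0}
    ),
    "nutridoma": pd.Series(
        {"g01": 1.4, "g02": 1.0, "g03": 0.3, "g04": 1.8, "g06": 0.4}
    ),
    "primary_human": pd.Series(
        {"g01": 2.1, "g02": 0.9, "g04": 2.4, "g05": -1.0, "g06": 1.2}
    ),
}
symbols = {"g01": "FPR1", "g02": "VAV1", "g03": "CXCR1", "g04": "PRKCB",
           "g05": "MYB", "g06": "PAK1"}
domains = pd.DataFrame(
    {
        "gene_id": ["g02", "g04", "g06", "g01"],
        "domain": ["PKINASE", "PKINASE", "PKINASE", "7TM_1"],
    }
)

cat = build_catalog(groups, symbols=symbols, domains=domains)
print(f"catalog: {len(cat.table)} genes x {len(cat.expression_columns)} states "
      "(missing state values stay NA, never a filled-in floor)\n")

top = query(cat, domain="PKINASE", sort_by="primary_human", top=3)
print("top PKINASE-domain genes by primary-neutrophil expression:")
print(top.round(2).to_string())

hit = query(cat, symbol="FPR1")
print("\nFPR1 across states:")
print(hit.round(2).to_string())
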