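"""Gene function-category bookkeeping (SCOP-style general/detailed tiers).

Catalogs are plain TSV tables mapping each gene to a general function
category, a detailed function category and a family label. Genes absent from
a catalog fall into the literal "NONA" / "not annotated" tier, mirroring how
unannotated predicted genes are reported.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable

import pandas as pd

from .table4 import fixture_path

NOT_ANNOTATED = ("NONA", "not annotated")


def _norm(label: str) -> str:
    """Case-insensitive, whitespace-normalized category key."""
    return " ".join(str(label).split()).lower()


def load_catalog(path: str | Path | None = None) -> pd.DataFrame:
    """Load a catalog TSV (gene_id, general_function, detailed_function, family).

    Without a path, the packaged toy catalog covering the physically mapped
    panel genes is loaded. Duplicate gene entries are rejected.
    """
    path = Path(path) if path is not None else fixture_path("scop_catalog_toy.tsv")
    cat = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "general_function", "detailed_function"}
    if not required <= set(cat.columns):
        raise ValueError(f"catalog must have columns {sorted(required)}")
    dupes = cat["gene_id"][cat["gene_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate catalog entries for {sorted(set(dupes))}")
    return cat


def tally_categories(gene_set: Iterable[str], catalog: pd.DataFrame) -> pd.DataFrame:
    """Count genes of a set per (general, detailed) category.

    Every gene is counted exactly once; genes missing from the catalog are
    tallied under "NONA" / "not annotated", so counts always sum to the set
    size. Category labels are matched case-insensitively after whitespace
    normalization; the first spelling seen in the catalog is reported.
    """
    genes = list(dict.fromkeys(gene_set))
    lookup: dict[str, tuple[str, str]] = {}
    display: dict[tuple[str, str], tuple[str, str]] = {}
    for _, row in catalog.iterrows():
        pair = (row["general_function"], row["detailed_function"])
        key = (_norm(pair[0]), _norm(pair[1]))
        display.setdefault(key, pair)
        lookup[row["gene_id"]] = key
    na_key = (_norm(NOT_ANNOTATED[0]), _norm(NOT_ANNOTATED[1]))
    display.setdefault(na_key, NOT_ANNOTATED)
    counts = Counter(lookup.get(g, na_key) for g in genes)
    rows = [
        {
            "general_function": display[key][0],
            "detailed_function": display[key][1],
            "count": n,
        }
        for key, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["general_function", "detailed_function", "count"])
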