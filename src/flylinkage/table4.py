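"""Loader for the transcribed 70-gene qPCR expression panel.

The packaged fixture ``table4_expression.tsv`` transcribes the study's
published relative-expression panel: 70 differentially expressed genes
assayed by qPCR in the resistant parent (ALHF) and the five substitution
lines, each cell a printed "mean ± SE" with an asterisk marking a Welch-test
significant change versus ALHF. Rows without usable data carry "-" cells
(those the source marked with a dagger carry the note "††").

The printed asterisks are authoritative significance calls: SEs are rounded
to one or two digits, so p-values recomputed from the printed summaries are
diagnostic only and never override the flags.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

import pandas as pd

LINE_COLUMNS = ("ALHF", "A2345", "A1345", "A1245", "A1235", "A1234")

_CELL_RE = re.compile(r"^(?P<mean>[0-9.]+) ± (?P<se>[0-9.]+)(?P<star>\*)?$")


def fixture_path(name: str = "table4_expression.tsv") -> Path:
    return Path(str(resources.files("flylinkage.data") / name))


def _parse_cell(cell: str) -> tuple[float | None, float | None, bool, str]:
    """Split a printed cell into (mean, se, significant, printed string)."""
    cell = cell.strip()
    if cell == "-":
        return None, None, False, cell
    m = _CELL_RE.match(cell)
    if m is None:
        raise ValueError(f"malformed expression cell {cell!r}")
    return float(m["mean"]), float(m["se"]), m["star"] is not None, cell


def load_table4(path: str | Path | None = None, n_replicates: int = 3) -> pd.DataFrame:
    """Load the panel as a tidy summary frame (one row per gene x line).

    Columns: gene_id, line, mean, se, n, significant, direction, missing,
    printed (the verbatim cell) plus the gene's general/detailed function
    and family annotation. ``n`` is the assay's replicate count (triplicate
    biological replication); no replicate-level data is published, so the
    printed asterisk is carried as the significance call.
    """
    path = Path(path) if path is not None else fixture_path()
    wide = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    records = []
    alhf_means: dict[str, float | None] = {}
    for _, row in wide.iterrows():
        alhf_means[row["gene_id"]], *_ = _parse_cell(row["ALHF"])
    for _, row in wide.iterrows():
        for line in LINE_COLUMNS:
            mean, se, star, printed = _parse_cell(row[line])
            base = alhf_means[row["gene_id"]]
            if mean is None or line == "ALHF" or base is None or mean == base:
                direction = "none"
            else:
                direction = "up" if mean > base else "down"
            records.append(
                {
                    "gene_id": row["gene_id"],
                    "line": line,
                    "mean": mean,
                    "se": se,
                    "n": n_replicates if mean is not None else 0,
                    "significant": star,
                    "direction": direction,
                    "missing": mean is None,
                    "printed": printed,
                    "note": row["note"],
                    "general_function": row["general_function"],
                    "detailed_function": row["detailed_function"],
                    "family": row["family"],
                }
            )
    return pd.DataFrame(records)


def serialize_table4(summary: pd.DataFrame) -> str:
    """Re-emit a loaded panel in the fixture's wide TSV layout.

    Round-trips bit-exactly with the packaged file: cells are rebuilt from
    the preserved printed strings.
    """
    meta_cols = ["general_function", "detailed_function", "family", "gene_id", "note"]
    first = summary.drop_duplicates("gene_id").set_index("gene_id")
    lines = ["\t".join(meta_cols + list(LINE_COLUMNS))]
    cells = summary.pivot(index="gene_id", columns="line", values="printed")
    for gene_id in first.index:
        meta = [
            first.at[gene_id, "general_function"],
            first.at[gene_id, "detailed_function"],
            first.at[gene_id, "family"],
            gene_id,
            first.at[gene_id, "note"],
        ]
        lines.append("\t".join(meta + [cells.at[gene_id, c] for c in LINE_COLUMNS]))
    return "\n".join(lines) + "\n"


def catalog_from_table4(path: str | Path | None = None) -> pd.DataFrame:
    """Derive a gene -> function-category catalog from the panel fixture."""
    summary = load_table4(path)
    return (
        summary.drop_duplicates("gene_id")[
            ["gene_id", "general_function", "detailed_function", "family"]
        ].reset_index(drop=True)
    )
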