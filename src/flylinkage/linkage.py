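"""Autosome linkage calling and Venn co-regulation partitioning.

A gene's *linkage set* is the set of autosomes whose substitution
significantly changes its expression relative to the all-resistant parent:
line A2345 probes autosome 1, A1345 probes 2, A1245 probes 3, A1235 probes 4
and A1234 probes 5. Significance in either direction creates a linkage edge;
direction is kept as provenance. Partitioning genes by their exact linkage
subset yields the co-regulation classes (the Venn analysis): a gene in class
{2,5} needs factors on both autosomes 2 and 5 for full up-regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .design import AUTOSOMES, SUBSTITUTION_LINE_NAMES, substituted_autosome
from .qpcr import _welch_arrays


@dataclass(frozen=True)
class LinkageCall:
    gene_id: str
    linked_autosomes: frozenset[int]
    status: str = "called"  # "called" or "no_data"
    provenance: dict[int, dict] = field(default_factory=dict, repr=False)


@dataclass
class VennPartition:
    """Exact-subset partition of called genes over their linkage sets."""

    classes: dict[frozenset[int], list[str]]

    @property
    def counts(self) -> dict[frozenset[int], int]:
        return {s: len(g) for s, g in self.classes.items()}

    @property
    def n_called(self) -> int:
        return sum(len(g) for g in self.classes.values())


def call_linkage(
    summary: pd.DataFrame, alpha: float = 0.05, use_printed_flags: bool = True
) -> list[LinkageCall]:
    """Derive per-gene linkage sets from a gene x line significance summary.

    ``summary`` is a tidy frame with columns gene_id, line and either a
    ``significant`` flag column (used when ``use_printed_flags`` is true —
    the published panel's asterisks are authoritative) or a ``p`` column
    tested at ``alpha``. Genes whose five line records are all missing get
    status ``no_data`` and are excluded from partitions.
    """
    lines_present = set(summary["line"]) - {"ALHF", "aabys"}
    unknown = lines_present - set(SUBSTITUTION_LINE_NAMES)
    if unknown:
        raise ValueError(f"unknown line name(s) {sorted(unknown)}")
    line_to_autosome = {name: substituted_autosome(name) for name in SUBSTITUTION_LINE_NAMES}
    use_flags = use_printed_flags and "significant" in summary.columns
    if not use_flags and "p" not in summary.columns:
        raise ValueError("summary needs a 'significant' or 'p' column")

    calls: list[LinkageCall] = []
    sub = summary[summary["line"].isin(SUBSTITUTION_LINE_NAMES)]
    for gene_id, rows in sub.groupby("gene_id", sort=False):
        missing = rows["missing"] if "missing" in rows.columns else rows.get("mean", pd.Series(dtype=float)).isna()
        usable = rows[~missing.astype(bool)] if len(missing) else rows
        if usable.empty:
            calls.append(LinkageCall(gene_id, frozenset(), status="no_data"))
            continue
        linked = set()
        prov: dict[int, dict] = {}
        for _, r in usable.iterrows():
            autosome = line_to_autosome[r["line"]]
            if use_flags:
                sig = bool(r["significant"])
                prov[autosome] = {"source": "printed_flag", "significant": sig,
                                  "direction": r.get("direction", "none")}
            else:
                sig = float(r["p"]) <= alpha
                prov[autosome] = {"source": "welch", "p": float(r["p"]),
                                  "significant": sig, "direction": r.get("direction", "none")}
            if sig:
                linked.add(autosome)
        calls.append(LinkageCall(gene_id, frozenset(linked), provenance=prov))
    return calls


def venn_partition(calls: Iterable[LinkageCall]) -> VennPartition:
    """Group called genes by their exact linkage subset (disjoint classes)."""
    classes: dict[frozenset[int], list[str]] = {}
    seen: set[str] = set()
    for call in calls:
        if call.gene_id in seen:
            raise ValueError(f"duplicate gene_id {call.gene_id!r}")
        seen.add(call.gene_id)
        if call.status != "called":
            continue
        classes.setdefault(call.linked_autosomes, []).append(call.gene_id)
    return VennPartition(classes)


def subset_count(partition: VennPartition, subset: Iterable[int]) -> int:
    """Gene count of one exact subset class; 0 if the class is unrealized."""
    subset = frozenset(subset)
    if not subset <= set(AUTOSOMES):
        raise ValueError(f"subset {sorted(subset)} is not a subset of autosomes 1-5")
    return len(partition.classes.get(subset, []))


def single_autosome_summary(partition: VennPartition) -> tuple[dict[int, int], int]:
    """Counts of genes linked to exactly one autosome, per autosome, with total."""
    per = {a: subset_count(partition, {a}) for a in AUTOSOMES}
    return per, sum(per.values())


def welch_diagnostics(summary: pd.DataFrame) -> pd.DataFrame:
    """Recompute Welch p-values from printed mean/SE/n summaries.

    Diagnostic only: printed summaries are rounded, so these p-values never
    override the published significance flags.
    """
    base = (
        summary[summary["line"] == "ALHF"]
        .set_index("gene_id")[["mean", "se", "n"]]
        .rename(columns={"mean": "b_mean", "se": "b_se", "n": "b_n"})
    )
    rows = summary[summary["line"].isin(SUBSTITUTION_LINE_NAMES) & ~summary["missing"]].copy()
    rows = rows.join(base, on="gene_id")
    t, df, p = _welch_arrays(rows["mean"], rows["se"], rows["n"],
                             rows["b_mean"], rows["b_se"], rows["b_n"])
    rows["t"], rows["welch_df"], rows["p_recomputed"] = t, df, p
    return rows[["gene_id", "line", "mean", "se", "n", "t", "welch_df", "p_recomputed"]].reset_index(
        drop=True
    )


def write_linkage(calls: Iterable[LinkageCall], path) -> None:
    rows = [
        {
            "gene_id": c.gene_id,
            "linked_autosomes": ",".join(str(a) for a in sorted(c.linked_autosomes)),
            "status": c.status,
            "provenance": ";".join(
                f"{a}:{c.provenance[a]['source']}" for a in sorted(c.provenance)
            ),
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_partition(partition: VennPartition, path) -> None:
    rows = [
        {
            "subset": ",".join(str(a) for a in sorted(s)) or "none",
            "count": len(genes),
            "gene_ids": ",".join(genes),
        }
        for s, genes in sorted(partition.classes.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
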