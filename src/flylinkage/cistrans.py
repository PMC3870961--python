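"""Cis/trans classification and simulation-recovery scoring.

At autosome resolution, a regulatory autosome is *cis* when it coincides
with the autosome the gene physically sits on and *trans* otherwise. A gene
whose linkage set is exactly its own location is cis-only; a linkage set
that excludes the location is trans-only; a set containing the location plus
others is cis-plus-trans. The design cannot distinguish a genuine cis
regulatory factor from the gene's own structural locus, so cis-plus-trans
calls carry a "cis-or-locus" flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .aspcr import MappingResult
from .design import AUTOSOMES
from .linkage import LinkageCall
from .simulate import GeneSpec


@dataclass(frozen=True)
class RegClass:
    gene_id: str
    reg_class: str                  # cis_only | trans_only | cis_plus_trans | unlinked
    location: int
    linked_autosomes: frozenset[int]
    flags: tuple[str, ...] = ()


def classify(linkage: LinkageCall, mapping: MappingResult) -> RegClass:
    """Classify one gene's regulation from its linkage set and physical location."""
    if mapping.outcome != "mapped":
        raise ValueError(
            f"gene {linkage.gene_id!r}: cannot classify an {mapping.outcome} gene"
        )
    if linkage.gene_id != mapping.gene_id:
        raise ValueError(f"gene mismatch: {linkage.gene_id!r} vs {mapping.gene_id!r}")
    loc = mapping.autosome
    linked = linkage.linked_autosomes
    if not linked:
        cls = "unlinked"
    elif linked == {loc}:
        cls = "cis_only"
    elif loc in linked:
        cls = "cis_plus_trans"
    else:
        cls = "trans_only"
    flags = ("cis-or-locus",) if cls == "cis_plus_trans" else ()
    return RegClass(linkage.gene_id, cls, loc, linked, flags)


def classify_all(
    calls: list[LinkageCall], mappings: list[MappingResult]
) -> tuple[list[RegClass], list[tuple[str, str]]]:
    """Classify every gene mapped and called; returns (classes, skipped).

    ``skipped`` lists (gene_id, reason) for genes that could not be
    classified (unmapped/ambiguous location or no expression data).
    """
    by_gene = {c.gene_id: c for c in calls}
    classes: list[RegClass] = []
    skipped: list[tuple[str, str]] = []
    for m in mappings:
        call = by_gene.get(m.gene_id)
        if call is None or call.status != "called":
            skipped.append((m.gene_id, "no linkage data"))
        elif m.outcome != "mapped":
            skipped.append((m.gene_id, f"location {m.outcome}"))
        else:
            classes.append(classify(call, m))
    return classes, skipped


@dataclass(frozen=True)
class RecoveryReport:
    """Edge-level and gene-level agreement between inferred and true linkage."""

    edge_sensitivity: float          # recovered true factor edges / true edges
    edge_fdp: float                  # false edges / called edges
    exact_set_fraction: float        # genes whose linkage set matches exactly
    per_autosome_sensitivity: dict[int, float]
    per_autosome_fdp: dict[int, float]
    class_confusion: pd.DataFrame    # true subset x inferred subset counts


def evaluate_recovery(calls: list[LinkageCall], truth: list[GeneSpec]) -> RecoveryReport:
    """Score inferred linkage sets against simulator ground truth."""
    inferred = {c.gene_id: c.linked_autosomes for c in calls if c.status == "called"}
    true_sets = {s.gene_id: s.factor_autosomes for s in truth}
    if set(inferred) != set(true_sets):
        raise ValueError("inferred calls and truth cover different genes")

    tp = fp = fn = 0
    per_tp = {a: 0 for a in AUTOSOMES}
    per_fp = {a: 0 for a in AUTOSOMES}
    per_true = {a: 0 for a in AUTOSOMES}
    per_called = {a: 0 for a in AUTOSOMES}
    exact = 0
    confusion: dict[tuple[str, str], int] = {}
    for gene_id in sorted(inferred):
        inf, tru = inferred[gene_id], true_sets[gene_id]
        tp += len(inf & tru)
        fp += len(inf - tru)
        fn += len(tru - inf)
        exact += inf == tru
        for a in AUTOSOMES:
            per_true[a] += a in tru
            per_called[a] += a in inf
            per_tp[a] += a in tru and a in inf
            per_fp[a] += a in inf and a not in tru
        key = (_subset_label(tru), _subset_label(inf))
        confusion[key] = confusion.get(key, 0) + 1

    called = tp + fp
    conf = pd.DataFrame(
        [{"true_subset": t, "inferred_subset": i, "count": n} for (t, i), n in sorted(confusion.items())]
    )
    return RecoveryReport(
        edge_sensitivity=tp / (tp + fn) if (tp + fn) else 1.0,
        edge_fdp=fp / called if called else 0.0,
        exact_set_fraction=exact / len(inferred) if inferred else 1.0,
        per_autosome_sensitivity={
            a: (per_tp[a] / per_true[a] if per_true[a] else 1.0) for a in AUTOSOMES
        },
        per_autosome_fdp={
            a: (per_fp[a] / per_called[a] if per_called[a] else 0.0) for a in AUTOSOMES
        },
        class_confusion=conf,
    )


def _subset_label(subset: frozenset[int]) -> str:
    return ",".join(str(a) for a in sorted(subset)) or "none"


def write_classification(classes: list[RegClass], skipped, path) -> None:
    rows = [
        {
            "gene_id": c.gene_id,
            "location": c.location,
            "linked_autosomes": _subset_label(c.linked_autosomes),
            "class": c.reg_class,
            "flags": ",".join(c.flags),
        }
        for c in classes
    ]
    rows += [
        {"gene_id": g, "location": "", "linked_autosomes": "", "class": "skipped", "flags": why}
        for g, why in skipped
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
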