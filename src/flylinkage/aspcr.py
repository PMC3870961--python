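"""Physical autosome mapping from allele-specific PCR band patterns.

The ALHF-allele-specific primers amplify only the resistant parent's allele,
so a substitution line yields a band exactly when it retains the ALHF copy
of the autosome carrying the gene. Absence of a band in exactly one
substitution line therefore localizes the gene to that line's substituted
autosome (no band in A1234 means the gene sits on autosome 5). Parental
lanes, when present, act purely as consistency controls: ALHF must band,
aabys must not.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .design import SUBSTITUTION_LINE_NAMES, substituted_autosome


@dataclass(frozen=True)
class MappingResult:
    gene_id: str
    outcome: str                    # "mapped", "unmapped" or "ambiguous"
    autosome: int | None = None
    evidence: tuple[str, ...] = ()  # lines lacking the band
    note: str = ""


def _as_bool(value) -> bool:
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("present", "1", "true", "yes"):
            return True
        if v in ("absent", "0", "false", "no"):
            return False
        raise ValueError(f"unrecognized band call {value!r}")
    return bool(value)


def infer_location(pattern: pd.Series | dict, gene_id: str = "") -> MappingResult:
    """Infer a gene's physical autosome from one band-pattern row.

    ``pattern`` maps line names to present/absent calls and must cover the
    five substitution lines; parental entries (ALHF, aabys) are optional and
    only checked for consistency. Outcome is invariant to column order.
    """
    pattern = dict(pattern)
    missing = [l for l in SUBSTITUTION_LINE_NAMES if l not in pattern]
    if missing:
        raise ValueError(f"band pattern lacks line column(s) {missing}")
    gene_id = gene_id or str(pattern.pop("gene_id", ""))
    bands = {line: _as_bool(pattern[line]) for line in SUBSTITUTION_LINE_NAMES}
    if "ALHF" in pattern and not _as_bool(pattern["ALHF"]):
        return MappingResult(gene_id, "ambiguous", note="inconsistent: no band in ALHF")
    if "aabys" in pattern and _as_bool(pattern["aabys"]):
        return MappingResult(gene_id, "ambiguous", note="inconsistent: band in aabys")
    lacking = tuple(l for l in SUBSTITUTION_LINE_NAMES if not bands[l])
    if len(lacking) == 0:
        return MappingResult(gene_id, "unmapped")
    if len(lacking) == 1:
        return MappingResult(gene_id, "mapped", substituted_autosome(lacking[0]), lacking)
    return MappingResult(gene_id, "ambiguous", evidence=lacking)


def merge_replicate_patterns(patterns: list[pd.Series | dict]) -> dict:
    """Majority-vote merge of replicated band patterns; ties become ambiguous.

    A tied line is marked 'tie', which :func:`infer_location` cannot parse as
    a band call — map ties explicitly before inferring, or treat the gene as
    ambiguous.
    """
    if not patterns:
        raise ValueError("no replicate patterns to merge")
    keys = set().union(*(dict(p).keys() for p in patterns)) - {"gene_id"}
    merged: dict = {}
    for key in keys:
        votes = [_as_bool(dict(p)[key]) for p in patterns if key in dict(p)]
        n_present = sum(votes)
        if 2 * n_present == len(votes):
            merged[key] = "tie"
        else:
            merged[key] = "present" if 2 * n_present > len(votes) else "absent"
    return merged


def map_genes(bands: pd.DataFrame) -> list[MappingResult]:
    """Run :func:`infer_location` over a band table (genes x line columns).

    Genes with a tied replicate merge are reported as ambiguous.
    """
    frame = bands.reset_index() if bands.index.name == "gene_id" else bands.copy()
    results = []
    for _, row in frame.iterrows():
        gene_id = str(row.get("gene_id", ""))
        if any(str(v).strip().lower() == "tie" for v in row.values):
            results.append(MappingResult(gene_id, "ambiguous", note="replicate tie"))
            continue
        results.append(infer_location(row.drop(labels=["gene_id"], errors="ignore"), gene_id))
    return results


def load_bands(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_mapping(results: list[MappingResult], path: str | Path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "outcome": r.outcome,
            "autosome": r.autosome if r.autosome is not None else "",
            "evidence": ",".join(r.evidence),
            "note": r.note,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
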