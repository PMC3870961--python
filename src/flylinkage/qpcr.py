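"""Relative qPCR quantification (2^-ddCt) and Welch significance calling.

Quantification follows the comparative-Ct method with a single endogenous
reference gene and perfect doubling efficiency: for each sample,
dCt = mean Ct(target) - mean Ct(reference); ddCt subtracts the calibrator
sample's dCt; relative expression is 2^-ddCt, so the calibrator is exactly 1.

Each line's relative expression is compared against the resistant parental
strain with a two-sided Welch (unequal-variance) t-test on the replicate
values; no multiple-testing correction is applied across lines or genes at
this stage, matching a per-test alpha of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import REFERENCE_GENE


class NormalizationError(ValueError):
    """Raised when reference-gene records needed for normalization are absent."""


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class DdctResult:
    """Per-sample relative expression for one target gene.

    ``sample_level`` holds 2^-ddCt computed from mean Cts (the calibrator is
    exactly 1). ``replicate_level`` spreads each target replicate around the
    sample value, preserving within-sample variability for the t-test.
    """

    target: str
    calibrator: str
    sample_level: pd.Series
    replicate_level: pd.DataFrame


def _mean_ct(ct: pd.DataFrame, target_id: str) -> pd.Series:
    sub = ct[ct["target_id"] == target_id]
    if sub.empty:
        raise NormalizationError(f"no Ct records for {target_id!r}")
    return sub.groupby("sample")["ct"].mean()


def ddct(
    ct: pd.DataFrame,
    target: str,
    reference: str = REFERENCE_GENE,
    calibrator: str = "aabys",
) -> DdctResult:
    """2^-ddCt relative expression of ``target`` in every sample vs the calibrator."""
    ref_means = _mean_ct(ct, reference)
    tgt = ct[ct["target_id"] == target]
    if tgt.empty:
        raise NormalizationError(f"no Ct records for target {target!r}")
    missing_ref = set(tgt["sample"]) - set(ref_means.index)
    if missing_ref:
        raise NormalizationError(
            f"samples {sorted(missing_ref)} lack reference ({reference!r}) Ct records"
        )
    tgt_means = tgt.groupby("sample")["ct"].mean()
    if calibrator not in tgt_means.index:
        raise NormalizationError(f"calibrator sample {calibrator!r} absent for {target!r}")
    dct = tgt_means - ref_means.loc[tgt_means.index]
    ddct_vals = dct - dct.loc[calibrator]
    sample_level = (2.0 ** -ddct_vals).rename("rel_expression")
    # Replicate-level: pair each target replicate with the same-index
    # reference replicate so reference-gene noise enters the within-sample
    # spread (a mean-normalized reference would hide it from the SE and bias
    # downstream t-tests liberal); unpaired replicates fall back to the
    # sample's mean reference Ct.
    ref = ct[ct["target_id"] == reference][["sample", "replicate", "ct"]].rename(
        columns={"ct": "ref_ct"}
    )
    rep = tgt.merge(ref, on=["sample", "replicate"], how="left")
    rep["ref_ct"] = rep["ref_ct"].fillna(rep["sample"].map(ref_means))
    rep["dct"] = rep["ct"] - rep["ref_ct"]
    rep["expression"] = 2.0 ** -(rep["dct"] - dct.loc[calibrator])
    replicate_level = rep[["sample", "replicate", "expression"]].reset_index(drop=True)
    return DdctResult(target, calibrator, sample_level, replicate_level)


def relative_expression_table(
    ct: pd.DataFrame,
    reference: str = REFERENCE_GENE,
    calibrator: str = "aabys",
) -> pd.DataFrame:
    """Replicate-level 2^-ddCt values for every target gene in a Ct table.

    Returns a tidy frame (gene_id, sample, replicate, expression) ready for
    :func:`summarize_lines`.
    """
    frames = []
    for target in ct["target_id"].unique():
        if target == reference:
            continue
        res = ddct(ct, target, reference=reference, calibrator=calibrator)
        rep = res.replicate_level.copy()
        rep.insert(0, "gene_id", target)
        frames.append(rep)
    if not frames:
        raise NormalizationError("Ct table contains no target genes")
    return pd.concat(frames, ignore_index=True)


def _welch_arrays(m1, se1, n1, m2, se2, n2):
    """Vectorized Welch test from summary statistics; returns (t, df, p)."""
    m1, se1, n1 = np.asarray(m1, float), np.asarray(se1, float), np.asarray(n1, float)
    m2, se2, n2 = np.asarray(m2, float), np.asarray(se2, float), np.asarray(n2, float)
    var = se1**2 + se2**2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(var)
        df = var**2 / (se1**4 / (n1 - 1) + se2**4 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = var == 0
    equal = zero_var & (m1 == m2)
    differ = zero_var & (m1 != m2)
    with np.errstate(invalid="ignore"):
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        t = np.where(differ, np.sign(m1 - m2) * np.inf, t)
        p = np.where(differ, 0.0, p)
    df = np.where(zero_var, np.nan, df)
    return t, df, p


def welch_test(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> WelchResult:
    """Two-sided Welch t-test from group means, standard errors and sizes.

    t = (mean1 - mean2) / sqrt(se1^2 + se2^2) with Welch-Satterthwaite degrees
    of freedom. When both SEs are zero the test is degenerate: p = 1 for equal
    means, p = 0 (flagged) otherwise.
    """
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two replicates")
    t, df, p = _welch_arrays([mean1], [se1], [n1], [mean2], [se2], [n2])
    degenerate = (se1 == 0.0) and (se2 == 0.0)
    return WelchResult(float(t[0]), float(df[0]), float(p[0]), degenerate)


def welch_from_replicates(x, y) -> WelchResult:
    """Welch test from raw replicate values (replicate data takes precedence
    over summary statistics when both are available)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two replicates")
    se_x = x.std(ddof=1) / np.sqrt(len(x))
    se_y = y.std(ddof=1) / np.sqrt(len(y))
    return welch_test(x.mean(), se_x, len(x), y.mean(), se_y, len(y))


def summarize_lines(
    rel: pd.DataFrame, alpha: float = 0.05, baseline: str = "ALHF"
) -> pd.DataFrame:
    """Per gene x line summary with Welch significance against the baseline strain.

    ``rel`` is a tidy replicate-level relative-expression frame (gene_id,
    sample, replicate, expression). Returns one row per gene x sample with
    mean, SE (= sd/sqrt(n)), n, two-sided Welch p vs the baseline, the
    significance flag at ``alpha`` and the direction of change. Genes absent
    from a sample yield a row flagged ``missing`` rather than being dropped.
    """
    if baseline not in set(rel["sample"]):
        raise ValueError(f"baseline sample {baseline!r} absent from the table")
    grp = rel.groupby(["gene_id", "sample"])["expression"]
    stats_df = grp.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    stats_df["se"] = stats_df["sd"] / np.sqrt(stats_df["n"])
    base = (
        stats_df[stats_df["sample"] == baseline]
        .set_index("gene_id")[["mean", "se", "n"]]
        .rename(columns={"mean": "b_mean", "se": "b_se", "n": "b_n"})
    )
    missing_base = set(stats_df["gene_id"]) - set(base.index)
    if missing_base:
        raise ValueError(f"genes {sorted(missing_base)[:5]} lack {baseline} records")

    # Dense gene x sample grid so absent combinations surface as missing rows.
    genes = stats_df["gene_id"].unique()
    samples = list(dict.fromkeys(rel["sample"]))
    full = pd.MultiIndex.from_product([genes, samples], names=["gene_id", "sample"])
    out = stats_df.set_index(["gene_id", "sample"]).reindex(full).reset_index()
    out = out.join(base, on="gene_id")
    out["missing"] = out["mean"].isna()

    is_line = (out["sample"] != baseline) & ~out["missing"]
    t, df, p = _welch_arrays(
        out["mean"].to_numpy(),
        out["se"].to_numpy(),
        out["n"].to_numpy(),
        out["b_mean"].to_numpy(),
        out["b_se"].to_numpy(),
        out["b_n"].to_numpy(),
    )
    out["p"] = np.where(is_line, p, np.nan)
    out["significant"] = is_line & (out["p"] <= alpha)
    diff = out["mean"] - out["b_mean"]
    out["direction"] = np.select(
        [~is_line | (diff == 0), diff > 0], ["none", "up"], default="down"
    )
    out = out.rename(columns={"sample": "line"})
    return out[
        ["gene_id", "line", "mean", "se", "n", "p", "significant", "direction", "missing"]
    ]


def write_summary(summary: pd.DataFrame, path) -> None:
    out = summary.copy()
    out["significant"] = out["significant"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
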