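"""Negative-binomial differential-expression screen with BH FDR control.

A desk-scale two-group screen of the kind used to nominate co-up-regulated
genes from RNA-seq counts: FPKM quantification, a single common NB
dispersion estimated by the method of moments, a two-sided conditional exact
test on each gene's total count, Benjamini-Hochberg correction, and the
two-comparison intersection (resistant vs each susceptible strain) that
defines the co-up- and co-down-regulated sets.

The exact test conditions on the gene's total count after library-size
equalization: outcome probabilities come from the NB laws of the two group
sums under the null common mean, and the two-sided p-value accumulates every
split at most as probable as the observed one (ties included, conservative).
With dispersion 0 it reduces exactly to the conditional binomial (exact
Poisson) test. Library sizes are equalized by total-count scaling to their
geometric mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import CountMatrix


def fpkm(count, length_nt, library_size):
    """Fragments per kilobase of gene length per million mapped fragments."""
    count = np.asarray(count, dtype=float)
    length_nt = np.asarray(length_nt, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if np.any(length_nt <= 0):
        raise ValueError("gene length must be positive")
    if np.any(library_size <= 0):
        raise ValueError("library size must be positive")
    result = 1e9 * count / (length_nt * library_size)
    return float(result) if result.ndim == 0 else result


def fpkm_matrix(cm: CountMatrix) -> pd.DataFrame:
    """FPKM for every gene x sample of a count matrix."""
    return pd.DataFrame(
        fpkm(
            cm.counts.to_numpy(),
            cm.lengths.to_numpy()[:, None],
            cm.library_sizes.to_numpy()[None, :],
        ),
        index=cm.counts.index,
        columns=cm.counts.columns,
    )


def _equalized(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Scale each sample's counts to the geometric-mean library size."""
    libs = library_sizes.loc[counts.columns].to_numpy(dtype=float)
    gm = float(np.exp(np.mean(np.log(libs))))
    return counts * (gm / libs)


def estimate_common_dispersion(cm: CountMatrix, groups: dict[str, str]) -> float:
    """Method-of-moments common NB dispersion across genes.

    After library-size scaling, each gene contributes
    max(0, (s^2 - m) / m^2) from its pooled within-group variance s^2 and
    overall mean m; the estimate is the median over genes with m > 0.

    With a handful of samples the pooled variance has very few degrees of
    freedom and the *median* of s^2 across genes sits well below the true
    variance (for normal-ish residuals, near chi2_median(d)/d of it), which
    would bias the dispersion low and make the downstream exact test
    anticonservative. The pooled variance is therefore rescaled by
    d / chi2_median(d), making the median over genes consistent for phi.
    """
    samples = [s for s in cm.counts.columns if s in groups]
    sizes = pd.Series(groups).value_counts()
    if (sizes < 2).all():
        raise ValueError("at least one group needs two or more samples")
    y = _equalized(cm.counts[samples], cm.library_sizes)
    m = y.mean(axis=1).to_numpy()
    ss = np.zeros(len(y))
    dof = 0
    for g in sizes.index:
        cols = [s for s in samples if groups[s] == g]
        if len(cols) < 2:
            continue
        ss += y[cols].var(axis=1, ddof=1).to_numpy() * (len(cols) - 1)
        dof += len(cols) - 1
    s2 = ss / stats.chi2.ppf(0.5, dof)  # median-unbiased pooled variance
    ok = m > 0
    phis = np.maximum(0.0, (s2[ok] - m[ok]) / m[ok] ** 2)
    return float(np.median(phis)) if phis.size else 0.0


def nb_exact_test(counts_a, counts_b, phi: float) -> float:
    """Two-sided conditional exact NB test on library-equalized group counts.

    ``counts_a``/``counts_b`` are the (already equalized) per-sample counts
    of one gene in each group; ``phi`` the common NB dispersion (variance
    mu + phi*mu^2).
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    a = np.atleast_1d(np.asarray(counts_a, dtype=float))
    b = np.atleast_1d(np.asarray(counts_b, dtype=float))
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    n_a, n_b = len(a), len(b)
    total = int(round(a.sum() + b.sum()))
    if total == 0:
        return 1.0
    obs = int(round(a.sum()))
    k = np.arange(total + 1)
    if phi == 0:
        logw = stats.binom.logpmf(k, total, n_a / (n_a + n_b))
    else:
        mu = total / (n_a + n_b)  # null per-sample mean
        r_a, r_b = n_a / phi, n_b / phi
        mu_a, mu_b = n_a * mu, n_b * mu
        logw = stats.nbinom.logpmf(k, r_a, r_a / (r_a + mu_a)) + stats.nbinom.logpmf(
            total - k, r_b, r_b / (r_b + mu_b)
        )
    logw = logw - logw.max()
    w = np.exp(logw)
    w = w / w.sum()
    return float(min(1.0, w[w <= w[obs] * (1.0 + 1e-12)].sum()))


def bh_fdr(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``alpha``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def de_test(
    cm: CountMatrix,
    samples_a: list[str],
    samples_b: list[str],
    alpha: float = 0.05,
    min_count: float = 0.0,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Two-group DE screen: common dispersion, exact test per gene, BH flags.

    Returns per gene: log2 fold-change (group A over group B, on equalized
    counts with a 0.5 pseudocount), p, BH ``significant`` flag at ``alpha``
    and direction. Genes whose total equalized count is below ``min_count``
    are reported with p = 1 and excluded from the BH family.
    """
    groups = {s: "A" for s in samples_a} | {s: "B" for s in samples_b}
    if dispersion is None:
        dispersion = estimate_common_dispersion(cm, groups)
    y = _equalized(cm.counts[samples_a + samples_b], cm.library_sizes)
    ya, yb = y[samples_a].to_numpy(), y[samples_b].to_numpy()
    mean_a, mean_b = ya.mean(axis=1), yb.mean(axis=1)
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))
    tested = (ya.sum(axis=1) + yb.sum(axis=1)) >= min_count
    p = np.ones(len(y))
    for i in np.nonzero(tested)[0]:
        p[i] = nb_exact_test(ya[i], yb[i], dispersion)
    significant = np.zeros(len(y), dtype=bool)
    if tested.any():
        significant[tested] = bh_fdr(p[tested], alpha)
    direction = np.select(
        [significant & (log2fc > 0), significant & (log2fc < 0)], ["up", "down"], default="none"
    )
    return pd.DataFrame(
        {
            "gene_id": cm.counts.index,
            "log2fc": log2fc,
            "p": p,
            "significant": significant,
            "direction": direction,
            "dispersion": dispersion,
        }
    ).set_index("gene_id")


def co_regulated_sets(de_a: pd.DataFrame, de_b: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Genes significantly up (resp. down) in BOTH comparisons.

    Direction conflicts (up in one, down in the other) belong to neither set.
    """
    if set(de_a.index) != set(de_b.index):
        raise ValueError("the two comparisons cover different gene universes")
    up_a = set(de_a.index[(de_a["significant"]) & (de_a["direction"] == "up")])
    up_b = set(de_b.index[(de_b["significant"]) & (de_b["direction"] == "up")])
    dn_a = set(de_a.index[(de_a["significant"]) & (de_a["direction"] == "down")])
    dn_b = set(de_b.index[(de_b["significant"]) & (de_b["direction"] == "down")])
    return up_a & up_b, dn_a & dn_b


def replicate_concordance(fpkm_a, fpkm_b) -> float | None:
    """Squared Pearson correlation of log2(FPKM + 1) between two replicates.

    Returns None (missing) when either vector is constant.
    """
    x = np.log2(np.asarray(fpkm_a, dtype=float) + 1.0)
    y = np.log2(np.asarray(fpkm_b, dtype=float) + 1.0)
    if x.size != y.size:
        raise ValueError("replicate FPKM vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 genes for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
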