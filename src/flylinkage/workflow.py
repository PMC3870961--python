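"""End-to-end pipelines tying the stages together.

Two entry points: a simulation-recovery experiment (generate a panel with
known regulatory architecture, quantify, call linkage, score against truth)
and the fixture report (published expression panel -> linkage sets -> Venn
partition -> AS-PCR locations -> cis/trans classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import aspcr, cistrans, de, linkage, qpcr, simulate, table4
from .design import build_line_designs


def run_recovery_experiment(
    scenario: simulate.Scenario | None = None, alpha: float = 0.05
) -> tuple[cistrans.RecoveryReport, list[linkage.LinkageCall], list[simulate.GeneSpec]]:
    """Simulate the panel, quantify, call linkage and score recovery.

    Replicate expression is generated per the scenario, each line is tested
    against the resistant parent with Welch's test at ``alpha``, and the
    resulting linkage sets are compared with the simulated factor sets.
    """
    scenario = scenario or simulate.Scenario()
    specs = scenario.gene_specs()
    designs = build_line_designs()
    rel = simulate.simulate_replicates(
        specs, designs, scenario.n_reps, scenario.noise_sd,
        seed=scenario.seed + 1, model=scenario.model,
    )
    summary = qpcr.summarize_lines(rel, alpha=alpha)
    calls = linkage.call_linkage(summary, alpha=alpha)
    report = cistrans.evaluate_recovery(calls, specs)
    return report, calls, specs


@dataclass
class DEBenchmark:
    """Operating characteristics of the DE screen on a known mixture."""

    empirical_fdr: float
    power: float
    n_called: int
    dispersion_estimate: float


def run_de_benchmark(
    seed: int = 0,
    n_genes: int = 2000,
    phi: float = 0.05,
    mean_depth: float = 1e5,
    log2fc: float = 2.0,
    frac_up: float = 0.10,
    n_per_group: int = 2,
    alpha: float = 0.05,
) -> DEBenchmark:
    """Measure the DE screen's empirical FDR and power by simulation.

    A fraction ``frac_up`` of genes is truly up-regulated by ``log2fc`` in
    group A; every other gene keeps the same expected count in both groups
    (sequencing effort per gene is held fixed, so the benchmark scores the
    test, not compositional normalization). Counts are NB(``phi``) at equal
    library sizes; the screen estimates its own common dispersion.
    """
    rng = np.random.default_rng(seed)
    true_up = rng.random(n_genes) < frac_up
    base = rng.uniform(2.0, 8.0, n_genes)
    lengths = rng.integers(500, 3001, n_genes).astype(float)
    weights = 2.0**base * lengths
    mu = mean_depth * weights / weights.sum()
    mu_a = mu * np.where(true_up, 2.0**log2fc, 1.0)
    cols: dict[str, np.ndarray] = {}
    for group, m in (("A", mu_a), ("B", mu)):
        for i in range(n_per_group):
            if phi > 0:
                r = 1.0 / phi
                cols[f"{group}{i + 1}"] = rng.negative_binomial(r, r / (r + m))
            else:
                cols[f"{group}{i + 1}"] = rng.poisson(m)
    gene_ids = [f"g{i}" for i in range(n_genes)]
    cm = simulate.CountMatrix(
        pd.DataFrame(cols, index=gene_ids),
        pd.Series(lengths, index=gene_ids, name="length_nt"),
        pd.Series(mean_depth, index=list(cols), name="library_size"),
    )
    samples_a = [s for s in cols if s.startswith("A")]
    samples_b = [s for s in cols if s.startswith("B")]
    res = de.de_test(cm, samples_a, samples_b, alpha=alpha)
    called = res["significant"].to_numpy()
    called_up = called & (res["direction"] == "up").to_numpy()
    n_called = int(called.sum())
    fdr = float((called & ~true_up).sum() / n_called) if n_called else 0.0
    power = float((called_up & true_up).sum() / max(true_up.sum(), 1))
    return DEBenchmark(fdr, power, n_called, float(res["dispersion"].iloc[0]))


@dataclass
class FixtureReport:
    summary: pd.DataFrame
    calls: list[linkage.LinkageCall]
    partition: linkage.VennPartition
    mappings: list[aspcr.MappingResult]
    classes: list[cistrans.RegClass]
    skipped: list[tuple[str, str]]


def run_fixture_report(alpha: float = 0.05, use_printed_flags: bool = True) -> FixtureReport:
    """Full analysis of the packaged published panel.

    Linkage sets come from the printed significance flags (the authoritative
    calls); physical locations come from the packaged AS-PCR worked-example
    band patterns; genes with both are classified cis/trans.
    """
    summary = table4.load_table4()
    calls = linkage.call_linkage(summary, alpha=alpha, use_printed_flags=use_printed_flags)
    partition = linkage.venn_partition(calls)
    bands = aspcr.load_bands(table4.fixture_path("aspcr_bands_synthetic.tsv"))
    mappings = aspcr.map_genes(bands)
    classes, skipped = cistrans.classify_all(calls, mappings)
    return FixtureReport(summary, calls, partition, mappings, classes, skipped)
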