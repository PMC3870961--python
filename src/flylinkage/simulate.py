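"""Synthetic data generator for the autosome-substitution expression panel.

Ground truth for every simulated gene is a :class:`GeneSpec`: the autosome the
gene physically sits on, the set of "factor" autosomes whose ALHF allele
raises its expression, and a positive log2 effect per factor. Expression is
additive on the log2 scale (multiplicative in linear scale): a line expresses

    log2 E = baseline + sum of beta_a over factor autosomes with the R allele

so replacing any factor autosome with its aabys copy drops expression by that
factor's beta. An alternative all-or-nothing ("and") mode, in which the gene
is only up-regulated when every factor autosome is R, is available for
sensitivity checks.

From that expectation the module emulates each assay of the study design:

* triplicate qPCR-style relative expression with lognormal replicate noise,
* negative-binomial fragment counts for an RNA-seq style screen,
* raw Ct cycle values with a constant reference gene (the generator is the
  exact inverse of the 2^-ddCt quantification), and
* allele-specific PCR band patterns, present exactly where the line carries
  the ALHF copy of the gene's physical autosome.

All generators are reproducible from an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .design import AUTOSOMES, Genotype, LineDesign, build_line_designs

REFERENCE_GENE = "beta_actin"

#: Default frequencies of factor-autosome subset classes. These mirror the
#: co-regulation partition observed in the study's 59-gene qPCR panel
#: (21 genes on {2,5}, 9 on {1,2,5}, 6 on {2,3,5}, singletons 4/6/1 on
#: autosomes 2/5/3, 3 on {1,2}, 3 on {1,2,3,5}, 2 each on {3,4,5} and
#: {2,4,5}, and 2 unregulated).
DEFAULT_CLASS_WEIGHTS: dict[frozenset[int], float] = {
    frozenset({2, 5}): 21 / 59,
    frozenset({1, 2, 5}): 9 / 59,
    frozenset({2, 3, 5}): 6 / 59,
    frozenset({2}): 4 / 59,
    frozenset({5}): 6 / 59,
    frozenset({3}): 1 / 59,
    frozenset({1, 2}): 3 / 59,
    frozenset({1, 2, 3, 5}): 3 / 59,
    frozenset({3, 4, 5}): 2 / 59,
    frozenset({2, 4, 5}): 2 / 59,
    frozenset(): 2 / 59,
}

# Loose category labels per subset class, echoing the functional make-up of
# the study's panel; purely cosmetic ground truth for the catalog stage.
_CLASS_CATEGORIES: dict[frozenset[int], tuple[str, str]] = {
    frozenset({2, 5}): ("metabolism", "redox"),
    frozenset({1, 2, 5}): ("metabolism", "redox"),
    frozenset({2, 3, 5}): ("regulation", "kinases/phosphatases"),
    frozenset({2}): ("regulation", "signal transduction"),
    frozenset({5}): ("metabolism", "redox"),
    frozenset({3}): ("intra-cellular processes", "proteases"),
    frozenset({1, 2}): ("regulation", "signal transduction"),
    frozenset({1, 2, 3, 5}): ("regulation", "kinases/phosphatases"),
    frozenset({3, 4, 5}): ("intra-cellular processes", "proteases"),
    frozenset({2, 4, 5}): ("intra-cellular processes", "proteases"),
    frozenset(): ("NONA", "not annotated"),
}


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass(frozen=True)
class GeneSpec:
    """Simulator ground truth for one gene."""

    gene_id: str
    physical_autosome: int
    factor_autosomes: frozenset[int]
    effect: dict[int, float]          # log2 effect per factor autosome, all > 0
    baseline_log2: float
    length_nt: int
    general_category: str = "NONA"
    detailed_category: str = "not annotated"

    def __post_init__(self) -> None:
        if self.physical_autosome not in AUTOSOMES:
            raise ValueError(f"physical_autosome must be in {AUTOSOMES}")
        if not self.factor_autosomes <= set(AUTOSOMES):
            raise ValueError("factor_autosomes must be a subset of the five autosomes")
        if set(self.effect) != set(self.factor_autosomes):
            raise ValueError("effect must be keyed exactly by factor_autosomes")
        if any(b <= 0 for b in self.effect.values()):
            raise ValueError("all log2 effects must be positive")
        if self.length_nt < 300:
            raise ValueError("length_nt must be >= 300 (minimum retained coding length)")


@dataclass(frozen=True)
class ArchitecturePriors:
    """Distribution over gene regulatory architectures.

    ``class_weights`` gives the probability of each factor-autosome subset;
    effects, baselines and lengths are drawn uniformly from the stated ranges.
    ``p_cis`` is the probability that a regulated gene physically resides on
    one of its own factor autosomes (the study's mapped genes all did).
    """

    class_weights: dict[frozenset[int], float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    effect_low: float = 0.8
    effect_high: float = 1.6
    baseline_low: float = 2.0
    baseline_high: float = 8.0
    length_low: int = 500
    length_high: int = 3000
    p_cis: float = 0.8

    def validate(self) -> None:
        total = sum(self.class_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-8):
            raise ConfigError(f"class weights must sum to 1, got {total}")
        if any(w < 0 for w in self.class_weights.values()):
            raise ConfigError("class weights must be non-negative")
        if not (0.0 <= self.p_cis <= 1.0):
            raise ConfigError("p_cis must lie in [0, 1]")
        if self.effect_low <= 0 or self.effect_high < self.effect_low:
            raise ConfigError("effect range must be positive and ordered")


@dataclass
class CountMatrix:
    """Integer fragment counts (genes x samples) with gene lengths and
    per-sample library sizes (the FPKM normalization denominators)."""

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series


def sample_architectures(
    n_genes: int, priors: ArchitecturePriors | None = None, seed: int = 0
) -> list[GeneSpec]:
    """Draw ``n_genes`` ground-truth gene architectures from the priors."""
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    priors = priors or ArchitecturePriors()
    priors.validate()
    rng = np.random.default_rng(seed)
    classes = sorted(priors.class_weights, key=lambda s: (len(s), sorted(s)))
    probs = np.array([priors.class_weights[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    specs: list[GeneSpec] = []
    width = len(str(n_genes))
    for i in range(n_genes):
        subset = classes[rng.choice(len(classes), p=probs)]
        effect = {
            a: float(rng.uniform(priors.effect_low, priors.effect_high)) for a in sorted(subset)
        }
        if subset and rng.random() < priors.p_cis:
            physical = int(rng.choice(sorted(subset)))
        else:
            physical = int(rng.choice(AUTOSOMES))
        general, detailed = _CLASS_CATEGORIES.get(subset, ("NONA", "not annotated"))
        specs.append(
            GeneSpec(
                gene_id=f"sim_{i:0{width}d}",
                physical_autosome=physical,
                factor_autosomes=subset,
                effect=effect,
                baseline_log2=float(rng.uniform(priors.baseline_low, priors.baseline_high)),
                length_nt=int(rng.integers(priors.length_low, priors.length_high + 1)),
                general_category=general,
                detailed_category=detailed,
            )
        )
    return specs


def expected_log2_expression(spec: GeneSpec, genotype: Genotype, model: str = "additive") -> float:
    """Expected log2 expression of a gene in a line with the given genotype."""
    present = [a for a in spec.factor_autosomes if genotype[a] == "R"]
    if model == "additive":
        return spec.baseline_log2 + sum(spec.effect[a] for a in present)
    if model == "and":
        if spec.factor_autosomes and len(present) == len(spec.factor_autosomes):
            return spec.baseline_log2 + sum(spec.effect.values())
        return spec.baseline_log2
    raise ConfigError(f"unknown expression model {model!r}")


def _expected_matrix(
    specs: list[GeneSpec], designs: list[LineDesign], model: str
) -> pd.DataFrame:
    data = {
        d.name: [expected_log2_expression(s, d.genotype, model) for s in specs] for d in designs
    }
    return pd.DataFrame(data, index=[s.gene_id for s in specs])


def simulate_replicates(
    specs: list[GeneSpec],
    designs: list[LineDesign] | None = None,
    n_reps: int = 3,
    noise_sd: float = 0.15,
    seed: int = 0,
    model: str = "additive",
) -> pd.DataFrame:
    """Linear-scale replicate expression: 2**(expected_log2 + N(0, noise_sd^2)).

    Returns a tidy frame (gene_id, sample, replicate, expression).
    """
    if n_reps < 2:
        raise ConfigError("n_reps must be >= 2")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    designs = designs or build_line_designs()
    rng = np.random.default_rng(seed)
    exp_log2 = _expected_matrix(specs, designs, model)
    eps = rng.normal(0.0, noise_sd, size=(len(specs), len(designs), n_reps))
    rows = []
    for gi, spec in enumerate(specs):
        for di, design in enumerate(designs):
            for r in range(n_reps):
                rows.append(
                    (
                        spec.gene_id,
                        design.name,
                        r + 1,
                        float(2.0 ** (exp_log2.iat[gi, di] + eps[gi, di, r])),
                    )
                )
    return pd.DataFrame(rows, columns=["gene_id", "sample", "replicate", "expression"])


def simulate_counts(
    specs: list[GeneSpec],
    designs: list[LineDesign] | None = None,
    mean_depth: float = 1e5,
    dispersion: float = 0.05,
    seed: int = 0,
    model: str = "additive",
) -> CountMatrix:
    """Negative-binomial fragment counts per gene x line.

    A sample's expected count for a gene is the library depth apportioned by
    the gene's share of expression x length (so expected FPKM is proportional
    to linear expression). ``dispersion`` is the NB phi with variance
    mu + phi*mu^2; phi = 0 degenerates to Poisson.
    """
    if dispersion < 0:
        raise ConfigError("dispersion must be >= 0")
    designs = designs or build_line_designs()
    rng = np.random.default_rng(seed)
    exp_lin = 2.0 ** _expected_matrix(specs, designs, model).to_numpy()
    lengths = np.array([s.length_nt for s in specs], dtype=float)
    weights = exp_lin * lengths[:, None]
    mu = mean_depth * weights / weights.sum(axis=0, keepdims=True)
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    gene_ids = [s.gene_id for s in specs]
    names = [d.name for d in designs]
    return CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=names),
        lengths=pd.Series(lengths.astype(int), index=gene_ids, name="length_nt"),
        library_sizes=pd.Series(float(mean_depth), index=names, name="library_size"),
    )


def simulate_ct(
    specs: list[GeneSpec],
    designs: list[LineDesign] | None = None,
    n_reps: int = 3,
    ct_noise_sd: float = 0.15,
    seed: int = 0,
    model: str = "additive",
    target_intercept: float = 34.0,
    reference_ct: float = 16.0,
) -> pd.DataFrame:
    """Raw qPCR cycle-threshold values, the exact inverse of 2^-ddCt.

    Target Ct = intercept - log2(linear expression) + noise; the reference
    gene's Ct is a strain-independent constant plus noise (the endogenous
    control is simulated strictly constant across lines, as the study's
    beta-actin control behaved). Perfect doubling efficiency is assumed.

    Returns a tidy frame (target_id, sample, replicate, ct).
    """
    if n_reps < 2:
        raise ConfigError("n_reps must be >= 2")
    designs = designs or build_line_designs()
    rng = np.random.default_rng(seed)
    exp_log2 = _expected_matrix(specs, designs, model)
    rows = []
    for spec in specs:
        for design in designs:
            base = target_intercept - exp_log2.at[spec.gene_id, design.name]
            for r in range(n_reps):
                rows.append(
                    (spec.gene_id, design.name, r + 1, float(base + rng.normal(0.0, ct_noise_sd)))
                )
    for design in designs:
        for r in range(n_reps):
            rows.append(
                (
                    REFERENCE_GENE,
                    design.name,
                    r + 1,
                    float(reference_ct + rng.normal(0.0, ct_noise_sd)),
                )
            )
    return pd.DataFrame(rows, columns=["target_id", "sample", "replicate", "ct"])


def simulate_bands(
    specs: list[GeneSpec],
    designs: list[LineDesign] | None = None,
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """ALHF-allele-specific PCR band patterns (gene x line, 'present'/'absent').

    A band appears exactly where the line carries the R (ALHF) allele of the
    gene's physical autosome; AS-PCR is treated as deterministic. A nonzero
    ``dropout_rate`` flips present bands to absent at that rate, for
    robustness checks only.
    """
    if not (0.0 <= dropout_rate <= 1.0):
        raise ConfigError("dropout_rate must lie in [0, 1]")
    designs = designs or build_line_designs()
    rng = np.random.default_rng(seed)
    data = {}
    for design in designs:
        col = []
        for spec in specs:
            present = design.genotype[spec.physical_autosome] == "R"
            if present and dropout_rate > 0 and rng.random() < dropout_rate:
                present = False
            col.append("present" if present else "absent")
        data[design.name] = col
    return pd.DataFrame(data, index=[s.gene_id for s in specs]).rename_axis("gene_id")


# ---------------------------------------------------------------------------
# Scenario configuration and TSV output


@dataclass
class Scenario:
    """A complete simulation scenario (the study-design defaults)."""

    n_genes: int = 200
    n_reps: int = 3
    noise_sd: float = 0.15
    dispersion: float = 0.05
    mean_depth: float = 1e5
    seed: int = 0
    model: str = "additive"
    priors: ArchitecturePriors = field(default_factory=ArchitecturePriors)

    def gene_specs(self) -> list[GeneSpec]:
        return sample_architectures(self.n_genes, self.priors, seed=self.seed)


def _parse_scalar(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def load_scenario(path: str | Path) -> Scenario:
    """Read a flat key=value scenario file.

    Recognized keys: n_genes, n_reps, noise_sd, dispersion, mean_depth, seed,
    model (additive|and), effect_low/high, baseline_low/high, length_low/high,
    p_cis, and subset-class weights as ``weight_<digits>`` (``weight_none``
    for the unregulated class), e.g. ``weight_25 = 0.3``.
    """
    scenario_fields = {f.name for f in fields(Scenario)} - {"priors"}
    prior_fields = {f.name for f in fields(ArchitecturePriors)} - {"class_weights"}
    sc_kwargs: dict = {}
    pr_kwargs: dict = {}
    weights: dict[frozenset[int], float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected key = value, got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in scenario_fields:
            sc_kwargs[key] = _parse_scalar(value)
        elif key in prior_fields:
            pr_kwargs[key] = _parse_scalar(value)
        elif key.startswith("weight_"):
            tag = key[len("weight_"):]
            subset = frozenset() if tag == "none" else frozenset(int(c) for c in tag)
            if not subset <= set(AUTOSOMES) and tag != "none":
                raise ConfigError(f"line {lineno}: bad subset key {key!r}")
            weights[subset] = float(value)
        else:
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
    priors = ArchitecturePriors(**pr_kwargs)
    if weights:
        priors = replace(priors, class_weights=weights)
    priors.validate()
    scenario = Scenario(priors=priors, **sc_kwargs)
    if scenario.model not in ("additive", "and"):
        raise ConfigError(f"model must be 'additive' or 'and', got {scenario.model!r}")
    return scenario


def write_truth(specs: list[GeneSpec], path: str | Path) -> None:
    rows = [
        {
            "gene_id": s.gene_id,
            "physical_autosome": s.physical_autosome,
            "factor_autosomes": ",".join(str(a) for a in sorted(s.factor_autosomes)),
            "effects": ",".join(f"{s.effect[a]:.4f}" for a in sorted(s.factor_autosomes)),
            "baseline_log2": f"{s.baseline_log2:.4f}",
            "length_nt": s.length_nt,
            "general_category": s.general_category,
            "detailed_category": s.detailed_category,
        }
        for s in specs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_scenario(scenario: Scenario, outdir: str | Path) -> list[GeneSpec]:
    """Generate every assay for a scenario and write the TSV bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs = scenario.gene_specs()
    designs = build_line_designs()
    kw = dict(model=scenario.model)
    simulate_replicates(
        specs, designs, scenario.n_reps, scenario.noise_sd, seed=scenario.seed + 1, **kw
    ).to_csv(outdir / "expression.tsv", sep="\t", index=False)
    cm = simulate_counts(
        specs, designs, scenario.mean_depth, scenario.dispersion, seed=scenario.seed + 2, **kw
    )
    cm.counts.rename_axis("gene_id").to_csv(outdir / "counts.tsv", sep="\t")
    cm.lengths.rename_axis("gene_id").to_frame().to_csv(outdir / "gene_lengths.tsv", sep="\t")
    cm.library_sizes.rename_axis("sample").to_frame().to_csv(outdir / "library_sizes.tsv", sep="\t")
    simulate_ct(
        specs, designs, scenario.n_reps, scenario.noise_sd, seed=scenario.seed + 3, **kw
    ).to_csv(outdir / "ct.tsv", sep="\t", index=False)
    simulate_bands(specs, designs).to_csv(outdir / "bands.tsv", sep="\t")
    write_truth(specs, outdir / "truth.tsv")
    return specs
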