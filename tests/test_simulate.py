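"""Generator correctness: architectures, expression model, counts, Ct, bands."""

import numpy as np
import pandas as pd
import pytest

from flylinkage.design import parse_line_name
from flylinkage.simulate import (
    ArchitecturePriors,
    ConfigError,
    GeneSpec,
    Scenario,
    expected_log2_expression,
    load_scenario,
    sample_architectures,
    simulate_bands,
    simulate_counts,
    simulate_ct,
    simulate_replicates,
)


def _spec(factors, beta=1.0, baseline=3.0, physical=2, gene_id="g"):
    return GeneSpec(
        gene_id=gene_id,
        physical_autosome=physical,
        factor_autosomes=frozenset(factors),
        effect={a: beta for a in factors},
        baseline_log2=baseline,
        length_nt=1000,
    )


class TestArchitectures:
    def test_seed_reproducibility(self):
        a = sample_architectures(30, seed=42)
        b = sample_architectures(30, seed=42)
        assert a == b
        assert a != sample_architectures(30, seed=43)

    def test_point_mass_prior(self):
        priors = ArchitecturePriors(class_weights={frozenset({2, 5}): 1.0})
        specs = sample_architectures(25, priors, seed=0)
        assert all(s.factor_autosomes == {2, 5} for s in specs)

    def test_class_frequencies_match_priors(self):
        # four equiprobable classes; realized frequencies within 3 binomial SEs
        classes = [frozenset({2, 5}), frozenset({5}), frozenset({1, 2, 5}), frozenset()]
        priors = ArchitecturePriors(class_weights={c: 0.25 for c in classes})
        n = 10_000
        specs = sample_architectures(n, priors, seed=1)
        se = np.sqrt(0.25 * 0.75 / n)
        for c in classes:
            freq = sum(s.factor_autosomes == c for s in specs) / n
            assert abs(freq - 0.25) < 3 * se

    def test_invalid_priors_rejected(self):
        priors = ArchitecturePriors(class_weights={frozenset({2}): 0.7})
        with pytest.raises(ConfigError):
            sample_architectures(5, priors)


class TestExpressionModel:
    def test_additive_closed_form(self, designs_by_name):
        spec = _spec({2, 5})
        assert expected_log2_expression(spec, designs_by_name["ALHF"].genotype) == 5.0
        assert expected_log2_expression(spec, designs_by_name["A1345"].genotype) == 4.0
        assert expected_log2_expression(spec, designs_by_name["aabys"].genotype) == 3.0

    def test_unregulated_gene_flat(self, designs):
        spec = _spec(set())
        vals = {expected_log2_expression(spec, d.genotype) for d in designs}
        assert vals == {3.0}

    def test_parental_fold_change_is_two_to_sum_beta(self, designs_by_name):
        spec = _spec({1, 2, 5}, beta=0.9)
        fc = 2.0 ** (
            expected_log2_expression(spec, designs_by_name["ALHF"].genotype)
            - expected_log2_expression(spec, designs_by_name["aabys"].genotype)
        )
        assert fc == pytest.approx(2.0 ** (3 * 0.9))

    def test_substitution_never_exceeds_parent(self, designs, designs_by_name):
        # equality holds exactly when the substituted autosome is not a factor
        specs = sample_architectures(50, seed=2)
        top = {s.gene_id: expected_log2_expression(s, designs_by_name["ALHF"].genotype) for s in specs}
        for d in designs:
            if d.substituted_autosome is None:
                continue
            for s in specs:
                v = expected_log2_expression(s, d.genotype)
                assert v <= top[s.gene_id]
                assert (v == top[s.gene_id]) == (d.substituted_autosome not in s.factor_autosomes)

    def test_and_model_all_or_nothing(self, designs_by_name):
        spec = _spec({2, 5})
        assert expected_log2_expression(spec, designs_by_name["A1345"].genotype, model="and") == 3.0
        assert expected_log2_expression(spec, designs_by_name["ALHF"].genotype, model="and") == 5.0


class TestReplicates:
    def test_noiseless_replicates_exact(self, designs):
        spec = _spec({2, 5})
        rel = simulate_replicates([spec], designs, n_reps=3, noise_sd=0.0, seed=0)
        alhf = rel[rel["sample"] == "ALHF"]["expression"]
        assert np.allclose(alhf, 2.0**5)
        assert np.allclose(rel[rel["sample"] == "aabys"]["expression"], 2.0**3)

    def test_seed_reproducibility(self, designs):
        spec = _spec({2})
        a = simulate_replicates([spec], designs, seed=9)
        b = simulate_replicates([spec], designs, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_log2_mean_converges(self, designs):
        # Monte-Carlo: mean of log2 replicates within 4 SE of the expectation
        spec = _spec({2, 5})
        rel = simulate_replicates([spec], designs, n_reps=10_000, noise_sd=0.3, seed=3)
        vals = np.log2(rel[rel["sample"] == "ALHF"]["expression"])
        assert abs(vals.mean() - 5.0) < 4 * 0.3 / np.sqrt(len(vals))


class TestCounts:
    def test_poisson_limit_variance(self, designs):
        # phi=0: sample variance over many draws matches the mean
        specs = [_spec(set(), baseline=5.0, gene_id=f"g{i}") for i in range(2000)]
        cm = simulate_counts(specs, designs, mean_depth=1e5, dispersion=0.0, seed=4)
        col = cm.counts["ALHF"].to_numpy(dtype=float)
        mu = col.mean()
        assert cm.counts.to_numpy().min() >= 0
        assert col.var() == pytest.approx(mu, rel=0.15)

    def test_doubling_depth_doubles_counts(self, designs):
        specs = [_spec({2, 5}, gene_id=f"g{i}", baseline=float(3 + i % 4)) for i in range(500)]
        lo = simulate_counts(specs, designs, mean_depth=5e4, dispersion=0.05, seed=5)
        hi = simulate_counts(specs, designs, mean_depth=1e5, dispersion=0.05, seed=6)
        ratio = hi.counts.to_numpy().sum() / lo.counts.to_numpy().sum()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_negative_dispersion_rejected(self, designs):
        with pytest.raises(ConfigError):
            simulate_counts([_spec({2})], designs, dispersion=-0.1)


class TestCt:
    def test_noiseless_fold_change_in_cycles(self, designs):
        # a gene 2-fold up in the parent shows a Ct exactly 1 cycle lower
        spec = _spec({2}, beta=1.0)
        ct = simulate_ct([spec], designs, ct_noise_sd=0.0, seed=0)
        tgt = ct[ct["target_id"] == "g"].groupby("sample")["ct"].mean()
        assert tgt["aabys"] - tgt["ALHF"] == pytest.approx(1.0)

    def test_reference_constant_across_samples(self, designs):
        ct = simulate_ct([_spec({2, 5})], designs, ct_noise_sd=0.0, seed=0)
        ref = ct[ct["target_id"] == "beta_actin"]["ct"]
        assert ref.nunique() == 1


class TestBands:
    @pytest.mark.parametrize(
        "physical,absent_in", [(5, {"A1234", "aabys"}), (2, {"A1345", "aabys"})]
    )
    def test_absence_marks_the_substituted_autosome(self, designs, physical, absent_in):
        spec = _spec({2, 5}, physical=physical)
        bands = simulate_bands([spec], designs)
        absent = {c for c in bands.columns if bands.at["g", c] == "absent"}
        assert absent == absent_in

    def test_parent_always_banded(self, designs):
        specs = sample_architectures(40, seed=7)
        bands = simulate_bands(specs, designs)
        assert (bands["ALHF"] == "present").all()
        assert (bands["aabys"] == "absent").all()


def test_scenario_config_round_trip(tmp_path):
    cfg = tmp_path / "scenario.cfg"
    cfg.write_text(
        "n_genes = 10\nnoise_sd = 0.2\nmodel = and\nweight_25 = 0.5\nweight_none = 0.5\np_cis = 1.0\n"
    )
    sc = load_scenario(cfg)
    assert sc.n_genes == 10 and sc.model == "and"
    assert sc.priors.class_weights == {frozenset({2, 5}): 0.5, frozenset(): 0.5}
    specs = sc.gene_specs()
    regulated = [s for s in specs if s.factor_autosomes]
    assert all(s.factor_autosomes == {2, 5} for s in regulated)
    # p_cis = 1: regulated genes sit on one of their own factor autosomes
    assert all(s.physical_autosome in s.factor_autosomes for s in regulated)


def test_scenario_bad_key_rejected(tmp_path):
    cfg = tmp_path / "bad.cfg"
    cfg.write_text("n_gene = 10\n")
    with pytest.raises(ConfigError):
        load_scenario(cfg)
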