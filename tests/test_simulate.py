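"""Synthetic panel generator: determinism, archetypes, operating characteristics."""

import numpy as np
import pandas as pd
import pytest

from delphistats import (
    ConfigError,
    ConsensusModel,
    ItemArchetype,
    SimulationConfig,
    recovery_experiment,
    simulate_study,
)


class TestArchetypes:
    def test_point_mass_limit(self):
        arch = ItemArchetype("consensus", location=2.0, dispersion=0.0)
        rng = np.random.default_rng(0)
        scores = arch.draw(rng, 24)
        assert (scores == 2).all()

    def test_ratings_always_on_scale(self):
        rng = np.random.default_rng(1)
        for arch in (
            ItemArchetype("consensus", location=1.0, dispersion=4.0),
            ItemArchetype("consensus", location=9.0, dispersion=4.0),
            ItemArchetype("polarized", dispersion=2.0),
            ItemArchetype("uniform"),
        ):
            scores = arch.draw(rng, 200)
            assert scores.dtype.kind == "i"
            assert scores.min() >= 1 and scores.max() <= 9

    def test_polarized_mix_is_panel_composition(self):
        arch = ItemArchetype("polarized", poles=(1.0, 9.0), mix=0.25, dispersion=0.0)
        scores = arch.draw(np.random.default_rng(2), 24)
        assert sorted(np.unique(scores)) == [1, 9]
        assert (scores == 1).sum() == 6  # round(0.25 * 24)

    def test_true_bands(self):
        assert ItemArchetype("consensus", location=2.0).true_band() == "inappropriate"
        assert ItemArchetype("uniform").true_band() == "equivocal"
        assert ItemArchetype("polarized", mix=0.9).true_band() == "inappropriate"

    def test_invalid_parameters(self):
        with pytest.raises(ConfigError):
            ItemArchetype("bimodal")
        with pytest.raises(ConfigError):
            ItemArchetype("consensus", location=0.5)
        with pytest.raises(ConfigError):
            ItemArchetype("consensus", dispersion=-1)
        with pytest.raises(ConfigError):
            ItemArchetype("polarized", mix=1.5)


class TestSimulateStudy:
    def test_same_seed_identical_studies(self):
        a = simulate_study(SimulationConfig(seed=11))
        b = simulate_study(SimulationConfig(seed=11))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_different_seeds_differ(self):
        a = simulate_study(SimulationConfig(seed=11))
        b = simulate_study(SimulationConfig(seed=12))
        assert not a.data.equals(b.data)

    def test_design_shape(self):
        study = simulate_study(SimulationConfig(seed=5))
        assert len(study.roster(1)) == 24
        assert len(study.item_ids(1)) == 20
        assert len(study.item_ids(2)) == 33
        assert set(study.roster(2)) <= set(study.roster(1))
        assert len(study.lineage) == 13
        relations = [ln.relation for ln in study.lineage]
        assert relations.count("split") == 2 and relations.count("modified") == 11

    def test_degenerate_consensus_item_classified_exactly(self):
        arch = {f"S{i:02d}": ItemArchetype("consensus", location=2.0, dispersion=0.0)
                for i in range(1, 4)}
        config = SimulationConfig(
            n_panellists_round1=10, n_items_round1=3, n_modified_items=0,
            attrition=0.0, feedback_shift=0.0, archetypes=arch, seed=3,
        )
        res = ConsensusModel(simulate_study(config)).fit()
        for (item, _), summ in res.summaries.items():
            assert summ.di == 0
            assert res.classifications[(item, 2)].band == "inappropriate"

    def test_attrition_mean_matches_expectation(self):
        config_attrition = 5.0 / 24.0
        sizes = [
            len(simulate_study(SimulationConfig(seed=s)).roster(2)) for s in range(120)
        ]
        expected = 24 * (1 - config_attrition)
        se = np.sqrt(24 * config_attrition * (1 - config_attrition) / len(sizes))
        assert abs(np.mean(sizes) - expected) < 3 * se

    def test_adding_items_preserves_existing_draws(self):
        shared = {f"S{i:02d}": ItemArchetype("consensus", location=2.0, dispersion=1.0)
                  for i in range(1, 6)}
        extended = dict(shared)
        extended["S06"] = ItemArchetype("uniform")
        small = SimulationConfig(n_items_round1=5, n_modified_items=0,
                                 archetypes=shared, seed=9)
        large = SimulationConfig(n_items_round1=6, n_modified_items=0,
                                 archetypes=extended, seed=9)
        a, b = simulate_study(small), simulate_study(large)
        for item in a.item_ids(1):
            assert list(a.ratings(item, 1)) == list(b.ratings(item, 1))

    def test_feedback_shift_moves_toward_round1_median(self):
        # with certain shift, round-2 scores sit one step closer to the
        # round-1 median than a zero-shift twin, never crossing it
        arch = {"S01": ItemArchetype("uniform")}
        base = SimulationConfig(n_panellists_round1=30, n_items_round1=1,
                                n_modified_items=0, attrition=0.0,
                                feedback_shift=0.0, archetypes=arch, seed=21)
        shifted = SimulationConfig(n_panellists_round1=30, n_items_round1=1,
                                   n_modified_items=0, attrition=0.0,
                                   feedback_shift=1.0, archetypes=arch, seed=21)
        a, b = simulate_study(base), simulate_study(shifted)
        med = np.median(a.ratings("S01", 1))
        raw = a.ratings("S01", 2)
        moved = b.ratings("S01", 2)
        for x, y in zip(raw, moved):
            if abs(med - x) >= 1:
                assert y == x + np.sign(med - x)
            else:
                assert y == x
            assert abs(med - y) <= abs(med - x)

    def test_feasibility_dimension_optional(self):
        config = SimulationConfig(seed=2, rate_feasibility=True)
        study = simulate_study(config)
        assert set(study.data["dimension"]) == {"appropriateness", "feasibility"}
        feas = study.data[study.data["dimension"] == "feasibility"]
        assert set(feas["round"]) == {2}

    def test_invalid_config(self):
        with pytest.raises(ConfigError):
            SimulationConfig(attrition=1.5)
        with pytest.raises(ConfigError):
            SimulationConfig(n_panellists_round1=0)
        with pytest.raises(ConfigError):
            SimulationConfig(archetypes={"S01": ItemArchetype()})  # wrong count

    def test_config_from_yaml(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text(
            "n_panellists_round1: 6\nn_items_round1: 2\nn_modified_items: 0\n"
            "archetypes:\n"
            "  S01: {kind: consensus, location: 2, dispersion: 0.5}\n"
            "  S02: {kind: polarized, poles: [1, 9], mix: 0.5}\n"
        )
        config = SimulationConfig.from_file(path)
        assert config.archetypes["S02"].kind == "polarized"
        assert simulate_study(config).item_ids(1) == ["S01", "S02"]


class TestRecoveryExperiment:
    def test_degenerate_consensus_is_always_recovered(self):
        arch = ItemArchetype("consensus", location=2.0, dispersion=0.0)
        table = recovery_experiment([(arch, 6), (arch, 24)], replicates=50, seed=0)
        assert (table["band_accuracy"] == 1.0).all()
        assert (table["p_agreement"] == 1.0).all()

    def test_uniform_agrees_less_than_tight_consensus(self):
        grid = [
            (ItemArchetype("uniform"), 24),
            (ItemArchetype("consensus", location=5.0, dispersion=1.0), 24),
        ]
        table = recovery_experiment(grid, replicates=1000, seed=1)
        uniform, consensus = table["p_agreement"]
        assert uniform < consensus - 0.2

    def test_accuracy_nondecreasing_in_panel_size(self):
        arch = ItemArchetype("consensus", location=2.0, dispersion=2.0)
        table = recovery_experiment(
            [(arch, n) for n in (6, 12, 24, 48)], replicates=2000, seed=2
        )
        acc = table.sort_values("n")["band_accuracy"].to_numpy()
        assert (np.diff(acc) >= 0).all()

    def test_reproducible_and_se_reported(self):
        grid = [(ItemArchetype("uniform"), 12)]
        a = recovery_experiment(grid, replicates=200, seed=3)
        b = recovery_experiment(grid, replicates=200, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert (a["p_agreement_se"] >= 0).all()
        assert (a["p_agreement"].between(0, 1)).all()

    def test_matches_item_pipeline_on_same_draws(self):
        # the vectorised experiment and the per-item summary path must agree
        from delphistats.simulate import _draw_matrix, _item_stream, _vector_summaries
        from delphistats.stats import DEFAULT_CONFIG, summarize_item

        arch = ItemArchetype("consensus", location=4.0, dispersion=2.0)
        draws = _draw_matrix(arch, _item_stream(0, 99), 20, 15)
        vec = _vector_summaries(draws, DEFAULT_CONFIG)
        for i in range(draws.shape[0]):
            s = summarize_item(draws[i])
            assert vec["median"].iloc[i] == pytest.approx(s.median)
            assert vec["di"].iloc[i] == pytest.approx(s.di)

    def test_bad_inputs(self):
        with pytest.raises(ConfigError):
            recovery_experiment([], replicates=10)
        with pytest.raises(ConfigError):
            recovery_experiment([(ItemArchetype(), 10)], replicates=0)
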