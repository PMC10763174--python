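"""Percentiles, the disagreement index and the classification rule."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delphistats import (
    Classification,
    ClassificationConfig,
    ConfigError,
    DomainError,
    EmptyPanelError,
    band_of,
    classify,
    disagreement_index,
    percentile,
    summarize_item,
)
from conftest import oracle_summary

scores_strategy = st.lists(st.integers(1, 9), min_size=1, max_size=40)


class TestPercentile:
    def test_constant_sample(self):
        assert percentile([2, 2, 2, 2, 2], 0.30) == 2

    def test_linear_interpolation_position(self):
        # position (n-1)q + 1 = 3.4 for n=9, q=0.30
        assert percentile(range(1, 10), 0.30) == pytest.approx(3.4)

    def test_alternative_methods(self):
        assert percentile(range(1, 10), 0.30, method="nearest_rank") == 3
        # weibull: position (n+1)q = 3.0
        assert percentile(range(1, 10), 0.30, method="weibull") == pytest.approx(3.0)

    def test_result_bounded_by_sample(self):
        s = [1, 4, 9]
        for q in (0.01, 0.3, 0.7, 0.99):
            assert min(s) <= percentile(s, q) <= max(s)

    def test_empty_and_domain_errors(self):
        with pytest.raises(EmptyPanelError):
            percentile([], 0.3)
        with pytest.raises(DomainError):
            percentile([1], 0.0)
        with pytest.raises(DomainError):
            percentile([1], 1.0)
        with pytest.raises(ConfigError):
            percentile([1], 0.3, method="harrell-davis")

    @given(scores_strategy, st.sampled_from([0.1, 0.3, 0.5, 0.7, 0.9]))
    @settings(derandomize=True, max_examples=80)
    def test_reflection_identity(self, scores, q):
        flipped = [10 - s for s in scores]
        assert percentile(flipped, 1 - q) == pytest.approx(10 - percentile(scores, q))


class TestDisagreementIndex:
    def test_symmetric_extreme(self):
        ipr, iprcp, ai, ipras, di = disagreement_index(1, 9)
        assert (ipr, iprcp, ai, ipras) == (8, 5.0, 0.0, 2.35)
        assert di == pytest.approx(8 / 2.35)

    def test_degenerate_pair(self):
        ipr, *_, di = disagreement_index(2, 2)
        assert ipr == 0 and di == 0

    def test_asymmetric_pair(self):
        ipr, iprcp, ai, ipras, di = disagreement_index(2, 3)
        assert (ipr, iprcp, ai) == (1, 2.5, 2.5)
        assert ipras == pytest.approx(6.10)
        assert di == pytest.approx(1 / 6.10)

    def test_inverted_pair_rejected(self):
        with pytest.raises(DomainError):
            disagreement_index(5, 3)


class TestSummarizeItem:
    def test_unanimous_panel(self):
        s = summarize_item([2] * 19)
        assert (s.median, s.p_low, s.p_high, s.di) == (2, 2, 2, 0)
        assert s.bins == (19, 0, 0)

    def test_split_panel_disagrees(self):
        s = summarize_item([1, 1, 1, 9, 9, 9])
        assert s.median == 5
        assert s.p_low <= 3 and s.p_high >= 7
        assert s.di > 1

    def test_empty_panel(self):
        with pytest.raises(EmptyPanelError):
            summarize_item([])

    @given(scores_strategy)
    @settings(derandomize=True, max_examples=80)
    def test_permutation_invariance(self, scores):
        rng = np.random.default_rng(1)
        a = summarize_item(scores)
        b = summarize_item(list(rng.permutation(scores)))
        assert a == b

    @given(scores_strategy)
    @settings(derandomize=True, max_examples=80)
    def test_reflection_symmetry(self, scores):
        a = summarize_item(scores)
        b = summarize_item([10 - s for s in scores])
        assert b.median == pytest.approx(10 - a.median)
        assert b.ipr == pytest.approx(a.ipr)
        assert b.ai == pytest.approx(a.ai)
        assert b.ipras == pytest.approx(a.ipras)
        assert b.di == pytest.approx(a.di)
        assert b.bins == a.bins[::-1]
        bands = {"inappropriate": "appropriate", "appropriate": "inappropriate",
                 "equivocal": "equivocal"}
        assert classify(b).band == bands[classify(a).band]

    def test_matches_oracle_small_samples(self):
        # exhaustive over multisets of size <= 4; size <= 6 runs in the
        # acceptance suite
        for n in range(1, 5):
            for combo in itertools.combinations_with_replacement(range(1, 10), n):
                s = summarize_item(combo)
                o = oracle_summary(combo)
                for field in ("median", "p_low", "p_high", "ipr", "ipras", "di"):
                    assert getattr(s, field) == pytest.approx(o[field], abs=1e-12), combo
                assert s.bins == o["bins"]

    def test_adding_median_rating_never_raises_di(self):
        for n in range(2, 6):
            for combo in itertools.combinations_with_replacement(range(1, 10), n):
                base = summarize_item(combo)
                med = base.median
                if med != int(med):
                    continue  # only integer medians can be added as ratings
                grown = summarize_item(list(combo) + [int(med)])
                assert grown.di <= base.di + 1e-12, combo


class TestClassification:
    def test_agreement_on_inappropriateness(self):
        c = classify(median=2, di=0.203)
        assert (c.agreement, c.band, c.label) == ("agreement", "inappropriate", "A/IA")

    def test_agreement_on_equivocality(self):
        c = classify(median=5, di=0.599)
        assert (c.agreement, c.band, c.label) == ("agreement", "equivocal", "Neutral")

    def test_agreement_on_appropriateness(self):
        assert classify(median=8, di=0.2).label == "A/A"

    def test_disagreement_at_high_di(self):
        assert classify(median=5, di=3.40).agreement == "disagreement"

    def test_threshold_is_disagreement(self):
        assert classify(median=5, di=1.0).agreement == "disagreement"
        assert classify(median=5, di=0.999).agreement == "agreement"

    def test_half_integer_medians(self):
        assert band_of(2.5) == "inappropriate"
        assert band_of(4.5) == "equivocal"
        assert band_of(3.5) == "equivocal"
        assert band_of(6.5) == "equivocal"
        assert band_of(7.5) == "appropriate"

    def test_label_round_trip(self):
        for label in ("A/IA", "Neutral", "A/A", "Disagreement"):
            assert Classification.from_label(label).label == label

    def test_config_overrides(self):
        lax = ClassificationConfig(di_threshold=2.0)
        assert classify(median=5, di=1.5, config=lax).agreement == "agreement"
        wide = ClassificationConfig(ipras_intercept=1.0, ipras_slope=0.0)
        *_, di = disagreement_index(1, 9, wide)
        assert di == pytest.approx(8.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            ClassificationConfig(q_low=0.0)
        with pytest.raises(ConfigError):
            ClassificationConfig(q_low=0.8, q_high=0.2)
        with pytest.raises(ConfigError):
            ClassificationConfig(method="magic")

    def test_config_from_yaml(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("di_threshold: 0.5\nmethod: nearest_rank\n")
        cfg = ClassificationConfig.from_file(path)
        assert cfg.di_threshold == 0.5 and cfg.method == "nearest_rank"
        bad = tmp_path / "bad.yaml"
        bad.write_text("frobnicate: 1\n")
        with pytest.raises(ConfigError):
            ClassificationConfig.from_file(bad)
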