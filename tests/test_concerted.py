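from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from txpanel import PipelineConfig
from txpanel.errors import InsufficientDataError, ValidationError
from txpanel import concerted as tc


class TestNullProbability:
    def test_full_support_is_one(self):
        assert tc.null_probability(60, 60) == 1.0

    def test_single_outcome(self):
        assert tc.null_probability(60, 0) == pytest.approx(2.0 ** -60)

    def test_matches_exact_rational_summation(self):
        expected = float(Fraction(sum(comb(60, k) for k in range(16)), 2 ** 60))
        assert tc.null_probability(60, 15) == expected

    @pytest.mark.parametrize("n,t", [(20, 5), (40, 10), (60, 15), (7, 3)])
    def test_cross_check_against_scipy_binomial_cdf(self, n, t):
        assert tc.null_probability(n, t) == pytest.approx(
            binom.cdf(t, n, 0.5), rel=1e-12)

    def test_increasing_in_threshold_decreasing_in_n(self):
        probs_t = [tc.null_probability(60, t) for t in range(0, 31)]
        assert all(a < b for a, b in zip(probs_t, probs_t[1:]))
        probs_n = [tc.null_probability(n, 15) for n in (40, 50, 60, 70)]
        assert all(a > b for a, b in zip(probs_n, probs_n[1:]))

    def test_threshold_outside_support_is_error(self):
        with pytest.raises(ValidationError):
            tc.null_probability(10, 11)
        with pytest.raises(ValidationError):
            tc.null_probability(10, -1)

    @pytest.mark.parametrize("n,t", [(20, 5), (40, 10), (60, 15)])
    def test_monte_carlo_agreement(self, n, t):
        """Exact tail within 3 binomial standard errors of a 10^6-draw
        Monte-Carlo estimate of P(#discordant <= t)."""
        rng = np.random.default_rng(1000 + n + t)
        draws = rng.binomial(n, 0.5, size=1_000_000)
        discordant = np.minimum(draws, n - draws)
        # P(min(X, n-X) <= t) = 2 P(X <= t) for t < n/2 (symmetric, disjoint)
        est = float((discordant <= t).mean())
        exact = 2.0 * tc.null_probability(n, t)
        se = np.sqrt(exact * (1 - exact) / 1_000_000)
        assert abs(est - exact) <= 3 * se


class TestClassify:
    def test_unanimous_up(self):
        call = tc.classify_concerted(np.ones(60), threshold=15, min_n=40)
        assert (call.direction, call.n_pos, call.n_neg) == ("up", 60, 0)

    def test_boundary_exceeded_is_none(self):
        fc = np.r_[np.ones(44), -np.ones(16)]
        assert tc.classify_concerted(fc, 15, 40).direction == "none"

    def test_boundary_inclusive(self):
        fc = np.r_[np.ones(45), -np.ones(15)]
        assert tc.classify_concerted(fc, 15, 40).direction == "up"

    def test_zeros_count_neither_direction(self):
        fc = np.r_[np.ones(45), np.zeros(15)]
        call = tc.classify_concerted(fc, 15, 40)
        assert (call.n_pos, call.n_neg, call.n_zero) == (45, 0, 15)
        assert call.direction == "up"

    def test_insufficient_lines_flagged(self):
        call = tc.classify_concerted(np.ones(30), 15, min_n=40)
        assert not call.sufficient
        assert call.direction == "none"

    def test_tie_is_none(self):
        fc = np.r_[np.ones(5), -np.ones(5)]
        assert tc.classify_concerted(fc, 15, min_n=1).direction == "none"

    def test_all_missing_is_error(self):
        with pytest.raises(InsufficientDataError):
            tc.classify_concerted([np.nan, np.nan])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1,
                    max_size=80),
           st.integers(0, 20))
    def test_sign_symmetry(self, fc, threshold):
        fc = np.asarray(fc)
        a = tc.classify_concerted(fc, threshold, min_n=1)
        b = tc.classify_concerted(-fc, threshold, min_n=1)
        assert (a.n_pos, a.n_neg) == (b.n_neg, b.n_pos)
        flip = {"up": "down", "down": "up", "none": "none"}
        assert flip[a.direction] == b.direction

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1,
                    max_size=80),
           st.integers(0, 20), st.integers(0, 20))
    def test_threshold_monotonicity(self, fc, t1, t2):
        """A concerted call at threshold t persists at any looser t' >= t."""
        lo, hi = sorted((t1, t2))
        a = tc.classify_concerted(fc, lo, min_n=1)
        b = tc.classify_concerted(fc, hi, min_n=1)
        if a.direction != "none":
            assert b.direction == a.direction


class TestAmplitudeTier:
    @pytest.mark.parametrize("fc,direction,tier", [
        ([2.437, 0.648, -0.696], "up", 1.0),
        ([4.2, 0.1], "up", 4.0),
        ([0.9, 0.3], "up", None),
        ([2.6, 0.0], "up", 2.5),
        ([-4.2, -0.1], "down", 4.0),
        ([-0.9], "down", None),
    ])
    def test_highest_reached_tier(self, fc, direction, tier):
        assert tc.amplitude_tier(fc, direction) == tier

    def test_undefined_for_direction_none(self):
        with pytest.raises(ValidationError):
            tc.amplitude_tier([1.0], "none")


class TestConsensusTable:
    @staticmethod
    def _tensor(fc_by_gene, agent="d", conc="high", t=24):
        rows = []
        for gene, values in fc_by_gene.items():
            for i, v in enumerate(values):
                rows.append((gene, f"CL{i:02d}", agent, conc, t, v))
        return pd.DataFrame(rows, columns=["gene", "cell_line", "agent",
                                           "concentration", "time_hr",
                                           "log2fc"])

    def test_planted_up_gene_called(self):
        rng = np.random.default_rng(0)
        fc = np.abs(rng.normal(1.2, 0.4, size=60))
        fc[:2] *= -1   # 58/60 lines up
        tensor = self._tensor({"GU": fc})
        table = tc.build_consensus_table(tensor, PipelineConfig())
        row = table.iloc[0]
        assert row["direction"] == "up"
        assert row["n_neg"] == 2
        assert row["null_p"] == pytest.approx(tc.null_probability(60, 15))

    def test_null_p_uses_directional_count(self):
        fc = np.r_[np.ones(45), np.zeros(10), -np.ones(5)]
        table = tc.build_consensus_table(self._tensor({"G": fc}),
                                         PipelineConfig())
        assert table.iloc[0]["null_p"] == pytest.approx(
            tc.null_probability(50, 15))

    def test_empty_condition_has_no_row(self):
        table = tc.build_consensus_table(self._tensor({"G": np.ones(60)}),
                                         PipelineConfig())
        assert len(table) == 1   # only the one condition with data

    def test_empty_tensor_is_error(self):
        with pytest.raises(ValidationError):
            tc.build_consensus_table(self._tensor({}), PipelineConfig())

    def test_rows_match_per_vector_classifier(self):
        rng = np.random.default_rng(3)
        tensor = self._tensor({f"G{i}": rng.normal(size=60)
                               for i in range(10)})
        cfg = PipelineConfig()
        table = tc.build_consensus_table(tensor, cfg)
        for row in table.itertuples():
            fc = tensor[tensor.gene == row.gene]["log2fc"].to_numpy()
            call = tc.classify_concerted(fc, cfg.discordance_threshold,
                                         cfg.min_cell_lines)
            assert (row.n_pos, row.n_neg, row.direction) == (
                call.n_pos, call.n_neg, call.direction)

    def test_compact_notation(self):
        tensor = pd.concat([
            self._tensor({"G": np.full(60, 2.7)}, conc="high", t=24),
            self._tensor({"G": np.full(60, -0.5)}, conc="low", t=6),
        ], ignore_index=True)
        table = tc.build_consensus_table(tensor, PipelineConfig())
        compact = tc.compact_notation(table)
        assert compact.iloc[0]["calls"] == "H24↑**,L6↓"
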