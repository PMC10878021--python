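import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from txpanel import PipelineConfig
from txpanel.errors import InsufficientDataError, ValidationError
from txpanel import association as ta
from txpanel.preprocess import collapse_probes, compute_log2fc


class TestCorrelate:
    def test_reversed_ranks_give_minus_one(self):
        """Three cell lines whose fold changes and log(GI50) are exactly
        rank-reversed: the sensitive line has the largest upregulation."""
        x = [2.437, 0.648, -0.696]
        y = [-8.0, -7.728, -4.952]
        res = ta.correlate(x, y, "spearman", min_pairs=3)
        assert res.rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("method", ["spearman", "pearson"])
    def test_identity_gives_one(self, method):
        x = np.arange(12.0)
        res = ta.correlate(x, x, method, min_pairs=10)
        assert res.rho == pytest.approx(1.0)
        assert res.n_pairs == 12

    def test_zero_variance_is_degenerate_not_zero(self):
        res = ta.correlate(np.ones(12), np.arange(12.0), "spearman",
                           min_pairs=10)
        assert res.degenerate and np.isnan(res.rho)

    def test_missing_pairs_dropped(self):
        x = np.r_[np.arange(11.0), np.nan]
        y = np.r_[np.nan, np.arange(11.0)]
        res = ta.correlate(x, y, "pearson", min_pairs=10)
        assert res.n_pairs == 10

    def test_too_few_pairs_is_error(self):
        with pytest.raises(InsufficientDataError):
            ta.correlate([1, 2, 3], [1, 2, 3], "spearman", min_pairs=10)

    def test_unknown_method_is_error(self):
        with pytest.raises(ValidationError):
            ta.correlate([1, 2], [1, 2], "kendall", min_pairs=2)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_spearman_monotone_invariance_pearson_affine_invariance(self, s):
        rng = np.random.default_rng(s)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base_s = ta.correlate(x, y, "spearman").rho
        assert ta.correlate(np.exp(x), y, "spearman").rho == pytest.approx(base_s)
        base_p = ta.correlate(x, y, "pearson").rho
        assert ta.correlate(3.0 * x + 7.0, y, "pearson").rho == pytest.approx(base_p)


def _bh_oracle(p):
    """Literal step-up definition: sort ascending, adjusted_(i) =
    min_{j>=i} m p_(j)/j capped at 1, restore original order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        best = 1.0
        for rank_j in range(rank_i, m + 1):
            best = min(best, m * p[order[rank_j - 1]] / rank_j)
        adjusted[idx] = best
    return adjusted


class TestBenjaminiHochberg:
    def test_monotone_envelope_example(self):
        out = ta.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    def test_single_p_unchanged(self):
        assert ta.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_capped_at_one(self):
        assert np.allclose(ta.bh_adjust([1.0, 1.0]), [1.0, 1.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 12))
    def test_matches_double_loop_oracle(self, s, m):
        p = np.random.default_rng(s).uniform(size=m)
        assert np.allclose(ta.bh_adjust(p), _bh_oracle(p))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_output_monotone_in_p0(self, s):
        p = np.random.default_rng(s).uniform(size=10)
        adj = ta.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestPoolFdr:
    @staticmethod
    def _frame():
        return pd.DataFrame({
            "agent": ["a", "a", "b", "b"] * 2,
            "method": ["spearman"] * 4 + ["pearson"] * 4,
            "p0": [0.01, 0.8, 0.02, 0.5, 0.03, 0.6, 0.04, np.nan],
        })

    def test_global_family_pools_across_agents(self):
        out = ta.pool_fdr(self._frame(), "global")
        sp = out[out.method == "spearman"]
        assert np.allclose(sp["p_fdr"], _bh_oracle([0.01, 0.8, 0.02, 0.5]))

    def test_per_agent_family(self):
        out = ta.pool_fdr(self._frame(), "per_agent")
        row = out[(out.method == "spearman") & (out.agent == "a")
                  & (out.p0 == 0.01)]
        assert row["p_fdr"].item() == pytest.approx(0.02)   # m=2 family

    def test_degenerate_rows_stay_nan(self):
        out = ta.pool_fdr(self._frame(), "global")
        assert out["p_fdr"].isna().sum() == 1

    def test_unknown_family_is_error(self):
        with pytest.raises(ValidationError):
            ta.pool_fdr(self._frame(), "per_gene")


@pytest.fixture(scope="module")
def screened(small_sim):
    sim = small_sim
    gm = collapse_probes(sim["expression"], sim["probe_map"])
    tensor = compute_log2fc(gm, sim["sheet"])
    from txpanel.preprocess import compute_baseline
    baseline = compute_baseline(gm, sim["sheet"], 6)
    cfg = PipelineConfig()
    out = ta.associate_panel(tensor, baseline, sim["response"], cfg)
    return sim, tensor, baseline, out


class TestAssociatePanel:

    def test_planted_gene_has_most_negative_rho(self, screened):
        sim, _, _, out = screened
        planted = set(sim["truth"].genes_of_class("associated"))
        sub = out[(out.agent == "dasatinib") & (out.condition == "high@24h")
                  & (out.method == "spearman")]
        strongest = sub.nsmallest(len(planted), "rho")
        assert set(strongest["gene"]) == planted
        assert strongest["rho"].max() < -0.5

    def test_baseline_condition_present(self, screened):
        _, _, _, out = screened
        assert (out.condition == "baseline").any()
        assert out.loc[out.condition == "baseline", "time_hr"].isna().all()

    def test_fdr_pooled_over_conditions_and_baseline(self, screened):
        """Global family: BH recomputed over each method's full p-value set
        (all conditions + baseline) reproduces p_fdr."""
        _, _, _, out = screened
        for method in ("spearman", "pearson"):
            sub = out[(out.method == method) & out.p0.notna()]
            assert np.allclose(np.sort(sub["p_fdr"]),
                               np.sort(ta.bh_adjust(sub["p0"].to_numpy())))

    def test_gene_list_restriction_and_missing_gene_warning(self, screened,
                                                            caplog):
        sim, tensor, baseline, _ = screened
        cfg = PipelineConfig(correlation_methods=("spearman",))
        genes = [sim["truth"].genes.index[0], "NOT_A_GENE"]
        with caplog.at_level("WARNING"):
            out = ta.associate_panel(tensor, baseline, sim["response"], cfg,
                                     genes=genes)
        assert set(out["gene"]) == {genes[0]}
        assert "NOT_A_GENE" in caplog.text

    def test_gene_vs_gene_mode(self, screened):
        sim, tensor, _, _ = screened
        cfg = PipelineConfig(correlation_methods=("spearman",))
        y_gene = sim["truth"].genes_of_class("associated")[0]
        out = ta.associate_panel(tensor, None, sim["response"], cfg,
                                 y_gene=y_gene)
        assert y_gene not in set(out["gene"])
        # other planted genes share the latent driver -> positive rho with
        # the y-gene at the planted condition
        sub = out[(out.agent == "dasatinib") & (out.condition == "high@24h")]
        others = sub[sub.gene.isin(sim["truth"].genes_of_class("associated"))]
        assert (others["rho"] > 0.3).all()

    def test_empty_tensor_is_error(self):
        with pytest.raises(ValidationError):
            ta.associate_panel(pd.DataFrame(columns=["agent"]), None,
                               pd.Series(dtype=float), PipelineConfig())
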