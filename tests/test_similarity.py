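import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_dag, random_rooted_dag
from oracles import naive_d1_paths
from tcrwmda.similarity import (
    DINUCLEOTIDES,
    cosine_similarity_matrix,
    gip_kernel,
    integrate_disease_similarity,
    integrate_mirna_similarity,
    semantic_value_model1,
    semantic_value_model2,
    sequence_composition,
    ss1_matrix,
    ss2_matrix,
)

import pandas as pd


def di(name):
    return 4 + DINUCLEOTIDES.index(name)


class TestSequenceComposition:
    @pytest.mark.parametrize(
        "seq, mono, dis",
        [
            ("AAAA", {"A": 1.0}, {"AA": 1.0}),
            ("ACGT", {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
             {"AC": 1 / 3, "CG": 1 / 3, "GT": 1 / 3}),
            ("AU", {"A": 0.5, "T": 0.5}, {"AT": 1.0}),  # U maps to T
        ],
    )
    def test_hand_counted_compositions(self, seq, mono, dis):
        v = sequence_composition(seq)
        expected = np.zeros(20)
        for nt, p in mono.items():
            expected["ACGT".index(nt)] = p
        for d, p in dis.items():
            expected[di(d)] = p
        np.testing.assert_allclose(v, expected, atol=1e-15)

    def test_ambiguous_windows_excluded(self):
        # N drops both windows touching it; mono counts skip N entirely
        v = sequence_composition("ANA")
        assert v[0] == 1.0  # A proportion over the 2 valid nucleotides
        assert v[4:].sum() == 0.0  # no valid dinucleotide window

    def test_case_insensitive(self):
        np.testing.assert_array_equal(sequence_composition("acgu"), sequence_composition("ACGU"))

    def test_blocks_sum_to_one(self):
        v = sequence_composition("ACGTTGCAACGT")
        assert math.isclose(v[:4].sum(), 1.0)
        assert math.isclose(v[4:].sum(), 1.0)

    def test_no_valid_nucleotides_rejected(self):
        with pytest.raises(ValueError, match="no valid"):
            sequence_composition("NNXX")


class TestCosine:
    def test_hand_computed_values(self):
        v = np.zeros(20)
        w = np.zeros(20)
        v[0] = 1.0
        w[0] = w[1] = 1.0
        x = np.zeros(20)
        x[2] = 1.0  # disjoint support from v
        s = cosine_similarity_matrix([v, w, x], ["a", "b", "c"])
        assert s.at["a", "a"] == 1.0
        assert math.isclose(s.at["a", "b"], 1 / math.sqrt(2), rel_tol=1e-12)
        assert s.at["a", "c"] == 0.0

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_similarity_matrix([np.zeros(20), np.ones(20)], ["a", "b"])


class TestSemanticModel1:
    def test_single_node(self):
        dag = make_dag("D", [])
        contrib, dv = semantic_value_model1(dag, delta=0.5)
        assert contrib == {"D": 1.0} and dv == 1.0

    def test_chain(self):
        dag = make_dag("D", [("D", "p")])
        contrib, dv = semantic_value_model1(dag, delta=0.5)
        assert contrib["p"] == 0.5 and dv == 1.5

    def test_diamond_max_rule(self):
        dag = make_dag("D", [("D", "a"), ("D", "b"), ("a", "g"), ("b", "g")])
        contrib, dv = semantic_value_model1(dag, delta=0.5)
        assert contrib["g"] == 0.25
        assert dv == 2.25

    def test_sum_aggregate_differs_on_diamond(self):
        dag = make_dag("D", [("D", "a"), ("D", "b"), ("a", "g"), ("b", "g")])
        contrib, dv = semantic_value_model1(dag, delta=0.5, aggregate="sum")
        assert contrib["g"] == 0.5  # 0.25 + 0.25
        assert dv == 2.5

    @given(st.integers(2, 8), st.floats(0.1, 1.0), st.integers(0, 10_000))
    def test_matches_exhaustive_path_oracle(self, n_nodes, delta, seed):
        dag = random_rooted_dag(np.random.default_rng(seed), n_nodes)
        contrib, _ = semantic_value_model1(dag, delta=delta)
        oracle = naive_d1_paths(dag, delta)
        assert contrib.keys() == oracle.keys()
        for node in contrib:
            assert math.isclose(contrib[node], oracle[node], rel_tol=1e-12)


class TestSS1:
    def test_shared_parent_pair(self):
        dags = {"d1": make_dag("d1", [("d1", "p")]), "d2": make_dag("d2", [("d2", "p")])}
        s = ss1_matrix(dags, ["d1", "d2"], delta=0.5)
        assert s.at["d1", "d1"] == 1.0
        assert math.isclose(s.at["d1", "d2"], 1 / 3, rel_tol=1e-12)

    def test_disjoint_dags_zero(self):
        dags = {"d1": make_dag("d1", [("d1", "p")]), "d2": make_dag("d2", [("d2", "q")])}
        assert ss1_matrix(dags, ["d1", "d2"]).at["d1", "d2"] == 0.0

    def test_missing_dag_is_nan(self):
        dags = {"d1": make_dag("d1", [])}
        s = ss1_matrix(dags, ["d1", "d2"])
        assert np.isnan(s.at["d1", "d2"])

    @given(st.integers(1, 4), st.integers(1, 4), st.floats(0.2, 0.9))
    def test_adding_shared_ancestor_never_decreases(self, len1, len2, delta):
        def chain(root, n, suffix):
            terms = [root] + [f"{suffix}{i}" for i in range(n)] + ["shared"]
            return [(terms[i], terms[i + 1]) for i in range(len(terms) - 1)]

        base = {
            "d1": make_dag("d1", chain("d1", len1, "x")),
            "d2": make_dag("d2", chain("d2", len2, "y")),
        }
        before = ss1_matrix(base, ["d1", "d2"], delta=delta).at["d1", "d2"]
        grown = {
            "d1": make_dag("d1", chain("d1", len1, "x") + [("shared", "top")]),
            "d2": make_dag("d2", chain("d2", len2, "y") + [("shared", "top")]),
        }
        after = ss1_matrix(grown, ["d1", "d2"], delta=delta).at["d1", "d2"]
        assert after >= before - 1e-12


class TestSemanticModel2:
    def test_ubiquitous_term_contributes_zero(self):
        dags = {
            "d1": make_dag("d1", [("d1", "p")]),
            "d2": make_dag("d2", [("d2", "p")]),
        }
        d2, _ = semantic_value_model2(dags, n_diseases=2)
        assert d2["p"] == 0.0  # p appears in both DAGs

    def test_rare_term_information_content(self):
        dags = {"d1": make_dag("d1", [])}
        d2, _ = semantic_value_model2(dags, n_diseases=10)
        assert math.isclose(d2["d1"], math.log(10), rel_tol=1e-12)

    def test_inconsistent_counts_rejected(self):
        dags = {
            "d1": make_dag("d1", [("d1", "p")]),
            "d2": make_dag("d2", [("d2", "p")]),
        }
        with pytest.raises(ValueError, match="appears in"):
            semantic_value_model2(dags, n_diseases=1)


class TestSS2:
    def test_worked_four_disease_universe(self):
        # universe of 4 diseases, DAGs for two of them sharing parent p:
        # D2(p) = ln 2, D2(d1) = D2(d2) = ln 4, SS2 = 2 ln2 / (2 (ln4 + ln2))
        dags = {"d1": make_dag("d1", [("d1", "p")]), "d2": make_dag("d2", [("d2", "p")])}
        s = ss2_matrix(dags, n_diseases=4, names=["d1", "d2"])
        assert math.isclose(s.at["d1", "d2"], 1 / 3, rel_tol=1e-12)
        assert s.at["d1", "d1"] == 1.0

    def test_disjoint_dags_zero(self):
        dags = {"d1": make_dag("d1", [("d1", "p")]), "d2": make_dag("d2", [("d2", "q")])}
        assert ss2_matrix(dags, 4, ["d1", "d2"]).at["d1", "d2"] == 0.0

    def test_zero_total_contribution_degenerate_case(self):
        # d2's only term appears in every DAG, so D2(d2) = 0 and DV2(d2) = 0;
        # the diagonal stays 1 and shared-term sums contribute nothing
        dags = {
            "d1": make_dag("d1", [("d1", "d2")]),
            "d2": make_dag("d2", []),
        }
        s = ss2_matrix(dags, n_diseases=2, names=["d1", "d2"])
        assert s.at["d2", "d2"] == 1.0
        assert s.at["d1", "d2"] == 0.0

    @given(st.integers(2, 6), st.integers(0, 1000))
    def test_log_base_invariance(self, n, seed):
        rng = np.random.default_rng(seed)
        dags = {}
        for i in range(n):
            parent = f"shared{rng.integers(2)}"
            dags[f"d{i}"] = make_dag(f"d{i}", [(f"d{i}", parent)])
        names = sorted(dags)
        nat = ss2_matrix(dags, n, names).to_numpy()
        # recompute with log10 contributions
        counts = {}
        for dag in dags.values():
            for t in dag.nodes:
                counts[t] = counts.get(t, 0) + 1
        d2 = {t: -math.log10(k / n) for t, k in counts.items()}
        base10 = np.eye(n)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i == j:
                    continue
                denom = sum(d2[t] for t in dags[a].nodes) + sum(d2[t] for t in dags[b].nodes)
                shared = dags[a].nodes & dags[b].nodes
                base10[i, j] = (
                    0.0 if denom == 0 else sum(2 * d2[t] for t in shared) / denom
                )
        np.testing.assert_allclose(nat, base10, atol=1e-12)


class TestGipKernel:
    def test_identity_association_hand_value(self):
        a = pd.DataFrame(np.eye(2), index=["m1", "m2"], columns=["d1", "d2"])
        k = gip_kernel(a, axis="rows", gamma_prime=1.0)
        assert k.at["m1", "m1"] == 1.0
        assert math.isclose(k.at["m1", "m2"], math.exp(-2.0), rel_tol=1e-12)

    def test_identical_profiles_give_one(self):
        a = pd.DataFrame([[1.0, 0.0], [1.0, 0.0]], index=["m1", "m2"], columns=["d1", "d2"])
        assert gip_kernel(a, "rows").at["m1", "m2"] == 1.0

    def test_all_zero_profiles_rejected(self):
        a = pd.DataFrame(np.zeros((2, 2)), index=["m1", "m2"], columns=["d1", "d2"])
        with pytest.raises(ValueError, match="bandwidth undefined"):
            gip_kernel(a, "rows")

    def test_cols_axis_uses_disease_profiles(self):
        a = pd.DataFrame([[1.0, 1.0], [0.0, 1.0]], index=["m1", "m2"], columns=["d1", "d2"])
        k = gip_kernel(a, axis="cols", gamma_prime=1.0)
        # profiles (1,0) and (1,1): ||diff||^2 = 1, mean sq norm = 1.5
        assert math.isclose(k.at["d1", "d2"], math.exp(-1 / 1.5), rel_tol=1e-12)


class TestIntegration:
    def _frames(self):
        idx = ["d1", "d2"]
        ss1 = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]], index=idx, columns=idx)
        ss2 = pd.DataFrame([[1.0, 0.2], [0.2, 1.0]], index=idx, columns=idx)
        kd = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=idx, columns=idx)
        return ss1, ss2, kd

    def test_semantic_pairs_use_mean_of_models(self):
        ss1, ss2, kd = self._frames()
        sd = integrate_disease_similarity(ss1, ss2, kd, [True, True])
        assert math.isclose(sd.at["d1", "d2"], 0.3)

    def test_unflagged_pairs_fall_back_to_kernel(self):
        ss1, ss2, kd = self._frames()
        ss1.iloc[0, 1] = ss1.iloc[1, 0] = np.nan
        ss2.iloc[0, 1] = ss2.iloc[1, 0] = np.nan
        sd = integrate_disease_similarity(ss1, ss2, kd, [True, False])
        assert sd.at["d1", "d2"] == 0.9

    def test_mirna_fs_where_covered_kernel_elsewhere(self):
        idx = ["m1", "m2", "m3"]
        fs = pd.DataFrame(
            [[1.0, 0.7], [0.7, 1.0]], index=["m1", "m2"], columns=["m1", "m2"]
        )
        km = pd.DataFrame(0.5 * np.ones((3, 3)), index=idx, columns=idx)
        np.fill_diagonal(km.values, 1.0)
        sm = integrate_mirna_similarity(fs, km)
        assert sm.at["m1", "m2"] == 0.7  # covered by FS
        assert sm.at["m1", "m3"] == 0.5  # m3 missing from FS -> kernel
        assert sm.at["m3", "m3"] == 1.0

    def test_fs_outside_unit_interval_rejected(self):
        idx = ["m1", "m2"]
        fs = pd.DataFrame([[1.0, 1.7], [1.7, 1.0]], index=idx, columns=idx)
        km = pd.DataFrame(np.eye(2), index=idx, columns=idx)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            integrate_mirna_similarity(fs, km)


class TestSimilarityInvariants:
    def test_emitted_matrices_symmetric_unit_interval(self, small_bundle):
        from tcrwmda import ThreeLayerRandomWalk

        ds, _ = small_bundle
        est = ThreeLayerRandomWalk().fit(ds)
        for mat in (est.sl_, est.sm_, est.sd_, est.km_, est.kd_):
            v = mat.to_numpy()
            assert np.max(np.abs(v - v.T)) < 1e-12
            assert v.min() >= 0.0 and v.max() <= 1.0
            np.testing.assert_allclose(np.diag(v), 1.0)
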