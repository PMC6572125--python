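"""Differential signature (pooled-variance t-test), hierarchical clustering
and the hypergeometric over-representation helper."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phosphopipe import ValidationError, cluster, differential_test, \
    overrepresentation_test, simulate_phospho_experiment, simulate_proteome, \
    compute_ratios
from phosphopipe.quant import QuantMatrix


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t and its two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def _qm_from_arrays(a: np.ndarray, b: np.ndarray, design) -> QuantMatrix:
    """Quant matrix whose non-type columns hold ``a`` and luminal/basal
    columns hold ``b`` (both n_peptides x 6 for the study design)."""
    cols_a = [(s, r) for s in ("T24", "J82", "UMUC3") for r in (1, 2)]
    cols_b = [(s, r) for s in ("SW780", "RT112", "VMCUB-1") for r in (1, 2)]
    data = pd.DataFrame(
        np.hstack([a, b]),
        index=[f"p{i}" for i in range(a.shape[0])],
        columns=pd.MultiIndex.from_tuples(cols_a + cols_b,
                                          names=["sample", "replicate"]),
    )
    return QuantMatrix(data, [])


class TestTTest:
    def test_identical_groups(self, design):
        vals = np.tile(np.linspace(-1, 1, 6), (3, 1))
        qm = _qm_from_arrays(vals, vals, design)
        res = differential_test(qm, design)
        assert np.allclose(res["t"], 0.0)
        assert np.allclose(res["p"], 1.0)
        assert not res["in_signature"].any()

    def test_closed_form_example(self, design):
        a = np.array([[1.0, 1.1, 0.9, 1.0, 1.05, 0.95]])
        b = np.array([[0.0, 0.1, -0.1, 0.05, 0.0, -0.05]])
        qm = _qm_from_arrays(a, b, design)
        res = differential_test(qm, design)
        t_exp, p_exp = pooled_t_oracle(a[0], b[0])
        assert res.loc[0, "t"] == pytest.approx(t_exp, abs=1e-10)
        assert res.loc[0, "p"] == pytest.approx(p_exp, abs=1e-10)
        assert res.loc[0, "in_signature"]

    def test_oracle_equivalence_random(self, design):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, size=(100, 6))
        b = rng.normal(0.3, 1.2, size=(100, 6))
        res = differential_test(_qm_from_arrays(a, b, design), design)
        for i in range(100):
            t_exp, p_exp = pooled_t_oracle(a[i], b[i])
            assert abs(res.loc[i, "t"] - t_exp) < 1e-10
            assert abs(res.loc[i, "p"] - p_exp) < 1e-10

    def test_zero_variance_guard(self, design):
        same = np.full((1, 6), 0.5)
        other = np.full((1, 6), 0.9)
        res_eq = differential_test(_qm_from_arrays(same, same, design), design)
        assert res_eq.loc[0, "p"] == 1.0 and res_eq.loc[0, "t"] == 0.0
        with pytest.warns(UserWarning, match="zero pooled variance"):
            res_ne = differential_test(
                _qm_from_arrays(same, other, design), design
            )
        assert res_ne.loc[0, "p"] == 0.0

    def test_small_group_rejected(self, design, record_factory):
        rec = record_factory(design, "p1")
        qm = compute_ratios([rec], design)
        with pytest.raises(ValidationError, match=">= 2 columns"):
            differential_test(qm, design, group_a=("non_type",),
                              group_b=("basal",), replicate_mean=True)

    def test_bh_properties(self, design):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, size=(50, 6))
        b = rng.normal(0, 1, size=(50, 6))
        res = differential_test(_qm_from_arrays(a, b, design), design)
        assert (res["q"] >= res["p"] - 1e-12).all()
        srt = res.sort_values("p")
        assert (np.diff(srt["q"]) >= -1e-12).all()
        # single test: q equals p
        res1 = differential_test(_qm_from_arrays(a[:1], b[:1], design), design)
        assert res1.loc[0, "q"] == pytest.approx(res1.loc[0, "p"])

    def test_null_signature_fraction(self, design):
        rng = np.random.default_rng(100)
        n = 2000
        a = rng.normal(0, 0.25, size=(n, 6))
        b = rng.normal(0, 0.25, size=(n, 6))
        res = differential_test(_qm_from_arrays(a, b, design), design)
        frac = res["in_signature"].mean()
        assert abs(frac - 0.05) < 0.02

    def test_planted_sensitivity(self, design):
        prot = simulate_proteome(300, (150, 250), seed=1)
        expt = simulate_phospho_experiment(
            design, prot, 1000, frac_differential=0.1, effect_size=1.0,
            noise_sd=0.25, n_active_kinases=0, n_null_kinases=0,
            frac_incomplete=0.0, seed=2,
        )
        qm = compute_ratios(expt.records, design)
        res = differential_test(qm, design)
        sig = set(res.loc[res["in_signature"], "peptide_id"])
        planted = set(expt.truth.differential)
        assert len(sig & planted) / len(planted) >= 0.9


class TestClustering:
    def test_identical_columns_merge_first(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(10, 3)),
                         columns=["a", "b", "c"])
        m["b"] = m["a"]
        res = cluster(m)
        heights = res.col_linkage[:, 2]
        first = {int(res.col_linkage[0, 0]), int(res.col_linkage[0, 1])}
        assert heights[0] == pytest.approx(0.0, abs=1e-12)
        assert first == {0, 1}  # columns a and b

    def test_planted_two_groups_recovered(self, design):
        prot = simulate_proteome(200, (150, 250), seed=3)
        expt = simulate_phospho_experiment(
            design, prot, 400, frac_differential=0.15, n_active_kinases=0,
            n_null_kinases=0, frac_incomplete=0.0, seed=4,
        )
        qm = compute_ratios(expt.records, design)
        res = differential_test(qm, design)
        sig = list(res.loc[res["in_signature"], "peptide_id"])
        cres = cluster(qm.data, rows=sig)
        assign = cres.cut_columns(2)
        nt = {c for c, g in assign.items()
              if design.group_of(c[0]) == "non_type"}
        other = set(assign) - nt
        assert len({assign[c] for c in nt}) == 1
        assert len({assign[c] for c in other}) == 1
        assert {assign[c] for c in nt} != {assign[c] for c in other}

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(30, 6)),
                         columns=list("abcdef"))
        m.iloc[:15, :3] += 2.0  # two-group structure
        res1 = cluster(m)
        perm = ["d", "a", "f", "b", "e", "c"]
        res2 = cluster(m[perm])
        c1 = res1.cut_columns(2)
        c2 = res2.cut_columns(2)
        groups1 = frozenset(
            frozenset(k for k, v in c1.items() if v == g)
            for g in set(c1.values())
        )
        groups2 = frozenset(
            frozenset(k for k, v in c2.items() if v == g)
            for g in set(c2.values())
        )
        assert groups1 == groups2

    def test_zero_variance_row_excluded(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0],
                          [0.0, 1.0, -1.0]], columns=["a", "b", "c"])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = cluster(m)
        assert res.z_matrix.shape[0] == 2

    def test_rows_z_scored(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(3, 2, size=(5, 4)))
        res = cluster(m)
        np.testing.assert_allclose(res.z_matrix.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(res.z_matrix.std(axis=1, ddof=0), 1,
                                   atol=1e-12)

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("wxyz"))
        nwk = cluster(m).newick("columns")
        assert nwk.endswith(";")
        for label in "wxyz":
            assert label in nwk


class TestOverrepresentation:
    def test_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        annot = {"A": {f"g{i}" for i in range(5)}}
        signature = {f"g{i}" for i in range(5)}
        res = overrepresentation_test(signature, annot, universe)
        expected = 1 / math.comb(20, 5)
        assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-10)

    def test_zero_overlap_tail_is_one(self):
        universe = {f"g{i}" for i in range(10)}
        annot = {"A": {"g0", "g1"}}
        res = overrepresentation_test({"g5"}, annot, universe)
        assert res.loc[0, "overlap"] == 0
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_bh_preserves_order(self):
        universe = {f"g{i}" for i in range(30)}
        annot = {"enriched": {f"g{i}" for i in range(5)},
                 "flat": {f"g{i}" for i in range(20, 25)}}
        res = overrepresentation_test({f"g{i}" for i in range(5)}, annot,
                                      universe)
        assert list(res.sort_values("p")["set"]) == \
            list(res.sort_values("q", kind="mergesort")["set"])

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            overrepresentation_test(set(), {"A": {"x"}}, set())
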