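"""Lin's concordance coefficient and transition aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from texconcord.concordance import (
    FeatureTable,
    aggregate_transitions,
    all_pairs,
    ccc_between_matrices,
    lins_ccc,
    neighboring_pairs,
)

from .oracles import ccc_moments_bruteforce


def make_table(values, matrix_size, families=None, **kw):
    values = np.asarray(values, float)
    cols = [f"f{i}" for i in range(values.shape[1])]
    fams = families or ["GLCM"] * values.shape[1]
    meta = dict(tissue="bone", mode="2D", normalization="raw")
    meta.update(kw)
    return FeatureTable(
        data=pd.DataFrame(values, index=[f"S{i}" for i in range(values.shape[0])],
                          columns=cols),
        matrix_size=matrix_size,
        families=fams,
        **meta,
    )


class TestLinsCcc:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert lins_ccc(x, x) == pytest.approx(1.0)

    def test_perfect_reversal(self):
        assert lins_ccc([-1.0, 0.0, 1.0], [1.0, 0.0, -1.0]) == pytest.approx(-1.0)

    def test_matches_moment_oracle(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 2.0, 4.0]
        assert lins_ccc(x, y) == pytest.approx(ccc_moments_bruteforce(x, y), abs=1e-12)

    def test_both_constant_undefined(self):
        assert np.isnan(lins_ccc([2.0, 2.0, 2.0], [3.0, 3.0, 3.0]))

    def test_one_constant_is_zero(self):
        assert lins_ccc([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            lins_ccc([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            lins_ccc([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=1000, deadline=None, derandomize=True)
    def test_lin_inequality_and_symmetry(self, seed):
        """|ρc| <= |Pearson ρ| and ρc(x,y) = ρc(y,x)."""
        rng = np.random.default_rng(seed)
        x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), 12)
        y = 0.5 * x + rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), 12)
        c = lins_ccc(x, y)
        rho = np.corrcoef(x, y)[0, 1]
        assert abs(c) <= abs(rho) + 1e-12
        assert c == pytest.approx(lins_ccc(y, x), abs=1e-12)
        assert -1.0 - 1e-12 <= c <= 1.0 + 1e-12

    @given(
        c=st.floats(min_value=0.1, max_value=10),
        d=st.floats(min_value=-20, max_value=20),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_common_affine_invariance(self, c, d):
        rng = np.random.default_rng(11)
        x = rng.normal(3, 1, 15)
        y = rng.normal(2.5, 1.2, 15)
        base = lins_ccc(x, y)
        moved = lins_ccc(c * x + d, c * y + d)
        assert moved == pytest.approx(base, abs=1e-9)

    def test_equal_moments_reduces_to_pearson(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.permutation(x)  # same mean and variance exactly
        rho = np.corrcoef(x, y)[0, 1]
        assert lins_ccc(x, y) == pytest.approx(rho, abs=1e-12)


class TestCccBetweenMatrices:
    def test_self_pairing_all_one(self, rng):
        vals = rng.normal(10, 2, (6, 5))
        a = make_table(vals, 256)
        b = make_table(vals, 512)
        res = ccc_between_matrices(a, b)
        np.testing.assert_allclose(res.table["ccc"], 1.0, atol=1e-12)

    def test_constant_feature_flagged_excluded(self, rng):
        vals_a = rng.normal(0, 1, (5, 3))
        vals_b = rng.normal(0, 1, (5, 3))
        vals_a[:, 1] = 7.0
        vals_b[:, 1] = 9.0
        res = ccc_between_matrices(make_table(vals_a, 256), make_table(vals_b, 320))
        assert np.isnan(res.table.loc[1, "ccc"])
        assert res.n_undefined == 1

    def test_matches_per_column_loop(self, rng):
        vals_a = rng.normal(5, 2, (8, 10))
        vals_b = vals_a + rng.normal(0, 0.5, (8, 10))
        res = ccc_between_matrices(make_table(vals_a, 384), make_table(vals_b, 448))
        for j in range(10):
            assert res.table.loc[j, "ccc"] == pytest.approx(
                lins_ccc(vals_a[:, j], vals_b[:, j]), abs=1e-12
            )

    def test_subject_mismatch_lists_difference(self, rng):
        a = make_table(rng.normal(size=(4, 2)), 256)
        b = make_table(rng.normal(size=(4, 2)), 320)
        b.data.index = ["S0", "S1", "S2", "SX"]
        with pytest.raises(ValueError, match="SX"):
            ccc_between_matrices(a, b)

    def test_same_matrix_rejected(self, rng):
        a = make_table(rng.normal(size=(4, 2)), 256)
        b = make_table(rng.normal(size=(4, 2)), 256)
        with pytest.raises(ValueError, match="different matrix"):
            ccc_between_matrices(a, b)


class TestAggregateTransitions:
    def _results(self, sizes, value=1.0, rng=None):
        out = []
        for lo, hi in all_pairs(sizes):
            if rng is None:
                va = np.tile([1.0, 2.0, 3.0, 4.0], (3, 1)).T
                vb = va * value if value != 1.0 else va
            else:
                va = rng.normal(size=(6, 3))
                vb = va + rng.normal(0, 0.3, size=(6, 3))
            out.append(
                ccc_between_matrices(
                    make_table(va, lo, families=["GLCM", "GLCM", "HIST"]),
                    make_table(vb, hi, families=["GLCM", "GLCM", "HIST"]),
                )
            )
        return out

    def test_all_ones_gives_unit_means_and_zero_change(self):
        sizes = (256, 320, 384, 448, 512)
        rep = aggregate_transitions(self._results(sizes), "neighboring")
        np.testing.assert_allclose(rep.table["mean_ccc"], 1.0, atol=1e-12)
        assert rep.mean_change() == pytest.approx(0.0)

    def test_pair_counts_per_scope(self, rng):
        sizes = (256, 320, 384, 448, 512)
        results = self._results(sizes, rng=rng)
        nb = aggregate_transitions(results, "neighboring")
        ap = aggregate_transitions(results, "all_pairs")
        assert nb.overall().shape[0] == 4
        assert ap.overall().shape[0] == 10

    def test_family_means_weighted_mean_is_overall(self, rng):
        results = self._results((256, 320), rng=rng)
        rep = aggregate_transitions(results, "neighboring")
        fams = rep.family_means().set_index("family")
        overall = rep.overall()["mean_ccc"].iloc[0]
        weighted = (
            fams["mean_ccc"] * fams["n_defined"]
        ).sum() / fams["n_defined"].sum()
        assert overall == pytest.approx(weighted, abs=1e-12)

    def test_hand_built_two_family_means(self):
        vals_a = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 40.0]])
        vals_b = np.array([[1.0, 10.0], [2.0, 25.0], [3.0, 35.0]])
        res = ccc_between_matrices(
            make_table(vals_a, 256, families=["GLCM", "HIST"]),
            make_table(vals_b, 320, families=["GLCM", "HIST"]),
        )
        rep = aggregate_transitions([res], "neighboring")
        fams = rep.family_means().set_index("family")["mean_ccc"]
        assert fams["GLCM"] == pytest.approx(1.0)
        assert fams["HIST"] == pytest.approx(
            ccc_moments_bruteforce(vals_a[:, 1], vals_b[:, 1])
        )

    def test_missing_pair_named(self, rng):
        results = self._results((256, 320, 384), rng=rng)
        del results[1]  # drop one pair
        dropped = [
            r for r in results
        ]
        with pytest.raises(ValueError, match=r"\(\d+, \d+\)"):
            aggregate_transitions(dropped, "all_pairs")

    def test_neighboring_pair_construction(self):
        assert neighboring_pairs((512, 256, 384)) == [(256, 384), (384, 512)]
        assert len(all_pairs((256, 320, 384, 448, 512))) == 10
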