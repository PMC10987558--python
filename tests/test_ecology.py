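"""Ecology layer: diversity, dissimilarity, PERMANOVA, PCoA, differential
abundance, compartment cross-talk and ΔΔCt."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from commflux.abundance import AbundanceTable, to_relative
from commflux.ecology import (
    DistanceMatrix,
    age_diversity_association,
    bray_curtis,
    cross_compartment_correlation,
    delta_delta_ct,
    diff_abundance,
    pcoa,
    permanova,
    shannon,
    shared_genus_analysis,
)
from conftest import make_metadata
from oracles import bray_curtis_pair


def table_from(values, normalized=False):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return AbundanceTable(
        pd.DataFrame(
            values,
            index=[f"s{i}" for i in range(values.shape[0])],
            columns=[f"g{j}" for j in range(values.shape[1])],
        ),
        normalized=normalized,
    )


class TestRelativeAbundance:
    def test_rows_sum_to_one(self, random_table):
        rel = to_relative(random_table)
        assert np.allclose(rel.values.sum(axis=1), 1.0, atol=1e-12)
        assert to_relative(rel) is rel  # idempotent

    def test_simple_row(self):
        rel = to_relative(table_from([[2, 2, 0]]))
        assert np.allclose(rel.values, [[0.5, 0.5, 0.0]])

    def test_zero_row_rejected_by_name(self):
        with pytest.raises(ValueError, match="s1"):
            to_relative(table_from([[1, 1], [0, 0]]))


class TestShannon:
    @pytest.mark.parametrize(
        "p, expected_H, expected_richness",
        [
            ([0.25] * 4, np.log(4), 4),
            ([1.0, 0.0, 0.0], 0.0, 1),
            ([0.5, 0.25, 0.25], -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25)), 3),
        ],
    )
    def test_closed_forms(self, p, expected_H, expected_richness):
        res = shannon(table_from([p], normalized=True))
        assert res["shannon"].iloc[0] == pytest.approx(expected_H, abs=1e-12)
        assert res["richness"].iloc[0] == expected_richness

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_shannon_bounded_by_log_richness(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=(5, 10))
        counts[:, 0] += 1
        rel = to_relative(table_from(counts))
        res = shannon(rel)
        assert (res["shannon"] <= np.log(res["richness"]) + 1e-12).all()
        assert (res["shannon"] >= -1e-12).all()

    def test_requires_normalized(self, random_table):
        with pytest.raises(ValueError, match="normalized"):
            shannon(random_table)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        dm = bray_curtis(table_from([[1, 2, 0], [1, 2, 0], [0, 0, 7]]))
        assert dm.D[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert dm.D[0, 2] == pytest.approx(1.0, abs=1e-12)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 5, size=(5, 8))
        dm = bray_curtis(table_from(values))
        for i, j in itertools.combinations(range(5), 2):
            assert dm.D[i, j] == pytest.approx(
                bray_curtis_pair(values[i], values[j]), abs=1e-12
            )


class TestPermanova:
    def two_clouds(self):
        # two tight clouds at mutual distance 1
        D = np.ones((6, 6)) - np.eye(6)
        D[:3, :3] = 0
        D[3:, 3:] = 0
        np.fill_diagonal(D, 0)
        return DistanceMatrix([f"s{i}" for i in range(6)], D)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            permanova(self.two_clouds(), ["a"] * 6, n_perm=10, seed=0)

    def test_maximal_separation_p_floor(self):
        # clouds big enough that no sampled permutation recreates the split
        n = 20
        D = np.ones((n, n))
        D[: n // 2, : n // 2] = 0
        D[n // 2 :, n // 2 :] = 0
        np.fill_diagonal(D, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], D)
        res = permanova(dm, ["a"] * (n // 2) + ["b"] * (n // 2), n_perm=99, seed=1)
        assert res.p_value == pytest.approx(1 / 100)

    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(6)], D)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(dm, labels, method="exhaustive")
        # independent brute force over all 20 distinct assignments
        from commflux.ecology import _pseudo_f

        D2 = D**2
        def f_of(lab):
            masks = [(lab == u).astype(float) for u in ("a", "b")]
            return _pseudo_f(D2, masks, 6)

        f_obs = f_of(labels)
        perms = {tuple(p) for p in itertools.permutations(labels)}
        hits = sum(f_of(np.array(p)) >= f_obs - 1e-12 for p in perms)
        assert res.n_permutations == 20
        assert res.p_value == pytest.approx(hits / 20)

    def test_seed_required_and_reproducible(self):
        dm = self.two_clouds()
        labels = ["a", "b", "a", "b", "a", "b"]
        with pytest.raises(ValueError, match="seed"):
            permanova(dm, labels, n_perm=50)
        r1 = permanova(dm, labels, n_perm=50, seed=42)
        r2 = permanova(dm, labels, n_perm=50, seed=42)
        assert r1.p_value == r2.p_value


class TestPCoA:
    def test_points_on_a_line(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        D = np.abs(x[:, None] - x[None])
        res = pcoa(DistanceMatrix(list("abcd"), D), k=1)
        c = res.coordinates["PCo1"].to_numpy()
        assert np.allclose(np.abs(c[:, None] - c[None]), D, atol=1e-8)

    def test_duplicated_sample_coincident(self):
        pts = np.array([[0, 0], [1, 0], [1, 0], [0, 2.0]])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(list("abcd"), D), k=2)
        c = res.coordinates.to_numpy()
        assert np.allclose(c[1], c[2], atol=1e-8)

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(7, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(7)], D), k=2)
        c = res.coordinates.to_numpy()
        Dr = np.sqrt(((c[:, None] - c[None]) ** 2).sum(-1))
        assert np.allclose(Dr, D, atol=1e-8)

    def test_k_exceeding_positive_axes_rejected(self):
        x = np.array([0.0, 1.0, 2.0])
        D = np.abs(x[:, None] - x[None])
        with pytest.raises(ValueError, match="positive eigenvalues"):
            pcoa(DistanceMatrix(list("abc"), D), k=3)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(2)
        values = rng.uniform(0, 1, size=(6, 9))
        dm = bray_curtis(table_from(values))
        res = pcoa(dm, k=2)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.D, dm.sample_ids), number_of_dimensions=2
        )
        # axes defined up to sign
        for ax in range(2):
            ours = res.coordinates.iloc[:, ax].to_numpy()
            theirs = ref.samples.iloc[:, ax].to_numpy()
            assert min(
                np.abs(ours - theirs).max(), np.abs(ours + theirs).max()
            ) < 1e-6


class TestDiffAbundance:
    def test_constant_genus_p_one(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(10, 100, size=(10, 4)).astype(float)
        counts[:, 2] = 0.0  # constant after normalization? no - make it exact
        rel = to_relative(table_from(counts))
        res = diff_abundance(rel, ["a"] * 5 + ["b"] * 5, n_perm=50, seed=1)
        assert res.loc["g2", "p_value"] == 1.0

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 200, size=(16, 20))
        rel = to_relative(table_from(counts))
        res = diff_abundance(rel, ["a"] * 8 + ["b"] * 8, n_perm=100, seed=3)
        ordered = res.sort_values("p_value")["q_value"].to_numpy()
        assert (np.diff(ordered) >= -1e-12).all()

    def test_planted_genus_attains_smallest_q(self):
        # strong planted shift should dominate the q ranking
        rng = np.random.default_rng(4)
        counts = rng.integers(50, 150, size=(20, 10)).astype(float)
        counts[10:, 0] *= 6.0
        rel = to_relative(table_from(counts))
        res = diff_abundance(rel, ["a"] * 10 + ["b"] * 10, n_perm=200, seed=5)
        assert res["q_value"].idxmin() == "g0"

    def test_small_group_rejected(self):
        rel = to_relative(table_from([[1, 2], [2, 1], [3, 1]]))
        with pytest.raises(ValueError, match="fewer than 2"):
            diff_abundance(rel, ["a", "b", "b"], n_perm=10, seed=0)


class TestCrossCompartment:
    def paired_setup(self, oral_vals, faecal_vals):
        n = oral_vals.shape[0]
        oral = AbundanceTable(
            pd.DataFrame(
                oral_vals,
                index=[f"p{i}_oral" for i in range(n)],
                columns=[f"og{j}" for j in range(oral_vals.shape[1])],
            )
        )
        faecal = AbundanceTable(
            pd.DataFrame(
                faecal_vals,
                index=[f"p{i}_faecal" for i in range(n)],
                columns=[f"fg{j}" for j in range(faecal_vals.shape[1])],
            )
        )
        ids = [f"p{i}_oral" for i in range(n)] + [f"p{i}_faecal" for i in range(n)]
        md = make_metadata(
            ids,
            groups=["HV"] * 2 * n,
            compartments=["oral"] * n + ["faecal"] * n,
            subjects=[f"p{i}" for i in range(n)] * 2,
        )
        return oral, faecal, md

    def test_perfect_and_reversed_rank_correlation(self):
        x = np.arange(1.0, 12.0)[:, None]
        oral, faecal, md = self.paired_setup(
            np.hstack([x, x]), np.hstack([x, 12.0 - x])
        )
        res = cross_compartment_correlation(oral, faecal, md)
        assert res.rho.loc["og0", "fg0"] == pytest.approx(1.0)
        assert res.rho.loc["og0", "fg1"] == pytest.approx(-1.0)
        assert res.n_subjects == 11

    def test_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(8)
        O, F = rng.uniform(size=(11, 3)), rng.uniform(size=(11, 4))
        oral, faecal, md = self.paired_setup(O, F)
        res = cross_compartment_correlation(oral, faecal, md)
        from scipy.stats import rankdata

        for i in range(3):
            for j in range(4):
                ro, rf = rankdata(O[:, i]), rankdata(F[:, j])
                expect = np.corrcoef(ro, rf)[0, 1]
                assert res.rho.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_too_few_pairs(self):
        oral, faecal, md = self.paired_setup(
            np.ones((2, 2)), np.ones((2, 2))
        )
        with pytest.raises(ValueError, match=">=3"):
            cross_compartment_correlation(oral, faecal, md)


class TestSharedGenus:
    def test_hand_built_venn(self):
        # 3 subjects, known per-individual sets
        oral = AbundanceTable(
            pd.DataFrame(
                [[1, 1, 0, 0], [1, 0, 1, 0], [1, 1, 1, 0]],
                index=["p0_oral", "p1_oral", "p2_oral"],
                columns=list("wxyz"),
            )
        )
        faecal = AbundanceTable(
            pd.DataFrame(
                [[1, 0, 0, 1], [1, 0, 0, 1], [0, 1, 0, 1]],
                index=["p0_faecal", "p1_faecal", "p2_faecal"],
                columns=list("wxyz"),
            )
        )
        ids = list(oral.sample_ids) + list(faecal.sample_ids)
        md = make_metadata(
            ids,
            groups=["HV"] * 6,
            compartments=["oral"] * 3 + ["faecal"] * 3,
            subjects=["p0", "p1", "p2"] * 2,
        )
        venn, _ = shared_genus_analysis(oral, faecal, md)
        hv = venn["HV"]
        # pooled: oral present {w,x,y}, faecal present {w,x,z}
        assert (hv.oral_only, hv.faecal_only, hv.shared) == (1, 1, 2)
        assert hv.per_individual_shared_pct == [
            pytest.approx(100 / 3),  # {w} over {w,x,z}
            pytest.approx(100 / 3),  # {w} over {w,y,z}
            pytest.approx(25.0),  # {x} over {w,x,y,z}
        ]

    def test_identical_tables_shared_100(self):
        vals = np.ones((2, 3))
        oral = AbundanceTable(pd.DataFrame(vals, index=["p0_oral", "p1_oral"], columns=list("abc")))
        faecal = AbundanceTable(pd.DataFrame(vals, index=["p0_faecal", "p1_faecal"], columns=list("abc")))
        ids = list(oral.sample_ids) + list(faecal.sample_ids)
        md = make_metadata(ids, ["HV"] * 4, ["oral", "oral", "faecal", "faecal"],
                           ["p0", "p1"] * 2)
        venn, _ = shared_genus_analysis(oral, faecal, md)
        assert all(p == 100.0 for p in venn["HV"].per_individual_shared_pct)

    def test_column_order_invariance(self, random_table):
        rng = np.random.default_rng(9)
        n = 4
        vals_o = rng.integers(0, 5, size=(n, 6))
        vals_f = rng.integers(0, 5, size=(n, 6)) + 1
        cols = [f"g{j}" for j in range(6)]
        ids_o = [f"p{i}_oral" for i in range(n)]
        ids_f = [f"p{i}_faecal" for i in range(n)]
        md = make_metadata(ids_o + ids_f, ["HV"] * 2 * n,
                           ["oral"] * n + ["faecal"] * n,
                           [f"p{i}" for i in range(n)] * 2)
        base = shared_genus_analysis(
            AbundanceTable(pd.DataFrame(vals_o + 1, index=ids_o, columns=cols)),
            AbundanceTable(pd.DataFrame(vals_f, index=ids_f, columns=cols)),
            md,
        )[0]["HV"]
        perm = rng.permutation(6)
        shuffled = shared_genus_analysis(
            AbundanceTable(pd.DataFrame((vals_o + 1)[:, perm], index=ids_o,
                                        columns=[cols[j] for j in perm])),
            AbundanceTable(pd.DataFrame(vals_f[:, perm], index=ids_f,
                                        columns=[cols[j] for j in perm])),
            md,
        )[0]["HV"]
        assert base.per_individual_shared_pct == shuffled.per_individual_shared_pct
        assert (base.oral_only, base.faecal_only, base.shared) == (
            shuffled.oral_only, shuffled.faecal_only, shuffled.shared)


class TestAgeDiversity:
    def test_monotone_trend_and_degenerate(self):
        ids = [f"s{i}" for i in range(6)]
        ages = np.arange(30, 60, 5).astype(float)
        md = make_metadata(ids, ["HV"] * 6, ages=ages)
        div = pd.DataFrame({"shannon": np.linspace(1, 2, 6), "richness": 5}, index=ids)
        rho, p, tied = age_diversity_association(div, md, "HV")
        assert rho == pytest.approx(1.0) and not tied
        flat = pd.DataFrame({"shannon": np.ones(6), "richness": 5}, index=ids)
        rho0, p0, tied0 = age_diversity_association(flat, md, "HV")
        assert (rho0, p0, tied0) == (0.0, 1.0, True)

    def test_sign_recovery_one_group_only(self):
        rng = np.random.default_rng(12)
        ids = [f"s{i}" for i in range(40)]
        groups = ["HV"] * 20 + ["MS"] * 20
        ages = np.concatenate([np.linspace(25, 65, 20)] * 2)
        md = make_metadata(ids, groups, ages=ages)
        h_hv = 1.0 + 0.02 * ages[:20] + rng.normal(0, 0.05, 20)
        h_ms = 1.5 + rng.normal(0, 0.05, 20)
        div = pd.DataFrame({"shannon": np.concatenate([h_hv, h_ms]), "richness": 5},
                           index=ids)
        rho_hv, p_hv, _ = age_diversity_association(div, md, "HV")
        rho_ms, p_ms, _ = age_diversity_association(div, md, "MS")
        assert rho_hv > 0.8 and p_hv < 0.01
        assert abs(rho_ms) < 0.5


class TestDeltaDeltaCt:
    def test_formula_and_baseline(self):
        idx = ["a", "b", "c", "d"]
        target = pd.Series([20.0, 21.0, 22.0, 23.0], index=idx)
        ref = pd.Series([15.0, 16.0, 16.0, 16.0], index=idx)
        groups = pd.Series(["HV", "HV", "MS", "MS"], index=idx)
        levels = delta_delta_ct(target, ref, groups, "HV")
        # baseline mean dCt = (5+5)/2 = 5
        assert levels["a"] == pytest.approx(1.0)
        assert levels["c"] == pytest.approx(2.0 ** -(6 - 5))  # ddCt=1 -> 0.5
        # random table matches direct evaluation
        rng = np.random.default_rng(3)
        t = pd.Series(rng.uniform(18, 30, 6), index=range(6))
        r = pd.Series(rng.uniform(12, 20, 6), index=range(6))
        g = pd.Series(["HV"] * 3 + ["MS"] * 3, index=range(6))
        lv = delta_delta_ct(t, r, g, "HV")
        d = t - r
        expected = 2.0 ** -(d - d[:3].mean())
        assert np.allclose(lv, expected)

    def test_missing_ct_rejected(self):
        idx = ["a", "b"]
        with pytest.raises(ValueError, match="missing Ct"):
            delta_delta_ct(
                pd.Series([20.0, np.nan], index=idx),
                pd.Series([15.0, 15.0], index=idx),
                pd.Series(["HV", "MS"], index=idx),
                "HV",
            )
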