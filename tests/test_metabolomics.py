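"""Tests for the two-group metabolomics layer."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import netdiff as nd
from netdiff.metabolomics import (
    IntensityTable,
    PathwayAnnotation,
    correlation_pair,
    differential_metabolites,
    fisher_z,
    hypergeometric_tail,
    pathway_enrichment,
    run_pipeline,
)


def hypergeom_upper_tail_bruteforce(N, n, m, k):
    """Direct summation of the hypergeometric mass function."""
    total = 0.0
    for i in range(k, min(n, m) + 1):
        total += comb(m, i) * comb(N - m, n - i) / comb(N, n)
    return total


def make_table(X, n_per_group, names=("control", "treated")):
    idx = [f"s{i}" for i in range(2 * n_per_group)]
    ints = pd.DataFrame(X, index=idx,
                        columns=[f"m{j + 1}" for j in range(X.shape[1])])
    groups = pd.Series([names[0]] * n_per_group + [names[1]] * n_per_group,
                       index=idx)
    return IntensityTable(intensities=ints, groups=groups)


class TestDifferential:
    def test_identical_groups(self):
        X = np.tile([100.0, 200.0, 50.0], (8, 1))
        res = differential_metabolites(make_table(X, 4))
        np.testing.assert_allclose(res["ratio"], 1.0)
        np.testing.assert_allclose(res["p_value"], 1.0)
        assert not res["significant"].any()

    def test_threefold_ratio(self):
        X = np.tile([10.0], (8, 1))
        X[4:] = 30.0
        res = differential_metabolites(make_table(X, 4))
        assert res["ratio"].iloc[0] == pytest.approx(3.0)
        assert bool(res["significant"].iloc[0])  # ratio > 2 alone flags it

    def test_significance_modes(self):
        rng = np.random.default_rng(0)
        X = 10 ** (3 + 0.05 * rng.standard_normal((10, 2)))
        X[5:, 0] *= 1.9  # p small, ratio below the 2-fold bound
        table = make_table(X, 5)
        either = differential_metabolites(table, mode="either")
        both = differential_metabolites(table, mode="both")
        assert bool(either["significant"].iloc[0])
        assert not bool(both["significant"].iloc[0])

    def test_power_for_three_sd_shift(self):
        """A 3-pooled-SD shift at n=5/5 is flagged in >= 90% of 200 draws."""
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            X = 4.0 + 0.2 * rng.standard_normal((10, 6))
            X[5:, 0] += 3 * 0.2
            res = differential_metabolites(make_table(10.0 ** X, 5), mode="p")
            hits += bool(res["significant"].iloc[0])
        assert hits >= 180

    def test_single_group_rejected(self):
        X = np.full((4, 2), 5.0)
        ints = pd.DataFrame(X, index=list("abcd"), columns=["m1", "m2"])
        groups = pd.Series(["g"] * 4, index=ints.index)
        with pytest.raises(ValueError, match="two groups"):
            differential_metabolites(IntensityTable(ints, groups))


class TestFisher:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    @given(st.floats(-1.0, 1.0, allow_nan=False))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    @given(st.floats(-0.999, 0.998, allow_nan=False), st.floats(1e-4, 1e-3))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone(self, r, eps):
        assert fisher_z(r + eps) > fisher_z(r)

    def test_perfect_correlation_clipped_finite(self):
        z = fisher_z(1.0)
        assert np.isfinite(z)
        # the clipped value is the maximum the transform can produce
        assert z > fisher_z(1 - 1e-9)


class TestCorrelationPair:
    def _table(self, seed=0, n=8, p=6):
        rng = np.random.default_rng(seed)
        X = 10 ** (4 + 0.3 * rng.standard_normal((2 * n, p)))
        return make_table(X, n)

    def test_matches_pairwise_pearson(self):
        table = self._table()
        pair = correlation_pair(table, fisher=False, log_transform=True)
        ctrl = np.log10(table.group_frame("control").to_numpy())
        i, j = 1, 4
        r_ref = stats.pearsonr(ctrl[:, i], ctrl[:, j]).statistic
        assert pair.A[i, j] == pytest.approx(r_ref, abs=1e-12)
        assert pair.A[i, j] == pair.A[j, i]
        np.testing.assert_allclose(np.diag(pair.A), 1.0)

    def test_fisher_transform_applied_off_diagonal(self):
        table = self._table()
        raw = correlation_pair(table, fisher=False)
        z = correlation_pair(table, fisher=True)
        i, j = 0, 3
        assert z.A[i, j] == pytest.approx(np.arctanh(raw.A[i, j]), abs=1e-12)
        assert z.A[i, i] == 1.0  # diagonal kept as given

    def test_duplicated_metabolite_clipped(self):
        rng = np.random.default_rng(1)
        X = 10 ** (4 + 0.3 * rng.standard_normal((12, 3)))
        X = np.hstack([X, X[:, :1]])  # m4 duplicates m1
        pair = correlation_pair(make_table(X, 6), fisher=True)
        z = pair.A[0, 3]
        assert np.isfinite(z)
        assert z == np.max(pair.A[np.triu_indices(4, 1)])

    def test_partial_correlation_variant(self):
        """Precision-matrix partial correlations: conditioning on the common
        driver removes the marginal correlation between its two children."""
        rng = np.random.default_rng(3)
        z = rng.standard_normal(400)
        x = z + 0.3 * rng.standard_normal(400)
        y = z + 0.3 * rng.standard_normal(400)
        X = np.column_stack([z, x, y, rng.standard_normal(400)])
        frame = pd.DataFrame(10.0 ** (0.05 * X + 4),
                             index=[f"s{i}" for i in range(400)],
                             columns=["z", "x", "y", "w"])
        groups = pd.Series(["a"] * 200 + ["b"] * 200, index=frame.index)
        table = IntensityTable(intensities=frame, groups=groups)
        marg = correlation_pair(table, fisher=False)
        part = correlation_pair(table, fisher=False, partial=True)
        assert marg.A[1, 2] > 0.7            # x ~ y marginally
        assert abs(part.A[1, 2]) < 0.3       # but not given z
        np.testing.assert_allclose(np.diag(part.A), 1.0)

    def test_too_few_samples(self):
        X = np.full((4, 2), 5.0)
        with pytest.raises(ValueError, match=">= 3"):
            correlation_pair(self._table(n=2))

    def test_constant_metabolite_named(self):
        rng = np.random.default_rng(2)
        X = 10 ** (4 + 0.3 * rng.standard_normal((8, 3)))
        X[:4, 1] = 100.0  # constant within control group
        with pytest.raises(ValueError, match="m2"):
            correlation_pair(make_table(X, 4))


class TestHypergeometric:
    @pytest.mark.parametrize(
        "N,n,m,k,expected",
        [
            (98, 22, 1, 1, 0.224),   # equals 22/98 analytically
            (98, 18, 1, 1, 0.184),   # equals 18/98
            (98, 22, 7, 4, 0.043),
            (98, 22, 10, 7, 0.001),
            (98, 18, 13, 4, 0.191),
        ],
    )
    def test_reported_pathway_probabilities(self, N, n, m, k, expected):
        assert round(hypergeometric_tail(N, n, m, k), 3) == expected

    def test_certain_event(self):
        assert hypergeometric_tail(98, 22, 7, 0) == 1.0

    def test_single_member_pathway_is_n_over_N(self):
        assert hypergeometric_tail(98, 22, 1, 1) == pytest.approx(22 / 98, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_against_bruteforce_summation(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 120))
        n = int(rng.integers(1, N + 1))
        m = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(n, m) + 1))
        assert hypergeometric_tail(N, n, m, k) == pytest.approx(
            hypergeom_upper_tail_bruteforce(N, n, m, k), abs=1e-12
        )

    def test_complement_rule(self):
        for k in range(1, 8):
            upper = hypergeometric_tail(98, 22, 7, k)
            lower = stats.hypergeom.cdf(k - 1, 98, 7, 22)
            assert upper + lower == pytest.approx(1.0, abs=1e-12)

    def test_infeasible_counts(self):
        with pytest.raises(ValueError, match="exceeds"):
            hypergeometric_tail(98, 5, 3, 4)
        with pytest.raises(ValueError, match="infeasible"):
            hypergeometric_tail(10, 12, 3, 1)


class TestEnrichment:
    @pytest.fixture()
    def annotation(self):
        membership = {}
        # pathway pw_a: 10 detected members, 7 in the cluster
        for i in range(10):
            membership[f"in{i}" if i < 7 else f"out{i}"] = {"pw_a"}
        # pathway pw_b: 1 member, inside the cluster
        membership["in7"] = {"pw_b"}
        # the rest of the universe is unannotated
        for i in range(98 - len(membership)):
            membership[f"na{i}"] = set()
        return PathwayAnnotation(membership=membership,
                                 pathway_names={"pw_a": "Pathway A"})

    def test_counts_and_probabilities(self, annotation):
        cluster = [f"in{i}" for i in range(7)] + ["in7"] + [f"na{i}" for i in range(14)]
        assert len(cluster) == 22
        frame = pathway_enrichment(cluster, annotation, N=98,
                                   metabolite_ids=list(annotation.membership))
        row_a = frame.loc["pw_a"]
        assert (row_a["k"], row_a["m"], row_a["n"]) == (7, 10, 22)
        assert round(row_a["p_upper"], 3) == 0.001
        assert bool(row_a["significant"])
        row_b = frame.loc["pw_b"]
        assert (row_b["k"], row_b["m"]) == (1, 1)
        assert round(row_b["p_upper"], 3) == 0.224
        assert not bool(row_b["significant"])

    def test_absent_pathways_not_reported(self, annotation):
        frame = pathway_enrichment(["na0", "na1"], annotation, N=98,
                                   metabolite_ids=list(annotation.membership))
        assert len(frame) == 0

    def test_universe_smaller_than_cluster(self, annotation):
        with pytest.raises(ValueError, match="smaller"):
            pathway_enrichment(["in0", "in1", "in2"], annotation, N=2)

    def test_multi_pathway_metabolites_counted_in_each(self):
        annot = PathwayAnnotation(membership={
            "x": {"p1", "p2"}, "y": {"p1"}, "z": set(),
        })
        frame = pathway_enrichment(["x", "y"], annot, N=3,
                                   metabolite_ids=["x", "y", "z"])
        assert frame.loc["p1", "k"] == 2
        assert frame.loc["p2", "k"] == 1


class TestPipeline:
    def test_report_structure(self, intensity_table):
        table, annot, truth = intensity_table
        rep = run_pipeline(table, annot=annot, taus=[6], M=200, seed=5)
        n = len(table.metabolite_ids)
        pos = rep["positions"]
        assert list(pos.columns) == ["original_position", "label",
                                     "position_first_column",
                                     "position_final_column"]
        assert sorted(pos["position_final_column"]) == list(range(1, n + 1))
        assert len(rep["clusters"]) == 4  # head+tail at each spectrum end
        for c in rep["clusters"]:
            assert 0.0 <= c["p_value"] <= 1.0
            assert len(c["metabolites"]) == 6
        for cid in rep["enrichment"]:
            assert any(c["cluster_id"] == cid and c["significant"]
                       for c in rep["clusters"])

    def test_taus_required(self, intensity_table):
        table, annot, _ = intensity_table
        with pytest.raises(ValueError, match="taus"):
            run_pipeline(table, annot=annot, taus=[])

    def test_identical_groups_never_significant(self):
        """With the two groups literally identical, A == B, every candidate
        ties with every null sample and p = 1 (conservative tie rule)."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            half = 10 ** (4 + 0.3 * rng.standard_normal((5, 30)))
            X = np.vstack([half, half])
            rep = run_pipeline(make_table(X, 5), taus=[8], M=200, seed=seed)
            assert all(c["p_value"] == 1.0 for c in rep["clusters"])

    def test_planted_pathway_is_top_hit(self):
        """End-to-end: a group-specific correlated block sharing one pathway
        is the top enrichment hit in nearly all draws (validation design:
        98 metabolites, 20 samples/group, two columns inspected per end)."""
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            ints, groups, annot, truth = nd.generate_intensity_table(
                n_metabolites=98, samples_per_group=20, planted_block=10,
                seed=seed)
            table = IntensityTable(intensities=ints, groups=groups)
            rep = run_pipeline(table, annot=PathwayAnnotation(membership=annot),
                               taus=[10], M=1000, n_columns=2, seed=seed + 1)
            best, best_p = None, 2.0
            for frame in rep["enrichment"].values():
                if len(frame):
                    i = frame["p_upper"].idxmin()
                    if frame.loc[i, "p_upper"] < best_p:
                        best, best_p = i, frame.loc[i, "p_upper"]
            hits += best == "path_planted"
        assert hits >= int(0.9 * n_seeds)
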