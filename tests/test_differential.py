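import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from splizkit import differential
from splizkit.differential import (
    DifferentialOptions,
    bh_adjust,
    call_significant,
    exact_permutation_pvalue,
    group_medians,
    median_null_pvalue,
    permutation_refine,
    sidak_min_p,
)


def scores_frame(values_by_cell: dict, gene="G") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": list(values_by_cell),
            "gene": gene,
            "n_reads": 10,
            "spliz": list(values_by_cell.values()),
            "computable": True,
        }
    )


def annotations_frame(group_by_cell: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": list(group_by_cell),
            "individual": "ind1",
            "tissue": "lung",
            "compartment": "immune",
            "cell_type": list(group_by_cell.values()),
        }
    )


class TestGroupMedians:
    def test_symmetric_group_has_median_zero(self):
        vals = {f"c{i}": v for i, v in enumerate(np.linspace(-1, 1, 10))}
        vals |= {f"d{i}": v + 1 for i, v in enumerate(np.linspace(-1, 1, 10))}
        ann = annotations_frame({c: ("A" if c.startswith("c") else "B") for c in vals})
        gm = group_medians(scores_frame(vals), ann, min_cells=10)
        assert gm.set_index("group").loc["lung immune A", "median"] == pytest.approx(0.0)

    def test_group_below_min_cells_is_omitted(self):
        vals = {f"c{i}": 0.1 for i in range(9)} | {f"d{i}": 0.2 for i in range(10)} | {
            f"e{i}": 0.3 for i in range(10)
        }
        ann = annotations_frame({c: c[0].upper() for c in vals})
        gm = group_medians(scores_frame(vals), ann, min_cells=10)
        assert set(gm["group"]) == {"lung immune D", "lung immune E"}

    def test_medians_invariant_to_cell_order(self):
        vals = {f"c{i}": float(i) for i in range(20)}
        ann = annotations_frame({c: ("A" if int(c[1:]) % 2 else "B") for c in vals})
        sc = scores_frame(vals)
        gm1 = group_medians(sc, ann)
        gm2 = group_medians(sc.iloc[::-1].reset_index(drop=True), ann)
        pd.testing.assert_frame_equal(gm1, gm2)


class TestMedianNullPvalue:
    def test_all_zero_medians_give_p_one(self):
        gm = pd.DataFrame(
            {"gene": "G", "group": ["A", "B"], "tissue": "lung", "compartment": "immune",
             "n_cells": [50, 50], "median": [0.0, 0.0]}
        )
        assert median_null_pvalue(gm)["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_single_group_tail(self):
        # median 0.5 over n=100: null sd = sqrt(pi/200) ~ 0.1253, z ~ 3.99
        p_group = 2 * stats.norm.sf(0.5 / math.sqrt(math.pi / 200))
        assert p_group == pytest.approx(6.6e-5, rel=0.01)
        # Sidak over one group is the group p itself
        assert sidak_min_p(np.array([0.5]), np.array([100])) == pytest.approx(p_group)

    @given(shift=st.floats(min_value=0.0, max_value=2.0))
    def test_p_monotone_nonincreasing_in_largest_median(self, shift):
        sizes = np.array([40, 40])
        base = sidak_min_p(np.array([0.3, -0.1]), sizes)
        shifted = sidak_min_p(np.array([0.3 + shift, -0.1]), sizes)
        assert shifted <= base + 1e-12


class TestPermutation:
    def test_exact_enumeration_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=8)
        labels = np.array(["A"] * 4 + ["B"] * 4)
        p_pkg = exact_permutation_pvalue(values, labels)

        # independent oracle: enumerate the 70 distinct A/B assignments
        def stat(lab):
            meds, sizes = [], []
            for g in ("A", "B"):
                sel = values[np.array(lab) == g]
                meds.append(np.median(sel))
                sizes.append(len(sel))
            return sidak_min_p(np.array(meds), np.array(sizes))

        observed = stat(labels)
        arrangements = {
            tuple("A" if i in comb else "B" for i in range(8))
            for comb in itertools.combinations(range(8), 4)
        }
        hits = sum(stat(a) <= observed + 1e-15 for a in arrangements)
        assert p_pkg == pytest.approx(hits / len(arrangements))

    def test_identical_seed_identical_pvalue(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=60)
        labels = np.repeat(["A", "B", "C"], 20)
        p1 = permutation_refine(values, labels, n_permutations=300, seed=5)
        p2 = permutation_refine(values, labels, n_permutations=300, seed=5)
        assert p1 == p2

    def test_planted_shift_hits_resolution_floor(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(size=50) + 2.0, rng.normal(size=100)])
        labels = np.array(["hi"] * 50 + ["lo"] * 100)
        p = permutation_refine(values, labels, n_permutations=1000, seed=3)
        assert p == pytest.approx(1 / 1001)

    def test_null_permutation_pvalues_are_uniform(self):
        """Exchangeable labels: the permutation p-value over many null genes is
        close to uniform (KS distance < 0.1)."""
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(200):
            values = rng.normal(size=60)
            labels = np.repeat(["A", "B"], 30)
            pvals.append(
                permutation_refine(values, labels, n_permutations=199, seed=int(rng.integers(2**31)),
                                   early_stop_exceedances=10**9)
            )
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.1


class TestBH:
    def test_hand_computed_vector(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("p, expected", [([0.2], [0.2]), ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])])
    def test_degenerate_vectors(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_adjusted_never_below_raw_and_in_range(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all((0 <= adj) & (adj <= 1))


class TestCallSignificant:
    def base_results(self, **overrides):
        row = {
            "gene": "G", "n_groups": 2, "effect_size": 1.0, "within_context_delta": 0.8,
            "consistent": np.nan, "p_raw": 0.001, "p_perm": 0.001, "p_final": 0.001,
            "p_bh": 0.01,
        }
        row.update(overrides)
        return pd.DataFrame([row])

    def test_small_effect_blocks_significance(self):
        res = call_significant(self.base_results(effect_size=0.3), DifferentialOptions())
        assert not res["significant"].iloc[0]

    def test_large_p_blocks_significance(self):
        res = call_significant(self.base_results(p_bh=0.2, effect_size=2.0), DifferentialOptions())
        assert not res["significant"].iloc[0]

    def test_all_gates_pass(self):
        res = call_significant(self.base_results(), DifferentialOptions())
        assert res["significant"].iloc[0]

    def test_cell_type_mode_requires_within_context_delta(self):
        res = call_significant(
            self.base_results(within_context_delta=0.2), DifferentialOptions()
        )
        assert not res["significant"].iloc[0]


class TestRunDifferentialEndToEnd:
    def make_dataset(self, shift, seed=0, n=40):
        rng = np.random.default_rng(seed)
        vals = {f"a{i}": float(v) for i, v in enumerate(rng.normal(size=n) + shift)}
        vals |= {f"b{i}": float(v) for i, v in enumerate(rng.normal(size=n))}
        ann = annotations_frame({c: c[0].upper() for c in vals})
        return scores_frame(vals), ann

    def test_planted_shift_is_called_with_correct_sign(self):
        scores, ann = self.make_dataset(shift=2.0)
        res = differential.run_differential(scores, ann, seed=1)
        assert res["significant"].iloc[0]
        gm = group_medians(scores, ann)
        extreme = gm.loc[gm["median"].abs().idxmax()]
        assert extreme["group"] == "lung immune A"
        assert extreme["median"] > 0

    def test_null_is_not_called(self):
        scores, ann = self.make_dataset(shift=0.0, seed=3)
        res = differential.run_differential(scores, ann, seed=1)
        assert not res["significant"].any()

    def test_calls_invariant_to_row_order(self):
        scores, ann = self.make_dataset(shift=1.5, seed=5)
        res1 = differential.run_differential(scores, ann, seed=2)
        res2 = differential.run_differential(
            scores.iloc[::-1].reset_index(drop=True), ann.iloc[::-1].reset_index(drop=True), seed=2
        )
        pd.testing.assert_frame_equal(res1, res2)


class TestConcordance:
    def _run(self, seed, shuffle_genes=False):
        from splizkit import core, simulate

        cfg = simulate.make_differential_config(
            n_planted=6, n_null=4, delta_usage=0.5, n_cells_per_type=120, seed=seed
        )
        counts, ann, _ = simulate.simulate_dataset(cfg)
        models = core.build_rank_models(counts)
        scores = core.compute_spliz(counts, models)
        if shuffle_genes:
            genes = scores["gene"].unique()
            rng = np.random.default_rng(99)
            mapping = dict(zip(genes, rng.permutation(genes)))
            scores = scores.assign(gene=scores["gene"].map(mapping))
        res = differential.run_differential(scores, ann, seed=seed)
        gm = group_medians(scores, ann)
        return res, gm

    def test_identical_runs_have_perfect_concordance(self):
        res, gm = self._run(seed=21)
        assert differential.replicate_concordance(res, res.copy(), gm, gm.copy()) == pytest.approx(1.0)

    def test_seeded_replicates_are_concordant(self):
        res_a, gm_a = self._run(seed=22)
        res_b, gm_b = self._run(seed=23)
        r = differential.replicate_concordance(res_a, res_b, gm_a, gm_b)
        assert r > 0.9

    def test_sweep_reports_undefined_beyond_max_effect(self):
        res_a, gm_a = self._run(seed=24)
        res_b, gm_b = self._run(seed=25)
        sweep = differential.effect_size_sweep(res_a, res_b, gm_a, gm_b, thresholds=[0.0, 0.5, 99.0])
        assert sweep["r"].iloc[0] == pytest.approx(sweep["r"].iloc[1], abs=0.2)
        assert np.isnan(sweep["r"].iloc[2])

    def test_too_few_pairs_is_an_error(self):
        res, gm = self._run(seed=26)
        empty = res.assign(significant=False)
        with pytest.raises(ValueError, match="matched"):
            differential.replicate_concordance(empty, empty, gm, gm)
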