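import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from splizkit import core
from conftest import frame, two_partner_counts


def single_anchor_dataset(n_per_cell: int) -> pd.DataFrame:
    """n_per_cell + 1 cells; cell j sends j reads to the farther partner."""
    rows = []
    for j in range(n_per_cell + 1):
        rows += two_partner_counts(n_per_cell - j, j, cell=f"c{j:02d}")
    return frame(rows)


class TestRankModels:
    def test_partner_ranks_follow_genomic_distance(self):
        # a 5' splice site at 56,160,320 with 3' partners at 56,160,626 and 56,161,387
        rows = [
            ("c1", "MYL6", "chr12", "+", 56160320, 56160626, 4),
            ("c2", "MYL6", "chr12", "+", 56160320, 56161387, 4),
        ]
        models = core.build_rank_models(frame(rows))
        model = models[("MYL6", 56160320, "donor")]
        assert model.partner_ranks == {56160626: 1, 56161387: 2}

    def test_single_partner_anchor_gets_no_model(self):
        rows = [("c1", "G", "chr1", "+", 1000, 2000, 10)]
        assert core.build_rank_models(frame(rows)) == {}

    def test_even_split_moments_and_residuals(self):
        rows = two_partner_counts(5, 5)
        models = core.build_rank_models(frame(rows))
        model = models[("G", 1000, "donor")]
        assert model.mean == pytest.approx(1.5)
        assert model.sd == pytest.approx(0.5)
        assert core.read_residual(1, model) == pytest.approx(-1.0)
        assert core.read_residual(2, model) == pytest.approx(1.0)

    def test_skewed_split_residuals(self):
        # 80/20 over ranks 1/2: mean 1.2, sd 0.4, residuals -0.5 and +2.0
        rows = two_partner_counts(8, 2)
        models = core.build_rank_models(frame(rows))
        model = models[("G", 1000, "donor")]
        assert model.mean == pytest.approx(1.2)
        assert model.sd == pytest.approx(0.4)
        assert core.read_residual(1, model) == pytest.approx(-0.5)
        assert core.read_residual(2, model) == pytest.approx(2.0)

    def test_residuals_have_zero_mean_unit_variance_by_construction(self):
        rows = two_partner_counts(13, 4) + [("c", "G", "chr1", "+", 1000, 9000, 3)]
        models = core.build_rank_models(frame(rows))
        model = models[("G", 1000, "donor")]
        counts = {2000: 13, 5000: 4, 9000: 3}
        res = np.concatenate(
            [[model.residual(p)] * n for p, n in counts.items()]
        )
        assert np.mean(res) == pytest.approx(0.0, abs=1e-12)
        assert np.var(res) == pytest.approx(1.0, abs=1e-12)


class TestSpliz:
    def test_cell_at_population_mean_scores_zero(self):
        rows = two_partner_counts(3, 3, cell="balanced") + two_partner_counts(7, 7, cell="other")
        counts = frame(rows)
        models = core.build_rank_models(counts)
        scores = core.compute_spliz(counts, models)
        balanced = scores.set_index("cell_id").loc["balanced"]
        assert balanced["spliz"] == pytest.approx(0.0, abs=1e-12)

    def test_sum_over_sqrt_count_scaling(self):
        # 4 reads, all at rank 2 of a 50/50 anchor (residual +1 each) -> 4/sqrt(4) = 2
        rows = two_partner_counts(0, 4, cell="far") + two_partner_counts(4, 0, cell="near")
        counts = frame(rows)
        models = core.build_rank_models(counts)
        scores = core.compute_spliz(counts, models, min_reads=1).set_index("cell_id")
        assert scores.loc["far", "spliz"] == pytest.approx(2.0)
        assert scores.loc["near", "spliz"] == pytest.approx(-2.0)

    def test_min_reads_gate(self):
        rows = two_partner_counts(2, 2, cell="shallow") + two_partner_counts(5, 5, cell="deep")
        counts = frame(rows)
        scores = core.compute_spliz(counts, core.build_rank_models(counts)).set_index("cell_id")
        assert not scores.loc["shallow", "computable"]
        assert np.isnan(scores.loc["shallow", "spliz"])
        assert scores.loc["deep", "computable"]

    @pytest.mark.parametrize("n", range(5, 13))
    def test_spliz_is_strictly_increasing_affine_in_psi(self, n):
        """With one two-partner anchor and fixed depth n, SpliZ is a strictly
        increasing affine function of the fraction of reads to the farther
        partner — the score reduces to PSI in the cassette-exon case."""
        counts = single_anchor_dataset(n)
        models = core.build_rank_models(counts)
        scores = core.compute_spliz(counts, models, min_reads=1)
        ordered = scores.sort_values("cell_id")["spliz"].to_numpy()
        diffs = np.diff(ordered)
        assert np.all(diffs > 0)
        assert np.allclose(diffs, diffs[0], atol=1e-9)

    def test_shifting_reads_nearer_strictly_decreases_spliz(self):
        counts = single_anchor_dataset(8)
        models = core.build_rank_models(counts)
        scores = core.compute_spliz(counts, models, min_reads=1).sort_values("cell_id")
        assert scores["spliz"].is_monotonic_increasing  # c00 (all near) ... c08 (all far)

    def test_relabeling_cells_preserves_the_score_multiset(self):
        counts = single_anchor_dataset(6)
        models = core.build_rank_models(counts)
        base = core.compute_spliz(counts, models, min_reads=1)
        relabeled = counts.assign(cell_id=counts["cell_id"].map(lambda c: "z" + c[::-1]))
        perm = core.compute_spliz(relabeled, core.build_rank_models(relabeled), min_reads=1)
        assert sorted(base["spliz"]) == pytest.approx(sorted(perm["spliz"]))

    def test_read_contributes_at_both_modeled_ends(self):
        # donor 1000 has two acceptors; acceptor 2000 has two donors: the
        # shared junction (1000, 2000) yields a residual at each end
        rows = [
            ("c1", "G", "chr1", "+", 1000, 2000, 3),
            ("c1", "G", "chr1", "+", 1000, 5000, 2),
            ("c1", "G", "chr1", "+", 1400, 2000, 1),
        ]
        counts = frame(rows)
        models = core.build_rank_models(counts)
        assert set(models) == {("G", 1000, "donor"), ("G", 2000, "acceptor")}
        scores = core.compute_spliz(counts, models, min_reads=1)
        # 5 reads at the donor anchor + 4 reads at the acceptor anchor
        assert scores["n_residuals"].iloc[0] == 9


class TestWeightedAverageRank:
    @pytest.mark.parametrize(
        "n1, n2, expected",
        [(3, 1, 1.25), (4, 0, 1.0)],
    )
    def test_two_partner_averages(self, n1, n2, expected):
        rows = two_partner_counts(n1, n2) + two_partner_counts(1, 1, cell="other")
        counts = frame(rows)
        models = core.build_rank_models(counts)
        war = core.weighted_average_rank(counts, models).set_index("cell_id")
        assert war.loc["c", "avg_rank"] == pytest.approx(expected)

    def test_three_partner_symmetric_case(self):
        rows = [
            ("c", "G", "chr1", "+", 1000, 2000, 1),
            ("c", "G", "chr1", "+", 1000, 3000, 1),
            ("c", "G", "chr1", "+", 1000, 4000, 1),
        ]
        counts = frame(rows)
        war = core.weighted_average_rank(counts, core.build_rank_models(counts))
        assert war["avg_rank"].iloc[0] == pytest.approx(2.0)

    def test_no_entry_without_reads_at_anchor(self, tiny_junctions):
        models = core.build_rank_models(tiny_junctions)
        war = core.weighted_average_rank(tiny_junctions, models)
        assert set(war["cell_id"]) == {"cell1", "cell2", "cell3"}
        assert (war["avg_rank"].between(1, 2)).all()
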