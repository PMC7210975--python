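import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from conftest import make_matrix, normalized
from oracles import naive_marker_table
from scatlas import io_core, markers
from scatlas._errors import ValidationError
from scatlas.markers import MarkerThresholds


def matrix_with_lognorm(values):
    values = np.asarray(values, dtype=float)
    m = make_matrix(np.ones_like(values, dtype=int))
    m.lognorm = sp.csr_matrix(values)
    return m


class TestPercentExpressing:
    def test_zero_gene(self):
        m = matrix_with_lognorm(np.zeros((4, 1)))
        assert markers.percent_expressing(m, m.cell_ids)["gene0"] == 0.0

    def test_quarter_exactly_fails_strict_gate(self):
        col = [1.0] * 3 + [0.0] * 9
        m = matrix_with_lognorm(np.array(col).reshape(-1, 1))
        pct = markers.percent_expressing(m, m.cell_ids)["gene0"]
        assert pct == pytest.approx(0.25)
        assert not pct > 0.25

    def test_third_passes(self):
        col = [1.0] * 4 + [0.0] * 8
        m = matrix_with_lognorm(np.array(col).reshape(-1, 1))
        assert markers.percent_expressing(m, m.cell_ids)["gene0"] == pytest.approx(1 / 3)

    def test_empty_set_errors(self):
        m = matrix_with_lognorm(np.zeros((2, 1)))
        with pytest.raises(ValidationError):
            markers.percent_expressing(m, [])


class TestLog2FoldChange:
    def test_identical_groups_zero(self):
        m = matrix_with_lognorm([[2.0], [2.0], [3.0], [3.0]])
        fc = markers.log2_fold_change(m, ["cell0", "cell2"], ["cell1", "cell3"])
        assert fc["gene0"] == pytest.approx(0.0)

    def test_difference_of_means(self):
        m = matrix_with_lognorm([[3.0], [3.0], [1.0], [1.0]])
        fc = markers.log2_fold_change(m, ["cell0", "cell1"], ["cell2", "cell3"])
        assert fc["gene0"] == pytest.approx(2.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        m = matrix_with_lognorm(rng.random((6, 4)))
        a, b = m.cell_ids[:3], m.cell_ids[3:]
        pd.testing.assert_series_equal(
            markers.log2_fold_change(m, a, b), -markers.log2_fold_change(m, b, a)
        )

    def test_overlap_errors(self):
        m = matrix_with_lognorm(np.zeros((3, 1)))
        with pytest.raises(ValidationError):
            markers.log2_fold_change(m, ["cell0", "cell1"], ["cell1", "cell2"])


class TestDifferentialMarkers:
    def simulate(self, seed=0, shift=2.0, sd=0.3, n=12):
        rng = np.random.default_rng(seed)
        values = rng.normal(3.0, sd, size=(2 * n, 20)).clip(min=0)
        values[:n, 0] += shift  # one shifted gene
        m = matrix_with_lognorm(values)
        return m, m.cell_ids[:n], m.cell_ids[n:]

    def test_shifted_gene_passes_and_matches_oracle(self):
        m, a, b = self.simulate()
        result = markers.differential_markers(m, a, b)
        top = result.set_index("gene").loc["gene0"]
        assert top["passed"]

        xa = m.lognorm_dense()[m.cell_index(a)]
        xb = m.lognorm_dense()[m.cell_index(b)]
        oracle = naive_marker_table(xa, xb)
        by_gene = result.set_index("gene")
        for g, row in enumerate(oracle):
            got = by_gene.loc[f"gene{g}"]
            assert got["p"] == pytest.approx(row["p"], abs=1e-10)
            assert got["log2fc"] == pytest.approx(row["log2fc"], abs=1e-10)
            assert got["adj_p"] == pytest.approx(row["adj_p"], abs=1e-10)

    def test_null_groups_yield_no_passing_genes(self):
        rng = np.random.default_rng(1)
        passing = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            values = rng.normal(2.0, 0.5, size=(24, 50)).clip(min=0)
            m = matrix_with_lognorm(values)
            res = markers.differential_markers(m, m.cell_ids[:12], m.cell_ids[12:])
            passing += int(res["passed"].sum())
        assert passing == 0

    def test_fold_change_gate(self):
        m, a, b = self.simulate(shift=0.9, sd=0.01)
        result = markers.differential_markers(m, a, b).set_index("gene")
        row = result.loc["gene0"]
        assert row["p"] < 0.01 and not row["passed"]  # significant but under the FC gate

    def test_sorted_by_log2fc_descending(self):
        m, a, b = self.simulate()
        result = markers.differential_markers(m, a, b)
        assert (np.diff(result["log2fc"]) <= 1e-12).all()

    def test_degenerate_variance_flagged(self):
        values = np.full((8, 2), 2.0)
        values[:, 1] = np.arange(8) * 0.1 + 1
        m = matrix_with_lognorm(values)
        res = markers.differential_markers(m, m.cell_ids[:4], m.cell_ids[4:])
        row = res.set_index("gene").loc["gene0"]
        assert row["degenerate"] and row["p"] == 1.0

    def test_bonferroni_properties(self):
        m, a, b = self.simulate(seed=4)
        res = markers.differential_markers(m, a, b)
        assert (res["adj_p"] <= 1.0).all()
        tested = res[res["tested"]].sort_values("p")
        assert (np.diff(tested["adj_p"]) >= -1e-12).all()  # monotone in p


class TestStageComparison:
    def build(self, shift):
        rng = np.random.default_rng(0)
        values = rng.normal(3.0, 0.05, size=(24, 5)).clip(min=0.5)
        values[:12, 0] += shift
        m = matrix_with_lognorm(values)
        return m, m.cell_ids[:12], m.cell_ids[12:]

    def test_downregulated_passes(self):
        m, a, b = self.build(-0.7)
        res = markers.stage_comparison_markers(m, a, b).set_index("gene")
        assert res.loc["gene0", "passed"]

    def test_small_fold_change_fails(self):
        m, a, b = self.build(0.5)
        res = markers.stage_comparison_markers(m, a, b).set_index("gene")
        assert not res.loc["gene0", "passed"]

    def test_threshold_is_log2_of_1_5_and_strict(self):
        assert markers.STAGE_COMPARISON_THRESHOLDS.min_abs_log2fc == pytest.approx(
            0.585, abs=5e-4
        )
        assert math.log2(1.5) == pytest.approx(0.58496, abs=1e-5)
        m, a, b = self.build(0.0)
        res = markers.stage_comparison_markers(m, a, b)
        # exactly-at-threshold fold changes are excluded by the strict gate
        fc = pd.Series(0.585, index=res.index)
        assert not (fc > 0.585).any()


class TestSignatureScore:
    def test_single_gene_identity(self):
        m = matrix_with_lognorm([[1.5, 9.0], [0.5, 9.0]])
        scores = markers.signature_score(m, ["gene0"])
        np.testing.assert_allclose(scores.to_numpy(), [1.5, 0.5])

    def test_two_gene_mean(self):
        m = matrix_with_lognorm([[2.0, 4.0]])
        assert markers.signature_score(m, ["gene0", "gene1"])["cell0"] == 3.0

    def test_zero_gene_lowers_scores(self):
        m = matrix_with_lognorm([[2.0, 4.0, 0.0], [1.0, 3.0, 0.0]])
        small = markers.signature_score(m, ["gene0", "gene1"])
        big = markers.signature_score(m, ["gene0", "gene1", "gene2"])
        assert (big < small).all()

    def test_missing_genes_error(self):
        m = matrix_with_lognorm([[1.0]])
        with pytest.raises(ValidationError, match="ABSENT"):
            markers.signature_score(m, ["ABSENT"])


class TestStratifyPercentiles:
    def test_one_to_eight(self):
        scores = pd.Series(np.arange(1.0, 9.0), index=[f"s{i}" for i in range(8)])
        strata = markers.stratify_percentiles(scores)
        assert set(strata[strata == "low"].index) == {"s0", "s1"}
        assert set(strata[strata == "high"].index) == {"s6", "s7"}

    def test_balanced_when_divisible_by_four(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.permutation(16).astype(float), index=[f"s{i}" for i in range(16)])
        strata = markers.stratify_percentiles(scores)
        assert (strata == "low").sum() == (strata == "high").sum()
        assert not set(strata[strata == "low"].index) & set(strata[strata == "high"].index)

    def test_constant_scores_error(self):
        scores = pd.Series(1.0, index=[f"s{i}" for i in range(8)])
        with pytest.raises(ValidationError):
            markers.stratify_percentiles(scores)


class TestSurvival:
    def test_death_beyond_ten_years_censored(self):
        out = markers.censor_survival(
            pd.Series([12 * 365.25, 5 * 365.25]), pd.Series([1, 1])
        )
        assert out.loc[0, "time_days"] == pytest.approx(10 * 365.25)
        assert out.loc[0, "event"] == 0
        assert out.loc[1, "event"] == 1

    def test_logrank_separates_shifted_groups(self):
        rng = np.random.default_rng(0)
        n = 40
        samples = [f"s{i}" for i in range(n)]
        scores = pd.Series(np.r_[np.zeros(n // 2), np.ones(n // 2) * 10], index=samples)
        times = np.r_[rng.exponential(3000, n // 2), rng.exponential(300, n // 2)]
        table = pd.DataFrame({"time_days": times, "event": 1}, index=samples)
        strata = markers.stratify_percentiles(scores)
        p = markers.survival_logrank(table, strata)
        assert p < 0.01


class TestSelectVariableGenes:
    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(0)
        values = rng.gamma(1, 1, size=(50, 30))
        values[:, 0] = 1.0
        m = matrix_with_lognorm(values)
        assert "gene0" not in markers.select_variable_genes(m, n_bins=3)

    def test_high_mean_excluded(self):
        rng = np.random.default_rng(1)
        values = rng.gamma(1, 0.5, size=(50, 30))
        values[:, 0] = rng.gamma(10, 1, size=50).clip(min=3.5)  # mean >> 3
        m = matrix_with_lognorm(values)
        assert "gene0" not in markers.select_variable_genes(m, n_bins=3)

    def test_dispersion_zscore_matches_hand_computation(self):
        # 6 genes in one mean-bin: z-scores computable by hand
        rng = np.random.default_rng(2)
        base = rng.normal(1.0, 0.1, size=(200, 6)).clip(min=0)
        base[:, 5] += rng.normal(0, 1.0, size=200).clip(min=-0.9)  # inflate one dispersion
        m = matrix_with_lognorm(base)
        dense = m.lognorm_dense()
        disp = dense.var(axis=0) / dense.mean(axis=0)
        z_hand = (disp - disp.mean()) / disp.std()
        selected = markers.select_variable_genes(m, mean_range=(0.01, 10), n_bins=1)
        expected = [f"gene{i}" for i in range(6) if z_hand[i] > 0.5]
        assert selected == expected


class TestPc1Partition:
    def build_two_populations(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        half = n // 2
        values = rng.normal(1.0, 0.3, size=(n, 40)).clip(min=0)
        values[:half, :10] += 2.0  # population A program incl. marker genes 0-1
        values[half:, 10:20] += 2.0  # population B program incl. markers 10-11
        m = matrix_with_lognorm(values)
        return m, ["gene0", "gene1"], ["gene10", "gene11"], half

    def test_recovers_planted_split(self):
        m, ma, mb, half = self.build_two_populations()
        labels = markers.pc1_partition(m, ma, mb, variable_genes=m.gene_ids)
        truth = np.array(["A"] * half + ["B"] * half)
        agreement = (labels.to_numpy() == truth).mean()
        assert agreement >= 0.99

    def test_low_marker_cell_undetermined(self):
        m, ma, mb, half = self.build_two_populations(seed=1)
        dense = m.lognorm_dense()
        dense[0, :20] = 0.9  # both marker-set averages below 1
        m.lognorm = sp.csr_matrix(dense)
        labels = markers.pc1_partition(m, ma, mb, variable_genes=m.gene_ids)
        assert labels.iloc[0] == "undetermined"

    def test_global_sign_flip_invariant(self):
        m, ma, mb, half = self.build_two_populations(seed=2)
        labels = markers.pc1_partition(m, ma, mb, variable_genes=m.gene_ids)
        flipped = matrix_with_lognorm(m.lognorm_dense()[::-1])
        flipped.cell_ids = m.cell_ids[::-1]
        labels_flip = markers.pc1_partition(flipped, ma, mb, variable_genes=m.gene_ids)
        assert (labels.loc[m.cell_ids] == labels_flip.loc[m.cell_ids]).all()

    def test_missing_markers_error(self):
        m, _, _, _ = self.build_two_populations()
        with pytest.raises(ValidationError):
            markers.pc1_partition(m, ["NOPE"], ["gene10"], variable_genes=m.gene_ids)
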