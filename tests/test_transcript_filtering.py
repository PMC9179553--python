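"""Literal rule checks and statistical behavior of the DEG stage."""

import numpy as np
import pandas as pd
import pytest

from loopweaver.core import ExpressionMatrix
from loopweaver.transcript_filtering import (
    call_deg,
    deg_gene_set,
    filter_low_expression,
    replace_vehicle_zeros,
    union_deg,
)
from loopweaver.synthetic_data import DegSpec, LandscapeSpec, simulate_expression
from oracles import random_genes


def make_matrix(values: dict, groups: dict) -> ExpressionMatrix:
    df = pd.DataFrame(values).T
    df.columns = list(groups)
    design = pd.DataFrame(
        {"group": list(groups.values()), "donor": "d1"}, index=list(groups)
    )
    return ExpressionMatrix(df, design)


V_E2 = {"v1": "V", "v2": "V", "v3": "V", "e1": "E2", "e2": "E2", "e3": "E2"}


class TestFilterLowExpression:
    def test_threshold_is_one_percent_of_dataset_mean(self):
        # 3 genes x 6 samples averaging 2.0 -> cutoff 0.02 (the donor-1 case)
        matrix = make_matrix(
            {
                "keep_hi": [4.0, 4.0, 4.0, 4.0, 4.0, 4.0],
                "keep_lo": [2.0, 2.0, 2.0, 2.0, 2.0, 1.985],
                "drop": [0.015, 0.0, 0.0, 0.0, 0.0, 0.0],
            },
            V_E2,
        )
        result = filter_low_expression(matrix)
        assert result.threshold == pytest.approx(0.02)
        assert result.matrix.gene_ids == ["keep_hi", "keep_lo"]
        summary = result.summary.set_index("gene_id")
        assert not summary.at["drop", "passed_filter"]
        assert summary.at["drop", "max_rpkm"] == pytest.approx(0.015)

    def test_max_exactly_at_threshold_is_retained(self):
        # power-of-two construction: dataset mean is exactly 1200m/12, so the
        # 1% threshold lands exactly on the edge gene's MAX (m = 2**-10)
        m = 2.0 ** -10
        matrix = make_matrix(
            {
                "hi": [1199 * m, 0.0, 0.0, 0.0, 0.0, 0.0],
                "edge": [m, 0.0, 0.0, 0.0, 0.0, 0.0],
            },
            V_E2,
        )
        result = filter_low_expression(matrix)
        assert result.threshold == m
        assert "edge" in result.matrix.gene_ids  # strict '<' removal

    def test_all_zero_gene_removed(self):
        matrix = make_matrix(
            {"hi": [2.0] * 6, "zero": [0.0] * 6}, V_E2
        )
        assert filter_low_expression(matrix).matrix.gene_ids == ["hi"]

    def test_degenerate_empty_dataset_is_error(self):
        # the gene holding the dataset maximum always passes the 1% rule, so
        # the only fully-degenerate case is an empty matrix
        m = make_matrix({"a": [1.0] * 6}, V_E2)
        with pytest.raises(ValueError, match="empty"):
            filter_low_expression(ExpressionMatrix(m.values.iloc[:0], m.design))

    def test_idempotent_on_simulated_data(self):
        spec = LandscapeSpec(seed=3)
        genes = random_genes(np.random.default_rng(0), 120)
        matrix, _ = simulate_expression(spec, genes, seed=5)
        once = filter_low_expression(matrix)
        twice = filter_low_expression(once.matrix)
        assert twice.matrix.gene_ids == once.matrix.gene_ids


class TestReplaceVehicleZeros:
    def test_zero_becomes_half_permille_of_max(self):
        matrix = make_matrix(
            {"g": [0.0, 3.0, 3.0, 100.0, 90.0, 80.0]}, V_E2
        )
        out = replace_vehicle_zeros(matrix, "V")
        assert out.values.at["g", "v1"] == pytest.approx(0.05)  # 0.0005 * 100

    def test_nonzero_baseline_untouched(self):
        matrix = make_matrix({"g": [0.3, 3.0, 3.0, 100.0, 90.0, 80.0]}, V_E2)
        out = replace_vehicle_zeros(matrix, "V")
        assert out.values.at["g", "v1"] == pytest.approx(0.3)

    def test_non_baseline_zero_untouched(self):
        matrix = make_matrix({"g": [1.0, 3.0, 3.0, 0.0, 90.0, 80.0]}, V_E2)
        out = replace_vehicle_zeros(matrix, "V")
        assert out.values.at["g", "e1"] == 0.0

    def test_max_zero_gene_is_error(self):
        matrix = make_matrix({"g": [0.0] * 6, "h": [1.0] * 6}, V_E2)
        with pytest.raises(ValueError, match="MAX = 0"):
            replace_vehicle_zeros(matrix, "V")


class TestCallDeg:
    def test_fourfold_significant_gene_is_deg_up(self):
        rng = np.random.default_rng(1)
        base = {
            f"null{i}": list(np.exp(rng.normal(1, 0.05, 6))) for i in range(20)
        }
        base["hit"] = [2.0, 2.1, 1.9, 8.0, 8.2, 7.9]
        table = call_deg(make_matrix(base, V_E2), ("E2", "V")).set_index("gene_id")
        row = table.loc["hit"]
        assert row["fold_change"] == pytest.approx(4.0, rel=0.05)
        assert row["is_deg"] and row["direction"] == "up"

    def test_fold_below_two_fails_gate_despite_tiny_p(self):
        base = {f"null{i}": [1.0, 1.01, 0.99, 1.0, 1.02, 0.98] for i in range(10)}
        base["near"] = [1.0, 1.0, 1.0, 1.9, 1.9, 1.9]
        table = call_deg(make_matrix(base, V_E2), ("E2", "V")).set_index("gene_id")
        row = table.loc["near"]
        assert row["fdr_p"] < 0.05 and not row["is_deg"]

    def test_group_smaller_than_two_errors(self):
        matrix = make_matrix({"g": [1, 2, 3, 4, 5, 6]}, V_E2)
        with pytest.raises(ValueError, match="fewer than 2"):
            call_deg(matrix, ("E2", "V"), exclude_samples=["e1", "e2"])

    def test_invariant_to_sample_and_gene_order(self):
        rng = np.random.default_rng(2)
        vals = {f"g{i}": list(rng.uniform(1, 10, 6)) for i in range(15)}
        matrix = make_matrix(vals, V_E2)
        shuffled = ExpressionMatrix(
            matrix.values.iloc[::-1, ::-1], matrix.design.iloc[::-1]
        )
        t1 = call_deg(matrix, ("E2", "V"))
        t2 = call_deg(shuffled, ("E2", "V"))
        pd.testing.assert_frame_equal(t1, t2)

    def test_bh_fdr_monotone_in_p_rank(self):
        rng = np.random.default_rng(3)
        vals = {f"g{i}": list(rng.uniform(1, 10, 6)) for i in range(40)}
        table = call_deg(make_matrix(vals, V_E2), ("E2", "V"))
        ordered = table.sort_values("p_value")
        assert ordered["fdr_p"].is_monotonic_increasing
        assert (table["fdr_p"] >= table["p_value"] - 1e-12).all()

    def test_null_genes_rarely_called(self):
        # 200 null lognormal genes, n=3/group: BH keeps false calls near zero
        false_rates = []
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            vals = {
                f"g{i}": list(np.exp(rng.normal(1.0, 0.25 * np.log(2), 6)))
                for i in range(200)
            }
            table = call_deg(make_matrix(vals, V_E2), ("E2", "V"))
            n_called = int(table["is_deg"].sum())
            false_rates.append(1.0 if n_called else 0.0)
        assert np.mean(false_rates) <= 0.05


class TestUnionDeg:
    def fake_table(self, deg, fold=4.0):
        return pd.DataFrame(
            {
                "gene_id": sorted(deg | {"bg1", "bg2"}),
                "fold_change": fold,
                "is_deg": [g in deg for g in sorted(deg | {"bg1", "bg2"})],
            }
        )

    def test_union_of_two_donors(self):
        combined = union_deg(
            {"d1": self.fake_table({"a", "b"}), "d2": self.fake_table({"b", "c"})}
        )
        assert list(combined["gene_id"]) == ["a", "b", "c"]
        assert combined.set_index("gene_id").at["a", "is_deg_d2"] == False  # noqa: E712

    def test_single_donor_identity(self):
        combined = union_deg([self.fake_table({"a", "b"})])
        assert set(combined["gene_id"]) == {"a", "b"}

    def test_disjoint_sets_add_up(self):
        d1 = {f"x{i}" for i in range(10)}
        d2 = {f"y{i}" for i in range(7)}
        combined = union_deg({"d1": self.fake_table(d1), "d2": self.fake_table(d2)})
        assert len(combined) == 17


class TestPlantedRecovery:
    def test_fold4_recovered_and_fold15_gated(self):
        spec = LandscapeSpec(deg_spec=DegSpec(
            n_up=20, n_down=0, true_fold=4.0, baseline_zero_fraction=0.0))
        genes = random_genes(np.random.default_rng(0), 120)
        hits = gated = 0
        n_rep = 40
        for seed in range(n_rep):
            matrix, truth = simulate_expression(
                spec, genes, seed=2000 + seed,
                fold_overrides={g.gene_id: 1.5 for g in genes[100:110]},
            )
            table = call_deg(matrix, ("E2", "V")).set_index("gene_id")
            planted4 = truth.loc[truth["true_fold_e2"] == 4.0, "gene_id"]
            hits += table.loc[planted4, "is_deg"].mean()
            sub = table.loc[[g.gene_id for g in genes[100:110]]]
            gated += (sub["log2_fold"].abs() < 1).mean()
        assert hits / n_rep >= 0.9        # planted fold-4 sensitivity
        assert gated / n_rep >= 0.9       # fold-1.5 rejected by the 2-fold gate
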