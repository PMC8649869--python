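"""Generators: library construction, screen simulation, FASTQ emission,
RNA-seq simulation, and truth-table round trips."""

import json

import numpy as np
import pandas as pd
import pytest

from dropscreen.errors import ParameterError, ValidationError
from dropscreen.matrix import CountMatrix
from dropscreen.synthetic import (
    ExpressionTruth,
    ScreenDesign,
    ShRNALibrary,
    ShRNARecord,
    generate_library,
    plant_expression_truth,
    plant_screen_truth,
    simulate_rnaseq,
    simulate_screen,
    write_barcode_fastq,
)


class TestGenerateLibrary:
    def test_counts_and_structure(self):
        lib = generate_library(n_genes=3, shrnas_per_gene=8, barcode_length=18, seed=1)
        assert len(lib) == 24
        genes = lib.genes
        assert len(genes) == 3
        per_gene = pd.Series([r.gene for r in lib.records]).value_counts()
        assert (per_gene == 8).all()
        assert all(len(r.barcode) == 18 for r in lib.records)

    def test_barcodes_distinct(self):
        lib = generate_library(n_genes=50, shrnas_per_gene=8, barcode_length=10, seed=2)
        barcodes = [r.barcode for r in lib.records]
        assert len(set(barcodes)) == len(barcodes)

    def test_barcode_space_boundary(self):
        # 4 barcodes needed, 4^1 = 4 available: boundary is allowed
        lib = generate_library(n_genes=2, shrnas_per_gene=2, barcode_length=1, seed=1)
        assert sorted(r.barcode for r in lib.records) == ["A", "C", "G", "T"]
        # 5 shRNAs cannot fit in 4 single-base barcodes
        with pytest.raises(ParameterError):
            generate_library(n_genes=5, shrnas_per_gene=1, barcode_length=1, seed=1)

    def test_deterministic_given_seed(self):
        a = generate_library(7, 5, 14, seed=9)
        b = generate_library(7, 5, 14, seed=9)
        assert a.records == b.records
        c = generate_library(7, 5, 14, seed=10)
        assert a.records != c.records

    def test_library_tsv_round_trip(self, tmp_path, small_library):
        path = tmp_path / "lib.tsv"
        small_library.to_tsv(path)
        back = ShRNALibrary.from_tsv(path)
        assert back.records == small_library.records
        assert back.barcode_length == small_library.barcode_length

    def test_duplicate_barcode_rejected(self):
        records = [ShRNARecord("a", "G1", "ACGT"), ShRNARecord("b", "G1", "ACGT")]
        with pytest.raises(ValidationError):
            ShRNALibrary(records=records, barcode_length=4)


class TestSimulateScreen:
    def test_no_selection_limit(self):
        """With all genes neutral and tiny dispersion, arm proportions match
        the baseline composition within sampling error."""
        lib = generate_library(30, 4, 10, seed=5)
        truth = plant_screen_truth(lib, n_drivers=0, n_acute=0, seed=6)
        design = ScreenDesign(depth=5e6, dispersion=0.0, replicates=1)
        counts = simulate_screen(lib, truth, design, seed=7)
        ref = counts.values["reference_rep1"].to_numpy(dtype=float)
        res = counts.values["resistant_selected_rep1"].to_numpy(dtype=float)
        p_ref, p_res = ref / ref.sum(), res / res.sum()
        assert np.abs(p_ref - p_res).max() < 5e-4

    def test_driver_sixteen_fold_drop(self):
        """s = -1/week, efficacy 1, 4 weeks: driver shRNA abundance falls
        16-fold, in the resistant-selected arm only."""
        lib = generate_library(40, 4, 10, seed=8)
        driver = lib.genes[0]
        truth = plant_screen_truth(lib, n_drivers=0, n_acute=0, seed=0)
        truth.gene_role[driver] = "resistance_driver"
        truth.selection_coeff[driver] = -1.0
        for r in lib.records:
            truth.efficacy[r.shrna_id] = 1.0 if r.gene == driver else truth.efficacy[r.shrna_id]
        design = ScreenDesign(depth=2e7, dispersion=0.0, replicates=2)
        counts = simulate_screen(lib, truth, design, seed=9)
        cpm = counts.values / counts.values.sum(axis=0) * 1e6
        is_driver = np.array([r.gene == driver for r in lib.records])
        ratio_res = (
            cpm.loc[is_driver, ["resistant_selected_rep1", "resistant_selected_rep2"]].mean(axis=1)
            / cpm.loc[is_driver, ["reference_rep1", "reference_rep2"]].mean(axis=1)
        )
        ratio_acute = (
            cpm.loc[is_driver, ["parental_acute_rep1", "parental_acute_rep2"]].mean(axis=1)
            / cpm.loc[is_driver, ["reference_rep1", "reference_rep2"]].mean(axis=1)
        )
        assert np.allclose(np.log2(ratio_res), -4.0, atol=0.4)
        assert np.allclose(np.log2(ratio_acute), 0.0, atol=0.4)

    def test_monte_carlo_mean_depletion_matches_closed_form(self):
        """Across seeds, active driver shRNAs deplete by 2^(s*eff*weeks) on
        average, within +/-0.3 in log2."""
        lib = generate_library(100, 8, 18, seed=20)
        truth = plant_screen_truth(lib, n_drivers=10, n_acute=5, seed=21)
        design = ScreenDesign(depth=2e6, dispersion=0.05, replicates=3)
        drivers = set(truth.genes_with_role("resistance_driver"))
        errors = []
        for seed in (31, 32, 33):
            counts = simulate_screen(lib, truth, design, seed=seed)
            cpm = counts.values / counts.values.sum(axis=0) * 1e6
            res = cpm[[c for c in cpm if c.startswith("resistant")]].mean(axis=1)
            ref = cpm[[c for c in cpm if c.startswith("reference")]].mean(axis=1)
            for r in lib.records:
                if r.gene in drivers and truth.efficacy[r.shrna_id] > 0.2:
                    planted = truth.selection_coeff[r.gene] * truth.efficacy[r.shrna_id] * 4
                    observed = np.log2((res[r.shrna_id] + 0.5) / (ref[r.shrna_id] + 0.5))
                    errors.append(observed - planted)
        assert abs(np.mean(errors)) < 0.3

    def test_missing_truth_rejected(self, small_library):
        truth = plant_screen_truth(small_library, 1, 1, seed=1)
        del truth.efficacy[small_library.shrna_ids[0]]
        with pytest.raises(ValidationError):
            simulate_screen(small_library, truth, ScreenDesign(), seed=1)

    def test_deterministic(self, small_library):
        truth = plant_screen_truth(small_library, 2, 1, seed=1)
        a = simulate_screen(small_library, truth, ScreenDesign(), seed=5)
        b = simulate_screen(small_library, truth, ScreenDesign(), seed=5)
        assert a.values.equals(b.values)


class TestScreenTruth:
    def test_json_round_trip(self, tmp_path, small_library):
        truth = plant_screen_truth(small_library, 3, 2, seed=4)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = type(truth).from_json(path)
        assert back.gene_role == truth.gene_role
        assert back.selection_coeff == truth.selection_coeff
        assert back.efficacy == truth.efficacy

    def test_neutral_selection_must_be_zero(self):
        with pytest.raises(ValidationError):
            from dropscreen.synthetic import ScreenTruth

            ScreenTruth(
                gene_role={"G": "neutral"}, selection_coeff={"G": -1.0}, efficacy={}
            )


class TestWriteBarcodeFastq:
    def test_exact_emission(self, tmp_path, small_library):
        ids = small_library.shrna_ids
        values = pd.DataFrame({"s1": [3] + [0] * (len(ids) - 1)}, index=pd.Index(ids, name="feature_id"))
        cm = CountMatrix(values=values)
        totals = write_barcode_fastq(
            cm, small_library, flank5="ACCG", flank3="GTTT", error_rate=0.0, seed=1, out_dir=tmp_path
        )
        assert totals == {"s1": 3}
        lines = (tmp_path / "s1.fastq").read_text().splitlines()
        assert len(lines) == 12
        bc1 = small_library.records[0].barcode
        for seq in lines[1::4]:
            assert seq == "ACCG" + bc1 + "GTTT"

    def test_read_totals_conserved(self, tmp_path, small_library):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(
            {"a": rng.integers(0, 20, len(small_library)), "b": rng.integers(0, 20, len(small_library))},
            index=pd.Index(small_library.shrna_ids, name="feature_id"),
        )
        cm = CountMatrix(values=values)
        totals = write_barcode_fastq(cm, small_library, error_rate=0.02, seed=2, out_dir=tmp_path)
        assert totals == {s: int(values[s].sum()) for s in ("a", "b")}
        for s in ("a", "b"):
            n_lines = len((tmp_path / f"{s}.fastq").read_text().splitlines())
            assert n_lines == 4 * totals[s]

    def test_unknown_row_rejected(self, tmp_path, small_library):
        cm = CountMatrix(values=pd.DataFrame({"s": [1]}, index=pd.Index(["nope"], name="feature_id")))
        with pytest.raises(ValidationError):
            write_barcode_fastq(cm, small_library, out_dir=tmp_path)

    def test_error_rate_bounds(self, tmp_path, small_library):
        cm = CountMatrix(
            values=pd.DataFrame({"s": [1] * len(small_library)}, index=pd.Index(small_library.shrna_ids, name="feature_id"))
        )
        with pytest.raises(ParameterError):
            write_barcode_fastq(cm, small_library, error_rate=0.3, out_dir=tmp_path)


class TestSimulateRnaseq:
    def test_null_poisson_equal_means(self):
        truth = plant_expression_truth(
            [f"G{i}" for i in range(300)], {"c": ("A", "B")}, None, seed=1
        )
        cm = simulate_rnaseq(truth, n_replicates=30, dispersion=0.0, seed=2)
        a = cm.values[cm.samples_in_group("A")].mean(axis=1)
        b = cm.values[cm.samples_in_group("B")].mean(axis=1)
        # equal means: log-ratio centred at 0
        assert abs(np.log2(b.sum() / a.sum())) < 0.02

    def test_planted_effect_recovered_by_de(self):
        """A +1 log2FC planted for half the genes is recovered by the DE
        stage at large replication."""
        from dropscreen.diffexpr import estimate_dispersion, nb_test, normalize_by_size_factors

        # keep planted genes a minority so median-of-ratios normalization holds
        genes = [f"G{i}" for i in range(400)]
        planted = genes[:80]
        truth = plant_expression_truth(
            genes, {"c": ("A", "B")}, {"c": {g: 1.0 for g in planted}}, seed=3
        )
        cm = simulate_rnaseq(truth, n_replicates=12, dispersion=0.05, seed=4)
        norm = normalize_by_size_factors(cm)
        ga, gb = norm.samples_in_group("A"), norm.samples_in_group("B")
        phi = estimate_dispersion(norm, {"A": ga, "B": gb})
        res = nb_test(norm, ga, gb, phi)
        background = [g for g in genes if g not in set(planted)]
        # one-sided DE shifts the size factors; the planted-vs-background
        # contrast is the estimable quantity and must recover the +1 effect
        shift = res.loc[planted, "log2fc"].mean() - res.loc[background, "log2fc"].mean()
        assert abs(shift - 1.0) < 0.15

    def test_negative_dispersion_rejected(self):
        truth = plant_expression_truth(["G1"], {"c": ("A", "B")}, None, seed=1)
        with pytest.raises(ParameterError):
            simulate_rnaseq(truth, n_replicates=3, dispersion=-0.1, seed=1)

    def test_deterministic(self):
        truth = plant_expression_truth(["G1", "G2"], {"c": ("A", "B")}, None, seed=1)
        a = simulate_rnaseq(truth, 3, 0.1, seed=9)
        b = simulate_rnaseq(truth, 3, 0.1, seed=9)
        assert a.values.equals(b.values)

    def test_expression_truth_round_trip(self, tmp_path):
        truth = plant_expression_truth(
            ["G1", "G2"], {"c": ("A", "B")}, {"c": {"G1": 1.5}}, seed=1
        )
        path = tmp_path / "t.json"
        truth.to_json(path)
        back = ExpressionTruth.from_json(path)
        assert back.baseline_mean == truth.baseline_mean
        assert back.contrasts == truth.contrasts
        assert back.de_effect == truth.de_effect
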