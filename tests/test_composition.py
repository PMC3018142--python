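"""Composition statistics: GC, RSCU, CA, regression, amino acids, identity."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from alvinest import composition, simulate
from alvinest.composition import (
    OMH_SCALE,
    aa_composition,
    codon_counts,
    codon_usage,
    compare_models,
    correspondence_analysis,
    fit_expression_gc,
    gc3,
    gc_fraction,
    mean_identity,
    optimal_codons,
    region_gc,
    rscu,
)


class TestRegionGC:
    def test_hand_counted_gc3(self):
        # third positions of non-stop codons: G (ATG), G (GCG)
        assert gc3("ATGGCGTAA") == 1.0
        assert gc3("ATGGCATAA") == 0.5  # G, A

    def test_all_at_utr(self):
        assert gc_fraction("ATATATAT") == 0.0

    def test_n_excluded(self):
        assert gc_fraction("GCNN") == 1.0
        assert np.isnan(gc3("ATNGCNTAA".replace("G", "N")))

    def test_region_gc_record(self):
        rg = region_gc("u1", utr5="ATAT", cds="ATGGCGTAA", utr3="GCGC", copy_number=3)
        assert rg.gc_utr5 == 0.0
        assert rg.gc_utr3 == 1.0
        assert rg.gc3 == 1.0
        assert rg.copy_number == 3


class TestCodonUsage:
    def test_single_codon_amino_acid(self):
        counts = codon_counts("ATGATGATG")
        assert counts["ATG"] == 3
        assert rscu(counts)["ATG"] == 1.0

    def test_uniform_leucine_family(self):
        leu = ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"]
        counts = codon_counts("".join(leu))
        values = rscu(counts)[leu]
        assert (values == 1.0).all()

    def test_pooled_equals_sum_of_genes(self):
        genes = {
            "g1": "ATGGCGGCATAA",
            "g2": "ATGTTATTGCTTTAA",
        }
        per_gene, pooled = codon_usage(genes)
        assert (per_gene.sum(axis=0) == pooled["count"]).all()

    def test_unused_amino_acid_is_na(self):
        counts = codon_counts("ATGATG")
        assert np.isnan(rscu(counts)["TGG"])  # Trp absent

    def test_rscu_family_mean_is_one(self):
        tx = simulate.generate_transcriptome(5, seed=3)
        counts = codon_counts("".join(t.cds_seq for t in tx))
        values = rscu(counts)
        for aa, family in composition._SYN_FAMILY.items():
            fam = values[family].dropna()
            if len(fam) == len(family):
                assert fam.mean() == pytest.approx(1.0)


class TestCorrespondenceAnalysis:
    def test_rank_one_matrix_single_axis(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(1, 5, 8)
        c = rng.uniform(1, 5, 12)
        m = pd.DataFrame(np.outer(r, c))
        # independence (rank-1 association): no residual inertia at all
        coa = correspondence_analysis(m)
        assert coa.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_identical_rows_zero_inertia(self):
        m = pd.DataFrame(np.tile([3.0, 1.0, 2.0, 4.0], (5, 1)))
        coa = correspondence_analysis(m)
        assert coa.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_total_inertia_is_chi2_over_n(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.integers(1, 40, size=(10, 8)).astype(float))
        coa = correspondence_analysis(m)
        chi2 = stats.chi2_contingency(m, correction=False)[0]
        assert coa.total_inertia == pytest.approx(chi2 / m.to_numpy().sum(), abs=1e-8)

    def test_axis_inertias_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = rng.integers(1, 60, size=(10, 59)).astype(float)
            P = m / m.sum()
            r, c = P.sum(axis=1), P.sum(axis=0)
            S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
            # oracle: symmetric eigendecomposition of S S^T
            eig = np.sort(linalg.eigh(S @ S.T, eigvals_only=True))[::-1]
            eig = np.clip(eig, 0, None)
            coa = correspondence_analysis(pd.DataFrame(m))
            expected = eig[: len(coa.inertia)] / eig.sum()
            assert np.allclose(coa.inertia, expected, atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.integers(1, 30, size=(12, 10)).astype(float))
        a = correspondence_analysis(m)
        b = correspondence_analysis(m)
        assert np.allclose(a.row_coords, b.row_coords)
        pivot = a.col_coords["axis1"].abs().idxmax()
        assert a.col_coords.loc[pivot, "axis1"] > 0

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            correspondence_analysis(pd.DataFrame(np.zeros((3, 3))))


class TestOptimalCodons:
    def test_planted_two_regime_recovery(self):
        # AT-ended codons enriched in low-expression genes
        rng = np.random.default_rng(4)
        at_codons = ["TTA", "CTA", "ATA", "TTT", "AGT", "GAA", "TCA"]
        gc_codons = ["TTG", "CTG", "ATC", "TTC", "AGC", "GAG", "TCG"]
        rows = {}
        expression = {}
        for g in range(60):
            low = g < 30
            expression[f"g{g:02d}"] = 2 if low else 150
            lam_at, lam_gc = (30, 8) if low else (8, 30)
            counts = {}
            for codon in at_codons:
                counts[codon] = rng.poisson(lam_at) + 1
            for codon in gc_codons:
                counts[codon] = rng.poisson(lam_gc) + 1
            rows[f"g{g:02d}"] = counts
        m = pd.DataFrame(rows).T
        coa = correspondence_analysis(m)
        report = optimal_codons(
            coa, pd.Series(expression), tail_fraction=0.5
        )
        assert set(report.low_pole_codons) == set(at_codons)
        assert abs(report.rho) > 0.8  # two-level expression ties cap Spearman

    def test_no_gradient_null_rho(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.integers(5, 30, size=(50, 14)).astype(float))
        m.index = [f"g{i}" for i in range(50)]
        coa = correspondence_analysis(m)
        expr = pd.Series(rng.integers(1, 100, 50), index=m.index)
        report = optimal_codons(coa, expr)
        assert abs(report.rho) < 0.35  # permutation-scale band at n=50

    def test_zero_tail_fraction_empty(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.integers(5, 30, size=(20, 10)).astype(float))
        m.index = [f"g{i}" for i in range(20)]
        coa = correspondence_analysis(m)
        expr = pd.Series(np.arange(20), index=m.index)
        report = optimal_codons(coa, expr, tail_fraction=0.0)
        assert report.low_pole_codons == [] and report.high_pole_codons == []


class TestExpressionFit:
    def test_power_noise_free_exact(self):
        x = np.arange(1, 50, dtype=float)
        y = 2.0 * x**0.5
        fit = fit_expression_gc(x, y, model="power")
        assert fit.params["a"] == pytest.approx(2.0, abs=1e-6)
        assert fit.params["b"] == pytest.approx(0.5, abs=1e-6)

    def test_constant_y_null_f(self):
        x = np.arange(1, 30, dtype=float)
        y = np.full(29, 0.5)
        fit = fit_expression_gc(x, y, model="linear")
        assert fit.params["a"] == pytest.approx(0.0, abs=1e-12)
        assert fit.f_stat == pytest.approx(0.0, abs=1e-6)

    def test_linear_matches_closed_form(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(1, 100, 60)
        y = 0.3 * x + 1.2 + rng.normal(0, 0.5, 60)
        fit = fit_expression_gc(x, y, model="linear")
        # closed-form least squares oracle
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.params["a"] == pytest.approx(beta[0], abs=1e-9)
        assert fit.params["b"] == pytest.approx(beta[1], abs=1e-9)

    def test_all_named_models_compared_by_rss(self):
        rng = np.random.default_rng(8)
        model = simulate.Gc3ExpressionModel()
        x = np.exp(rng.uniform(0, np.log(200), 84)).round().clip(1)
        y = model(x) + rng.normal(0, 0.02, 84)
        table = compare_models(x, y)
        assert set(table["model"]) == {
            "linear", "power", "exponential", "logarithmic", "saturating"
        }
        assert table.iloc[0]["model"] in ("saturating", "logarithmic", "power")

    def test_nonpositive_x_rejected_for_power(self):
        with pytest.raises(ValueError):
            fit_expression_gc([0, 1, 2], [1, 2, 3], model="power")


class TestAaComposition:
    def test_charge_fractions(self):
        profiles, _ = aa_composition({"t1": ["KRKR"], "t2": ["DEDE"]})
        by_taxon = {p.taxon: p for p in profiles}
        assert by_taxon["t1"].positive_fraction == 1.0
        assert by_taxon["t1"].charged_fraction == 1.0
        assert by_taxon["t2"].positive_fraction == 0.0
        assert by_taxon["t2"].charged_fraction == 1.0

    def test_identical_compositions_zero_statistics(self):
        profiles, hom = aa_composition(
            {"a": ["ACDEFGHIKLMNPQRSTVWY"], "b": ["ACDEFGHIKLMNPQRSTVWY"]}
        )
        assert hom["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert hom["g"] == pytest.approx(0.0, abs=1e-12)

    def test_frequencies_sum_to_one(self):
        fams = simulate.generate_ortholog_families(["a", "b"], n_families=5, seed=1)
        proteomes = {t: [f[t] for f in fams] for t in ("a", "b")}
        profiles, _ = aa_composition(proteomes)
        for p in profiles:
            assert p.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_homogeneity_invariant_under_permutation(self):
        fams = simulate.generate_ortholog_families(
            ["a", "b", "c"], n_families=8, divergence={"c": 0.4}, seed=2
        )
        proteomes = {t: [f[t] for f in fams] for t in ("a", "b", "c")}
        _, hom1 = aa_composition(proteomes)
        permuted = {t: proteomes[t] for t in ("c", "a", "b")}
        _, hom2 = aa_composition(permuted)
        assert hom1["chi2"] == pytest.approx(hom2["chi2"])
        assert hom1["g"] == pytest.approx(hom2["g"])

    def test_omh_scale_complete(self):
        assert set(OMH_SCALE) == set("ACDEFGHIKLMNPQRSTVWY")

    def test_histidine_flag(self):
        profiles_no, _ = aa_composition({"t": ["HHKK"]})
        profiles_yes, _ = aa_composition({"t": ["HHKK"]}, include_histidine=True)
        assert profiles_no[0].charged_fraction == 0.5
        assert profiles_yes[0].charged_fraction == 1.0

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            aa_composition({"t": [""]})


class TestMeanIdentity:
    def test_identical_sequences_100(self):
        fams = [{"a": "MKV", "b": "MKV"}]
        result = mean_identity(fams, ["a", "b"])
        assert result.matrix.loc["a", "b"] == 100.0
        assert (np.diag(result.matrix) == 100.0).all()

    def test_half_differing_columns(self):
        fams = [{"a": "AAAA", "b": "AAKK"}]
        result = mean_identity(fams, ["a", "b"])
        assert result.matrix.loc["a", "b"] == 50.0

    def test_gap_column_removed_for_all_pairs(self):
        fams = [{"a": "AC-E", "b": "ACDE", "c": "ACDE"}]
        result = mean_identity(fams, ["a", "b", "c"])
        assert result.n_columns == 3
        # b and c agree everywhere, including the column dropped for a's gap
        assert result.matrix.loc["b", "c"] == 100.0

    def test_missing_taxon_family_skipped_with_warning(self):
        fams = [{"a": "MKV", "b": "MKV"}, {"a": "MKV"}]
        with pytest.warns(UserWarning):
            result = mean_identity(fams, ["a", "b"])
        assert result.n_columns == 3

    def test_matrix_symmetric(self):
        fams = simulate.generate_ortholog_families(["a", "b", "c"], n_families=10, seed=3)
        result = mean_identity(fams, ["a", "b", "c"])
        assert np.allclose(result.matrix, result.matrix.T)
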