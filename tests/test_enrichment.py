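"""Blank-normalized enrichment, ranking, logos, correlations, selectivity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acylseq import (LibraryDesign, VariantCountTable, compute_enrichment,
                     condition_correlation, enumerate_variants, make_truth,
                     percentile_rank, position_matrix, selectivity_score,
                     simulate_selection_reads, extract_variants, top_fraction,
                     top_selectivity)

K1 = LibraryDesign("G", 1, "C", name="k1")
K3 = LibraryDesign("GAUUC", 3, "UUCCA", name="k3")


def _table(design, counts, label="sel"):
    full = {v: counts.get(v, 0) for v in enumerate_variants(design.k)}
    return VariantCountTable(design=design, condition_label=label,
                             counts=full, matched=sum(full.values()))


class TestComputeEnrichment:
    def test_identical_tables_give_unit_enrichment(self):
        t = _table(K3, {"CUC": 10, "AAA": 5})
        e = compute_enrichment(t, t)
        assert np.allclose(e.table["enrichment"], 1.0)

    def test_hand_computed_pseudocounted_ratio(self):
        sel = _table(K1, {"A": 50, "C": 25, "G": 25, "U": 0})
        blank = _table(K1, {"A": 25, "C": 25, "G": 25, "U": 25}, "blank")
        e = compute_enrichment(sel, blank, pseudocount=1.0)
        # freq_sel(A) = 51/104, freq_blank(A) = 26/104
        assert e.table.loc["A", "enrichment"] == pytest.approx(51 / 26)
        assert e.table.loc["U", "enrichment"] > 0  # pseudocount floor

    def test_all_zero_tables_allowed(self):
        z = _table(K1, {})
        e = compute_enrichment(z, z)
        assert np.allclose(e.table["enrichment"], 1.0)

    def test_frequency_normalization_and_rank_permutation(self, small_screen,
                                                          stem_design):
        _, sel, blank = small_screen
        e = compute_enrichment(extract_variants(sel, stem_design),
                               extract_variants(blank, stem_design))
        assert e.table["freq_sel"].sum() == pytest.approx(1.0, abs=1e-9)
        assert e.table["freq_blank"].sum() == pytest.approx(1.0, abs=1e-9)
        assert sorted(e.table["rank_by_raw_count"]) == list(range(1, 65))

    def test_scale_invariance_with_scaled_pseudocount(self):
        sel = _table(K3, {"CUC": 40, "AAA": 10, "GGG": 2})
        blank = _table(K3, {"CUC": 9, "AAA": 12, "GGG": 4}, "blank")
        e1 = compute_enrichment(sel, blank, pseudocount=1.0)
        sel10 = _table(K3, {v: 10 * c for v, c in sel.counts.items()})
        blank10 = _table(K3, {v: 10 * c for v, c in blank.counts.items()}, "blank")
        e10 = compute_enrichment(sel10, blank10, pseudocount=10.0)
        assert np.allclose(e1.table["enrichment"], e10.table["enrichment"])

    def test_design_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_enrichment(_table(K1, {}), _table(K3, {}))


class TestRankingAndTopFraction:
    def test_top_fraction_sizes(self):
        e5 = compute_enrichment(_table(LibraryDesign("UCGCU", 5, ""), {}),
                                _table(LibraryDesign("UCGCU", 5, ""), {}))
        assert len(top_fraction(e5, 0.1)) == 103  # ceil(102.4)
        assert len(top_fraction(e5, 1.0)) == 1024
        e3 = compute_enrichment(_table(K3, {}), _table(K3, {}))
        assert len(top_fraction(e3, 0.1)) == 7  # ceil(6.4)

    def test_fraction_bounds(self):
        e = compute_enrichment(_table(K1, {}), _table(K1, {}))
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                top_fraction(e, bad)

    def test_percentile_endpoints(self):
        sel = _table(K3, {v: i for i, v in enumerate(enumerate_variants(3))})
        e = compute_enrichment(sel, _table(K3, {}, "blank"))
        assert percentile_rank(e, "UUU") == pytest.approx(100 / 64)  # most reads
        assert percentile_rank(e, "AAA") == pytest.approx(100.0)  # fewest
        with pytest.raises(KeyError):
            percentile_rank(e, "AAAAA")

    def test_ties_broken_lexicographically(self):
        sel = _table(K1, {"A": 5, "C": 5, "G": 5, "U": 5})
        e = compute_enrichment(sel, _table(K1, {}, "blank"))
        assert list(e.table.sort_values("rank_by_raw_count").index) == \
            ["A", "C", "G", "U"]


class TestPositionMatrix:
    def test_single_variant_top_set_is_indicator(self):
        sel = _table(K3, {"CUC": 100})
        e = compute_enrichment(sel, _table(K3, {}, "blank"))
        pm = position_matrix(e, fraction=1 / 64, weighting="raw_reads")
        assert np.allclose(pm.information, 2.0)
        assert pm.probs.loc[0, "C"] == 1.0
        assert pm.probs.loc[1, "U"] == 1.0

    def test_uniform_position_has_zero_information(self):
        # four variants AXA with X covering all bases, equal counts
        sel = _table(K3, {f"A{b}A": 10 for b in "ACGU"})
        e = compute_enrichment(sel, _table(K3, {}, "blank"))
        pm = position_matrix(e, fraction=4 / 64)
        assert pm.information[1] == pytest.approx(0.0, abs=1e-12)
        assert pm.information[0] == pytest.approx(2.0)

    def test_dominant_variant_matches_direct_entropy(self):
        # one variant at 44% of the weight, remainder spread uniformly
        others = ["AAA", "ACG", "GGA", "UGC", "CCU", "GUU", "UAG"]
        counts = {"CUC": 440, **{v: 80 for v in others}}
        sel = _table(K3, counts)
        e = compute_enrichment(sel, _table(K3, {}, "blank"))
        pm = position_matrix(e, fraction=8 / 64, weighting="raw_reads")
        # brute-force oracle: weighted base frequencies and plain entropy sums
        total = sum(counts.values())
        for j in range(3):
            for base in "ACGU":
                p_direct = sum(c for v, c in counts.items() if v[j] == base) / total
                assert pm.probs.loc[j, base] == pytest.approx(p_direct, abs=1e-12)
            ic_direct = 2.0 + sum(
                (w := sum(c for v, c in counts.items() if v[j] == b) / total)
                and w * math.log2(w) for b in "ACGU")
            assert pm.information[j] == pytest.approx(ic_direct, abs=1e-12)

    def test_rows_sum_to_one(self, small_screen, stem_design):
        _, sel, blank = small_screen
        e = compute_enrichment(extract_variants(sel, stem_design),
                               extract_variants(blank, stem_design))
        pm = position_matrix(e, fraction=0.1)
        assert np.allclose(pm.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((pm.information >= -1e-12) & (pm.information <= 2 + 1e-12))


class TestConditionCorrelation:
    def test_self_correlation_is_one(self):
        t = _table(K3, {"CUC": 10, "AAA": 3})
        assert condition_correlation(t, t) == pytest.approx(1.0)

    def test_reversed_counts_anticorrelate(self):
        a = _table(K1, {"A": 1, "C": 2, "G": 3, "U": 4})
        b = _table(K1, {"A": 4, "C": 3, "G": 2, "U": 1}, "b")
        assert condition_correlation(a, b) == pytest.approx(-1.0)

    def test_matches_reference_implementation(self, stem_design):
        truth = make_truth(3, bias_sd=0.5, seed=21)
        s1, _ = simulate_selection_reads(truth, stem_design, depth=10_000, seed=22)
        s2, _ = simulate_selection_reads(truth, stem_design, depth=10_000, seed=23)
        t1 = extract_variants(s1, stem_design)
        t2 = extract_variants(s2, stem_design)
        x = np.array([t1.counts[v] for v in enumerate_variants(3)], float)
        y = np.array([t2.counts[v] for v in enumerate_variants(3)], float)
        ref = stats.pearsonr(x, y).statistic
        assert condition_correlation(t1, t2) == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_is_an_error(self):
        flat = _table(K1, {"A": 1, "C": 1, "G": 1, "U": 1})
        other = _table(K1, {"A": 2, "C": 1, "G": 1, "U": 1}, "b")
        with pytest.raises(ValueError):
            condition_correlation(flat, other)


class TestSelectivityScore:
    def _etables(self, count_maps):
        blank = _table(K3, {}, "blank")
        return {aa: compute_enrichment(_table(K3, m, aa), blank)
                for aa, m in count_maps.items()}

    def test_identical_conditions_score_zero(self):
        t = self._etables({"Ala": {"CAG": 10}, "Gly": {"CAG": 10}})
        scores = selectivity_score(t)
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_log2_margin_over_best_competitor(self):
        # enrichment ratio of 4 vs 2 on the same blank -> margin log2(2) = 1
        blank = _table(K3, {v: 100 for v in enumerate_variants(3)}, "blank")
        sel_a = _table(K3, {"CAG": 400, **{v: 100 for v in enumerate_variants(3)
                                           if v != "CAG"}}, "Ala")
        sel_b = _table(K3, {"CAG": 200, **{v: 100 for v in enumerate_variants(3)
                                           if v != "CAG"}}, "Gly")
        tables = {aa: compute_enrichment(s, blank)
                  for aa, s in (("Ala", sel_a), ("Gly", sel_b))}
        scores = selectivity_score(tables)
        expected = (tables["Ala"].table.loc["CAG", "log2_enrichment"]
                    - tables["Gly"].table.loc["CAG", "log2_enrichment"])
        assert scores.loc["CAG", "Ala"] == pytest.approx(expected)
        assert expected == pytest.approx(1.0, abs=0.05)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            selectivity_score(self._etables({"Ala": {}}))

    def test_planted_specific_variant_tops_its_condition(self, stem_design):
        """An Ala-specific variant wins Ala's selectivity ranking."""
        base = make_truth(3, bias_sd=0.3, seed=31)
        tables = {}
        for i, aa in enumerate(["Ala", "Gly", "Pro"]):
            p = np.full(64, 0.2)
            if aa == "Ala":
                p[enumerate_variants(3).index("CAG")] = 0.9
            truth = make_truth(3, bias_sd=0.0, p_spec=dict(
                zip(enumerate_variants(3), p)), seed=31)
            truth.b = base.b  # shared procedural bias across conditions
            sel, blank = simulate_selection_reads(truth, stem_design,
                                                  depth=50_000, seed=40 + i)
            tables[aa] = compute_enrichment(
                extract_variants(sel, stem_design),
                extract_variants(blank, stem_design))
        scores = selectivity_score(tables)
        assert top_selectivity(scores, "Ala", n=1) == ["CAG"]


def test_permutation_equivariance():
    """Relabeling variants permutes enrichments and ranks consistently."""
    rng = np.random.default_rng(3)
    variants = enumerate_variants(2)
    c_sel = dict(zip(variants, rng.integers(0, 200, 16)))
    c_blank = dict(zip(variants, rng.integers(50, 150, 16)))
    design = LibraryDesign("G", 2, "C")
    e = compute_enrichment(_table(design, {v: int(c) for v, c in c_sel.items()}),
                           _table(design, {v: int(c) for v, c in c_blank.items()},
                                  "blank"))
    perm = list(rng.permutation(variants))
    mapping = dict(zip(variants, perm))
    e_perm = compute_enrichment(
        _table(design, {mapping[v]: int(c_sel[v]) for v in variants}),
        _table(design, {mapping[v]: int(c_blank[v]) for v in variants}, "blank"))
    for v in variants:
        assert e_perm.table.loc[mapping[v], "enrichment"] == pytest.approx(
            e.table.loc[v, "enrichment"])
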