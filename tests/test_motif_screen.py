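"""Chi-square contingency screening: closed form, calibration, reports."""

import logging

import numpy as np
import pytest
from scipy import stats

import toxsar as tx
from toxsar.motif_screen import (
    ContingencyTable2x2,
    build_contingency,
    chi2_2x2,
    expected_counts,
    fisher_exact_2x2,
    motif_distribution_table,
    permutation_pvalue,
    screen_motifs,
    screen_table,
    selected_motifs,
)


class TestChi2ClosedForm:
    def test_perfect_association(self):
        chi2, p = chi2_2x2(ContingencyTable2x2(10, 0, 0, 10))
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(stats.chi2.sf(20.0, 1))

    def test_perfect_independence(self):
        chi2, p = chi2_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert chi2 == 0.0
        assert p == 1.0

    def test_zero_column_margin_is_degenerate(self):
        chi2, p = chi2_2x2(ContingencyTable2x2(0, 51, 0, 20))
        assert (chi2, p) == (0.0, 1.0)

    def test_carrier_skew_table(self):
        """18 of 51 toxic carriers vs 0 of 20 non-toxic."""
        chi2, p = chi2_2x2(ContingencyTable2x2(18, 33, 0, 20))
        assert chi2 == pytest.approx(9.4562, abs=1e-4)
        assert p == pytest.approx(0.0021044, abs=1e-6)

    def test_matches_generic_observed_vs_expected(self):
        """Closed form equals sum (O-E)^2/E computed from the margins."""
        rng = np.random.default_rng(0)
        for _ in range(500):
            a, b, c, d = rng.integers(0, 40, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            obs = t.as_array()
            exp = expected_counts(t)
            generic = float(((obs - exp) ** 2 / exp).sum())
            assert chi2_2x2(t)[0] == pytest.approx(generic, abs=1e-9)

    def test_matches_scipy_contingency(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 40, size=4)
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            ref = stats.chi2_contingency(t.as_array(), correction=False)
            got = chi2_2x2(t)
            assert got[0] == pytest.approx(ref.statistic, abs=1e-9)
            assert got[1] == pytest.approx(ref.pvalue, abs=1e-9)

    def test_continuity_correction_matches_scipy(self):
        t = ContingencyTable2x2(18, 33, 2, 18)
        ref = stats.chi2_contingency(t.as_array(), correction=True)
        got = chi2_2x2(t, continuity_correction=True)
        assert got[0] == pytest.approx(ref.statistic, abs=1e-9)

    def test_class_swap_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(1, 30, size=4))
            chi_ab = chi2_2x2(ContingencyTable2x2(a, b, c, d))[0]
            chi_cd = chi2_2x2(ContingencyTable2x2(c, d, a, b))[0]
            assert chi_ab == pytest.approx(chi_cd, abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2(ContingencyTable2x2(5, 5, 0, 0))


class TestPermutationNull:
    def test_estimate_matches_exact_hypergeometric_tail(self):
        """Label shuffling reproduces the exact conditional null."""
        table = ContingencyTable2x2(18, 33, 0, 20)
        chi2_obs = chi2_2x2(table)[0]
        exact = 0.0
        for a in range(0, 19):
            t = ContingencyTable2x2(a, 51 - a, 18 - a, 2 + a)
            if chi2_2x2(t)[0] >= chi2_obs - 1e-12:
                exact += stats.hypergeom.pmf(a, 71, 18, 51)
        p_hat, se = permutation_pvalue(table, n_perm=100_000, seed=0)
        assert abs(p_hat - exact) <= 3 * se

    def test_asymptotic_tail_within_factor_two_of_exact(self):
        """The chi2(1) approximation is rough but same order on this table
        (min expected cell ~5); it overestimates the exact permutation p
        by ~30% here."""
        table = ContingencyTable2x2(18, 33, 0, 20)
        p_asym = chi2_2x2(table)[1]
        p_hat, _ = permutation_pvalue(table, n_perm=100_000, seed=0)
        assert p_hat / 2 < p_asym < p_hat * 2

    def test_fisher_crosscheck(self):
        p = fisher_exact_2x2(ContingencyTable2x2(18, 33, 0, 20))
        assert p == pytest.approx(
            stats.fisher_exact([[18, 33], [0, 20]])[1], abs=1e-12
        )


class TestContingencyFromData:
    def test_panel_tcc_counts(self, panel_dataset):
        """TCC occurs in four toxic and one non-toxic panel compound."""
        t = build_contingency("TCC", panel_dataset)
        assert (t.a, t.b, t.c, t.d) == (4, 2, 1, 4)

    def test_planted_carrier_fractions(self):
        """A generated set with 18/51 toxic TCC carriers and none elsewhere."""
        spec = tx.SyntheticSpec(planted_motifs=("TCC",), penetrance=18 / 51)
        ds, _ = tx.generate(spec, seed=3)
        t = build_contingency("TCC", ds)
        assert (t.a, t.b, t.c, t.d) == (18, 33, 0, 20)

    def test_absent_motif_degenerate(self, panel_dataset):
        t = build_contingency("GGGGG", panel_dataset)
        assert (t.a, t.c) == (0, 0)
        assert (t.b, t.d) == (6, 5)

    def test_single_class_rejected(self):
        ds = tx.Dataset([tx.GapmerRecord(id="a", bases="TAATCGTCGATACC", toxic=True)])
        with pytest.raises(ValueError, match="both classes"):
            build_contingency("TCC", ds)


class TestScreen:
    def test_planted_motifs_selected(self, catalogue):
        ds, _ = tx.generate(tx.SyntheticSpec(penetrance=0.5), seed=11)
        fm = tx.featurize(ds, catalogue)
        sel = set(selected_motifs(screen_motifs(fm)))
        assert {"TGC", "TCC"} <= sel

    def test_untestable_motifs_never_selected(self, panel_dataset, catalogue):
        results = screen_motifs(tx.featurize(panel_dataset, catalogue))
        for r in results:
            if not r.testable:
                assert not r.selected
                assert r.p_value == 1.0
            else:
                assert r.selected == (r.p_value < r.alpha)

    def test_row_order_equivariance(self, catalogue):
        """Shuffling the sequence order changes nothing per motif."""
        ds, _ = tx.generate(tx.SyntheticSpec(n_toxic=15, n_nontoxic=10), seed=4)
        fm = tx.featurize(ds, catalogue)
        rev = tx.Dataset(list(ds.records)[::-1])
        fm_rev = tx.featurize(rev, catalogue)
        by_motif = {r.motif: r for r in screen_motifs(fm)}
        for r in screen_motifs(fm_rev):
            assert r.chi2 == pytest.approx(by_motif[r.motif].chi2, abs=1e-12)
            assert r.selected == by_motif[r.motif].selected

    def test_constant_labels_rejected(self, catalogue):
        ds = tx.Dataset(
            [tx.GapmerRecord(id=f"s{i}", bases="TAATCGTCGATACC", toxic=True) for i in range(3)]
        )
        with pytest.raises(ValueError):
            screen_motifs(tx.featurize(ds, catalogue))

    def test_bh_selection_is_subset_of_raw(self, catalogue):
        ds, _ = tx.generate(tx.SyntheticSpec(), seed=5)
        fm = tx.featurize(ds, catalogue)
        raw = set(selected_motifs(screen_motifs(fm)))
        bh = set(selected_motifs(screen_motifs(fm, fdr_method="bh")))
        assert bh <= raw

    def test_small_expected_count_warning_logged(self, panel_dataset, catalogue, caplog):
        with caplog.at_level(logging.WARNING, logger="toxsar.motif_screen"):
            screen_motifs(tx.featurize(panel_dataset, catalogue))
        assert any("expected cell" in rec.message for rec in caplog.records)

    def test_screen_type_I_error_is_valid(self, catalogue):
        """Under label shuffling the selected fraction never exceeds alpha
        (the discrete chi2 screen is conservative, so the empirical rate
        sits below the nominal level; validity is the guarantee)."""
        ds, _ = tx.generate(tx.SyntheticSpec(), seed=6)
        fm = tx.featurize(ds, catalogue)
        rates = []
        for s in range(30):
            shuffled = tx.shuffle_labels(ds, seed=s)
            fm_s = tx.FeatureMatrix(
                index=fm.index, row_ids=fm.row_ids, X=fm.X,
                y=tuple(r.toxic for r in shuffled),
            )
            res = screen_motifs(fm_s)
            n_testable = sum(r.testable for r in res)
            rates.append(sum(r.selected for r in res) / n_testable)
        mean = float(np.mean(rates))
        mc_se = float(np.std(rates) / np.sqrt(len(rates)))
        assert mean <= 0.05 + 3 * mc_se
        assert mean > 0.0  # the screen does reject sometimes under the null


class TestReports:
    def test_distribution_table_ordering_and_counts(self, catalogue):
        ds, _ = tx.generate(tx.SyntheticSpec(), seed=7)
        results = screen_motifs(tx.featurize(ds, catalogue))
        dist = motif_distribution_table(results)
        assert list(dist.columns[:3]) == ["motif", "toxic_with_motif", "nontoxic_with_motif"]
        assert (dist["chi2"].diff().dropna() <= 1e-12).all()  # descending
        planted = dist[dist["motif"].isin(["TGC", "TCC"])]
        assert len(planted) == 2
        assert (planted["nontoxic_with_motif"] == 0).all()

    def test_empty_selection_gives_empty_table_with_header(self):
        dist = motif_distribution_table([])
        assert len(dist) == 0
        assert "motif" in dist.columns

    def test_screen_table_shape(self, panel_dataset, catalogue):
        results = screen_motifs(tx.featurize(panel_dataset, catalogue))
        df = screen_table(results)
        assert len(df) == 1360
        assert (df["a_toxic_with"] + df["b_toxic_without"] == 6).all()
        assert (df["c_nontoxic_with"] + df["d_nontoxic_without"] == 5).all()
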