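"""Spearman screening, BH adjustment, Fisher enrichment and set labels."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cispair.expression import ExpressionMatrix
from cispair.pairing import GenePair
from cispair.screen import (
    ConstantInputError,
    bh_adjust,
    fisher_exact_2x2,
    pair_class_enrichment,
    screen_pairs,
    spearman,
    summarize_and_label,
)
from oracles import bh_step_up, fisher_two_sided, spearman_rho


def lc_pair(anchor, partner, window=100_000):
    return GenePair(anchor, partner, "lncRNA", 0, "antisense_overlap", window)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 3.0, 4.0, 10.0, 20.0])
        rho, p = spearman(x, x**3)
        assert rho == 1.0
        assert 0 < p < 1e-300  # numeric floor, not zero

    def test_perfect_antimonotone(self):
        x = np.arange(5.0)
        rho, _ = spearman(x, -x)
        assert rho == -1.0

    def test_hand_example_matches_rank_pearson(self):
        x = [1, 2, 3, 4, 5]
        y = [3, 1, 2, 5, 4]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(spearman_rho(x, y), abs=1e-12)

    def test_matches_bruteforce_on_random_vectors(self):
        """Midrank Pearson oracle over 200 random vectors incl. heavy ties."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(10, 40))
            x = rng.integers(0, 8, size=n).astype(float)  # many ties
            y = rng.normal(size=n)
            rho, p = spearman(x, y)
            try:
                expected = spearman_rho(x, y)
            except ZeroDivisionError:
                continue
            assert rho == pytest.approx(expected, abs=1e-12)
            ref = scipy.stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.exponential(10, size=50)
        y = rng.exponential(10, size=50)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(np.log2(x + 1), y)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantInputError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_matches_independent_step_up(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(1e-8, 1.0, size=20)
        np.testing.assert_allclose(bh_adjust(p), bh_step_up(list(p)), atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(1e-6, 1, size=50)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact_2x2(10, 10, 10, 10) == pytest.approx(1.0)

    def test_matches_enumeration_on_small_margins(self):
        rng = np.random.default_rng(3)
        tables = [(5, 0, 0, 5)] + [
            tuple(int(v) for v in rng.integers(0, 16, size=4)) for _ in range(60)
        ]
        for a, b, c, d in tables:
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_two_sided(a, b, c, d), rel=1e-9
            )

    def test_symmetric_under_row_and_column_swap(self):
        for a, b, c, d in [(3, 9, 2, 14), (0, 5, 7, 1)]:
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_exact_2x2(d, c, b, a), rel=1e-12
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


def _cohort_from_latent(rho_target_gamma, n, rng, base=(80.0, 15.0)):
    """Two anti-coupled NB genes + unrelated filler genes, one cancer type."""
    z = rng.normal(size=n)
    mu_c = base[0] * np.exp(-rho_target_gamma * z)
    mu_l = base[1] * np.exp(rho_target_gamma * z)
    r = 1 / 0.2
    data = {
        "CG0": rng.negative_binomial(r, r / (r + mu_c)),
        "LNC0": rng.negative_binomial(r, r / (r + mu_l)),
    }
    for i in range(8):
        data[f"F{i}"] = rng.poisson(50, size=n)
    df = pd.DataFrame(data, index=[f"S{j}" for j in range(n)]).T * 100.0
    return {"CT1": ExpressionMatrix("CT1", df, unit="cpm")}


class TestScreenPairs:
    def test_planted_negative_pair_is_significant(self):
        """A pair with population rho about -0.6 at n=300 reaches corrected
        P < 1e-5 in essentially every replicate."""
        hits = 0
        reps = 60
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            cpms = _cohort_from_latent(0.7, 300, rng)
            pairs = [lc_pair("CG0", "LNC0")] + [
                lc_pair("CG0", f"F{i}") for i in range(8)
            ]
            rec = screen_pairs(pairs, cpms, min_samples_filter=1)
            row = rec[(rec.partner_id == "LNC0")].iloc[0]
            if row.rho < 0 and row.p_adj < 1e-5:
                hits += 1
        assert hits >= int(0.95 * reps)

    def test_null_family_yields_no_significant_records(self):
        rng = np.random.default_rng(0)
        n = 100
        genes = {f"G{i}": rng.poisson(60, size=n) * 50.0 for i in range(120)}
        df = pd.DataFrame(genes, index=[f"S{j}" for j in range(n)]).T
        cpms = {"CT1": ExpressionMatrix("CT1", df, unit="cpm")}
        pairs = [
            lc_pair(f"G{i}", f"G{i + 60}") for i in range(60)
        ]
        rec = screen_pairs(pairs, cpms, min_samples_filter=1)
        assert (rec.p_adj < 1e-5).sum() == 0

    def test_unexpressed_pair_produces_no_record(self):
        df = pd.DataFrame(
            {"S0": [0, 100] * 6, "S1": [0, 100] * 6},
            index=[f"G{i}" for i in range(12)],
        ).astype(float)
        cpms = {"CT1": ExpressionMatrix("CT1", df, unit="cpm")}
        rec = screen_pairs([lc_pair("G0", "G2")], cpms, min_samples_for_test=2,
                           min_samples_filter=1)
        assert rec.empty


def records_from_rows(rows):
    return pd.DataFrame(
        rows,
        columns=["anchor_id", "partner_id", "partner_class", "window_bp",
                 "cancer_type", "n", "rho", "p_raw", "p_adj"],
    )


class TestSummarize:
    def make(self, sig_neg, sig_pos, nonsig_neg=0, nonsig_pos=0, partner_class="lncRNA"):
        rows = []
        ct = 0
        for _ in range(sig_neg):
            rows.append(("A", "B", partner_class, 100_000, f"CT{ct}", 50, -0.4, 1e-9, 1e-8)); ct += 1
        for _ in range(sig_pos):
            rows.append(("A", "B", partner_class, 100_000, f"CT{ct}", 50, 0.4, 1e-9, 1e-8)); ct += 1
        for _ in range(nonsig_neg):
            rows.append(("A", "B", partner_class, 100_000, f"CT{ct}", 50, -0.1, 0.3, 0.6)); ct += 1
        for _ in range(nonsig_pos):
            rows.append(("A", "B", partner_class, 100_000, f"CT{ct}", 50, 0.1, 0.3, 0.6)); ct += 1
        return records_from_rows(rows)

    def test_negative_majority_with_significance_is_lcn(self):
        # pattern of a tumor-suppressor / antisense pair: 0 significant
        # positive, 3 significant negative types
        out = summarize_and_label(self.make(3, 0, nonsig_neg=2, nonsig_pos=1))
        assert out.loc[0, "set_label"] == "LCN"

    def test_opposite_sign_significances_do_not_veto(self):
        # 2 significant positive, 5 significant negative, negative majority
        out = summarize_and_label(self.make(5, 2, nonsig_neg=2))
        row = out.iloc[0]
        assert (row.n_sig_pos, row.n_sig_neg, row.set_label) == (2, 5, "LCN")

    def test_no_significance_is_none(self):
        out = summarize_and_label(self.make(0, 0, nonsig_neg=5))
        assert out.loc[0, "set_label"] == "none"

    def test_coding_partner_gets_ccn(self):
        out = summarize_and_label(self.make(3, 0, partner_class="coding"))
        assert out.loc[0, "set_label"] == "CCN"

    def test_positive_mirror_is_lcp(self):
        out = summarize_and_label(self.make(0, 3, nonsig_pos=2))
        assert out.loc[0, "set_label"] == "LCP"

    def test_majority_all_mode_uses_cohort_size(self):
        rec = self.make(3, 0)  # negative in 3 of 3 testable
        out = summarize_and_label(rec, majority="all", n_cancer_types=32)
        assert out.loc[0, "set_label"] == "none"  # 3 of 32 is no majority

    def test_labels_partition(self, default_run):
        summ = default_run["summaries"]
        assert summ["set_label"].isin(["LCN", "LCP", "CCN", "CCP", "none"]).all()
        lnc_rows = summ[summ.partner_class == "lncRNA"]
        assert not lnc_rows["set_label"].isin(["CCN", "CCP"]).any()
        cc_rows = summ[summ.partner_class == "coding"]
        assert not cc_rows["set_label"].isin(["LCN", "LCP"]).any()
        assert (summ.n_sig_neg <= summ.n_neg_rho).all()
        assert (summ.n_neg_rho <= summ.n_testable).all()


class TestEnrichment:
    def rec(self, n_sig, n_total, partner_class, ct="CT1", w=100_000):
        rows = []
        for i in range(n_total):
            sig = i < n_sig
            rows.append(
                (f"A{i}", f"B{i}", partner_class, w, ct, 50,
                 -0.5 if sig else 0.01, 1e-9 if sig else 0.5, 1e-8 if sig else 0.9)
            )
        return records_from_rows(rows)

    def test_strong_lc_excess_is_flagged(self):
        table = pair_class_enrichment(
            self.rec(50, 100, "lncRNA"), self.rec(10, 100, "coding")
        )
        row = table.iloc[0]
        assert row.enriched and row.fisher_p < 0.01

    def test_identical_fractions_not_enriched(self):
        table = pair_class_enrichment(
            self.rec(10, 100, "lncRNA"), self.rec(10, 100, "coding")
        )
        assert not table.iloc[0].enriched

    def test_empty_stratum_row_emitted_unflagged(self):
        table = pair_class_enrichment(
            self.rec(5, 20, "lncRNA"), self.rec(0, 0, "coding").iloc[0:0]
        )
        row = table.iloc[0]
        assert np.isnan(row.cc_frac) and not row.enriched
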