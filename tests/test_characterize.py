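"""Tau specificity, exonic conservation, categories, methylation and RCI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cispair.characterize import (
    ScoreTrack,
    assign_probe_to_tss,
    category_enrichment,
    exonic_conservation,
    localization_compare,
    methylation_coupling,
    t_test_two_sample,
    tau,
    tau_table,
)
from cispair.expression import ExpressionMatrix, MeanProfile
from conftest import make_gene
from oracles import conservation_per_base


def profile(values, gene_id="G"):
    return MeanProfile(gene_id=gene_id, values=pd.Series(
        {f"CT{i}": v for i, v in enumerate(values)}
    ))


class TestTau:
    @pytest.mark.parametrize("log_mode", [True, False])
    def test_constant_profile_is_zero(self, log_mode):
        assert tau(profile([5.0] * 6), log_transform=log_mode).tau == 0.0

    @pytest.mark.parametrize("log_mode", [True, False])
    def test_single_support_is_one(self, log_mode):
        assert tau(profile([0, 0, 9.0, 0]), log_transform=log_mode).tau == 1.0

    def test_direct_arithmetic_raw_mode(self):
        assert tau(profile([1, 2, 4]), log_transform=False).tau == pytest.approx(0.625)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            tau(profile([0.0, 0.0]))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            tau(profile([1.0]))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(0.0, 1e4), min_size=2, max_size=8).filter(lambda v: max(v) > 0),
        st.floats(0.1, 100.0),
    )
    def test_scale_invariant_raw_mode(self, values, c):
        t1 = tau(profile(values), log_transform=False).tau
        t2 = tau(profile([c * v for v in values]), log_transform=False).tau
        assert t1 == pytest.approx(t2, abs=1e-9)
        assert 0.0 <= t1 <= 1.0 + 1e-12

    def test_concentration_never_decreases_tau(self):
        """Moving mass toward the max entry (same max) raises specificity."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = np.sort(rng.uniform(0.1, 10, size=5))
            y = x.copy()
            i = int(rng.integers(0, 4))
            y[i] = y[i] * rng.uniform(0.0, 1.0)  # shrink a non-max entry
            t_x = tau(profile(x), log_transform=False).tau
            t_y = tau(profile(y), log_transform=False).tau
            assert t_y >= t_x - 1e-12

    def test_table_matches_scalar_and_handles_zero_rows(self):
        df = pd.DataFrame(
            [[1, 2, 4], [3, 3, 3], [0, 0, 0]],
            index=["a", "b", "c"], columns=["x", "y", "z"], dtype=float,
        )
        out = tau_table(df, log_transform=False)
        assert out["a"] == pytest.approx(0.625)
        assert out["b"] == 0.0
        assert np.isnan(out["c"])


class TestConservation:
    def test_constant_track(self):
        track = ScoreTrack({"chr1": [(0, 10_000, 0.8)]})
        g = make_gene(start=1000, end=2000, exons=[(1000, 2000)])
        res = exonic_conservation(g, track)
        assert res.mean_score == pytest.approx(0.8)
        assert res.n_bases == 1000

    def test_fully_masked_lncRNA_exon(self):
        track = ScoreTrack({"chr1": [(0, 10_000, 0.8)]})
        g = make_gene(biotype="lncRNA", start=1000, end=2000, exons=[(1000, 2000)])
        res = exonic_conservation(g, track, mask=[(500, 2500)])
        assert res.n_bases == 0 and np.isnan(res.mean_score)

    def test_two_equal_exons_weighted_mean(self):
        track = ScoreTrack({"chr1": [(0, 1500, 0.2), (1500, 10_000, 0.6)]})
        g = make_gene(start=1000, end=3000, exons=[(1000, 1500), (2500, 3000)])
        assert exonic_conservation(g, track).mean_score == pytest.approx(0.4)

    def test_uncovered_bases_score_zero(self):
        track = ScoreTrack({"chr1": [(1000, 1500, 1.0)]})
        g = make_gene(start=1000, end=2000, exons=[(1000, 2000)])
        assert exonic_conservation(g, track).mean_score == pytest.approx(0.5)

    def test_matches_per_base_loop(self):
        rng = np.random.default_rng(6)
        segs = []
        pos = 0
        while pos < 8000:
            length = int(rng.integers(50, 400))
            if rng.random() < 0.7:
                segs.append((pos, pos + length, float(rng.uniform(0, 1))))
            pos += length
        track = ScoreTrack({"chr1": segs})
        for _ in range(20):
            s = int(rng.integers(0, 6000))
            exons = [(s, s + int(rng.integers(10, 500)))]
            extra = s + int(rng.integers(600, 1500))
            exons.append((extra, extra + int(rng.integers(10, 300))))
            g = make_gene(start=exons[0][0], end=exons[-1][1], exons=exons)
            mask = [(s + 20, s + 60)]
            res = exonic_conservation(g, track, mask=mask)
            from cispair.annotation import merge_exons, subtract_intervals
            support = subtract_intervals(merge_exons(g), mask)
            expected_mean, expected_n = conservation_per_base(support, segs)
            assert res.n_bases == expected_n
            if expected_n:
                assert res.mean_score == pytest.approx(expected_mean, abs=1e-9)

    def test_overlapping_track_intervals_rejected(self):
        with pytest.raises(ValueError):
            ScoreTrack({"chr1": [(0, 100, 0.5), (50, 150, 0.6)]})


class TestCategoryEnrichment:
    def summaries(self):
        rows = []
        for i in range(20):
            rows.append((f"C{i:02d}", f"L{i:02d}", "lncRNA", "LCN"))
        for i in range(20, 60):
            rows.append((f"C{i:02d}", f"L{i:02d}", "lncRNA", "LCP"))
        for i in range(60, 80):
            rows.append((f"C{i:02d}", f"X{i:02d}", "coding", "CCN"))
        for i in range(80, 120):
            rows.append((f"C{i:02d}", f"X{i:02d}", "coding", "CCP"))
        return pd.DataFrame(rows, columns=["anchor_id", "partner_id",
                                           "partner_class", "set_label"])

    def test_saturating_category(self):
        summ = self.summaries()
        out = category_enrichment(summ, set(summ.anchor_id), "all")
        assert (out["fraction"] == 1.0).all()
        assert np.allclose(out["fisher_p"], 1.0)

    def test_planted_enrichment_detected(self):
        summ = self.summaries()
        # category: 15 of 20 LCN coding genes, 5 of the remaining 100
        cat = {f"C{i:02d}" for i in range(15)} | {"C30", "C45", "C61", "C90", "C95"}
        out = category_enrichment(summ, cat, "driver").set_index("set_label")
        assert out.loc["LCN", "fisher_p"] < 0.01
        assert out.loc["LCN", "fraction"] > out.loc["LCP", "fraction"]

    def test_empty_category_gives_zero_fractions(self):
        out = category_enrichment(self.summaries(), set(), "none")
        assert (out["fraction"] == 0.0).all()


class TestProbeAssignment:
    manifest = pd.DataFrame(
        {
            "probe_id": ["cg1", "cg2", "cg3", "cg4"],
            "gene_id": ["G1", "G1", "G1", "G2"],
            "region": ["TSS200", "TSS1500", "Body", "TSS200"],
        }
    )

    def betas(self, cg1, cg2):
        return pd.DataFrame(
            {"S1": [cg1, cg2, 0.9], "S2": [cg1, cg2, 0.9]},
            index=["cg1", "cg2", "cg3"],
        )

    def test_single_probe(self):
        assert assign_probe_to_tss(self.manifest, self.betas(0.5, 0.5).loc[["cg1"]], "G1") == "cg1"

    def test_max_mean_beta_wins(self):
        assert assign_probe_to_tss(self.manifest, self.betas(0.2, 0.7), "G1") == "cg2"

    def test_tie_breaks_lexicographically(self):
        assert assign_probe_to_tss(self.manifest, self.betas(0.4, 0.4), "G1") == "cg1"

    def test_body_probe_never_selected(self):
        assert assign_probe_to_tss(self.manifest, self.betas(0.1, 0.1), "G1") != "cg3"

    def test_missing_gene_returns_none(self):
        assert assign_probe_to_tss(self.manifest, self.betas(0.1, 0.1), "G9") is None


class TestMethylationCoupling:
    def build(self, coupled, n=120, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=n)
        samples = [f"S{j}" for j in range(n)]
        lnc = 15 * np.exp(0.6 * z) * np.exp(rng.normal(0, 0.2, n))
        cpm = pd.DataFrame({"LNC0": lnc, "CG0": rng.exponential(50, n)},
                           index=samples).T
        link = z if coupled else rng.normal(size=n)
        beta = 1 / (1 + np.exp(-(-1.0 + 1.0 * link + rng.normal(0, 0.5, n))))
        betas = pd.DataFrame({s: [b] for s, b in zip(samples, beta)}, index=["cg1"])
        manifest = pd.DataFrame(
            {"probe_id": ["cg1"], "gene_id": ["CG0"], "region": ["TSS200"]}
        )
        cpms = {"CT1": ExpressionMatrix("CT1", cpm, unit="cpm")}
        pairs = pd.DataFrame({"anchor_id": ["CG0"], "partner_id": ["LNC0"]})
        return pairs, cpms, {"CT1": betas}, manifest

    def test_mediated_pair_positively_coupled(self):
        records, flags = methylation_coupling(*self.build(coupled=True))
        assert records.iloc[0].rho_meth > 0
        assert bool(flags.iloc[0].positively_coupled)

    def test_independent_beta_rarely_coupled(self):
        hits = 0
        for seed in range(20):
            _, flags = methylation_coupling(*self.build(coupled=False, seed=seed))
            hits += int(flags.iloc[0].positively_coupled)
        assert hits <= 14  # sign is a coin flip without coupling

    def test_no_matched_samples_yields_no_records(self):
        pairs, cpms, betas, manifest = self.build(coupled=True)
        betas["CT1"].columns = [f"OTHER{j}" for j in range(betas["CT1"].shape[1])]
        records, flags = methylation_coupling(pairs, cpms, betas, manifest)
        assert records.empty and flags.empty


class TestTTest:
    def test_identical_groups(self):
        t, p = t_test_two_sample([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert t == 0.0 and p == 1.0

    def test_separated_constant_groups_floor(self):
        t, p = t_test_two_sample([0.0, 0, 0, 0], [1.0, 1, 1, 1])
        assert p < 1e-300

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1.3, 25)
        t, p = t_test_two_sample(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_ref, abs=1e-12)
        import scipy.stats
        assert p == pytest.approx(
            2 * scipy.stats.t.sf(abs(t_ref), na + nb - 2), abs=1e-12
        )

    def test_welch_variant_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.2, 10)
        b = rng.normal(0, 3.0, 40)
        t_s, _ = t_test_two_sample(a, b, variant="student")
        t_w, _ = t_test_two_sample(a, b, variant="welch")
        assert t_s != pytest.approx(t_w)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            t_test_two_sample([1.0], [1.0, 2.0])


class TestLocalization:
    def rci(self, lcn_shift, n=50, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for cl in ("CL1", "CL2"):
            for i in range(n):
                rows.append((f"N{i}", cl, rng.normal(lcn_shift, 1)))
                rows.append((f"P{i}", cl, rng.normal(0, 1)))
                rows.append((f"B{i}", cl, rng.normal(0, 1)))
        return pd.DataFrame(rows, columns=["gene_id", "cell_line", "rci"])

    def ids(self, n=50):
        return ([f"N{i}" for i in range(n)], [f"P{i}" for i in range(n)],
                [f"B{i}" for i in range(n)])

    def test_shifted_group_detected(self):
        lcn, lcp, bg = self.ids()
        hits = 0
        for seed in range(20):
            out = localization_compare(self.rci(-1.0, seed=seed), lcn, lcp, bg)
            hits += int((out["p_vs_background"] < 0.05).all()
                        and (out["median_lcn"] < 0).all())
        assert hits >= 19

    def test_identical_groups_give_p_one_scale(self):
        df = self.rci(0.0, seed=1)
        lcn, lcp, bg = self.ids()
        out = localization_compare(df, lcn, lcn, lcn)
        assert np.allclose(out["t_vs_lcp"], 0.0)
        assert np.allclose(out["p_vs_lcp"], 1.0)

    def test_small_group_skipped(self):
        df = self.rci(-1.0)
        out = localization_compare(df, ["N0"], [], [])
        assert out.empty
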