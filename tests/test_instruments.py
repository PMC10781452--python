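import numpy as np
import pytest
from hypothesis import given, strategies as st

from drugmr.datatypes import GeneRegion, LDMatrix
from drugmr.errors import (
    InsufficientInstrumentsError,
    NoOverlapError,
    SampleSizeError,
)
from drugmr.instruments import (
    InstrumentSelectionConfig,
    compute_f_statistics,
    f_statistic,
    harmonize,
    select_cis_instruments,
    steiger_filter,
)

from conftest import make_hset, make_summary_frame


def region(**kw):
    base = dict(
        gene="LDLR", chrom="19", start=1_000, end=100_000,
        exposure_trait="LDL_C", flank_bp=0,
    )
    base.update(kw)
    return GeneRegion(**base)


def ld_from(ids, pairs, default=0.0):
    m = np.full((len(ids), len(ids)), default, float)
    np.fill_diagonal(m, 1.0)
    idx = {v: i for i, v in enumerate(ids)}
    for (a, b), r2 in pairs.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = r2
    return LDMatrix(variant_ids=list(ids), r2=m)


def cfg(**kw):
    base = dict(min_snps=1, flank_bp=0)
    base.update(kw)
    return InstrumentSelectionConfig(**base)


def brute_force_clump(cand, ld, clump_r2, window, missing=1.0):
    """Independent reference: repeatedly pick the lowest-p remaining SNP
    (ties by pos then id) from a set, then delete its LD partners."""
    remaining = {
        row.variant_id: (row.pvalue, row.pos, row.variant_id)
        for row in cand.itertuples()
    }
    pos = dict(zip(cand["variant_id"], cand["pos"]))
    kept = []
    while remaining:
        best = min(remaining, key=remaining.get)
        kept.append(best)
        del remaining[best]
        for other in list(remaining):
            if abs(pos[other] - pos[best]) > window:
                continue
            r2 = ld.get(best, other)
            if r2 is None:
                r2 = missing
            if r2 >= clump_r2:
                del remaining[other]
    return kept


class TestCisSelection:
    def test_single_significant_snp_kept(self):
        stats = make_summary_frame(
            [{"variant_id": "rs1", "chrom": "19", "pos": 5000,
              "effect_allele": "A", "other_allele": "G",
              "beta": 0.1, "se": 0.01, "pvalue": 1e-9}]
        )
        kept = select_cis_instruments(
            stats, region(), ld_from(["rs1"], {}), cfg()
        )
        assert list(kept["variant_id"]) == ["rs1"]

    def test_clump_discards_correlated_neighbour(self):
        rows = [
            {"variant_id": f"rs{i}", "chrom": "19", "pos": p,
             "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01, "pvalue": pv}
            for i, (p, pv) in enumerate(
                [(5000, 1e-20), (6000, 1e-10), (7000, 1e-9)], start=1
            )
        ]
        stats = make_summary_frame(rows)
        ld = ld_from(
            ["rs1", "rs2", "rs3"],
            {("rs1", "rs2"): 0.9, ("rs1", "rs3"): 0.0, ("rs2", "rs3"): 0.0},
        )
        kept = select_cis_instruments(stats, region(), ld, cfg())
        assert list(kept["variant_id"]) == ["rs1", "rs3"]

    def test_no_ld_means_clumping_is_identity(self):
        rows = [
            {"variant_id": f"rs{i}", "chrom": "19", "pos": 1000 * i + 2000,
             "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01, "pvalue": 10.0**-(9 + i)}
            for i in range(1, 6)
        ]
        stats = make_summary_frame(rows)
        ld = ld_from([f"rs{i}" for i in range(1, 6)], {})
        kept = select_cis_instruments(stats, region(), ld, cfg())
        assert len(kept) == 5
        # returned in ascending p order
        assert kept["pvalue"].is_monotonic_increasing

    def test_window_limits_clumping_reach(self):
        # rs2 is in perfect LD with rs1 but 200 kb away: outside the window
        rows = [
            {"variant_id": "rs1", "chrom": "19", "pos": 5_000,
             "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01, "pvalue": 1e-20},
            {"variant_id": "rs2", "chrom": "19", "pos": 205_000,
             "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01, "pvalue": 1e-10},
        ]
        stats = make_summary_frame(rows)
        ld = ld_from(["rs1", "rs2"], {("rs1", "rs2"): 1.0})
        kept = select_cis_instruments(
            stats, region(end=300_000), ld, cfg(clump_window_bp=100_000)
        )
        assert len(kept) == 2

    def test_pvalue_and_window_filters(self):
        rows = [
            {"variant_id": "in", "chrom": "19", "pos": 5000,
             "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01, "pvalue": 1e-9},
            {"variant_id": "weak", "chrom": "19", "pos": 6000,
             "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.05, "pvalue": 1e-4},
            {"variant_id": "far", "chrom": "19", "pos": 900_000,
             "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01, "pvalue": 1e-9},
            {"variant_id": "other_chrom", "chrom": "1", "pos": 5000,
             "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01, "pvalue": 1e-9},
        ]
        stats = make_summary_frame(rows)
        ld = ld_from(["in", "weak", "far", "other_chrom"], {})
        kept = select_cis_instruments(stats, region(), ld, cfg())
        assert list(kept["variant_id"]) == ["in"]

    def test_insufficient_instruments_carries_count(self):
        stats = make_summary_frame(
            [{"variant_id": "rs1", "chrom": "19", "pos": 5000,
              "effect_allele": "A", "other_allele": "G",
              "beta": 0.1, "se": 0.01, "pvalue": 1e-9}]
        )
        with pytest.raises(InsufficientInstrumentsError) as exc:
            select_cis_instruments(
                stats, region(), ld_from(["rs1"], {}), cfg(min_snps=3)
            )
        assert exc.value.n_selected == 1

    def test_missing_ld_defaults_to_discard(self):
        rows = [
            {"variant_id": "rs1", "chrom": "19", "pos": 5000,
             "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01, "pvalue": 1e-20},
            {"variant_id": "rs_absent", "chrom": "19", "pos": 6000,
             "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01, "pvalue": 1e-10},
        ]
        stats = make_summary_frame(rows)
        ld = ld_from(["rs1"], {})  # rs_absent not in the panel
        kept = select_cis_instruments(stats, region(), ld, cfg())
        assert list(kept["variant_id"]) == ["rs1"]
        kept = select_cis_instruments(
            stats, region(), ld, cfg(missing_ld_r2=0.0)
        )
        assert len(kept) == 2

    def test_greedy_clumping_matches_bruteforce_on_random_instances(self, rng):
        for trial in range(60):
            k = int(rng.integers(2, 13))
            ids = [f"rs{i}" for i in range(k)]
            pos = np.sort(rng.integers(2000, 90_000, size=k))
            corr = rng.uniform(0, 1, size=(k, k))
            r2 = (corr + corr.T) / 2
            np.fill_diagonal(r2, 1.0)
            ld = LDMatrix(variant_ids=ids, r2=r2)
            rows = [
                {"variant_id": ids[i], "chrom": "19", "pos": int(pos[i]),
                 "effect_allele": "A", "other_allele": "G", "beta": 0.1,
                 "se": 0.01,
                 "pvalue": float(rng.choice([1e-9, 1e-10, 1e-11, 1e-12]))}
                for i in range(k)
            ]
            cand = make_summary_frame(rows)
            window = int(rng.choice([5_000, 20_000, 100_000]))
            thr = float(rng.choice([0.1, 0.3, 0.6]))
            kept = select_cis_instruments(
                cand, region(), ld,
                cfg(clump_r2=thr, clump_window_bp=window),
            )
            ref = brute_force_clump(cand, ld, thr, window)
            assert sorted(kept["variant_id"]) == sorted(ref), f"trial {trial}"
            # invariant: no retained pair correlated within the window
            kp = kept.set_index("variant_id")["pos"]
            for a in kp.index:
                for b in kp.index:
                    if a < b and abs(kp[a] - kp[b]) <= window:
                        assert ld.get(a, b) < thr


def _stats(rows):
    return make_summary_frame(rows)


class TestHarmonize:
    def _pair(self, exp_alleles, out_alleles, beta_y=-0.05, eaf_x=0.2,
              eaf_y=0.2):
        exp = _stats([
            {"variant_id": "rs1", "effect_allele": exp_alleles[0],
             "other_allele": exp_alleles[1], "beta": 0.10, "se": 0.01,
             "pvalue": 1e-10, "eaf": eaf_x}
        ])
        out = _stats([
            {"variant_id": "rs1", "effect_allele": out_alleles[0],
             "other_allele": out_alleles[1], "beta": beta_y, "se": 0.02,
             "pvalue": 0.01, "eaf": eaf_y}
        ])
        return exp, out

    def test_swapped_alleles_negate_outcome_beta(self):
        exp, out = self._pair(("A", "G"), ("G", "A"))
        h = harmonize(exp, out)
        assert h.table["beta_out"].iloc[0] == pytest.approx(0.05)
        assert bool(h.table["flipped"].iloc[0])

    def test_matching_alleles_copy(self):
        exp, out = self._pair(("A", "G"), ("A", "G"))
        h = harmonize(exp, out)
        assert h.table["beta_out"].iloc[0] == pytest.approx(-0.05)
        assert not bool(h.table["flipped"].iloc[0])

    def test_inconsistent_alleles_excluded(self):
        # A/G vs A/C is strictly excluded
        exp, out = self._pair(("A", "G"), ("A", "C"))
        with pytest.raises(NoOverlapError):
            harmonize(exp, out)

    def test_strand_complement_resolved(self):
        # outcome reported on the opposite strand: A/G vs T/C
        exp, out = self._pair(("A", "G"), ("T", "C"))
        h = harmonize(exp, out)
        assert h.table["beta_out"].iloc[0] == pytest.approx(-0.05)
        assert not bool(h.table["flipped"].iloc[0])

    def test_strand_complement_swapped(self):
        exp, out = self._pair(("A", "G"), ("C", "T"))
        h = harmonize(exp, out)
        assert h.table["beta_out"].iloc[0] == pytest.approx(0.05)
        assert bool(h.table["flipped"].iloc[0])

    def test_palindromic_dropped_by_default(self):
        exp, out = self._pair(("A", "T"), ("A", "T"))
        with pytest.raises(NoOverlapError, match="palindromic"):
            harmonize(exp, out)

    def test_palindromic_ambiguous_at_half_even_when_inferring(self):
        exp, out = self._pair(("A", "T"), ("A", "T"), eaf_x=0.50, eaf_y=0.50)
        with pytest.raises(NoOverlapError, match="ambiguous"):
            harmonize(exp, out, policy="infer_by_eaf")

    def test_palindromic_inferred_when_frequencies_agree(self):
        exp, out = self._pair(("A", "T"), ("A", "T"), eaf_x=0.1, eaf_y=0.12)
        h = harmonize(exp, out, policy="infer_by_eaf")
        assert h.table["beta_out"].iloc[0] == pytest.approx(-0.05)

    def test_palindromic_inferred_flip_when_frequencies_mirror(self):
        exp, out = self._pair(("A", "T"), ("A", "T"), eaf_x=0.1, eaf_y=0.9)
        h = harmonize(exp, out, policy="infer_by_eaf")
        assert h.table["beta_out"].iloc[0] == pytest.approx(0.05)
        assert bool(h.table["flipped"].iloc[0])

    def test_no_shared_variants_raises(self):
        exp = _stats([{"variant_id": "rs1", "effect_allele": "A",
                       "other_allele": "G", "beta": 0.1, "se": 0.01,
                       "pvalue": 1e-10}])
        out = _stats([{"variant_id": "rs2", "effect_allele": "A",
                       "other_allele": "G", "beta": 0.1, "se": 0.01,
                       "pvalue": 0.1}])
        with pytest.raises(NoOverlapError):
            harmonize(exp, out)

    def _multi(self):
        exp = _stats([
            {"variant_id": f"rs{i}", "effect_allele": ea, "other_allele": oa,
             "beta": b, "se": 0.01, "pvalue": 1e-10, "eaf": 0.2}
            for i, (ea, oa, b) in enumerate(
                [("A", "G", 0.1), ("C", "T", -0.08), ("A", "C", 0.12)], 1
            )
        ])
        out = _stats([
            {"variant_id": "rs1", "effect_allele": "G", "other_allele": "A",
             "beta": -0.05, "se": 0.02, "pvalue": 0.01, "eaf": 0.8},
            {"variant_id": "rs2", "effect_allele": "C", "other_allele": "T",
             "beta": 0.03, "se": 0.02, "pvalue": 0.1, "eaf": 0.2},
            {"variant_id": "rs3", "effect_allele": "A", "other_allele": "C",
             "beta": 0.07, "se": 0.02, "pvalue": 0.2, "eaf": 0.2},
        ])
        return exp, out

    def test_idempotent_on_harmonized_output(self):
        exp, out = self._multi()
        h1 = harmonize(exp, out)
        # rebuild an outcome table from the harmonized set and re-harmonize
        out2 = _stats([
            {"variant_id": r.variant_id, "effect_allele": r.effect_allele,
             "other_allele": r.other_allele, "beta": r.beta_out,
             "se": r.se_out, "pvalue": 0.05, "eaf": 0.2}
            for r in h1.table.itertuples()
        ])
        h2 = harmonize(exp, out2)
        np.testing.assert_array_equal(
            h1.table["beta_out"].to_numpy(), h2.table["beta_out"].to_numpy()
        )
        assert not h2.table["flipped"].any()

    def test_flipping_all_outcome_records_is_invisible(self):
        exp, out = self._multi()
        h1 = harmonize(exp, out)
        flipped = out.copy()
        flipped["effect_allele"], flipped["other_allele"] = (
            out["other_allele"],
            out["effect_allele"],
        )
        flipped["beta"] = -out["beta"]
        flipped["eaf"] = 1.0 - out["eaf"]
        h2 = harmonize(exp, flipped)
        for col in ("beta_out", "se_out", "beta_exp"):
            np.testing.assert_array_equal(
                h1.table[col].to_numpy(), h2.table[col].to_numpy()
            )


class TestSteiger:
    def test_strong_exposure_snp_retained(self):
        # t_exp = 10, t_out = 1 at equal n: clearly forward
        h = make_hset([0.10], [0.01], [0.002], [0.002],
                      n_exp=100_000, n_out=100_000)
        kept, rep = steiger_filter(h)
        assert kept.k == 1
        assert bool(rep["direction_forward"].iloc[0])

    def test_equal_r2_tie_is_removed_in_direction_only_mode(self):
        h = make_hset([0.10, 0.05], [0.01, 0.005], [0.10, 0.001],
                      [0.01, 0.0005], n_exp=50_000, n_out=50_000)
        kept, rep = steiger_filter(h)
        assert not bool(rep["direction_forward"].iloc[0])
        assert bool(rep["removed"].iloc[0])
        assert kept.k == 1

    def test_significant_mode_keeps_nonsignificant_reversals(self):
        # marginal reversal: r2_out barely above r2_exp, steiger p large
        h = make_hset([0.100, 0.05], [0.01, 0.005], [0.101, 0.001],
                      [0.01, 0.0005], n_exp=5_000, n_out=5_000)
        cfg_sig = InstrumentSelectionConfig(steiger_mode="significant")
        kept, rep = steiger_filter(h, cfg_sig)
        assert kept.k == 2  # reversal not significant, retained
        kept2, _ = steiger_filter(h)
        assert kept2.k == 1  # direction_only removes it

    def test_small_sample_size_raises(self):
        h = make_hset([0.1], [0.01], [0.01], [0.01], n_exp=3, n_out=100)
        with pytest.raises(SampleSizeError):
            steiger_filter(h)

    def test_r2_invariant_to_beta_sign_and_monotone_in_t(self):
        h_pos = make_hset([0.1, 0.2], [0.01, 0.01], [0.01, 0.01],
                          [0.01, 0.01])
        h_neg = make_hset([-0.1, -0.2], [0.01, 0.01], [0.01, 0.01],
                          [0.01, 0.01])
        _, rep_pos = steiger_filter(h_pos)
        _, rep_neg = steiger_filter(h_neg)
        np.testing.assert_allclose(rep_pos["r2_exp"], rep_neg["r2_exp"])
        # |t| = 10 vs 20 at equal n: r2 strictly increases
        assert rep_pos["r2_exp"].iloc[1] > rep_pos["r2_exp"].iloc[0]


class TestFStatistics:
    def test_closed_form_value(self):
        assert f_statistic(0.5, 102, 1) == pytest.approx(100.0)

    def test_zero_r2_gives_zero_f(self):
        assert f_statistic(0.0, 1000, 5) == 0.0

    def test_consortium_scale_example(self):
        # R2=0.01 across k=10 instruments at a 173,082-sample lipid GWAS
        assert f_statistic(0.01, 173_082, 10) == pytest.approx(
            0.01 * 173_071 / (0.99 * 10), rel=1e-12
        )
        assert f_statistic(0.01, 173_082, 10) == pytest.approx(174.82, abs=0.5)

    @given(
        r2=st.floats(0.001, 0.6),
        n=st.integers(100, 10**6),
        k=st.integers(1, 50),
    )
    def test_monotonicity(self, r2, n, k):
        f = f_statistic(r2, n, k)
        assert f >= 0
        assert f_statistic(min(r2 * 1.5, 0.99), n, k) >= f
        assert f_statistic(r2, n, k + 1) <= f

    def test_report_from_harmonized_set(self):
        h = make_hset([0.1, 0.2], [0.01, 0.01], [0.01, 0.02], [0.01, 0.01],
                      n_exp=102)
        rep = compute_f_statistics(h)
        assert rep.k == 2
        assert rep.n == 102
        assert 0 <= rep.overall_r2 < 1
        # per-SNP F uses k=1: f = r2 (n-2) / (1-r2)
        r2 = rep.per_snp["r2_explained"].to_numpy()
        np.testing.assert_allclose(
            rep.per_snp["f_stat"], r2 * 100 / (1 - r2), rtol=1e-12
        )
        assert not rep.weak_flag

    def test_weak_flag_set_for_tiny_r2(self):
        h = make_hset([0.001, 0.001], [0.01, 0.01], [0.0, 0.0], [0.01, 0.01],
                      n_exp=1000)
        rep = compute_f_statistics(h)
        assert rep.weak_flag

    def test_degenerate_design_rejected(self):
        h = make_hset([0.1, 0.2, 0.3], [0.01] * 3, [0.0] * 3, [0.01] * 3,
                      n_exp=4)
        with pytest.raises(Exception, match="degenerate"):
            compute_f_statistics(h)
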