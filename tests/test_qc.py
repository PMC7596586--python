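"""Quality-control filters: call rates, discordance, batch, HWE, IBD, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import mhcfinemap as mfm
from mhcfinemap.data import ConfigurationError, DosageMatrix
from mhcfinemap.qc import (
    QCThresholds,
    filter_hwe,
    filter_maf,
    filter_variant_metadata,
    hard_genotypes,
    ld_prune,
    relatedness_filter,
)
from mhcfinemap.simulate import simulate_array_genotypes, simulate_related_pair


def hwe_oracle_recurrence(n0, n1, n2):
    """Independent mode-anchored recurrence for the exact HWE distribution.

    Builds the conditional heterozygote-count distribution from the ratio
    P(h+2)/P(h) = 4 n_AA n_aa / ((h+2)(h+1)) outward from the mode, then
    sums the mass of outcomes no more probable than the observed.
    """
    n = n0 + n1 + n2
    na = 2 * n0 + n1
    nb = 2 * n - na
    h_min, h_max = na % 2, min(na, nb)
    hs = list(range(h_min, h_max + 1, 2))
    mode = int(round(na * nb / (2.0 * n - 1.0)))
    if (mode - h_min) % 2:
        mode += 1
    mode = min(max(mode, h_min), h_max)
    probs = {mode: 1.0}
    h = mode
    while h + 2 <= h_max:
        naa, ncc = (na - h) // 2, (nb - h) // 2
        probs[h + 2] = probs[h] * 4.0 * naa * ncc / ((h + 2.0) * (h + 1.0))
        h += 2
    h = mode
    while h - 2 >= h_min:
        naa, ncc = (na - h) // 2 + 1, (nb - h) // 2 + 1
        probs[h - 2] = probs[h] * h * (h - 1.0) / (4.0 * naa * ncc)
        h -= 2
    total = sum(probs.values())
    p_obs = probs[n1]
    return min(sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total, 1.0)


class TestHWE:
    def test_modal_configuration_total_mass(self):
        # an observed het count at the mode accumulates the whole mass
        assert mfm.hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-9)

    def test_extreme_het_deficit_excluded(self):
        p = mfm.hwe_exact_test(50, 0, 50)
        assert p < 1e-6

    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    def test_matches_recurrence_oracle(self, n0, n1, n2):
        if n0 + n1 + n2 == 0:
            with pytest.raises(ValueError):
                mfm.hwe_exact_test(n0, n1, n2)
        else:
            assert mfm.hwe_exact_test(n0, n1, n2) == pytest.approx(
                hwe_oracle_recurrence(n0, n1, n2), rel=1e-9)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            mfm.hwe_exact_test(0, 0, 0)

    def test_null_exclusion_rate_tiny(self):
        # null simulation: fraction excluded at 1e-6 should be <= 1e-5
        g, _ = simulate_array_genotypes(500, 10_000, 17)
        bad, _ = filter_hwe(g, QCThresholds())
        assert len(bad) / 10_000 <= 1e-5


class TestCallRateFilters:
    @pytest.fixture()
    def toy(self):
        idx = pd.Index([f"S{i}" for i in range(6)], name="sample_id")
        d = pd.DataFrame(np.ones((6, 10)), index=idx,
                         columns=[f"v{j}" for j in range(10)])
        cohorts = pd.Series(["BBJ", "BBJ", "Aichi1", "Aichi1", "Aichi2", "Aichi2"],
                            index=idx, name="cohort")
        return d, cohorts

    def test_sample_thresholds_applied_per_cohort(self, toy):
        d, cohorts = toy
        d.iloc[0, :1] = np.nan   # BBJ sample, call rate 0.9 < 0.99 -> excluded
        d.iloc[2, :4] = np.nan   # Aichi1 sample, call rate 0.6 < 0.95 -> excluded
        d.iloc[3, :0] = np.nan
        bad = mfm.filter_sample_call_rate(d, cohorts, QCThresholds())
        assert set(bad) == {"S0", "S2"}

    def test_boundary_rates_bbj_vs_aichi(self):
        # 0.985 fails BBJ's 0.99 floor; 0.96 passes Aichi1's 0.95 floor
        idx = pd.Index(["b", "a"], name="sample_id")
        n = 200
        d = pd.DataFrame(np.ones((2, n)), index=idx, columns=[f"v{j}" for j in range(n)])
        d.iloc[0, :3] = np.nan   # 197/200 = 0.985
        d.iloc[1, :8] = np.nan   # 192/200 = 0.96
        cohorts = pd.Series(["BBJ", "Aichi1"], index=idx)
        assert mfm.filter_sample_call_rate(d, cohorts, QCThresholds()) == ["b"]

    def test_complete_sample_always_retained(self, toy):
        d, cohorts = toy
        assert mfm.filter_sample_call_rate(d, cohorts, QCThresholds()) == []

    def test_variant_fails_in_any_cohort(self):
        idx = pd.Index([f"S{i}" for i in range(40)], name="sample_id")
        cohorts = pd.Series(["BBJ"] * 20 + ["Aichi2"] * 20, index=idx)
        d = pd.DataFrame(np.ones((40, 3)), index=idx, columns=["v0", "v1", "v2"])
        d.loc["S25":"S27", "v1"] = np.nan  # 17/20 = 0.85 in Aichi2 only
        bad = mfm.filter_variant_call_rate(d, cohorts, QCThresholds())
        assert bad == ["v1"]

    def test_unknown_cohort_raises(self, toy):
        d, cohorts = toy
        cohorts.iloc[0] = "Osaka"
        with pytest.raises(ConfigurationError, match="Osaka"):
            mfm.filter_sample_call_rate(d, cohorts, QCThresholds())

    def test_hand_enumerated_exclusions(self):
        idx = pd.Index([f"S{i}" for i in range(5)], name="sample_id")
        d = pd.DataFrame(np.ones((5, 4)), index=idx, columns=list("wxyz"))
        d.iloc[0, [0, 1]] = np.nan  # 0.5
        d.iloc[1, [0]] = np.nan     # 0.75
        d.iloc[4, :3] = np.nan      # 0.25
        cohorts = pd.Series(["Aichi1"] * 5, index=idx)
        th = QCThresholds(sample_call_rate_min={"Aichi1": 0.7})
        assert set(mfm.filter_sample_call_rate(d, cohorts, th)) == {"S0", "S4"}


class TestFreqDiscordance:
    def _frame(self, freqs_by_cohort, n=200):
        frames, labels = [], []
        for name, f in freqs_by_cohort.items():
            rng = np.random.default_rng(abs(hash(name)) % 2**31)
            g = rng.binomial(2, f, size=(n, len(f))).astype(float)
            frames.append(pd.DataFrame(g, columns=[f"v{j}" for j in range(len(f))]))
            labels += [name] * n
        d = pd.concat(frames, ignore_index=True)
        d.index = pd.Index([f"S{i}" for i in range(len(d))], name="sample_id")
        return d, pd.Series(labels, index=d.index)

    def test_pairwise_excess_excluded(self):
        # exact frequencies, not sampled: |0.35 - 0.10| = 0.25 > 0.20
        idx = pd.Index([f"S{i}" for i in range(30)], name="sample_id")
        vals = np.concatenate([np.repeat(0.2, 10), np.repeat(0.7, 10), np.repeat(0.24, 10)])
        d = pd.DataFrame({"v0": vals}, index=idx)
        cohorts = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10, index=idx)
        bad = mfm.filter_freq_discordance(d, cohorts, QCThresholds())
        assert bad == ["v0"]

    def test_identical_frequencies_retained(self):
        idx = pd.Index([f"S{i}" for i in range(20)], name="sample_id")
        d = pd.DataFrame({"v0": np.repeat(0.5, 20)}, index=idx)
        cohorts = pd.Series(["A"] * 10 + ["B"] * 10, index=idx)
        assert mfm.filter_freq_discordance(d, cohorts, QCThresholds()) == []

    def test_matches_brute_force_all_pairs(self):
        d, cohorts = self._frame({"A": [0.1, 0.3, 0.45], "B": [0.12, 0.31, 0.2],
                                  "C": [0.4, 0.29, 0.44]}, n=400)
        got = set(mfm.filter_freq_discordance(d, cohorts, QCThresholds()))
        expected = set()
        for v in d.columns:
            fs = [d.loc[cohorts == c, v].mean() / 2 for c in ["A", "B", "C"]]
            if max(abs(a - b) for a in fs for b in fs) > 0.20:
                expected.add(v)
        assert got == expected

    def test_single_cohort_raises(self):
        idx = pd.Index(["S0", "S1"], name="sample_id")
        d = pd.DataFrame({"v0": [1.0, 0.0]}, index=idx)
        with pytest.raises(ConfigurationError):
            mfm.filter_freq_discordance(d, pd.Series(["A", "A"], index=idx), QCThresholds())


class TestCaseBatchAssociation:
    def test_null_variant_retained(self):
        rng = np.random.default_rng(21)
        idx = pd.Index([f"S{i}" for i in range(400)], name="sample_id")
        d = pd.DataFrame({"v0": rng.binomial(2, 0.3, 400).astype(float)}, index=idx)
        labels = pd.Series(["X"] * 200 + ["Y"] * 200, index=idx)
        assert mfm.filter_case_batch_association(d, labels, QCThresholds()) == []

    def test_gross_frequency_split_excluded(self):
        # 0.05 vs 0.60 at n=200 per data set: chi-square p far below 1e-7
        rng = np.random.default_rng(22)
        idx = pd.Index([f"S{i}" for i in range(400)], name="sample_id")
        v = np.concatenate([rng.binomial(2, 0.05, 200), rng.binomial(2, 0.60, 200)])
        d = pd.DataFrame({"v0": v.astype(float)}, index=idx)
        labels = pd.Series(["X"] * 200 + ["Y"] * 200, index=idx)
        assert mfm.filter_case_batch_association(d, labels, QCThresholds()) == ["v0"]

    def test_single_dataset_noop_logged(self):
        idx = pd.Index(["S0", "S1"], name="sample_id")
        d = pd.DataFrame({"v0": [1.0, 0.0]}, index=idx)
        log = []
        out = mfm.filter_case_batch_association(
            d, pd.Series(["X", "X"], index=idx), QCThresholds(), log)
        assert out == [] and any("no-op" in line for line in log)


class TestMetadataFilters:
    def test_indels_and_duplicates(self):
        info = pd.DataFrame({
            "chrom": ["6"] * 4, "pos": [100, 200, 200, 300],
            "ref": ["A", "AT", "C", "G"], "alt": ["T", "A", "G", "GC"],
        }, index=["a", "b", "c", "d"])
        indels, dups = filter_variant_metadata(info)
        assert indels == ["b", "d"]
        assert dups == ["c"]  # first occurrence at pos 200 kept

    def test_duplicate_check_skips_hla_markers_at_gene_position(self):
        # derived HLA markers share the gene coordinate by design; only
        # SNVs at the same (chrom, pos) are duplicates
        info = pd.DataFrame({
            "chrom": ["6"] * 5, "pos": [31_323_000] * 4 + [100],
            "category": ["HLA_4D", "HLA_4D", "AA_residue", "SNV", "SNV"],
        }, index=["B*52:01", "B*15:01", "HLA-B_171_H", "s1", "s2"])
        indels, dups = filter_variant_metadata(info)
        assert indels == [] and dups == []
        info.loc["s3"] = ["6", 100, "SNV"]
        _, dups = filter_variant_metadata(info)
        assert dups == ["s3"]


@pytest.fixture(scope="module")
def freqs():
    return np.random.default_rng(30).uniform(0.1, 0.5, 5000)


class TestPiHat:
    def test_duplicate_pair_near_one(self, freqs):
        g1, g2 = simulate_related_pair(freqs[:1500], 2, 31)
        assert mfm.pi_hat(g1, g2, freqs[:1500], min_overlap=500) > 0.99

    def test_unrelated_pair_near_zero(self, freqs):
        g1, g2 = simulate_related_pair(freqs, 0, 32)
        assert abs(mfm.pi_hat(g1, g2, freqs, min_overlap=500)) < 0.05

    def test_parent_offspring_near_half_and_excluded(self, freqs):
        g1, g2 = simulate_related_pair(freqs, 1, 33)
        ph = mfm.pi_hat(g1, g2, freqs, min_overlap=500)
        assert ph == pytest.approx(0.5, abs=0.05)
        geno = pd.DataFrame([g1, g2], index=pd.Index(["child", "parent"]))
        out = relatedness_filter(geno, freqs, QCThresholds())
        assert len(out) == 1  # one member of the pair removed at 0.125

    def test_insufficient_overlap_skipped(self, freqs):
        g1, g2 = simulate_related_pair(freqs[:100], 2, 34)
        assert np.isnan(mfm.pi_hat(g1, g2, freqs[:100], min_overlap=500))

    def test_lower_call_rate_member_excluded(self, freqs):
        g1, g2 = simulate_related_pair(freqs[:1000], 2, 35)
        g1 = g1.copy()
        g1[:50] = np.nan
        geno = pd.DataFrame([g1, g2], index=pd.Index(["low", "high"]))
        assert relatedness_filter(geno, freqs[:1000], QCThresholds()) == ["low"]


class TestPCA:
    def test_homogeneous_population_no_outliers(self):
        g, _ = simulate_array_genotypes(800, 300, 40)
        pos = pd.Series(np.arange(300) * 1000, index=g.columns)
        res = mfm.pca_outliers(g, pos, QCThresholds())
        assert res.outliers == []

    def test_spiked_divergent_samples_flagged(self):
        rng = np.random.default_rng(41)
        n_var = 400
        freqs = rng.uniform(0.1, 0.5, n_var)
        main = rng.binomial(2, freqs, size=(2000, n_var)).astype(float)
        shifted = np.clip(freqs + rng.choice([-0.35, 0.35], n_var), 0.02, 0.98)
        outl = rng.binomial(2, shifted, size=(5, n_var)).astype(float)
        g = pd.DataFrame(np.vstack([main, outl]),
                         index=pd.Index([f"S{i}" for i in range(2005)], name="sample_id"),
                         columns=[f"v{j}" for j in range(n_var)])
        pos = pd.Series(np.arange(n_var) * 1000, index=g.columns)
        res = mfm.pca_outliers(g, pos, QCThresholds())
        assert set(res.outliers) == {f"S{i}" for i in range(2000, 2005)}

    def test_recomputed_scores_change_schema_stable(self):
        rng = np.random.default_rng(42)
        n_var = 200
        freqs = rng.uniform(0.1, 0.5, n_var)
        main = rng.binomial(2, freqs, size=(500, n_var)).astype(float)
        outl = rng.binomial(2, np.clip(freqs + 0.4, 0, 0.98), size=(4, n_var)).astype(float)
        g = pd.DataFrame(np.vstack([main, outl]),
                         index=pd.Index([f"S{i}" for i in range(504)], name="sample_id"),
                         columns=[f"v{j}" for j in range(n_var)])
        pos = pd.Series(np.arange(n_var) * 1000, index=g.columns)
        res = mfm.pca_outliers(g, pos, QCThresholds())
        assert list(res.scores_final.columns) == list(res.scores_initial.columns)
        assert len(res.scores_final) == 504 - len(res.outliers)
        survivors = res.scores_final.index
        assert not np.allclose(res.scores_final.abs().to_numpy(),
                               res.scores_initial.loc[survivors].abs().to_numpy())

    def test_too_few_samples_raises(self):
        g, _ = simulate_array_genotypes(8, 50, 43)
        pos = pd.Series(np.arange(50) * 1000, index=g.columns)
        with pytest.raises(ValueError):
            mfm.pca_outliers(g, pos, QCThresholds())

    def test_ld_prune_respects_cap(self):
        g, _ = simulate_array_genotypes(500, 30, 44)
        g["v_dup"] = g["arr00000"]  # perfect LD with the first variant
        pos = pd.Series(np.r_[np.arange(30) * 1000, 50], index=g.columns)
        kept = ld_prune(g, pos, 0.2)
        assert ("arr00000" in kept) ^ ("v_dup" in kept)


@pytest.fixture(scope="module")
def dirty():
    rng = np.random.default_rng(50)
    n, n_var = 300, 60
    g, _ = simulate_array_genotypes(n, n_var, 51)
    # plant a rare variant (fails MAF) and an HWE-violating variant
    g["v_rare"] = rng.binomial(2, 0.002, n).astype(float)
    g["v_hwe"] = np.repeat([0.0, 2.0], n // 2)
    info = pd.DataFrame({
        "chrom": "6", "pos": np.arange(len(g.columns)) * 2000 + 25_000_000,
        "category": "SNV", "gene": "", "aa_pos": np.nan, "residue": "",
        "est_r2": np.nan, "ref": "A", "alt": "T",
    }, index=g.columns)
    dm = DosageMatrix(g, info)
    cohort = pd.DataFrame({
        "status": rng.integers(0, 2, n),
        "age": 50.0, "bmi": 22.0,
        "cohort": rng.choice(["BBJ", "Aichi1"], n),
    }, index=g.index)
    return dm, cohort


class TestRunQC:
    def test_planted_failures_caught_with_reasons(self, dirty):
        dm, cohort = dirty
        clean, report = mfm.run_qc(dm, cohort)
        assert report.excluded_variants.get("v_rare") == "maf"
        assert report.excluded_variants.get("v_hwe") in ("hwe", "freq_discordance")
        assert "v_rare" not in clean.variant_ids

    def test_idempotent_on_own_output(self, dirty):
        dm, cohort = dirty
        clean, _ = mfm.run_qc(dm, cohort)
        clean2, report2 = mfm.run_qc(clean, cohort.loc[clean.sample_ids])
        assert list(clean2.sample_ids) == list(clean.sample_ids)
        assert list(clean2.variant_ids) == list(clean.variant_ids)

    def test_counts_reconcile(self, dirty):
        dm, cohort = dirty
        clean, report = mfm.run_qc(dm, cohort)
        assert len(dm.sample_ids) - len(report.excluded_samples) == len(clean.sample_ids)
        assert len(dm.variant_ids) - len(report.excluded_variants) == len(clean.variant_ids)
        assert sum(report.counts.values()) == (
            len(report.excluded_samples) + len(report.excluded_variants))
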