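import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ampfp.benchmark import (
    EvaluationResult,
    bray_curtis_per_sample,
    build_gold_standard,
    compare_databases,
    evaluate_predictions,
    match_taxa_to_heldout,
    parse_taxonomy,
    spearman_per_sample,
)
from ampfp.metagenome import run_prediction


def s(values, ids=None):
    ids = ids or [f"K{i}" for i in range(len(values))]
    return pd.Series(values, index=ids, dtype=float)


class TestSpearman:
    def test_identity_with_ties(self):
        v = s([1, 2, 2, 5, 0])
        assert spearman_per_sample(v, v.copy()) == pytest.approx(1.0)

    def test_anti_rank(self):
        assert spearman_per_sample(s([1, 2, 3, 4]), s([4, 3, 2, 1])) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(25):
            a = s(rng.integers(0, 6, 10).astype(float))  # ints force ties
            b = s(rng.integers(0, 6, 10).astype(float))
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            rho = spearman_per_sample(a, b)
            oracle = np.corrcoef(stats.rankdata(a), stats.rankdata(b))[0, 1]
            assert rho == pytest.approx(oracle, rel=1e-12)

    def test_zero_variance_warns_nan(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            out = spearman_per_sample(s([1, 1, 1]), s([1, 2, 3]))
        assert np.isnan(out)

    def test_union_of_ids_with_zeros(self):
        pred = s([1, 2], ids=["K1", "K2"])
        gold = s([1, 2], ids=["K2", "K3"])
        # union {K1,K2,K3}: pred (1,2,0), gold (0,1,2)
        oracle = stats.spearmanr([1, 2, 0], [0, 1, 2]).statistic
        assert spearman_per_sample(pred, gold) == pytest.approx(oracle)


class TestBrayCurtis:
    def test_identity_zero(self):
        v = s([1, 2, 3])
        assert bray_curtis_per_sample(v, v.copy()) == 0.0

    def test_disjoint_supports_one(self):
        pred = s([1, 0, 2], ids=list("abc"))
        gold = s([0, 5, 0], ids=list("abc"))
        assert bray_curtis_per_sample(pred, gold) == 1.0

    def test_hand_example_one_third(self):
        assert bray_curtis_per_sample(s([1, 2, 3]), s([3, 2, 1])) == pytest.approx(1 / 3)

    def test_matches_scipy_oracle(self, rng):
        from scipy.spatial.distance import braycurtis
        for _ in range(25):
            a, b = rng.uniform(0, 10, 8), rng.uniform(0, 10, 8)
            assert bray_curtis_per_sample(s(a), s(b)) == pytest.approx(braycurtis(a, b))

    def test_common_rescale_invariance(self, rng):
        a, b = s(rng.uniform(0, 5, 6)), s(rng.uniform(0, 5, 6))
        assert bray_curtis_per_sample(a * 7, b * 7) == pytest.approx(
            bray_curtis_per_sample(a, b)
        )

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            assert np.isnan(bray_curtis_per_sample(s([0, 0]), s([0, 0])))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis_per_sample(s([-1, 2]), s([1, 2]))


class TestGoldStandard:
    def test_single_genome_hand_arithmetic(self):
        abundances = pd.DataFrame({"s1": [2.0]}, index=["g1"])
        ann = pd.DataFrame({"K1": [5.0]}, index=["g1"])
        gold = build_gold_standard(abundances, ann, pd.Series({"g1": 1.0}))
        assert gold.loc["s1", "K1"] == 10.0

    def test_identical_samples_identical_rows(self, rng):
        abundances = pd.DataFrame({"s1": [2.0, 3.0], "s2": [2.0, 3.0]}, index=["g1", "g2"])
        ann = pd.DataFrame(rng.uniform(0, 5, (2, 4)), index=["g1", "g2"],
                           columns=[f"K{i}" for i in range(4)])
        copies = pd.Series({"g1": 2.0, "g2": 3.0})
        gold = build_gold_standard(abundances, ann, copies)
        pd.testing.assert_series_equal(gold.loc["s1"], gold.loc["s2"], check_names=False)

    def test_matches_triple_loop_oracle(self, rng):
        genomes = [f"g{i}" for i in range(4)]
        abundances = pd.DataFrame(rng.uniform(0, 10, (4, 3)), index=genomes,
                                  columns=["s1", "s2", "s3"])
        ann = pd.DataFrame(rng.uniform(0, 4, (4, 5)), index=genomes,
                           columns=[f"K{i}" for i in range(5)])
        copies = pd.Series(rng.uniform(1, 6, 4), index=genomes)
        gold = build_gold_standard(abundances, ann, copies)
        for smp in abundances.columns:
            for f in ann.columns:
                oracle = sum(abundances.loc[g, smp] / copies[g] * ann.loc[g, f]
                             for g in genomes)
                assert gold.loc[smp, f] == pytest.approx(oracle, rel=1e-12)

    def test_no_normalize_switch(self):
        abundances = pd.DataFrame({"s1": [2.0]}, index=["g1"])
        ann = pd.DataFrame({"K1": [5.0]}, index=["g1"])
        gold = build_gold_standard(abundances, ann, pd.Series({"g1": 4.0}),
                                   normalize_by_copies=False)
        assert gold.loc["s1", "K1"] == 10.0

    def test_coverage_gap_errors(self):
        abundances = pd.DataFrame({"s1": [2.0]}, index=["g1"])
        with pytest.raises(KeyError, match="g1"):
            build_gold_standard(abundances, pd.DataFrame(), pd.Series(dtype=float))


class TestMatchTaxa:
    POOL = pd.Series({
        "g1": "d__Bacteria;p__P;c__C;o__O;f__F;g__GenA;s__SpA",
        "g2": "d__Bacteria;p__P;c__C;o__O;f__F;g__GenA;s__SpB",
        "g3": "d__Archaea;p__Q;c__D;o__N;f__E;g__GenB;s__SpC",
    })

    def test_exact_species_matches_full_retention(self):
        profile = pd.DataFrame(
            {"s1": [5.0, 3.0]},
            index=["d__Bacteria;p__P;c__C;o__O;f__F;g__GenA;s__SpA",
                   "d__Archaea;p__Q;c__D;o__N;f__E;g__GenB;s__SpC"],
        )
        abund, report = match_taxa_to_heldout(profile, self.POOL)
        assert report["retained_abundance_fraction"] == 1.0
        assert abund.loc["g1", "s1"] == 5.0 and abund.loc["g3", "s1"] == 3.0

    def test_genus_tie_lexicographic(self):
        profile = pd.DataFrame({"s1": [4.0]},
                               index=["d__Bacteria;p__P;c__C;o__O;f__F;g__GenA;s__SpZ"])
        abund, report = match_taxa_to_heldout(profile, self.POOL)
        # SpZ matches no species; genus GenA matches g1 and g2 -> g1 wins
        assert list(abund.index) == ["g1"]

    def test_retained_fraction_bookkeeping(self):
        profile = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0, 4.0, 5.0]},
            index=["d__Bacteria;p__P;c__C;o__O;f__F;g__GenA;s__SpA",
                   "d__Bacteria;p__P;c__C;o__O;f__F;g__GenA;s__SpB",
                   "d__Archaea;p__Q;c__D;o__N;f__E;g__GenB;s__SpC",
                   "d__Eukaryota;p__Z;c__Z;o__Z;f__Z;g__Z;s__Z",
                   "d__Eukaryota;p__Y;c__Y;o__Y;f__Y;g__Y;s__Y"],
        )
        abund, report = match_taxa_to_heldout(profile, self.POOL, min_retained_fraction=0.3)
        assert report["retained_abundance_fraction"] == pytest.approx(6.0 / 15.0)
        assert report["n_matched"] == 3

    def test_low_retention_strict_raises(self):
        profile = pd.DataFrame({"s1": [10.0]},
                               index=["d__Eukaryota;p__Z;c__Z;o__Z;f__Z;g__Z;s__Z"])
        with pytest.raises(ValueError, match="matched"):
            match_taxa_to_heldout(profile, self.POOL, strict=True)

    def test_parse_taxonomy(self):
        tax = parse_taxonomy("d__Bacteria;p__P;s__Sp")
        assert tax == {"domain": "Bacteria", "phylum": "P", "species": "Sp"}


class TestCompareDatabases:
    def _eval(self, rho, bc, nsti, label=""):
        n = len(rho)
        df = pd.DataFrame({"spearman_rho": rho, "bray_curtis": bc, "weighted_nsti": nsti},
                          index=[f"s{i}" for i in range(n)])
        return EvaluationResult(per_sample=df, label=label)

    def test_null_comparison(self, rng):
        ev = self._eval(rng.uniform(0.5, 1, 10), rng.uniform(0, 0.5, 10),
                        rng.uniform(0, 0.3, 10))
        report = compare_databases(ev, ev)
        for metric in report["metrics"].values():
            assert metric["p_value"] == 1.0
            assert metric["significant"] is False
            assert metric["median_difference"] == 0.0

    def test_shift_with_noise_significant(self, rng):
        base = rng.uniform(0.5, 0.8, 20)
        noise = rng.normal(0, 0.01, 20)
        ev_a = self._eval(base + 0.1 + noise, np.full(20, 0.3), np.full(20, 0.1), "a")
        ev_b = self._eval(base, np.full(20, 0.3), np.full(20, 0.1), "b")
        report = compare_databases(ev_a, ev_b)
        m = report["metrics"]["spearman_rho"]
        assert m["significant"] is True
        # independent paired-t oracle from the closed form
        d = (base + 0.1 + noise) - base
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_oracle = 2 * stats.t.sf(abs(t_stat), df=len(d) - 1)
        assert m["p_value"] == pytest.approx(p_oracle, rel=1e-9)

    def test_median_matches_sort_oracle(self, rng):
        vals = rng.uniform(0, 1, 11)
        ev = self._eval(vals, vals, vals)
        report = compare_databases(ev, ev)
        oracle = np.sort(vals)[5]
        assert report["metrics"]["spearman_rho"]["median_a"] == pytest.approx(oracle)

    def test_sample_mismatch_listed(self):
        ev_a = self._eval([0.5] * 3, [0.1] * 3, [0.1] * 3)
        ev_b = self._eval([0.5] * 4, [0.1] * 4, [0.1] * 4)
        with pytest.raises(ValueError, match="s3"):
            compare_databases(ev_a, ev_b)


class TestEndToEndConsistency:
    def test_exact_tip_queries_reproduce_gold(self, tips_world):
        res = run_prediction(tips_world.database, tips_world.query_seqs,
                             tips_world.feature_table, frameworks=["KO"])
        mm = res.metagenomes["KO"]
        gold = tips_world.mock.gold_standard["KO"]
        ev = evaluate_predictions(mm.data, gold, weighted_nsti=mm.weighted_nsti)
        assert (ev.per_sample["spearman_rho"] == 1.0).all()
        assert (ev.per_sample["bray_curtis"] == 0.0).all()
        assert (ev.per_sample["weighted_nsti"] == 0.0).all()

    def test_heldout_property_enforced(self, small_world):
        ref_tips = {t for ref in small_world.database.domains.values() for t in ref.tip_ids}
        small_world.mock.assert_heldout(ref_tips)
        with pytest.raises(ValueError, match="present in the reference"):
            small_world.mock.assert_heldout(set(small_world.mock.genome_ids))

    def test_degradation_with_divergence(self, small_world):
        from ampfp.synth import diverge_heldout
        medians = []
        for i, depth in enumerate([0.0, 0.2, 0.5]):
            seqs, gold, table = diverge_heldout(small_world, depth, seed=7 + i)
            res = run_prediction(small_world.database, seqs, table, frameworks=["KO"])
            mm = res.metagenomes["KO"]
            ev = evaluate_predictions(mm.data, gold, weighted_nsti=mm.weighted_nsti)
            medians.append(ev.per_sample.median())
        nstis = [m["weighted_nsti"] for m in medians]
        rhos = [m["spearman_rho"] for m in medians]
        assert nstis[0] < nstis[1] < nstis[2]
        assert rhos[0] > rhos[1] > rhos[2]
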