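"""k-mer association scoring, thresholds, projection, binning and regions."""

import numpy as np
import pandas as pd
import pytest

from tefpop.gwas import (associate_kmers, associate_snps, bin_index,
                         bin_scores, call_regions, kmer_threshold, map_kmers,
                         snp_threshold)
from tefpop.kmers import KmerMatrix, extract_canonical_kmers

from conftest import make_geno
from oracles import brute_force_regions, random_bin_layout


class TestThresholds:
    def test_length_adjusted_bonferroni_published_scale(self):
        thr = kmer_threshold(187_226_135, 51)
        assert thr == pytest.approx(1.36e-8, abs=0.005e-8)
        assert round(-np.log10(thr), 2) == 7.87

    def test_kmer_threshold_formula(self):
        assert kmer_threshold(100, 1) == pytest.approx(5e-4)
        assert kmer_threshold(51, 51) == pytest.approx(0.05)

    def test_product_identity_exact(self):
        for n, k in [(1000, 31), (187_226_135, 51), (7, 7)]:
            assert kmer_threshold(n, k) * (n / k) == pytest.approx(0.05,
                                                                   rel=1e-12)

    def test_snp_threshold(self):
        assert snp_threshold(49_660) == pytest.approx(1.01e-6, abs=0.005e-6)
        assert snp_threshold(1) == 0.05
        assert snp_threshold(500) == pytest.approx(1e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            kmer_threshold(0, 51)
        with pytest.raises(ValueError):
            snp_threshold(0)


def tiny_matrix(states, ids=None):
    states = np.asarray(states, dtype=bool)
    ids = ids or [f"a{i}" for i in range(states.shape[0])]
    kmers = [f"{'ACGTT'[j % 5] * 5}"[:5] for j in range(states.shape[1])]
    kmers = [f"KM{j:03d}" for j in range(states.shape[1])]
    return KmerMatrix(ids, kmers, states, 5, 1)


class TestAssociateKmers:
    def test_closed_form_ols_example(self):
        m = tiny_matrix([[0], [0], [1], [1]])
        pheno = pd.Series([1.0, 2.0, 3.0, 4.0], index=m.ids)
        res = associate_kmers(m, pheno, min_class=2)
        assert res.tested[0]
        assert res.direction[0] == 1
        # slope 2, t = 2.83 on 2 df
        from scipy import stats

        t = 2.0 / np.sqrt(0.5 / 1.0)
        assert t == pytest.approx(2.828, abs=0.001)
        expect_score = -np.log10(2 * stats.t.sf(t, 2))
        assert res.score[0] == pytest.approx(expect_score, abs=1e-9)

    def test_ubiquitous_kmer_untested(self):
        m = tiny_matrix([[1], [1], [1], [1]])
        res = associate_kmers(m, pd.Series([1, 2, 3, 4.0], index=m.ids),
                              min_class=1)
        assert not res.tested[0]
        assert res.n_tested == 0

    def test_min_class_rule(self):
        m = tiny_matrix([[1], [0], [0], [0], [0], [0], [0], [0], [0], [0]])
        pheno = pd.Series(np.arange(10.0), index=m.ids)
        assert associate_kmers(m, pheno, min_class=5).n_tested == 0
        assert associate_kmers(m, pheno, min_class=1).n_tested == 1

    def test_constant_phenotype_rejected(self):
        m = tiny_matrix([[0], [1], [0], [1]])
        with pytest.raises(ValueError, match="constant"):
            associate_kmers(m, pd.Series([1.0] * 4, index=m.ids))

    def test_missing_phenotype_rejected(self):
        m = tiny_matrix([[0], [1], [0], [1]])
        with pytest.raises(ValueError, match="undefined"):
            associate_kmers(m, pd.Series([1.0], index=[m.ids[0]]))

    def test_perfect_separation_capped_and_flagged(self):
        m = tiny_matrix([[0], [0], [0], [1], [1], [1]])
        pheno = pd.Series([0, 0, 0, 5, 5, 5.0], index=m.ids)
        res = associate_kmers(m, pheno, min_class=3, score_cap=50.0)
        assert res.capped[0]
        assert res.score[0] == 50.0

    def test_permuted_phenotype_controls_type_i(self):
        # independent columns: plain Bonferroni (k-mer length adjustment
        # presumes overlapping, correlated k-mers)
        rng = np.random.default_rng(0)
        states = rng.random((30, 4000)) < 0.5
        m = KmerMatrix([f"a{i}" for i in range(30)],
                       [f"K{j}" for j in range(4000)], states, 31, 1)
        pheno = pd.Series(rng.normal(size=30), index=m.ids)
        res = associate_kmers(m, pheno, min_class=5)
        thr = -np.log10(snp_threshold(res.n_tested))
        assert (res.score[res.tested] >= thr).sum() == 0


class TestAssociateSnps:
    def test_dosage_regression_recovers_signal(self):
        rng = np.random.default_rng(1)
        n = 40
        causal = rng.choice([0, 2], size=n)
        calls = rng.choice([0, 2], size=(20, n))
        calls[7] = causal
        g = make_geno(calls.tolist())
        pheno = pd.Series(causal * 2.0 + rng.normal(0, 0.5, n),
                          index=g.samples)
        out = associate_snps(g, pheno)
        assert out["score"].idxmax() == 7
        assert out.loc[7, "score"] > -np.log10(snp_threshold(20))


class TestMapKmers:
    def test_exact_position_and_reverse_strand(self, panel40):
        ref = panel40.reference
        window = ref["chr1"][25_000:25_051]  # 1-based 25,001..25,051
        canon = extract_canonical_kmers(window, 51).pop()
        mapped, unmapped = map_kmers(ref, [canon])
        assert unmapped == []
        assert ("chr1", 25_001) in mapped[canon]
        # the reverse complement of the window canonicalises identically,
        # so a k-mer observed only on the reverse strand maps to the same
        # forward-strand start
        from tefpop.kmers import reverse_complement

        rc_canon = extract_canonical_kmers(
            reverse_complement(window), 51).pop()
        assert rc_canon == canon

    def test_absent_kmer_unmapped(self, panel40):
        fake = "A" * 51
        mapped, unmapped = map_kmers(panel40.reference, [fake])
        assert fake in unmapped or ("chr1", 1) in mapped.get(fake, [])


class TestBinning:
    def test_boundary_convention(self):
        assert bin_index(25_000) == 3
        assert bin_index(10_000) == 1
        assert bin_index(10_001) == 2
        assert bin_index(1) == 1

    def test_counts_by_level_and_direction(self):
        mapped = {"K1": [("c1", 25_000)], "K2": [("c1", 25_500)],
                  "K3": [("c1", 95_000)]}
        scores = {"K1": 8.2, "K2": 7.9, "K3": 9.0}
        dirs = {"K1": 1, "K2": 1, "K3": -1}
        out = bin_scores(mapped, scores, dirs)
        b3 = out[(out["bin_start"] == 20_001) & (out["level"] == 8)]
        assert b3["count"].sum() == 2
        assert set(out["bin_start"]) == {20_001, 90_001}

    def test_multi_mapping_and_first_match_only(self):
        mapped = {"K1": [("c1", 100), ("c1", 55_000)]}
        scores, dirs = {"K1": 8.0}, {"K1": 1}
        assert len(bin_scores(mapped, scores, dirs)) == 2
        assert len(bin_scores(mapped, scores, dirs,
                              first_match_only=True)) == 1

    def test_empty_input(self):
        assert bin_scores({}, {}, {}).empty


class TestCallRegions:
    def _bins(self, spec):
        return pd.DataFrame([
            {"chrom": c, "bin_start": s, "bin_end": s + 9_999, "level": 8,
             "direction": d, "count": n} for c, s, n, d in spec])

    def test_no_significant_kmers_empty(self):
        assert call_regions(self._bins([])) == []

    def test_manual_gap_trace(self):
        # bins at 1.00 Mb (300) and 1.20 Mb (500): gap 190 kb < 500 kb
        bins = self._bins([("c1", 1_000_001, 300, 1),
                           ("c1", 1_200_001, 500, 1)])
        regions = call_regions(bins, gap_bp=500_000, min_kmers=750)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (1_000_001, 1_210_000)
        assert r.n_kmers == 800
        assert r.significant
        assert r.majority_direction == 1

    def test_min_kmers_contract(self):
        bins = self._bins([("c1", 1_000_001, 300, 1),
                           ("c1", 1_200_001, 500, 1)])
        regions = call_regions(bins, gap_bp=500_000, min_kmers=1000)
        assert len(regions) == 1
        assert not regions[0].significant

    def test_large_gap_splits_regions(self):
        bins = self._bins([("c1", 1, 100, 1), ("c1", 600_001, 100, -1)])
        regions = call_regions(bins, gap_bp=500_000, min_kmers=50)
        assert len(regions) == 2
        assert regions[1].majority_direction == -1

    def test_input_order_invariance_and_no_overlap(self):
        rng = np.random.default_rng(3)
        bins = random_bin_layout(rng)
        shuffled = bins.sample(frac=1.0, random_state=0)
        r1 = call_regions(bins, min_kmers=100)
        r2 = call_regions(shuffled, min_kmers=100)
        assert [vars(r) for r in r1] == [vars(r) for r in r2]
        by_chrom: dict = {}
        for r in r1:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            bins = random_bin_layout(rng)
            got = call_regions(bins, gap_bp=500_000, min_kmers=750)
            want = brute_force_regions(bins, gap_bp=500_000, min_kmers=750)
            assert [(r.chrom, r.start, r.end, r.n_kmers, r.significant)
                    for r in got] == \
                [(w["chrom"], w["start"], w["end"], w["n_kmers"],
                  w["significant"]) for w in want]
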