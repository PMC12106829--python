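"""Genotype I/O, site filters, LD pruning/decay, distances and NJ trees."""

import numpy as np
import pytest

from tefpop import genotypes as gt
from tefpop.genotypes import (HET, HOM_ALT, HOM_REF, MISSING, DistanceMatrix,
                              filter_sites, heterozygosity_rate, ld_decay,
                              ld_prune, nj_path_distances, p_distance,
                              read_vcf, site_maf, write_vcf)

from conftest import make_geno

VCF_3x2 = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB\tsC
chr1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tC\tT\t.\t.\t.\tGT\t./.\t0/0\t0/1
chr1\t300\t.\tG\tA,T\t.\t.\t.\tGT\t0/0\t0/1\t0/2
"""


class TestVcfIO:
    def test_handcrafted_records_transcribed(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(VCF_3x2)
        g = read_vcf(str(p))
        assert g.samples == ["sA", "sB", "sC"]
        assert g.n_sites == 2  # multiallelic row skipped
        assert g.n_skipped_records == 1
        expected = np.array([[HOM_REF, HET, HOM_ALT],
                             [MISSING, HOM_REF, HET]], dtype=np.int8)
        assert np.array_equal(g.calls, expected)

    def test_round_trip_preserves_calls_and_sites(self, tmp_path):
        rng = np.random.default_rng(0)
        calls = rng.choice([HOM_REF, HET, HOM_ALT, MISSING], size=(30, 5))
        g = make_geno(calls)
        out = tmp_path / "rt.vcf"
        write_vcf(g, str(out))
        g2 = read_vcf(str(out))
        assert g2.samples == g.samples
        assert np.array_equal(g2.calls, g.calls)
        assert g2.sites[["chrom", "pos", "ref", "alt"]].equals(
            g.sites[["chrom", "pos", "ref", "alt"]])

    def test_missing_gt_header_rejected(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("##fileformat=VCFv4.2\n"
                     "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        with pytest.raises(ValueError, match="GT"):
            read_vcf(str(p))


class TestFilterSites:
    def test_passing_site_retained_and_low_maf_removed(self):
        # 25 accessions: site 1 complete with MAF 0.20; site 2 MAF 0.02
        site_ok = [HOM_ALT] * 5 + [HOM_REF] * 20
        site_low = [HET] + [HOM_REF] * 24
        g = make_geno([site_ok, site_low])
        assert np.allclose(site_maf(g), [0.20, 0.02])
        kept = filter_sites(g)
        assert kept.n_sites == 1
        assert kept.sites["pos"].tolist() == [100]

    def test_maf_boundary_is_inclusive(self):
        # a single homozygous-ALT accession among 40: MAF exactly 0.025
        site = [HOM_ALT] + [HOM_REF] * 39
        g = make_geno([site])
        assert filter_sites(g).n_sites == 1

    def test_call_rate_below_90_percent_removed(self):
        site = [MISSING, MISSING] + [HOM_ALT] * 4 + [HOM_REF] * 4
        g = make_geno([site])
        assert filter_sites(g).n_sites == 0

    def test_idempotent(self, geno40):
        once = filter_sites(geno40)
        twice = filter_sites(once)
        assert np.array_equal(once.calls, twice.calls)

    def test_all_removed_warns(self):
        g = make_geno([[HET] + [HOM_REF] * 24])
        with pytest.warns(UserWarning, match="every site"):
            out = filter_sites(g)
        assert out.n_sites == 0


class TestLdPrune:
    def test_duplicated_column_pair_drops_one(self):
        col = [HOM_REF, HOM_REF, HET, HOM_ALT, HOM_ALT, HOM_REF]
        other = [HOM_ALT, HOM_REF, HOM_REF, HOM_REF, HOM_ALT, HET]
        g = make_geno(np.array([col, col, other]).tolist())
        pruned = ld_prune(g)
        assert pruned.n_sites == 2
        # equal MAF: the later position of the duplicated pair is dropped
        assert pruned.sites["pos"].tolist() == [100, 120]

    def test_independent_sites_untouched(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([HOM_REF, HOM_ALT], size=(10, 60))
        g = make_geno(calls.tolist())
        pruned = ld_prune(g)
        r2 = gt._pairwise_r2(pruned.dosage())
        np.fill_diagonal(r2, 0.0)
        assert (r2 <= 0.5).all()

    def test_hand_computed_r2_pair_designated_member_removed(self):
        # dosage columns A (MAF 0.4) and B (MAF 0.3): hand r^2
        A = [HOM_ALT] * 4 + [HOM_REF] * 6
        B = [HOM_ALT] * 3 + [HOM_REF] * 7
        a, b = np.array(A, float), np.array(B, float)
        sxy = (a * b).sum() - 10 * a.mean() * b.mean()
        r2_hand = sxy ** 2 / (((a ** 2).sum() - 10 * a.mean() ** 2)
                              * ((b ** 2).sum() - 10 * b.mean() ** 2))
        assert r2_hand == pytest.approx(0.643, abs=0.001)
        neutral = [HOM_REF, HOM_ALT] * 5
        g = make_geno([A, B, neutral])
        pruned = ld_prune(g)
        # B has the lower MAF, so B (pos 110) is removed
        assert pruned.sites["pos"].tolist() == [100, 120]

    def test_no_high_ld_pair_survives_full_rescan(self, geno40):
        sub = filter_sites(geno40)
        sub = sub.take_sites(np.arange(0, min(sub.n_sites, 400)))
        pruned = ld_prune(sub)
        pos = pruned.sites["pos"].to_numpy()
        for chrom in pruned.sites["chrom"].unique():
            idx = np.flatnonzero((pruned.sites["chrom"] == chrom).to_numpy())
            for start in range(0, len(idx), 5):
                win = idx[start:start + 20]
                if len(win) < 2:
                    continue
                r2 = gt._pairwise_r2(pruned.dosage()[win])
                np.fill_diagonal(r2, 0.0)
                assert (r2 <= 0.5).all()
        assert len(pos) <= sub.n_sites


class TestLdDecay:
    def test_identical_sites_never_decay_and_flag(self):
        col = [HOM_REF] * 5 + [HOM_ALT] * 5
        g = make_geno([col] * 8, positions=list(range(1000, 9000, 1000)))
        with pytest.warns(UserWarning, match="never decays"):
            res = ld_decay(g, bin_width_bp=1000)
        assert not res.reached
        assert np.allclose(res.mean_r2, 1.0)

    def test_independent_sites_decay_at_first_bin(self):
        rng = np.random.default_rng(2)
        calls = rng.choice([HOM_REF, HOM_ALT], size=(120, 80))
        g = make_geno(calls.tolist(),
                      positions=list(range(500, 500 + 120 * 400, 400)))
        res = ld_decay(g, bin_width_bp=2000)
        assert res.reached
        assert res.decay_bp == res.bin_mid_bp[0]

    def test_geometric_decay_recovered_within_one_bin(self):
        # latent AR(1) field thresholded to hom calls: corr(y_d, y_0) =
        # (2/pi) arcsin(rho^d), giving a closed-form decay distance
        rng = np.random.default_rng(3)
        n_acc, n_sites, spacing = 400, 120, 100
        rho_site = 0.9
        z = np.empty((n_sites, n_acc))
        z[0] = rng.normal(size=n_acc)
        for j in range(1, n_sites):
            z[j] = rho_site * z[j - 1] + np.sqrt(1 - rho_site ** 2) * \
                rng.normal(size=n_acc)
        calls = np.where(z > 0, HOM_ALT, HOM_REF)
        g = make_geno(calls.tolist(),
                      positions=list(range(spacing, spacing * (n_sites + 1),
                                           spacing)))
        bin_bp = 500
        res = ld_decay(g, r2_threshold=0.2, bin_width_bp=bin_bp)
        # analytic: r2(d) = ((2/pi) arcsin(rho^(d/spacing)))^2 = 0.2
        target_rho_pow = np.sin(np.sqrt(0.2) * np.pi / 2)
        d_true = spacing * np.log(target_rho_pow) / np.log(rho_site)
        assert res.reached
        assert abs(res.decay_bp - d_true) <= bin_bp


class TestHetAndDistance:
    def test_heterozygosity_examples(self):
        g = make_geno([[HET], [HET], [HET], [HET]])
        assert heterozygosity_rate(g, "s1") == 1.0
        g2 = make_geno([[HET], [HOM_REF], [HOM_ALT], [HOM_REF], [MISSING]])
        assert heterozygosity_rate(g2, "s1") == 0.25
        g3 = make_geno([[MISSING], [MISSING]])
        with pytest.raises(ValueError, match="undefined"):
            heterozygosity_rate(g3, "s1")

    def test_p_distance_counting_rules(self):
        # 10 shared sites, one opposite-homozygote difference -> 0.1
        a = [HOM_REF] * 10
        b = [HOM_REF] * 9 + [HOM_ALT]
        g = make_geno(np.array([a, b]).T.tolist())
        assert p_distance(g).get("s1", "s2") == pytest.approx(0.1)
        # 4 shared sites, one hom/het mismatch -> 0.5/4
        a = [HOM_REF] * 4
        b = [HOM_REF] * 3 + [HET]
        g = make_geno(np.array([a, b]).T.tolist())
        assert p_distance(g).get("s1", "s2") == pytest.approx(0.125)

    def test_p_distance_identity_and_symmetry(self):
        rng = np.random.default_rng(4)
        calls = rng.choice([HOM_REF, HET, HOM_ALT, MISSING], size=(50, 6))
        calls[:, 3] = calls[:, 2]  # duplicate accession
        d = p_distance(make_geno(calls.tolist()))
        assert np.allclose(d.values, d.values.T)
        assert d.values[2, 3] == 0.0
        assert (np.diag(d.values) == 0).all()

    def test_zero_shared_sites_flagged(self):
        calls = [[HOM_REF, MISSING], [MISSING, HOM_ALT]]
        with pytest.warns(UserWarning, match="zero sites"):
            d = p_distance(make_geno(calls))
        assert np.isnan(d.get("s1", "s2"))


class TestNjPathDistances:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 0.2, 0.3],
                                     [0.2, 0, 0.4],
                                     [0.3, 0.4, 0]]))
        paths, newick = nj_path_distances(d)
        assert np.allclose(paths.to_frame().loc[d.ids, d.ids].to_numpy(),
                           d.values, atol=1e-12)
        assert newick.count(",") == 2

    def test_additive_four_taxon_matrix_reproduced(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) gives an additive distance matrix
        vals = np.array([[0, 3, 8, 9],
                         [3, 0, 9, 10],
                         [8, 9, 0, 9],
                         [9, 10, 9, 0]], dtype=float)
        d = DistanceMatrix(list("ABCD"), vals)
        paths, _ = nj_path_distances(d)
        got = paths.to_frame().loc[list("ABCD"), list("ABCD")].to_numpy()
        assert np.allclose(got, vals, atol=1e-9)

    def test_zero_distances_give_zero_paths(self):
        d = DistanceMatrix(list("ABCD"), np.zeros((4, 4)))
        paths, _ = nj_path_distances(d)
        assert np.allclose(paths.values, 0.0)

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(0.1, 1.0, size=(6, 6))
        vals = (m + m.T) / 2
        np.fill_diagonal(vals, 0)
        d = DistanceMatrix([f"t{i}" for i in range(6)], vals)
        paths, newick = nj_path_distances(d)
        assert (paths.values >= 0).all()
        assert ":-" not in newick

    def test_too_few_taxa_rejected(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 0.1], [0.1, 0]]))
        with pytest.raises(ValueError, match=">= 3"):
            nj_path_distances(d)
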