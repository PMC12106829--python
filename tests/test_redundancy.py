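"""Redundancy grouping, k-mer cross-validation and consensus pooling."""

import numpy as np
import pandas as pd
import pytest

from tefpop.genotypes import (HET, HOM_ALT, HOM_REF, MISSING, DistanceMatrix)
from tefpop.redundancy import (RedundancyGrouping, define_groups,
                               exclude_outliers, kmer_validate_groups,
                               pool_groups)

from conftest import make_geno


def dm(ids, pairs, default=0.5):
    n = len(ids)
    v = np.full((n, n), default)
    np.fill_diagonal(v, 0.0)
    for (a, b), d in pairs.items():
        i, j = ids.index(a), ids.index(b)
        v[i, j] = v[j, i] = d
    return DistanceMatrix(ids, v)


class TestExcludeOutliers:
    def test_paper_scale_rates(self):
        rates = {"mix1": 0.227, "mix2": 0.249, "normal": 0.015}
        out = exclude_outliers(rates)
        assert {e["accession"] for e in out} == {"mix1", "mix2"}
        assert all(e["reason"] == "seed mixture suspect" for e in out)

    def test_zero_rates_no_exclusions(self):
        assert exclude_outliers({"a": 0.0, "b": 0.0}) == []

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="out of"):
            exclude_outliers({"a": 1.5})


class TestDefineGroups:
    def test_close_pair_groups_far_singleton(self):
        d = dm(["A", "B", "C"], {("A", "B"): 0.001})
        g = define_groups(d)
        assert g.groups == [{"members": ["A", "B"], "representative": "A"}]
        assert g.singlets == ["C"]

    def test_complete_linkage_blocks_chaining(self):
        # A-B and B-C are close but A-C violates the any-pair rule
        d = dm(["A", "B", "C"],
               {("A", "B"): 0.004, ("B", "C"): 0.004, ("A", "C"): 0.006})
        g = define_groups(d)
        assert g.groups == [{"members": ["A", "B"], "representative": "A"}]
        assert g.singlets == ["C"]

    def test_threshold_is_strict(self):
        d = dm(["A", "B", "C"], {}, default=0.005)
        g = define_groups(d)
        assert g.groups == []
        assert g.singlets == ["A", "B", "C"]

    def test_exclusions_left_out(self):
        d = dm(["A", "B", "C"], {("A", "B"): 0.001})
        g = define_groups(d, exclusions=[{"accession": "A",
                                          "reason": "seed mixture suspect"}])
        assert g.groups == []
        assert g.singlets == ["B", "C"]

    def test_missing_distance_rejected(self):
        v = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="missing distance"):
            define_groups(DistanceMatrix(["A", "B"], v))

    def test_partition_is_valid(self):
        rng = np.random.default_rng(0)
        ids = [f"t{i}" for i in range(12)]
        m = rng.uniform(0.001, 0.02, size=(12, 12))
        v = (m + m.T) / 2
        np.fill_diagonal(v, 0)
        g = define_groups(DistanceMatrix(ids, v))
        seen = [m for grp in g.groups for m in grp["members"]] + g.singlets
        assert sorted(seen) == sorted(ids)
        # any-pair rule holds inside every group
        for grp in g.groups:
            for i, a in enumerate(grp["members"]):
                for b in grp["members"][i + 1:]:
                    assert v[ids.index(a), ids.index(b)] < 0.005


def rates_frame(ids, pairs, default=0.85):
    n = len(ids)
    v = np.full((n, n), default)
    np.fill_diagonal(v, 1.0)
    for (a, b), r in pairs.items():
        i, j = ids.index(a), ids.index(b)
        v[i, j] = v[j, i] = r
    return pd.DataFrame(v, index=ids, columns=ids)


class TestKmerValidation:
    def test_concordant_case_no_promotions(self):
        grouping = RedundancyGrouping(
            [{"members": ["A", "B"], "representative": "A"}], ["C", "D"],
            [], 0.005)
        rates = rates_frame(list("ABCD"), {("A", "B"): 0.99})
        d = dm(list("ABCD"), {("A", "B"): 0.001})
        report, updated = kmer_validate_groups(grouping, rates, d)
        assert report["intra_pairs_at_or_above_threshold"] == 1
        assert report["intra_pairs_below_threshold"] == 0
        assert report["non_group_pairs_at_or_above_threshold"] == 0
        assert updated.groups == grouping.groups

    def test_high_rate_low_distance_pair_promoted(self):
        # the single above-threshold non-group pair at distance 0.007
        grouping = RedundancyGrouping([], ["A", "B", "C"], [], 0.005)
        rates = rates_frame(list("ABC"), {("A", "B"): 0.97})
        d = dm(list("ABC"), {("A", "B"): 0.007})
        report, updated = kmer_validate_groups(grouping, rates, d)
        assert report["promotions"] == [
            {"members": ["A", "B"], "rate": 0.97, "distance": 0.007}]
        assert updated.groups == [{"members": ["A", "B"],
                                   "representative": "A"}]
        assert updated.singlets == ["C"]

    def test_high_rate_large_distance_reported_not_promoted(self):
        grouping = RedundancyGrouping([], ["A", "B", "C"], [], 0.005)
        rates = rates_frame(list("ABC"), {("A", "B"): 0.97})
        d = dm(list("ABC"), {("A", "B"): 0.2})
        report, updated = kmer_validate_groups(grouping, rates, d)
        assert report["non_group_pairs_at_or_above_threshold"] == 1
        assert report["promotions"] == []
        assert updated.singlets == ["A", "B", "C"]

    def test_promotion_never_merges_groups(self):
        grouping = RedundancyGrouping(
            [{"members": ["A", "B"], "representative": "A"},
             {"members": ["C", "D"], "representative": "C"}], ["E"],
            [], 0.005)
        rates = rates_frame(list("ABCDE"), {("A", "C"): 0.99})
        d = dm(list("ABCDE"), {("A", "C"): 0.004})
        _, updated = kmer_validate_groups(grouping, rates, d)
        assert len(updated.groups) == 2
        seen = [m for g in updated.groups for m in g["members"]]
        assert sorted(seen + updated.singlets) == list("ABCDE")


class TestPoolGroups:
    GROUPING = RedundancyGrouping(
        [{"members": ["s1", "s2", "s3"], "representative": "s1"}], ["s4"],
        [], 0.005)

    def test_consensus_rules(self):
        calls = [
            [HOM_ALT, HOM_ALT, HOM_ALT, HOM_REF],   # unanimity -> homALT
            [HOM_REF, HOM_ALT, HOM_REF, HOM_REF],   # conflict -> missing
            [HOM_REF, HET, MISSING, HOM_ALT],       # het->missing, unanimous
            [MISSING, MISSING, MISSING, HOM_REF],   # all missing -> missing
        ]
        pooled = pool_groups(make_geno(calls), self.GROUPING)
        assert pooled.samples == ["s1", "s4"]
        col = pooled.calls[:, 0].tolist()
        assert col == [HOM_ALT, MISSING, HOM_REF, MISSING]
        assert pooled.calls[:, 1].tolist() == [HOM_REF, HOM_REF, HOM_ALT,
                                               HOM_REF]

    def test_pooled_width_is_units(self, geno40, panel40):
        truth = panel40.truth
        groups = [{"members": sorted(m), "representative": sorted(m)[0]}
                  for m in truth.groups.values()]
        grouped = {a for m in truth.groups.values() for a in m}
        singlets = [a for a in geno40.samples if a not in grouped]
        grouping = RedundancyGrouping(groups, singlets, [], 0.005)
        pooled = pool_groups(geno40, grouping)
        assert pooled.n_samples == grouping.n_units


class TestPlantedRecovery:
    def test_planted_partition_recovered(self, panel40, geno40, kmat40):
        from tefpop import genotypes as gt
        from tefpop.kmers import shared_rate_matrix

        f = gt.filter_sites(geno40)
        het = {a: gt.heterozygosity_rate(geno40, a) for a in geno40.samples}
        genome = sum(len(s) for s in panel40.reference.values())
        d = gt.p_distance(f)
        d = DistanceMatrix(d.ids, d.values * f.n_sites / genome)
        grouping = define_groups(d, 0.005, exclude_outliers(het))
        _, grouping = kmer_validate_groups(grouping, shared_rate_matrix(kmat40),
                                           d)
        truth = sorted(sorted(v) for v in panel40.truth.groups.values())
        found = sorted(sorted(g["members"]) for g in grouping.groups)
        assert found == truth
        mixtures = {a for a, c in panel40.truth.het_class.items()
                    if c == "seed_mixture"}
        assert {e["accession"] for e in grouping.exclusions} == mixtures
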