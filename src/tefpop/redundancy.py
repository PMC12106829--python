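"""Redundancy grouping of near-identical accessions.

Diversity panels of selfing crops often harbour duplicated germplasm: sets of
accessions whose pairwise genetic distance is essentially zero.  This module
partitions accessions into redundancy groups (complete-linkage clusters whose
members are all pairwise closer than a distance threshold), excludes
suspected seed mixtures (abnormally heterozygous accessions), cross-validates
groups against k-mer shared-state rates, and pools each group into a single
consensus genotype column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .genotypes import HET, MISSING, DistanceMatrix, GenotypeMatrix


@dataclass
class RedundancyGrouping:
    """Partition of accessions into groups, singlets and exclusions.

    Each group has >= 2 members and a representative (alphabetically first
    member); every non-excluded accession appears in exactly one group or as
    a singlet.
    """

    groups: list[dict]  # {"members": [...], "representative": str}
    singlets: list[str]
    exclusions: list[dict]  # {"accession": str, "reason": str}
    distance_threshold: float
    rate_threshold: float | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for grp in self.groups:
            if len(grp["members"]) < 2:
                raise ValueError("redundancy group with < 2 members")
            for m in grp["members"]:
                if m in seen:
                    raise ValueError(f"accession {m} in more than one group")
                seen.add(m)
        for s in self.singlets:
            if s in seen:
                raise ValueError(f"accession {s} both singlet and group member")
            seen.add(s)

    @property
    def n_units(self) -> int:
        """Number of effective accessions (groups + singlets)."""
        return len(self.groups) + len(self.singlets)

    def unit_of(self) -> dict[str, str]:
        """Map accession -> unit id (representative for groups, self for singlets)."""
        out = {}
        for grp in self.groups:
            for m in grp["members"]:
                out[m] = grp["representative"]
        for s in self.singlets:
            out[s] = s
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, grp in enumerate(self.groups, start=1):
            for m in grp["members"]:
                rows.append((m, f"G{gi:03d}", grp["representative"], "group"))
        for s in self.singlets:
            rows.append((s, "", s, "singlet"))
        for e in self.exclusions:
            rows.append((e["accession"], "", "", f"excluded: {e['reason']}"))
        return pd.DataFrame(rows, columns=["accession", "group", "representative",
                                           "status"])

    def to_json(self) -> str:
        return json.dumps({
            "groups": self.groups, "singlets": self.singlets,
            "exclusions": self.exclusions,
            "distance_threshold": self.distance_threshold,
            "rate_threshold": self.rate_threshold}, indent=2)


def exclude_outliers(het_rates: dict[str, float],
                     absolute_threshold: float = 0.10) -> list[dict]:
    """Flag accessions with heterozygosity above the threshold.

    In a highly selfing crop, baseline heterozygosity sits near 1-2%; rates an
    order of magnitude higher indicate a seed mixture rather than a pure
    accession, so such entries are kept out of redundancy grouping.
    """
    for acc, r in het_rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"heterozygosity rate out of [0,1] for {acc}: {r}")
    return [{"accession": acc, "reason": "seed mixture suspect"}
            for acc, r in het_rates.items() if r > absolute_threshold]


def define_groups(d: DistanceMatrix, threshold: float = 0.005,
                  exclusions: list[dict] | None = None) -> RedundancyGrouping:
    """Complete-linkage clustering of accessions cut strictly below ``threshold``.

    Every pair within a resulting group is closer than the threshold (the
    any-pair rule); clusters of size >= 2 become groups with the
    alphabetically first member as representative, the rest are singlets.
    """
    exclusions = exclusions or []
    excluded = {e["accession"] for e in exclusions}
    ids = [a for a in d.ids if a not in excluded]
    idx = [d.ids.index(a) for a in ids]
    sub = d.values[np.ix_(idx, idx)]
    if np.isnan(sub).any():
        bad = np.argwhere(np.isnan(sub))
        i, j = bad[0]
        raise ValueError(
            f"missing distance between {ids[i]} and {ids[j]}")
    if len(ids) < 2:
        return RedundancyGrouping([], ids, exclusions, threshold)
    Z = linkage(squareform(sub, checks=False), method="complete")
    # fcluster merges at cophenetic distance <= t; the grouping rule is
    # strict (< threshold), so cut just below it.
    labels = fcluster(Z, t=np.nextafter(threshold, 0), criterion="distance")
    groups, singlets = [], []
    for lab in np.unique(labels):
        members = sorted(np.array(ids)[labels == lab])
        if len(members) >= 2:
            groups.append({"members": list(members), "representative": members[0]})
        else:
            singlets.append(members[0])
    groups.sort(key=lambda grp: grp["representative"])
    return RedundancyGrouping(groups, sorted(singlets), exclusions, threshold)


def kmer_validate_groups(grouping: RedundancyGrouping,
                         shared_rates: pd.DataFrame,
                         d: DistanceMatrix | None = None,
                         rate_threshold: float = 0.96,
                         promote_distance_ceiling: float = 0.01):
    """Cross-validate distance-based groups against k-mer shared-state rates.

    Counts intra-group pairs at/above the rate threshold, discordant
    intra-group pairs below it, and non-group pairs at/above it.  A non-group
    pair whose shared rate clears the threshold *and* whose distance is below
    ``promote_distance_ceiling`` is promoted into a new two-member group
    (both members must currently be singlets; promotion never merges or
    splits existing groups).

    Returns ``(report dict, updated RedundancyGrouping)``.
    """
    unit = {}
    for gi, grp in enumerate(grouping.groups):
        for m in grp["members"]:
            unit[m] = gi
    members = sorted(unit)
    singlets = set(grouping.singlets)
    everyone = members + sorted(singlets)

    intra_ok = intra_bad = inter_hi = 0
    discordant: list[tuple[str, str, float]] = []
    candidates: list[tuple[str, str, float, float]] = []
    for i, a in enumerate(everyone):
        for b in everyone[i + 1:]:
            rate = float(shared_rates.loc[a, b])
            same = a in unit and b in unit and unit[a] == unit[b]
            if same:
                if rate >= rate_threshold:
                    intra_ok += 1
                else:
                    intra_bad += 1
                    discordant.append((a, b, rate))
            elif rate >= rate_threshold:
                inter_hi += 1
                dist = d.get(a, b) if d is not None else np.inf
                candidates.append((a, b, rate, dist))

    new_groups = [dict(grp) for grp in grouping.groups]
    new_singlets = set(grouping.singlets)
    promotions = []
    for a, b, rate, dist in candidates:
        if dist < promote_distance_ceiling and a in new_singlets and b in new_singlets:
            pair = sorted((a, b))
            new_groups.append({"members": pair, "representative": pair[0]})
            new_singlets -= {a, b}
            promotions.append({"members": pair, "rate": rate, "distance": dist})
    new_groups.sort(key=lambda grp: grp["representative"])
    updated = RedundancyGrouping(new_groups, sorted(new_singlets),
                                 list(grouping.exclusions),
                                 grouping.distance_threshold, rate_threshold)
    report = {
        "intra_pairs_at_or_above_threshold": intra_ok,
        "intra_pairs_below_threshold": intra_bad,
        "discordant_pairs": discordant,
        "non_group_pairs_at_or_above_threshold": inter_hi,
        "promotions": promotions,
        "rate_threshold": rate_threshold,
        "promote_distance_ceiling": promote_distance_ceiling,
    }
    return report, updated


def pool_groups(g: GenotypeMatrix, grouping: RedundancyGrouping) -> GenotypeMatrix:
    """Collapse each redundancy group to one consensus genotype column.

    Heterozygous member calls are treated as missing; the group call is the
    unanimous non-missing member call, and any disagreement (or all-missing)
    yields a missing call.  Output has one column per group plus one per
    singlet, ordered by unit id.
    """
    unit_map = grouping.unit_of()
    units = sorted(set(unit_map.values()))
    cols = np.full((g.n_sites, len(units)), MISSING, dtype=np.int8)
    for uj, unit in enumerate(units):
        members = [a for a, u in unit_map.items() if u == unit]
        sub = g.calls[:, [g.sample_index(m) for m in members]].copy()
        sub[sub == HET] = MISSING
        valid = sub != MISSING
        any_valid = valid.any(axis=1)
        # unanimity among non-missing member calls
        first = np.where(any_valid, sub[np.arange(g.n_sites),
                                        np.argmax(valid, axis=1)], MISSING)
        agree = ((sub == first[:, None]) | ~valid).all(axis=1)
        cols[:, uj] = np.where(any_valid & agree, first, MISSING)
    return GenotypeMatrix(units, g.sites.copy(), cols)
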