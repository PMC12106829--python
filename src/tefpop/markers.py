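"""Minimal discriminating SNP panel selection (greedy set cover).

Given pooled group/singlet genotypes, select the smallest practical set of
biallelic SNPs at which every pair of units is distinguished by opposite
non-missing homozygous calls.  Heterozygous calls are first converted to
missing (het loci are unstable across generations in a selfing crop, so they
make unreliable fingerprinting markers), and missing calls never distinguish
a pair.  A second, disjoint round of selection provides backup markers
against assay failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix


def het_to_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Convert every heterozygous call to missing; idempotent."""
    calls = g.calls.copy()
    calls[calls == HET] = MISSING
    return GenotypeMatrix(list(g.samples), g.sites.copy(), calls)


@dataclass
class MarkerPanel:
    """Selected fingerprinting SNPs, one ordered list per round.

    ``rounds[r]`` is the list of site indices (into ``sites``) chosen in
    round ``r``; rounds are disjoint.  ``resolved`` maps each round-1 site
    index to the number of previously unresolved pairs it resolved when
    picked.
    """

    sites: pd.DataFrame                 # site table of the source matrix
    rounds: list[list[int]]
    resolved: dict[int, int]
    samples: list[str]

    def to_frame(self, g: GenotypeMatrix) -> pd.DataFrame:
        code = {HOM_REF: "REF", HOM_ALT: "ALT", MISSING: "NA", HET: "HET"}
        rows = []
        for r, idxs in enumerate(self.rounds, start=1):
            for i in idxs:
                s = g.sites.iloc[i]
                rec = {"round": r, "chrom": s.chrom, "pos": int(s.pos),
                       "ref": s.ref, "alt": s.alt}
                for j, acc in enumerate(g.samples):
                    rec[acc] = code[int(g.calls[i, j])]
                rows.append(rec)
        return pd.DataFrame(rows)


def _pair_resolution_masks(calls: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Boolean matrix site x pair: does the site distinguish the pair?

    A site distinguishes a pair iff both calls are non-missing homozygous
    and different.
    """
    n = calls.shape[1]
    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    homR = calls == HOM_REF
    homA = calls == HOM_ALT
    masks = np.zeros((calls.shape[0], len(pairs)), dtype=bool)
    for p, (a, b) in enumerate(pairs):
        masks[:, p] = (homR[:, a] & homA[:, b]) | (homA[:, a] & homR[:, b])
    return masks, pairs


def select_minimal_panel(g: GenotypeMatrix, rounds: int = 2,
                         apply_het_to_missing: bool = True) -> MarkerPanel:
    """Greedy maximum-coverage selection of discriminating SNPs.

    Each step picks the site resolving the most still-unresolved pairs
    (ties broken by lowest chromosome name, then position) until all pairs
    are resolved.  Subsequent rounds re-run the selection with previously
    chosen sites removed.

    Raises ``ValueError`` listing indistinguishable pairs if some pair
    cannot be resolved by any available site.
    """
    if apply_het_to_missing:
        g = het_to_missing(g)
    masks, pairs = _pair_resolution_masks(g.calls)
    # tie-break order: (chrom, pos) ascending
    order = np.lexsort((g.sites["pos"].to_numpy(),
                        g.sites["chrom"].to_numpy()))
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(len(order))

    chosen_rounds: list[list[int]] = []
    resolved_counts: dict[int, int] = {}
    available = np.ones(g.n_sites, dtype=bool)
    for r in range(rounds):
        unresolved = np.ones(len(pairs), dtype=bool)
        picked: list[int] = []
        while unresolved.any():
            gains = (masks[:, unresolved] & available[:, None]).sum(axis=1)
            gains[~available] = 0
            best_gain = gains.max()
            if best_gain == 0:
                bad = [(g.samples[a], g.samples[b])
                       for p, (a, b) in enumerate(pairs) if unresolved[p]]
                if r == 0:
                    raise ValueError(
                        f"indistinguishable pairs remain: {bad[:20]}"
                        + (" ..." if len(bad) > 20 else ""))
                break  # later rounds may legitimately run out of sites
            cand = np.flatnonzero(gains == best_gain)
            site = cand[np.argmin(rank[cand])]
            picked.append(int(site))
            if r == 0:
                resolved_counts[int(site)] = int(best_gain)
            unresolved &= ~masks[site]
            available[site] = False
        chosen_rounds.append(picked)
    return MarkerPanel(g.sites.copy(), chosen_rounds, resolved_counts,
                       list(g.samples))


def brute_force_minimum_panel(g: GenotypeMatrix,
                              apply_het_to_missing: bool = True) -> int:
    """Exact minimum panel size by exhaustive subset search (tiny inputs only).

    Independent oracle for the greedy heuristic; enumerates site subsets in
    increasing size over the (deduplicated) resolution masks.
    """
    from itertools import combinations

    if apply_het_to_missing:
        g = het_to_missing(g)
    masks, pairs = _pair_resolution_masks(g.calls)
    npairs = len(pairs)
    # drop dominated/duplicate columns to keep the search feasible
    uniq = {}
    for i in range(masks.shape[0]):
        key = masks[i].tobytes()
        if key not in uniq and masks[i].any():
            uniq[key] = i
    sites = list(uniq.values())
    full = np.ones(npairs, dtype=bool)
    if not (np.any([masks[i] for i in sites], axis=0) == full).all():
        raise ValueError("instance has indistinguishable pairs")
    for size in range(1, len(sites) + 1):
        for combo in combinations(sites, size):
            if masks[list(combo)].any(axis=0).all():
                return size
    raise AssertionError("unreachable")


def verify_member_consistency(panel: MarkerPanel, members: GenotypeMatrix,
                              grouping,
                              pooled: GenotypeMatrix | None = None
                              ) -> pd.DataFrame:
    """Check individual group members against their group's panel genotypes.

    For every panel site and redundancy group, a member is flagged when its
    non-missing *homozygous* call differs from the group call at that site
    (``pooled`` — the matrix the panel was selected from — or a fresh
    consensus of ``members`` when omitted); het or missing member calls are
    uninformative and never flagged.  Returns a table of flags (empty when
    all members are consistent).
    """
    from .redundancy import pool_groups

    if pooled is None:
        pooled = pool_groups(members, grouping)
    flags = []
    panel_sites = [i for rnd in panel.rounds for i in rnd]
    site_key = {(r.chrom, int(r.pos)): i
                for i, r in enumerate(members.sites.itertuples())}
    pooled_key = {(r.chrom, int(r.pos)): i
                  for i, r in enumerate(pooled.sites.itertuples())}
    for grp in grouping.groups:
        unit = grp["representative"]
        uj = pooled.sample_index(unit)
        for pi in panel_sites:
            s = panel.sites.iloc[pi]
            key = (s.chrom, int(s.pos))
            if key not in site_key or key not in pooled_key:
                continue
            group_call = int(pooled.calls[pooled_key[key], uj])
            if group_call == MISSING:
                continue
            for m in grp["members"]:
                call = int(members.calls[site_key[key],
                                         members.sample_index(m)])
                if call in (HOM_REF, HOM_ALT) and call != group_call:
                    flags.append({"group": unit, "member": m,
                                  "chrom": s.chrom, "pos": int(s.pos),
                                  "member_call": call,
                                  "group_call": group_call})
    return pd.DataFrame(flags, columns=["group", "member", "chrom", "pos",
                                        "member_call", "group_call"])
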