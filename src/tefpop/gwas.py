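"""k-mer presence/absence association, genomic binning and region calling.

Each matrix k-mer is scored by ordinary regression of the phenotype on its
presence indicator (equivalent to a pooled two-sample t-test), with a
length-adjusted Bonferroni threshold 0.05 / (n / k): the number of tested
k-mers is divided by the k-mer length because overlapping k-mers are not
independent tests.  Significant k-mers are projected onto the reference by
exact canonical match, counted per 10 kb bin, and runs of significant bins
separated by less than a 500 kb gap are merged into candidate regions; a
region is called trait-associated when it holds at least ``min_kmers``
significant k-mers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .kmers import KmerMatrix


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

def kmer_threshold(n_kmers: int, k: int) -> float:
    """Length-adjusted Bonferroni p threshold: 0.05 / (n_kmers / k)."""
    if n_kmers < 1 or k < 1:
        raise ValueError("n_kmers and k must be positive")
    return 0.05 / (n_kmers / k)


def snp_threshold(n_snps: int) -> float:
    """Plain Bonferroni p threshold for SNP association: 0.05 / n."""
    if n_snps < 1:
        raise ValueError("n_snps must be positive")
    return 0.05 / n_snps


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """Per-k-mer association scores.

    ``score`` is -log10 p from the slope t-test; ``direction`` is the sign
    of the slope (+1: presence associated with higher trait values).
    Untested k-mers (presence or absence count below ``min_class``) carry
    NaN scores and ``tested`` False.
    """

    kmers: list[str]
    score: np.ndarray
    direction: np.ndarray
    presence_count: np.ndarray
    tested: np.ndarray
    n_tested: int
    k: int
    score_cap: float
    capped: np.ndarray

    @property
    def threshold(self) -> float:
        return kmer_threshold(self.n_tested, self.k)

    def significant(self) -> np.ndarray:
        """Boolean mask of tested k-mers past the adjusted threshold."""
        thr = -np.log10(self.threshold)
        return self.tested & (self.score >= thr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "kmer": self.kmers, "score": self.score,
            "direction": self.direction,
            "presence_count": self.presence_count,
            "tested": self.tested, "capped": self.capped})


def associate_kmers(m: KmerMatrix, phenotype: pd.Series | dict,
                    min_class: int = 5,
                    score_cap: float = 300.0) -> AssociationResult:
    """Regress the phenotype on each k-mer's presence indicator.

    ``phenotype`` must provide a value for every matrix accession.  k-mers
    present (or absent) in fewer than ``min_class`` accessions are skipped
    as untested.  Perfect-separation / zero-residual fits are flagged and
    capped at ``score_cap``.
    """
    if isinstance(phenotype, dict):
        phenotype = pd.Series(phenotype)
    missing = [a for a in m.ids if a not in phenotype.index]
    if missing:
        raise ValueError(f"phenotype undefined for accessions {missing[:5]}")
    y = phenotype.reindex(m.ids).to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    n = len(y)
    X = m.states
    n1 = X.sum(axis=0).astype(float)
    tested = (n1 >= min_class) & ((n - n1) >= min_class)

    ybar = y.mean()
    Syy = ((y - ybar) ** 2).sum()
    Sxy = X.T.astype(float) @ y - n1 * ybar
    Sxx = n1 - n1 ** 2 / n
    nk = X.shape[1]
    score = np.full(nk, np.nan)
    direction = np.zeros(nk, dtype=np.int8)
    capped = np.zeros(nk, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(Sxx > 0, Sxy / Sxx, 0.0)
        rss = Syy - slope * Sxy
        dof = n - 2
        s2 = rss / dof
        tstat = slope / np.sqrt(s2 / np.where(Sxx > 0, Sxx, np.nan))
    ok = tested & (s2 > 1e-12 * max(Syy, 1.0))
    p = 2.0 * stats.t.sf(np.abs(tstat[ok]), dof)
    sc = -np.log10(np.maximum(p, 10.0 ** (-score_cap)))
    score[ok] = np.minimum(sc, score_cap)
    capped[ok] = sc >= score_cap
    degenerate = tested & ~ok
    score[degenerate] = score_cap
    capped[degenerate] = True
    direction[tested] = np.where(slope[tested] >= 0, 1, -1)
    return AssociationResult(list(m.kmers), score, direction,
                             n1.astype(int), tested, int(tested.sum()),
                             m.k, score_cap, capped)


def associate_snps(g: GenotypeMatrix, phenotype: pd.Series | dict,
                   min_calls: int = 5) -> pd.DataFrame:
    """Naive single-marker dosage regression per SNP (stand-in model).

    A simple per-SNP ordinary regression of the phenotype on allele dosage;
    no kinship or structure correction.  Returns a per-site table with
    slope, score (-log10 p) and direction, for use with
    :func:`snp_threshold`.
    """
    if isinstance(phenotype, dict):
        phenotype = pd.Series(phenotype)
    y_all = phenotype.reindex(g.samples).to_numpy(dtype=float)
    if np.ptp(y_all[~np.isnan(y_all)]) == 0:
        raise ValueError("constant phenotype")
    dos = g.dosage()
    out = []
    for i in range(g.n_sites):
        x = dos[i]
        ok = ~np.isnan(x) & ~np.isnan(y_all)
        if ok.sum() < min_calls or np.ptp(x[ok]) == 0:
            out.append((np.nan, np.nan, 0))
            continue
        res = stats.linregress(x[ok], y_all[ok])
        score = -np.log10(max(res.pvalue, 1e-300))
        out.append((res.slope, score, 1 if res.slope >= 0 else -1))
    df = g.sites.copy()
    df[["slope", "score", "direction"]] = pd.DataFrame(out, index=df.index)
    return df


# ---------------------------------------------------------------------------
# Projection onto the reference and binning
# ---------------------------------------------------------------------------

def map_kmers(reference: dict[str, str], kmers: list[str]):
    """Exact-match canonical k-mers against both strands of the reference.

    Returns ``(positions, unmapped)`` where ``positions`` maps each k-mer to
    a list of ``(chromosome, 1-based forward-strand start)`` hits and
    ``unmapped`` lists k-mers with no hit.  Matching the canonical form of
    every reference window covers both strands.
    """
    if not kmers:
        return {}, []
    from .kmers import _canonical_windows, _strings_to_packed, _unpack_to_bytes

    k = len(kmers[0])
    packed_targets = _strings_to_packed(set(kmers), k)
    target_pairs = {(int(h), int(l))
                    for h, l in zip(packed_targets["hi"], packed_targets["lo"])}
    target_his = np.unique(packed_targets["hi"])
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in reference.items():
        canon, starts = _canonical_windows(seq, k)
        if canon.size == 0:
            continue
        maybe = np.flatnonzero(np.isin(canon["hi"], target_his))
        for j in maybe:
            pair = (int(canon["hi"][j]), int(canon["lo"][j]))
            if pair in target_pairs:
                km = _unpack_to_bytes(canon[j:j + 1], k)[0].decode()
                index.setdefault(km, []).append((chrom, int(starts[j]) + 1))
    unmapped = [km for km in kmers if km not in index]
    return {km: index[km] for km in kmers if km in index}, unmapped


def bin_index(pos: int, bin_bp: int = 10_000) -> int:
    """1-based bin number: bin i covers [(i-1)*bin_bp + 1, i*bin_bp]."""
    return (pos - 1) // bin_bp + 1


def bin_scores(mapped: dict[str, list[tuple[str, int]]], scores: dict[str, float],
               directions: dict[str, int], bin_bp: int = 10_000,
               first_match_only: bool = False) -> pd.DataFrame:
    """Count mapped k-mers per 10 kb bin by rounded score level and direction.

    Multi-mapping k-mers contribute to every matched bin unless
    ``first_match_only``.  Returns a long table (chrom, bin_start, bin_end,
    level, direction, count).
    """
    rows: dict[tuple, int] = {}
    for km, hits in mapped.items():
        if first_match_only:
            hits = hits[:1]
        level = int(round(scores[km]))
        direc = int(directions[km])
        for chrom, pos in hits:
            b = bin_index(pos, bin_bp)
            key = (chrom, (b - 1) * bin_bp + 1, b * bin_bp, level, direc)
            rows[key] = rows.get(key, 0) + 1
    if not rows:
        return pd.DataFrame(columns=["chrom", "bin_start", "bin_end",
                                     "level", "direction", "count"])
    df = pd.DataFrame(
        [(c, s, e, lv, d, n) for (c, s, e, lv, d), n in rows.items()],
        columns=["chrom", "bin_start", "bin_end", "level", "direction", "count"])
    return df.sort_values(["chrom", "bin_start", "level",
                           "direction"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Region calling
# ---------------------------------------------------------------------------

@dataclass
class TraitRegion:
    """A called interval of significant k-mers on one chromosome."""

    trait: str
    chrom: str
    start: int
    end: int
    n_kmers: int
    n_positive: int
    n_negative: int
    significant: bool

    @property
    def majority_direction(self) -> int:
        return 1 if self.n_positive >= self.n_negative else -1

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end


def call_regions(binned: pd.DataFrame, gap_bp: int = 500_000,
                 min_kmers: int = 750, trait: str = "") -> list[TraitRegion]:
    """Merge significant bins into regions by the maximum-gap rule.

    ``binned`` holds per-bin counts of *significant* k-mers (columns
    ``chrom``, ``bin_start``, ``bin_end``, ``count`` and optionally
    ``direction``).  Scanning bins in order per chromosome, a region opens
    at the first bin containing a significant k-mer and closes when the next
    such bin starts more than ``gap_bp`` after the current last bin's end.
    The region spans first bin start to last bin end; regions with total
    k-mers >= ``min_kmers`` are flagged significant.
    """
    regions: list[TraitRegion] = []
    if binned.empty:
        return regions
    work = binned[binned["count"] > 0].copy()
    if "direction" not in work.columns:
        work["direction"] = 1
    for chrom in sorted(work["chrom"].unique()):
        sub = work[work["chrom"] == chrom]
        per_bin = (sub.assign(
            n_pos=np.where(sub["direction"] == 1, sub["count"], 0),
            n_neg=np.where(sub["direction"] == -1, sub["count"], 0))
            .groupby(["bin_start", "bin_end"], as_index=False)
            [["count", "n_pos", "n_neg"]].sum()
            .sort_values("bin_start"))
        cur = None
        for row in per_bin.itertuples():
            if cur is None:
                cur = {"start": row.bin_start, "end": row.bin_end,
                       "n": int(row.count), "pos": int(row.n_pos),
                       "neg": int(row.n_neg)}
            elif row.bin_start - cur["end"] > gap_bp:
                regions.append(_close_region(trait, chrom, cur, min_kmers))
                cur = {"start": row.bin_start, "end": row.bin_end,
                       "n": int(row.count), "pos": int(row.n_pos),
                       "neg": int(row.n_neg)}
            else:
                cur["end"] = row.bin_end
                cur["n"] += int(row.count)
                cur["pos"] += int(row.n_pos)
                cur["neg"] += int(row.n_neg)
        if cur is not None:
            regions.append(_close_region(trait, chrom, cur, min_kmers))
    return regions


def _close_region(trait: str, chrom: str, cur: dict,
                  min_kmers: int) -> TraitRegion:
    return TraitRegion(trait, chrom, int(cur["start"]), int(cur["end"]),
                       cur["n"], cur["pos"], cur["neg"],
                       cur["n"] >= min_kmers)


def regions_to_frame(regions: list[TraitRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trait": r.trait, "chrom": r.chrom, "start": r.start, "end": r.end,
        "n_kmers": r.n_kmers, "n_positive": r.n_positive,
        "n_negative": r.n_negative,
        "majority_direction": r.majority_direction,
        "significant": r.significant} for r in regions])
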