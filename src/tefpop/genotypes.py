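"""SNP genotype matrices: I/O, site filtering, LD pruning/decay and distances.

Genotype calls are stored as small integer codes per (site, accession):
``0`` homozygous reference, ``1`` heterozygous, ``2`` homozygous alternate,
``-1`` missing.  Only biallelic SNPs are represented; multiallelic or
non-SNP records are skipped at read time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls for a panel of accessions.

    Parameters
    ----------
    samples : list of str
        Accession identifiers, column order of ``calls``.
    sites : pandas.DataFrame
        One row per SNP with columns ``chrom``, ``pos`` (1-based), ``ref``,
        ``alt``; sorted by (chrom, pos) with unique positions per chromosome.
    calls : numpy.ndarray of int8, shape (n_sites, n_samples)
        Genotype codes (0/1/2/-1).
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        order = np.lexsort((self.sites["pos"].to_numpy(),
                            self.sites["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(order))):
            self.sites = self.sites.iloc[order].reset_index(drop=True)
            self.calls = self.calls[order]
        dup = self.sites.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate (chrom, pos) in site table")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def dosage(self) -> np.ndarray:
        """ALT allele dosage (0/1/2) with NaN at missing calls."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples),
            self.sites.iloc[index].reset_index(drop=True),
            self.calls[index],
        )

    def sample_index(self, accession: str) -> int:
        try:
            return self.samples.index(accession)
        except ValueError:
            raise KeyError(f"accession {accession!r} not in matrix") from None


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix in substitutions per site."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(v - v.T)) > 1e-12:
                raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal not zero")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class LdDecayResult:
    """Binned mean r-squared against physical distance.

    ``decay_bp`` is the distance at which the binned mean first falls below
    the threshold (linear interpolation between the straddling bins);
    ``reached`` is False when no bin falls below the threshold, in which case
    ``decay_bp`` is the maximum observed pair distance.
    """

    bin_mid_bp: np.ndarray
    mean_r2: np.ndarray
    threshold: float
    decay_bp: float
    reached: bool
    n_pairs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_mid_bp": self.bin_mid_bp, "mean_r2": self.mean_r2,
             "n_pairs": self.n_pairs}
        )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF (v4.2, GT field required).

    Multiallelic and non-SNP records are skipped; the skip count is logged.
    ``./.`` calls become missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise ValueError(f"{path}: VCF has no GT FORMAT definition")
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    bases = {"A", "C", "G", "T"}
    for i, rec in enumerate(vcf):
        try:
            alt = rec.ALT
            if (len(alt) != 1 or rec.REF not in bases or alt[0] not in bases):
                n_skipped += 1
                continue
            # gts012: 0=HOM_REF, 1=HET, 2=HOM_ALT, 3=UNKNOWN
            gt = np.asarray(rec.gt_types, dtype=np.int8)
            gt[gt == 3] = MISSING
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            refs.append(rec.REF)
            alts.append(alt[0])
            rows.append(gt)
        except Exception as exc:  # pragma: no cover - malformed record path
            raise ValueError(f"{path}: malformed VCF record #{i + 1}: {exc}") from exc
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    calls = (np.vstack(rows) if rows
             else np.empty((0, len(samples)), dtype=np.int8))
    g = GenotypeMatrix(samples, sites, calls)
    g.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return g


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a GT-only VCF v4.2; round-trips through :func:`read_vcf`."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for i in range(g.n_sites):
            row = g.sites.iloc[i]
            gts = "\t".join(_GT_STRINGS[int(c)] for c in g.calls[i])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Site filters and LD
# ---------------------------------------------------------------------------

def site_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency per site from non-missing calls.

    A het call contributes one copy of each allele.  Sites with zero
    non-missing calls get MAF 0.
    """
    nonmiss = (g.calls != MISSING).sum(axis=1)
    alt = np.where(g.calls == MISSING, 0, g.calls).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(nonmiss > 0, alt / (2 * nonmiss), 0.0)
    return np.minimum(p_alt, 1 - p_alt)


def filter_sites(g: GenotypeMatrix, max_missing_fraction: float = 0.10,
                 min_maf: float = 0.025) -> GenotypeMatrix:
    """Apply call-rate and minor-allele-frequency site filters.

    Retains sites with at least ``1 - max_missing_fraction`` non-missing
    calls and MAF >= ``min_maf`` (defaults follow the standard vcftools-style
    thresholds ``--max-missing 0.90`` / ``--maf 0.025``).
    """
    miss_frac = (g.calls == MISSING).mean(axis=1)
    keep = (miss_frac <= max_missing_fraction) & (site_maf(g) >= min_maf)
    if not keep.any():
        warnings.warn("filter_sites removed every site", stacklevel=2)
    return g.take_sites(np.flatnonzero(keep))


def _pairwise_r2(dos: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage rows (sites x samples),
    pairwise-complete over non-missing samples; degenerate pairs get 0."""
    M = (~np.isnan(dos)).astype(float)
    X = np.nan_to_num(dos)
    X2 = X * X
    n = M @ M.T
    sx = X @ M.T           # sum of x_i over samples valid in both i and j
    sxx = X2 @ M.T
    sxy = X @ X.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sx.T / n
        var_i = sxx - sx * sx / n
        denom = var_i * var_i.T
        r2 = np.where((n >= 2) & (denom > 0), cov * cov / denom, 0.0)
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_prune(g: GenotypeMatrix, window_snps: int = 20, step_snps: int = 5,
             r2_threshold: float = 0.5) -> GenotypeMatrix:
    """Sliding-window LD pruning on genotype dosage (plink-style 20/5/0.5).

    Within each window, for every retained pair with r^2 above the threshold
    the member with the lower MAF is removed (tie: larger position).  The
    window slides by ``step_snps``; passes repeat until no within-window pair
    exceeds the threshold.
    """
    dos = g.dosage()
    maf = site_maf(g)
    pos = g.sites["pos"].to_numpy()
    keep = np.ones(g.n_sites, dtype=bool)
    for chrom in pd.unique(g.sites["chrom"]):
        cidx = np.flatnonzero((g.sites["chrom"] == chrom).to_numpy())
        changed = True
        while changed:
            changed = False
            alive = cidx[keep[cidx]]
            start = 0
            while start < len(alive):
                win = alive[start:start + window_snps]
                win = win[keep[win]]
                if len(win) > 1:
                    r2 = _pairwise_r2(dos[win])
                    for a in range(len(win)):
                        if not keep[win[a]]:
                            continue
                        for b in range(a + 1, len(win)):
                            if not keep[win[b]]:
                                continue
                            if r2[a, b] > r2_threshold:
                                ia, ib = win[a], win[b]
                                if maf[ia] < maf[ib]:
                                    drop = ia
                                elif maf[ib] < maf[ia]:
                                    drop = ib
                                else:
                                    drop = ia if pos[ia] > pos[ib] else ib
                                keep[drop] = False
                                changed = True
                start += step_snps
    return g.take_sites(np.flatnonzero(keep))


def ld_decay(g: GenotypeMatrix, r2_threshold: float = 0.2,
             bin_width_bp: int = 1000,
             max_sites_per_chrom: int = 1500) -> LdDecayResult:
    """LD decay: binned mean pairwise r^2 against physical distance.

    All intra-chromosome site pairs contribute (chromosomes denser than
    ``max_sites_per_chrom`` are thinned to evenly spaced sites, keeping the
    pair count tractable).  The decay distance is where the binned mean r^2
    curve first crosses below ``r2_threshold``, linearly interpolated
    between the straddling bin midpoints.
    """
    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    dos = g.dosage()
    pos = g.sites["pos"].to_numpy()
    any_pair = False
    for chrom in pd.unique(g.sites["chrom"]):
        cidx = np.flatnonzero((g.sites["chrom"] == chrom).to_numpy())
        if len(cidx) < 2:
            continue
        if len(cidx) > max_sites_per_chrom:
            take = np.linspace(0, len(cidx) - 1, max_sites_per_chrom).astype(int)
            cidx = cidx[np.unique(take)]
        any_pair = True
        r2 = _pairwise_r2(dos[cidx])
        iu = np.triu_indices(len(cidx), k=1)
        dists.append(np.abs(pos[cidx][iu[0]] - pos[cidx][iu[1]]).astype(float))
        r2s.append(r2[iu])
    if not any_pair:
        raise ValueError("ld_decay requires >= 2 sites on some chromosome")
    dist = np.concatenate(dists)
    r2 = np.concatenate(r2s)
    nbins = int(dist.max() // bin_width_bp) + 1
    which = (dist // bin_width_bp).astype(int)
    mids = (np.arange(nbins) + 0.5) * bin_width_bp
    sums = np.bincount(which, weights=r2, minlength=nbins)
    counts = np.bincount(which, minlength=nbins)
    occupied = counts > 0
    mids, mean_r2, counts = mids[occupied], sums[occupied] / counts[occupied], counts[occupied]
    below = mean_r2 < r2_threshold
    if not below.any():
        warnings.warn("LD never decays below threshold within observed range",
                      stacklevel=2)
        return LdDecayResult(mids, mean_r2, r2_threshold,
                             float(dist.max()), False, counts)
    first = int(np.argmax(below))
    if first == 0:
        decay = float(mids[0])
    else:
        x0, x1 = mids[first - 1], mids[first]
        y0, y1 = mean_r2[first - 1], mean_r2[first]
        decay = float(x0 + (y0 - r2_threshold) * (x1 - x0) / (y0 - y1))
    return LdDecayResult(mids, mean_r2, r2_threshold, decay, True, counts)


# ---------------------------------------------------------------------------
# Heterozygosity and distances
# ---------------------------------------------------------------------------

def heterozygosity_rate(g: GenotypeMatrix, accession: str) -> float:
    """Fraction of non-missing calls that are heterozygous."""
    col = g.calls[:, g.sample_index(accession)]
    nonmiss = int((col != MISSING).sum())
    if nonmiss == 0:
        raise ValueError(f"{accession}: no non-missing calls, rate undefined")
    return float((col == HET).sum() / nonmiss)


def p_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise p-distances in substitutions per site.

    Per shared (both non-missing) site: identical calls score 0, opposite
    homozygotes 1, and a hom/het pair 0.5 — i.e. half the absolute dosage
    difference.  Pairs with zero shared sites get NaN.
    """
    if g.n_samples < 2:
        raise ValueError("p_distance requires >= 2 accessions")
    dos = g.dosage().T  # samples x sites
    valid = ~np.isnan(dos)
    M = valid.astype(float)
    # |a-b| over dosage 0/1/2 decomposes into the two step indicators
    # u = 1[x>=1], v = 1[x>=2]: |a-b| = |u_a-u_b| + |v_a-v_b|
    U = np.where(valid, dos >= 1, 0.0)
    V = np.where(valid, dos >= 2, 0.0)
    N = M @ M.T
    SU = U @ M.T
    SV = V @ M.T
    D = (SU + SU.T - 2 * (U @ U.T)) + (SV + SV.T - 2 * (V @ V.T))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(N > 0, D / 2.0 / N, np.nan)
    if np.isnan(d).any():
        warnings.warn("some accession pairs share zero sites; their "
                      "distances are missing", stacklevel=2)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(g.samples), d)


def nj_path_distances(d: DistanceMatrix):
    """Neighbour-joining tree and its leaf-to-leaf path-length matrix.

    Negative branch lengths from the NJ reconstruction are clamped to zero
    and the deficit is moved onto the sister branch, after which path lengths
    are sums of branch lengths.  Returns ``(DistanceMatrix, newick_string)``.
    """
    import skbio

    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbour joining requires >= 3 taxa")
    if np.isnan(d.values).any():
        raise ValueError("distance matrix contains missing entries")
    dm = skbio.DistanceMatrix(d.values, ids=d.ids)
    tree = skbio.tree.nj(dm, neg_as_zero=False)
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            deficit = -node.length
            node.length = 0.0
            siblings = [s for s in node.siblings() if s.length is not None]
            if siblings:
                siblings[0].length += deficit
    tt = tree.tip_tip_distances(endpoints=d.ids)
    paths = DistanceMatrix(list(tt.ids), np.asarray(tt.data))
    return paths, str(tree)
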