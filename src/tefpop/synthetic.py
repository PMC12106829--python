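"""Seeded synthetic diversity panels with known truth.

Emulates the structure of a resequenced germplasm core collection from a
highly selfing crop:

* a set of founder lineages diverged from a common ancestor at a configured
  per-base substitution rate;
* planted redundancy groups — clones of one founder separated by a small
  per-base mutation rate (intra-group distances far below founder
  divergence);
* occasional "seed mixture" accessions carrying two divergent haplotypes,
  hence elevated apparent heterozygosity;
* one accession with a novel-sequence introgression replacing a contiguous
  region, inflating its distinct-k-mer count;
* optional swept causal haplotypes: a contiguous segment where all carrier
  accessions share the ancestral (reference) sequence exactly, the way a
  major allele rides a conserved haplotype; trait effects attach to carrier
  status;
* a three-location augmented block design with replicated checks, trait
  values drawn from the location-fixed / block- and genotype-random mixed
  model; and two-class metabolite feature tables.

Substitutions are i.i.d. per base with a uniform choice among the three
alternative bases; there are no indels, so k-mer and SNP coordinates stay
aligned to the ancestor, which doubles as the reference genome.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .mixedmodel import inverse_transform

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_UNALIGNED = 4  # sentinel haplotype code: sequence absent from the reference


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class CausalLocus:
    """A swept causal haplotype: carriers share the ancestral segment."""

    chrom: str
    start: int          # 1-based, inclusive
    length: int = 2000
    carrier_fraction: float = 0.5


@dataclass
class PanelConfig:
    """Conditions for one synthetic panel.

    Defaults describe the standard desk-scale panel: 40 accessions in 6
    redundancy groups of 2-5 members (intra-group rate 0.002/bp) plus
    singlet founders, founder divergence 0.05/bp, one seed-mixture
    accession and one introgression carrier, on 2 x 60 kb chromosomes.
    """

    n_founders: int = 24
    group_spec: list[tuple[int, float]] = field(
        default_factory=lambda: [(4, 0.002), (3, 0.002), (5, 0.002),
                                 (2, 0.002), (4, 0.002), (3, 0.002)])
    inter_founder_divergence: float = 0.05
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 30_000, "chr2": 30_000})
    n_seed_mixtures: int = 1
    mixture_extra_divergence: float = 0.04
    introgression_fraction: float = 0.10
    causal_loci: list[CausalLocus] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for size, rate in self.group_spec:
            if size < 2:
                raise ValueError(f"group size must be >= 2, got {size}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"group rate out of [0,1]: {rate}")
        if not 0.0 <= self.inter_founder_divergence <= 1.0:
            raise ValueError("inter_founder_divergence out of [0,1]")
        if not 0.0 <= self.introgression_fraction <= 1.0:
            raise ValueError("introgression_fraction out of [0,1]")
        for chrom, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ValueError(f"zero-length chromosome {chrom}")
        if self.n_founders < len(self.group_spec):
            raise ValueError("need at least one founder per planted group")
        for locus in self.causal_loci:
            if locus.chrom not in self.chromosome_lengths:
                raise ValueError(f"causal locus on undefined chromosome {locus.chrom}")
            if locus.start + locus.length - 1 > self.chromosome_lengths[locus.chrom]:
                raise ValueError("causal locus extends past chromosome end")

    @property
    def n_accessions(self) -> int:
        n_members = sum(s for s, _ in self.group_spec)
        n_singlets = self.n_founders - len(self.group_spec)
        return n_members + n_singlets + self.n_seed_mixtures


@dataclass
class SyntheticTruth:
    """Ground truth of a generated panel; serialisable, seed-reproducible."""

    groups: dict[str, list[str]]          # group id -> member accessions
    het_class: dict[str, str]             # accession -> normal | seed_mixture
    introgression: dict | None            # accession, chrom, start, end
    causal_loci: list[dict]               # chrom, start, end, carriers
    seed: int
    realized: dict = field(default_factory=dict)

    def group_of(self) -> dict[str, str]:
        out = {}
        for gid, members in self.groups.items():
            for m in members:
                out[m] = gid
        return out

    def to_json(self) -> str:
        return json.dumps({
            "groups": self.groups, "het_class": self.het_class,
            "introgression": self.introgression,
            "causal_loci": self.causal_loci, "seed": self.seed,
            "realized": self.realized}, indent=2, default=str)


@dataclass
class Panel:
    """Generated sequences plus their truth.

    ``haplotypes[acc]`` is a list of one (pure accession) or two (seed
    mixture) haplotypes, each a chromosome -> sequence mapping.
    ``reference`` is the ancestral genome, used as the mapping reference.
    """

    reference: dict[str, str]
    haplotypes: dict[str, list[dict[str, str]]]
    truth: SyntheticTruth

    @property
    def accessions(self) -> list[str]:
        return list(self.haplotypes)

    def sequences(self, accession: str) -> list[str]:
        """All chromosome sequences of all haplotypes of one accession."""
        return [seq for hap in self.haplotypes[accession]
                for seq in hap.values()]


# ---------------------------------------------------------------------------
# Sequence machinery
# ---------------------------------------------------------------------------

def _decode(arr: np.ndarray) -> str:
    return bytes(_BASE_BYTES[arr]).decode()


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. per-base substitution, uniform over the 3 alternative bases."""
    out = arr.copy()
    if rate <= 0:
        return out
    mask = rng.random(arr.size) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    out[mask] = (out[mask] + shift) % 4
    return out


def generate_panel(config: PanelConfig) -> Panel:
    """Generate seeded panel sequences and truth per the configuration.

    Group members derive from a shared founder by independent per-base
    substitution at the group rate; founders diverge from the ancestor at
    half the inter-founder divergence so founder pairs sit near the
    configured divergence.  Bit-identical regeneration from (config, seed).
    """
    for _, rate in config.group_spec:
        if 2 * rate >= 0.005:
            warnings.warn(
                f"group rate {rate} implies intra-group distances near or above "
                "the 0.005 redundancy threshold; planted groups may be "
                "undetectable", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    chroms = list(config.chromosome_lengths)
    ancestor = {c: rng.integers(0, 4, config.chromosome_lengths[c],
                                dtype=np.uint8) for c in chroms}
    founders = []
    for _ in range(config.n_founders):
        founders.append({c: _mutate(ancestor[c],
                                    config.inter_founder_divergence / 2, rng)
                         for c in chroms})

    haplo_codes: dict[str, list[dict[str, np.ndarray]]] = {}
    groups: dict[str, list[str]] = {}
    het_class: dict[str, str] = {}
    counter = 0

    def next_name() -> str:
        nonlocal counter
        counter += 1
        return f"acc{counter:03d}"

    for gi, (size, rate) in enumerate(config.group_spec):
        gid = f"group{gi + 1:02d}"
        members = []
        for _ in range(size):
            name = next_name()
            haplo_codes[name] = [{c: _mutate(founders[gi][c], rate, rng)
                                  for c in chroms}]
            het_class[name] = "normal"
            members.append(name)
        groups[gid] = members
    singlet_founder_ids = list(range(len(config.group_spec), config.n_founders))
    singlet_names = []
    for fi in singlet_founder_ids:
        name = next_name()
        haplo_codes[name] = [{c: founders[fi][c].copy() for c in chroms}]
        het_class[name] = "normal"
        singlet_names.append(name)
    for _ in range(config.n_seed_mixtures):
        name = next_name()
        fa, fb = rng.choice(config.n_founders, size=2, replace=False)
        # mixtures often involve off-types from outside the core panel, so
        # each haplotype carries extra divergence beyond its founder
        xtra = config.mixture_extra_divergence
        haplo_codes[name] = [
            {c: _mutate(founders[fa][c], xtra, rng) for c in chroms},
            {c: _mutate(founders[fb][c], xtra, rng) for c in chroms}]
        het_class[name] = "seed_mixture"

    # introgression: novel random segment replacing a contiguous region of
    # one singlet accession (the last singlet founder)
    introgression = None
    if config.introgression_fraction > 0:
        if not singlet_names:
            raise ValueError("introgression requires at least one singlet founder")
        acc = singlet_names[-1]
        total = sum(config.chromosome_lengths.values())
        seg_len = int(round(config.introgression_fraction * total))
        # keep the introgression off chromosomes carrying causal loci
        causal_chroms = {loc.chrom for loc in config.causal_loci}
        free = [c for c in chroms if c not in causal_chroms]
        candidates = free if free else chroms
        chrom = max(candidates, key=lambda c: config.chromosome_lengths[c])
        clen = config.chromosome_lengths[chrom]
        seg_len = min(seg_len, clen)
        start0 = int(rng.integers(0, clen - seg_len + 1))
        novel = rng.integers(0, 4, seg_len, dtype=np.uint8)
        haplo_codes[acc][0][chrom][start0:start0 + seg_len] = novel
        # unbalanced introgressions also bring unplaced novel content, which
        # is what inflates the carrier's distinct-k-mer count
        extra = rng.integers(0, 4, seg_len, dtype=np.uint8)
        haplo_codes[acc][0][f"{chrom}_introgression"] = extra
        introgression = {"accession": acc, "chrom": chrom,
                         "start": start0 + 1, "end": start0 + seg_len}

    # swept causal haplotypes: carriers revert to the ancestral segment
    unit_members = list(groups.values()) + [[s] for s in singlet_names]
    causal_records = []
    for locus in config.causal_loci:
        n_carrier_units = int(round(locus.carrier_fraction * len(unit_members)))
        pick = rng.choice(len(unit_members), size=n_carrier_units, replace=False)
        carriers = sorted(acc for ui in pick for acc in unit_members[ui])
        s0 = locus.start - 1
        segment = ancestor[locus.chrom][s0:s0 + locus.length]
        for acc in carriers:
            haplo_codes[acc][0][locus.chrom][s0:s0 + locus.length] = segment
        causal_records.append({
            "chrom": locus.chrom, "start": locus.start,
            "end": locus.start + locus.length - 1, "carriers": carriers})

    reference = {c: _decode(ancestor[c]) for c in chroms}
    haplotypes = {
        acc: [{c: _decode(arr) for c, arr in hap.items()} for hap in haps]
        for acc, haps in haplo_codes.items()}
    truth = SyntheticTruth(groups, het_class, introgression, causal_records,
                           config.seed)
    panel = Panel(reference, haplotypes, truth)
    panel._codes = haplo_codes          # kept for fast genotype calling
    panel._ancestor = ancestor
    return panel


def call_genotypes(panel: Panel, missing_rate: float = 0.0,
                   seed: int | None = None) -> GenotypeMatrix:
    """Derive biallelic SNP genotypes by comparing haplotypes to the reference.

    A site enters the matrix when at least one accession carries exactly one
    alternate base there (multiallelic positions are skipped).  Seed-mixture
    accessions are heterozygous where their two haplotypes disagree.  The
    introgressed region of the introgression carrier is treated as unaligned
    (missing calls), as reads from novel sequence would not map.  Optional
    uniform missingness is injected at ``missing_rate``.
    """
    rng = np.random.default_rng(seed if seed is not None else panel.truth.seed + 1)
    accs = panel.accessions
    n = len(accs)
    chrom_frames = []
    call_blocks = []
    for chrom, ref_seq in panel.reference.items():
        ref = (panel._ancestor[chrom] if hasattr(panel, "_ancestor")
               else np.frombuffer(ref_seq.encode(), dtype=np.uint8))
        L = ref.size
        H1 = np.empty((n, L), dtype=np.uint8)
        H2 = np.empty((n, L), dtype=np.uint8)
        for i, acc in enumerate(accs):
            haps = (panel._codes[acc] if hasattr(panel, "_codes") else None)
            if haps is None:  # pragma: no cover - string fallback
                raw = panel.haplotypes[acc]
                haps = [{c: np.frombuffer(s.encode(), np.uint8) for c, s in h.items()}
                        for h in raw]
                haps = [{c: _encode_bytes(a) for c, a in h.items()} for h in haps]
            H1[i] = haps[0][chrom]
            H2[i] = haps[-1][chrom]
        intro = panel.truth.introgression
        if intro is not None and intro["chrom"] == chrom:
            ai = accs.index(intro["accession"])
            H1[ai, intro["start"] - 1:intro["end"]] = _UNALIGNED
            H2[ai, intro["start"] - 1:intro["end"]] = _UNALIGNED

        aligned1 = H1 != _UNALIGNED
        aligned2 = H2 != _UNALIGNED
        var1 = (H1 != ref) & aligned1
        var2 = (H2 != ref) & aligned2
        cols = np.flatnonzero(var1.any(axis=0) | var2.any(axis=0))
        if cols.size == 0:
            continue
        A1, A2 = H1[:, cols].astype(np.int16), H2[:, cols].astype(np.int16)
        refc = ref[cols].astype(np.int16)
        nr1 = np.where((A1 != refc) & (A1 != _UNALIGNED), A1, -1)
        nr2 = np.where((A2 != refc) & (A2 != _UNALIGNED), A2, -1)
        alt_max = np.maximum(nr1.max(axis=0), nr2.max(axis=0))
        lo1 = np.where(nr1 >= 0, nr1, 9)
        lo2 = np.where(nr2 >= 0, nr2, 9)
        alt_min = np.minimum(lo1.min(axis=0), lo2.min(axis=0))
        biallelic = alt_max == alt_min
        cols, refc, alt = cols[biallelic], refc[biallelic], alt_max[biallelic]
        A1, A2 = A1[:, biallelic], A2[:, biallelic]
        g = (A1 == alt).astype(np.int8) + (A2 == alt).astype(np.int8)
        unaligned = (A1 == _UNALIGNED) | (A2 == _UNALIGNED)
        g[unaligned] = MISSING
        calls = g.T.copy()  # (sites, samples)
        base_chr = np.array(list("ACGT"))
        chrom_frames.append(pd.DataFrame({
            "chrom": chrom, "pos": cols + 1,
            "ref": base_chr[refc], "alt": base_chr[alt]}))
        call_blocks.append(calls)
    if not chrom_frames:
        raise ValueError("panel produced no variable biallelic sites")
    sites = pd.concat(chrom_frames, ignore_index=True)
    calls = np.vstack(call_blocks)
    if missing_rate > 0:
        drop = rng.random(calls.shape) < missing_rate
        calls[drop] = MISSING
    return GenotypeMatrix(accs, sites, calls)


def _encode_bytes(b: np.ndarray) -> np.ndarray:  # pragma: no cover
    lut = np.full(256, _UNALIGNED, dtype=np.uint8)
    for i, ch in enumerate(b"ACGT"):
        lut[ch] = i
    return lut[b]


def write_fasta(panel: Panel, path: str, accession: str | None = None) -> None:
    """Multi-record FASTA export (``accession|haplotype|chromosome`` ids)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    accs = [accession] if accession else panel.accessions
    for acc in accs:
        for hi, hap in enumerate(panel.haplotypes[acc]):
            for chrom, seq in hap.items():
                records.append(SeqRecord(Seq(seq), id=f"{acc}|h{hi + 1}|{chrom}",
                                         description=""))
    seqio_write(records, path, "fasta")


def write_reference_fasta(panel: Panel, path: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in panel.reference.items()]
    seqio_write(records, path, "fasta")


# ---------------------------------------------------------------------------
# Trial phenotypes
# ---------------------------------------------------------------------------

@dataclass
class TraitSpec:
    """Variance components and effects generating one trait.

    ``causal_effects`` maps a causal-locus index (into the panel truth's
    ``causal_loci``) to an additive allele-substitution effect; carriers
    contribute ``2 x effect``.
    """

    sigma2_g: float = 1.0
    sigma2_block: float = 0.25
    sigma2_e: float = 0.25
    intercept: float = 10.0
    location_effects: dict[str, float] = field(default_factory=dict)
    causal_effects: dict[int, float] = field(default_factory=dict)
    transformation: str = "none"

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_block", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TrialConfig:
    """Augmented block design across locations with replicated checks."""

    locations: list[str] = field(
        default_factory=lambda: ["LocA", "LocB", "LocC"])
    blocks_per_location: int = 4
    control_accessions: list[str] = field(default_factory=list)
    control_reps_per_location: int = 4
    trait_specs: dict[str, TraitSpec] = field(default_factory=dict)
    seed: int = 0


def generate_trial(truth: SyntheticTruth, accessions: list[str],
                   config: TrialConfig) -> pd.DataFrame:
    """Plot-level phenotype table from the mixed model, with known components.

    Non-control accessions appear once per location; controls appear
    ``control_reps_per_location`` times per location.  Each plot value is
    ``f_inv(intercept + location + block + genotype + causal + residual)``
    with block and genotype effects drawn at the configured variances.
    """
    if not config.trait_specs:
        raise ValueError("trial config defines no traits")
    for ctrl in config.control_accessions:
        if ctrl not in accessions:
            raise ValueError(f"control accession {ctrl!r} not in panel")
    rng = np.random.default_rng(config.seed)
    rows = []
    for loc in config.locations:
        entries = []
        for acc in accessions:
            reps = (config.control_reps_per_location
                    if acc in config.control_accessions else 1)
            entries.extend([acc] * reps)
        order = rng.permutation(len(entries))
        for k, idx in enumerate(order):
            block = f"B{k % config.blocks_per_location + 1}"
            rows.append({"location": loc, "block": block,
                         "accession": entries[idx],
                         "plot_id": f"{loc}-{k + 1:04d}"})
    table = pd.DataFrame(rows)

    group_of = truth.group_of()
    unit_of = {acc: group_of.get(acc, acc) for acc in accessions}
    units = sorted(set(unit_of.values()))
    realized = {}
    for trait, spec in config.trait_specs.items():
        # clonal group members share one genotype effect
        unit_eff = {u: rng.normal(0.0, np.sqrt(spec.sigma2_g)) for u in units}
        g_eff = {acc: unit_eff[unit_of[acc]] for acc in accessions}
        blocks = table[["location", "block"]].drop_duplicates()
        b_eff = {(r.location, r.block): rng.normal(0.0, np.sqrt(spec.sigma2_block))
                 for r in blocks.itertuples()}
        causal_shift = np.zeros(len(accessions))
        acc_index = {a: i for i, a in enumerate(accessions)}
        for li, eff in spec.causal_effects.items():
            locus = truth.causal_loci[li]
            for acc in locus["carriers"]:
                if acc in acc_index:
                    causal_shift[acc_index[acc]] += 2.0 * eff
        linear = np.empty(len(table))
        for i, r in enumerate(table.itertuples()):
            linear[i] = (spec.intercept
                         + spec.location_effects.get(r.location, 0.0)
                         + b_eff[(r.location, r.block)]
                         + g_eff[r.accession]
                         + causal_shift[acc_index[r.accession]]
                         + rng.normal(0.0, np.sqrt(spec.sigma2_e)))
        if spec.transformation == "sqrt" and (linear < 0).any():
            bad = table["plot_id"].to_numpy()[linear < 0][:10]
            raise ValueError(
                f"sqrt-scale values negative, inverse undefined at plots {list(bad)}")
        table[trait] = inverse_transform(linear, spec.transformation)
        realized[trait] = {
            "sigma2_g_realized": float(np.var(list(unit_eff.values()), ddof=1)),
            "sigma2_block_realized": float(np.var(list(b_eff.values()), ddof=1))
            if len(b_eff) > 1 else 0.0,
        }
    truth.realized.update({"trial": realized})
    return table


# ---------------------------------------------------------------------------
# Metabolite features
# ---------------------------------------------------------------------------

def generate_metabolite_features(n_features: int, classes: dict[str, str],
                                 effect_fraction: float, effect_size: float,
                                 seed: int = 0, noise_sd_log10: float = 0.2):
    """Two-class metabolite intensity table with planted log10-scale shifts.

    ``effect_fraction`` of features receive an ``effect_size`` shift (log10
    scale) in the alphabetically first class; the remainder are null.
    Intensities are strictly positive (log-normal around a per-feature
    baseline).  Returns ``(samples x features DataFrame, truth dict)``.
    """
    levels = sorted(set(classes.values()))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 classes, got {levels}")
    for lev in levels:
        n_in = sum(1 for v in classes.values() if v == lev)
        if n_in < 3:
            raise ValueError(f"class {lev!r} has {n_in} samples; need >= 3")
    rng = np.random.default_rng(seed)
    samples = list(classes)
    n_eff = int(round(effect_fraction * n_features))
    shifted = sorted(rng.choice(n_features, size=n_eff, replace=False).tolist())
    base = rng.uniform(3.0, 6.0, size=n_features)
    shift_row = np.zeros(n_features)
    shift_row[shifted] = effect_size
    is_first = np.array([classes[s] == levels[0] for s in samples], dtype=float)
    log10 = (base[None, :] + is_first[:, None] * shift_row[None, :]
             + rng.normal(0.0, noise_sd_log10, size=(len(samples), n_features)))
    table = pd.DataFrame(10.0 ** log10, index=samples,
                         columns=[f"mz{j + 1:05d}" for j in range(n_features)])
    truth = {"shifted_features": [f"mz{j + 1:05d}" for j in shifted],
             "shifted_class": levels[0], "effect_size": effect_size}
    return table, truth
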