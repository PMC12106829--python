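"""End-to-end orchestration: simulate -> genotypes/k-mers -> redundancy ->
marker panel -> BLUP/heritability -> k-mer GWAS -> regions.

All stages run behind one seeded configuration; every stage is also
independently callable with the same results.  The run emits a
machine-readable report comparing detected structure against the planted
truth (group recovery, panel sizes, heritabilities, called regions vs the
causal locus).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genotypes as gt
from . import gwas, kmers, markers, phenostats, redundancy
from .mixedmodel import TrialMixedModel
from .synthetic import (CausalLocus, PanelConfig, TraitSpec, TrialConfig,
                        call_genotypes, generate_metabolite_features,
                        generate_panel, generate_trial)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All pipeline thresholds; defaults are the study's stated values.

    Desk-scale synthetic runs override ``min_kmers`` via
    ``min_kmers_synthetic`` because the full-scale default (750) assumes
    hundreds of millions of matrix k-mers.
    """

    seed: int = 0
    # genotype filters
    max_missing_fraction: float = 0.10
    min_maf: float = 0.025
    ld_window: int = 20
    ld_step: int = 5
    ld_r2: float = 0.5
    r2_decay_threshold: float = 0.2
    decay_bin_bp: int = 1000
    # redundancy
    distance_threshold: float = 0.005
    rate_threshold: float = 0.96
    promote_distance_ceiling: float = 0.01
    het_threshold: float = 0.10
    # k-mers
    k: int = 51
    min_presence: int = 2
    # GWAS
    min_class: int = 5
    bin_bp: int = 10_000
    gap_bp: int = 500_000
    min_kmers: int = 750
    min_kmers_synthetic: int = 50
    # metabolites
    fdr: float = 0.05
    fc_lo: float = 0.83
    fc_hi: float = 1.2
    # synthetic panel / trial
    panel: PanelConfig | None = None
    trial: TrialConfig | None = None

    def __post_init__(self) -> None:
        if self.panel is None:
            self.panel = default_panel_config(self.seed)
        if self.trial is None:
            self.trial = default_trial_config(self.seed)
        if not 0 < self.distance_threshold < 1:
            raise ValueError("distance_threshold out of range")
        if not 0 < self.rate_threshold <= 1:
            raise ValueError("rate_threshold out of range")
        if self.k % 2 == 0 or self.k < 3:
            raise ValueError("k must be odd and >= 3")


def default_panel_config(seed: int) -> PanelConfig:
    """Standard desk-scale panel: 40 accessions, 6 planted groups, one seed
    mixture, one introgression carrier and one swept causal locus."""
    return PanelConfig(
        causal_loci=[CausalLocus(chrom="chr1", start=15_001, length=2_000,
                                 carrier_fraction=0.5)],
        seed=seed)


def default_trial_config(seed: int) -> TrialConfig:
    """Three locations, four blocks, one polygenic and one major-gene trait."""
    return TrialConfig(
        locations=["LocA", "LocB", "LocC"],
        blocks_per_location=4,
        control_reps_per_location=4,
        trait_specs={
            "yield_like": TraitSpec(sigma2_g=1.0, sigma2_block=0.25,
                                    sigma2_e=0.25, intercept=10.0,
                                    location_effects={"LocB": 1.0,
                                                      "LocC": -0.5}),
            "major_gene": TraitSpec(sigma2_g=0.1, sigma2_block=0.05,
                                    sigma2_e=0.1, intercept=5.0,
                                    causal_effects={0: 3.0}),
        },
        seed=seed + 1)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def _rand_index(part_a: dict[str, str], part_b: dict[str, str]) -> float:
    """Unadjusted Rand index between two partitions over the same items."""
    items = sorted(part_a)
    agree = total = 0
    for i, x in enumerate(items):
        for y in items[i + 1:]:
            same_a = part_a[x] == part_a[y]
            same_b = part_b[x] == part_b[y]
            agree += same_a == same_b
            total += 1
    return agree / total if total else 1.0


@_stage("simulate")
def stage_simulate(config: RunConfig):
    panel = generate_panel(config.panel)
    geno = call_genotypes(panel, missing_rate=0.02, seed=config.seed + 101)
    return panel, geno


@_stage("genotypes")
def stage_genotypes(config: RunConfig, geno):
    filtered = gt.filter_sites(geno, config.max_missing_fraction,
                               config.min_maf)
    # apparent heterozygosity from the raw calls: a seed mixture's extra het
    # sites are singletons that the MAF filter would hide
    het = {a: gt.heterozygosity_rate(geno, a) for a in geno.samples}
    # constant-site-corrected distances: per genomic bp, matching the
    # substitutions-per-base-pair scale of the redundancy threshold
    genome_bp = sum(len(s) for s in _reference_of(config).values())
    dist = gt.p_distance(filtered)
    scale = filtered.n_sites / genome_bp
    dist = gt.DistanceMatrix(dist.ids, dist.values * scale)
    pruned = gt.ld_prune(filtered, config.ld_window, config.ld_step,
                         config.ld_r2)
    decay = gt.ld_decay(pruned, config.r2_decay_threshold, config.decay_bin_bp)
    return filtered, het, dist, pruned, decay


def _reference_of(config: RunConfig) -> dict[str, str]:
    # chromosome lengths suffice; avoid regenerating sequences
    return {c: "N" * L for c, L in config.panel.chromosome_lengths.items()}


@_stage("kmers")
def stage_kmers(config: RunConfig, panel):
    sets = {acc: kmers.kmer_array(panel.sequences(acc), config.k)
            for acc in panel.accessions}
    matrix = kmers.build_kmer_matrix(sets, config.min_presence, config.k)
    rates = kmers.shared_rate_matrix(matrix)
    return sets, matrix, rates


@_stage("redundancy")
def stage_redundancy(config: RunConfig, het, dist, rates):
    exclusions = redundancy.exclude_outliers(het, config.het_threshold)
    grouping = redundancy.define_groups(dist, config.distance_threshold,
                                        exclusions)
    report, grouping = redundancy.kmer_validate_groups(
        grouping, rates, dist, config.rate_threshold,
        config.promote_distance_ceiling)
    return grouping, report


@_stage("marker_panel")
def stage_marker_panel(config: RunConfig, geno, grouping):
    pooled = redundancy.pool_groups(geno, grouping)
    panel = markers.select_minimal_panel(pooled, rounds=2)
    consistency = markers.verify_member_consistency(panel, geno, grouping,
                                                    pooled=pooled)
    return pooled, panel, consistency


@_stage("blup")
def stage_blup(config: RunConfig, panel, grouping):
    trial = config.trial
    if not trial.control_accessions:
        # replicated checks default to the first three singlet units
        singles = [a for a in panel.accessions
                   if a in grouping.singlets][:3]
        trial = TrialConfig(trial.locations, trial.blocks_per_location,
                            singles, trial.control_reps_per_location,
                            trial.trait_specs, trial.seed)
    table = generate_trial(panel.truth, panel.accessions, trial)
    unit = grouping.unit_of()
    table = table[table["accession"].isin(unit)].copy()
    table["accession"] = table["accession"].map(unit)
    fits = {}
    for trait, spec in config.trial.trait_specs.items():
        model = TrialMixedModel(table, trait,
                                transformation=spec.transformation)
        fits[trait] = model.fit()
    return table, fits


@_stage("kgwas")
def stage_kgwas(config: RunConfig, panel, kmer_sets, grouping, fits,
                trait: str):
    unit_map = grouping.unit_of()
    units = sorted(set(unit_map.values()))
    unit_sets = {}
    for u in units:
        unit_sets[u] = kmers.union_kmers(
            [kmer_sets[acc] for acc, uu in unit_map.items() if uu == u])
    matrix = kmers.build_kmer_matrix(unit_sets, config.min_presence, config.k)
    blups = fits[trait].blups
    assoc = gwas.associate_kmers(matrix, blups, min_class=config.min_class)
    sig = assoc.significant()
    sig_kmers = [matrix.kmers[i] for i in np.flatnonzero(sig)]
    mapped, unmapped = gwas.map_kmers(panel.reference, sig_kmers)
    scores = {matrix.kmers[i]: float(assoc.score[i])
              for i in np.flatnonzero(sig)}
    dirs = {matrix.kmers[i]: int(assoc.direction[i])
            for i in np.flatnonzero(sig)}
    binned = gwas.bin_scores(mapped, scores, dirs, config.bin_bp)
    regions = gwas.call_regions(binned, config.gap_bp,
                                config.min_kmers_synthetic, trait=trait)
    return assoc, mapped, unmapped, binned, regions


@_stage("metabolites")
def stage_metabolites(config: RunConfig, panel, grouping):
    unit_map = grouping.unit_of()
    units = sorted(set(unit_map.values()))
    rng = np.random.default_rng(config.seed + 77)
    classes = {u: ("brown" if rng.random() < 0.5 else "white") for u in units}
    # guarantee both classes are populated at desk scale
    levels = set(classes.values())
    if len(levels) < 2:  # pragma: no cover - vanishing probability
        classes[units[0]] = "brown" if "white" in levels else "white"
    table, truth = generate_metabolite_features(
        400, classes, effect_fraction=0.2, effect_size=0.5,
        seed=config.seed + 78)
    diff = phenostats.differential_features(table, [classes[s] for s in
                                                    table.index],
                                            config.fdr, config.fc_lo,
                                            config.fc_hi)
    return table, truth, diff, classes


def run_end_to_end(config: RunConfig, outdir: str | None = None) -> dict:
    """Run all stages on a synthetic panel; returns the JSON-able report.

    With ``outdir`` set, stage outputs (VCF, k-mer matrix, grouping tables,
    BLUPs, region tables, report) are written there as plain-text files.
    """
    if not config.trial.trait_specs:
        raise ValueError("run config has no trait_specs section")
    report: dict = {"seed": config.seed}

    panel, geno = stage_simulate(config)
    filtered, het, dist, pruned, decay = stage_genotypes(config, geno)
    kmer_sets, kmat, rates = stage_kmers(config, panel)
    grouping, validation = stage_redundancy(config, het, dist, rates)
    # distinct-k-mer outlier scan on pure accessions (seed mixtures conflate
    # two genotypes, so their counts are excluded from the baseline)
    pure = {a: s for a, s in kmer_sets.items()
            if a not in {e["accession"] for e in grouping.exclusions}}
    kstats = kmers.distinct_kmer_stats(pure)
    pooled, marker_panel, consistency = stage_marker_panel(config, filtered,
                                                           grouping)
    table, fits = stage_blup(config, panel, grouping)
    gwas_trait = next((t for t, s in config.trial.trait_specs.items()
                       if s.causal_effects), None)
    if gwas_trait is not None:
        assoc, mapped, unmapped, binned, regions = stage_kgwas(
            config, panel, kmer_sets, grouping, fits, gwas_trait)
    else:
        assoc = mapped = unmapped = binned = None
        regions = []
    met_table, met_truth, met_diff, met_classes = stage_metabolites(
        config, panel, grouping)

    # --- report ---------------------------------------------------------
    truth_part = panel.truth.group_of()
    excluded = {e["accession"] for e in grouping.exclusions}
    items = [a for a in panel.accessions if a not in excluded]
    truth_full = {a: truth_part.get(a, f"singleton:{a}") for a in items}
    found = {a: u for a, u in grouping.unit_of().items()}
    rand = _rand_index(truth_full, {a: found[a] for a in items})
    report["n_accessions"] = len(panel.accessions)
    report["n_sites_raw"] = geno.n_sites
    report["n_sites_filtered"] = filtered.n_sites
    report["n_sites_pruned"] = pruned.n_sites
    report["ld_decay_bp"] = decay.decay_bp
    report["ld_decay_reached"] = bool(decay.reached)
    report["het_exclusions"] = sorted(excluded)
    report["n_groups_truth"] = len(panel.truth.groups)
    report["n_groups_found"] = len(grouping.groups)
    report["n_units"] = grouping.n_units
    report["group_rand_index"] = rand
    report["group_recovery_exact"] = bool(rand == 1.0)
    report["kmer_validation"] = {
        k: v for k, v in validation.items() if not isinstance(v, list)}
    report["introgression_flagged"] = bool(
        kstats.loc[kstats["accession"] ==
                   (panel.truth.introgression or {}).get("accession", ""),
                   "outlier"].any()) if panel.truth.introgression else None
    report["panel_round_sizes"] = [len(r) for r in marker_panel.rounds]
    report["panel_member_inconsistencies"] = int(len(consistency))
    report["heritability"] = {
        t: {"h2_cullis": f.h2_cullis, "h2_regression": f.h2_regression,
            "sigma2_g": f.sigma2_g, "sigma2_block": f.sigma2_block,
            "sigma2_e": f.sigma2_e}
        for t, f in fits.items()}
    if gwas_trait is not None:
        causal = panel.truth.causal_loci[0]
        hit = any(r.significant and r.overlaps(causal["chrom"],
                                               causal["start"], causal["end"])
                  for r in regions)
        report["kgwas"] = {
            "trait": gwas_trait,
            "n_tested_kmers": assoc.n_tested,
            "threshold_p": assoc.threshold,
            "n_significant": int(assoc.significant().sum()),
            "n_mapped": len(mapped),
            "n_unmapped": len(unmapped),
            "regions": [vars(r) for r in regions],
            "causal_locus": causal,
            "causal_region_recovered": bool(hit),
        }
    report["metabolites"] = {
        "n_features": int(met_table.shape[1]),
        "n_differential": int(met_diff["differential"].sum()),
        "n_planted": len(met_truth["shifted_features"]),
        "recall": float(np.mean([f in set(
            met_diff.index[met_diff["differential"]])
            for f in met_truth["shifted_features"]]))
        if met_truth["shifted_features"] else None,
    }

    if outdir is not None:
        _write_outputs(outdir, config, panel, geno, filtered, grouping,
                       validation, pooled, marker_panel, consistency, table,
                       fits, binned, regions, met_diff, decay, report)
    return report


def _write_outputs(outdir, config, panel, geno, filtered, grouping,
                   validation, pooled, marker_panel, consistency, table,
                   fits, binned, regions, met_diff, decay, report) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gt.write_vcf(geno, out / "genotypes.vcf")
    gt.write_vcf(filtered, out / "genotypes.filtered.vcf")
    (out / "truth.json").write_text(panel.truth.to_json())
    (out / "grouping.json").write_text(grouping.to_json())
    grouping.to_frame().to_csv(out / "grouping.tsv", sep="\t", index=False)
    marker_panel.to_frame(pooled).to_csv(out / "marker_panel.tsv", sep="\t",
                                         index=False)
    consistency.to_csv(out / "panel_consistency.tsv", sep="\t", index=False)
    table.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    blups = pd.DataFrame({t: f.blups for t, f in fits.items()})
    blups.to_csv(out / "blups.tsv", sep="\t")
    decay.to_frame().to_csv(out / "ld_decay.tsv", sep="\t", index=False)
    if binned is not None:
        binned.to_csv(out / "kgwas_bins.tsv", sep="\t", index=False)
        gwas.regions_to_frame(regions).to_csv(out / "kgwas_regions.tsv",
                                              sep="\t", index=False)
    met_diff.to_csv(out / "metabolite_differential.tsv", sep="\t")
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True, default=str))
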