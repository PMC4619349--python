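"""Reproducible replicate studies comparing SNP- and ancestry-based tests.

A replicate study simulates two independent locus chromosomes (the two
interacting loci live on different chromosomes, so their ancestries are
uncorrelated), fixes the genetic and local-ancestry data, and redraws the
causal configuration, effect sizes and outcome across replicates.  Each
replicate is analysed with the best-tag SNP interaction test (S_G) at the
GWAS-scale Bonferroni threshold and the local-ancestry interaction test
(S_L) at the segment-scale threshold, the latter also at cost-adjusted
fold increases of the sample size.  Empirical power per scenario cell is
reported with exact binomial confidence intervals.

All randomness flows from a single master seed through named substreams,
so any stage can be re-run independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .admixture import AdmixedCohort, SegmentMap, build_cohort, degrade_ancestry
from .founders import draw_ancestral_frequencies, sample_founder_haplotypes
from .interactions import fit_interaction
from .power import bonferroni_alpha, empirical_power
from .traits import (
    TraitModel,
    build_latent,
    causal_eligibility,
    draw_effects,
    EffectSpec,
    select_causals,
    simulate_phenotype,
)

logger = logging.getLogger(__name__)


def substream(master_seed: int, *names: object) -> np.random.Generator:
    """Named, order-independent child RNG stream of a master seed."""
    keys = [int(master_seed) & 0x7FFFFFFF]
    keys += [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence(keys))


@dataclass
class ExperimentConfig:
    """Full parameterization of a replicate study.

    The defaults are the package's desk-scale study conditions: two
    50-Mb locus chromosomes carrying 1,000 SNPs over 4 ancestry segments
    each, founder haplotypes with template-mosaic LD so tag SNPs exist,
    a two-way 20/80 admixed cohort with recombination 1e-8 per base
    pair, half-normal causal effects drawn over adjacent differentiated
    SNPs, and an interaction explaining 10% of the outcome variance so
    that power at the genome-wide thresholds (which assume 10M imputed
    SNPs and 1,000 segments) is in a measurable range at n ~ 10^3
    samples.
    """

    seed: int = 1
    # founder panel, per locus chromosome
    n_snps: int = 1000
    fst: float = 0.25
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    n_founders_per_pop: int = 100
    ld_templates: int | None = 4
    ld_block_size: int = 25
    # admixed cohort
    n_individuals: int = 2000
    chrom_length: int = 50_000_000
    recomb_rate: float = 1e-8
    admix_props: tuple[float, float] = (0.2, 0.8)
    n_segments: int = 4
    locus_segments: tuple[int, int] = (1, 2)
    ancestry_r2: float = 1.0
    # trait architecture
    K_values: tuple[int, ...] = (1, 5)
    effect_family: str = "left-truncated-normal"
    differentiation_thresholds: tuple[float, ...] = (0.1, 0.5)
    maf_min: float = 0.10
    target_interaction_variance: float = 0.10
    theta12: float = 1.0
    snp_main_effects: bool = False
    causal_layout: str = "adjacent"  # "adjacent" (contiguous eligible run) or "random"
    # test design
    alpha_nominal: float = 0.05
    n_variants_gwas: int = 10_000_000
    n_variants_ancestry: int = 1_000
    folds: tuple[int, ...] = (1, 6)
    replicates: int = 500
    tags_include_causals: bool = True

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_to_plain(dataclasses.asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if isinstance(val, list):
                val = tuple(val)
            kwargs[f.name] = val
        return cls(**kwargs)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _simulate_locus(config: ExperimentConfig, locus: int, n_total: int) -> AdmixedCohort:
    freqs = draw_ancestral_frequencies(
        config.n_snps, config.fst, config.ancestral_freq_range,
        seed=substream(config.seed, "frequencies", locus),
        chrom_length=config.chrom_length,
    )
    founders = sample_founder_haplotypes(
        freqs, config.n_founders_per_pop, config.ld_templates,
        seed=substream(config.seed, "founders", locus),
        block_size=config.ld_block_size,
        chromosome=f"chr{locus + 1}",
    )
    cohort = build_cohort(
        founders, n_total, config.chrom_length, config.recomb_rate,
        config.admix_props, config.n_segments,
        seed=substream(config.seed, "cohort", locus),
    )
    if config.ancestry_r2 < 1.0:
        cohort.local_ancestry = degrade_ancestry(
            cohort.local_ancestry, config.ancestry_r2,
            seed=substream(config.seed, "ancestry-noise", locus),
        )
    return cohort


def run_replicate_study(config: ExperimentConfig) -> pd.DataFrame:
    """Run the full scenario grid and tabulate empirical power.

    For every cell (K causal SNPs x differentiation threshold) the study
    redraws causal sets, half-normal/normal effects and outcomes across
    ``config.replicates`` replicates, then reports empirical power of
    S_G at the base sample size and of S_L at every cost fold.  An
    infeasible cell (not enough eligible causal SNPs) yields a flagged
    row instead of aborting the study.
    """
    folds = tuple(sorted(config.folds))
    n_total = config.n_individuals * max(folds)
    n_base = config.n_individuals
    cohorts = [_simulate_locus(config, locus, n_total) for locus in (0, 1)]
    logger.info("simulated %d individuals on 2 locus chromosomes", n_total)

    alpha_g = bonferroni_alpha(config.alpha_nominal, config.n_variants_gwas)
    alpha_l = bonferroni_alpha(config.alpha_nominal, config.n_variants_ancestry)

    # per-locus precomputation: standardized segment genotypes + correlations
    seg_data = []
    for locus, cohort in enumerate(cohorts):
        seg = config.locus_segments[locus]
        snp_idx = cohort.snps_in_segment(seg)
        G = cohort.genotypes[:, snp_idx].astype(float)
        sd = G.std(axis=0)
        poly = sd > 0
        Gs = np.zeros_like(G)
        Gs[:, poly] = (G[:, poly] - G[:, poly].mean(axis=0)) / sd[poly]
        corr = (Gs.T @ Gs) / n_total
        L = cohort.local_ancestry[:, seg].astype(float)
        seg_data.append(dict(seg=seg, snp_idx=snp_idx, Gs=Gs, poly=poly,
                             corr=corr, L=L))

    v = config.target_interaction_variance
    model = (
        TraitModel(theta12=config.theta12,
                   target_interaction_variance=v,
                   snp_main_effects=config.snp_main_effects)
        if v > 0 else None
    )

    rows = []
    for K in config.K_values:
        for thr in config.differentiation_thresholds:
            cell = f"K={K},thr={thr}"
            elig = []
            feasible = True
            for locus, cohort in enumerate(cohorts):
                e = causal_eligibility(cohort, seg_data[locus]["seg"], thr,
                                       config.maf_min)
                elig.append(e)
                if e.n_eligible < K:
                    feasible = False
            if not feasible:
                note = (f"infeasible: eligible SNPs per locus = "
                        f"{[e.n_eligible for e in elig]}, K = {K}")
                logger.warning("%s %s", cell, note)
                rows.append(dict(K=K, threshold=thr, test="S_G", fold=1,
                                 N=n_base, alpha=alpha_g, replicates=0,
                                 power=np.nan, ci_low=np.nan, ci_high=np.nan,
                                 note=note))
                continue

            p_g = np.full(config.replicates, np.nan)
            p_l = {f: np.full(config.replicates, np.nan) for f in folds}
            for rep in range(config.replicates):
                rng = substream(config.seed, "replicate", cell, rep)
                if model is None:
                    y = rng.standard_normal(n_total)
                    # any causal set works for tagging under the null
                    picks = [np.nonzero(e.eligible)[0][:K] for e in elig]
                    signs = [np.where(e.flip[p], -1.0, 1.0)
                             for e, p in zip(elig, picks)]
                    betas = [np.ones(K), np.ones(K)]
                else:
                    picks, signs, betas, Zs, Gstd = [], [], [], [], []
                    for locus in (0, 1):
                        e = elig[locus]
                        el = np.nonzero(e.eligible)[0]
                        if config.causal_layout == "adjacent":
                            # the causal set is a contiguous run of eligible
                            # SNPs, mimicking co-localized regulatory variants
                            start = rng.integers(0, len(el) - K + 1)
                            pick = el[start:start + K]
                        else:
                            pick = np.sort(rng.choice(el, size=K, replace=False))
                        beta = draw_effects(
                            EffectSpec(K=K, family=config.effect_family), rng)
                        sign = np.where(e.flip[pick], -1.0, 1.0)
                        Gs = seg_data[locus]["Gs"][:, pick] * sign
                        Zs.append(Gs @ beta)
                        Gstd.append(Gs)
                        picks.append(pick)
                        signs.append(sign)
                        betas.append(beta)
                    pheno = simulate_phenotype(
                        Zs[0], Zs[1], model, rng,
                        causal_genotypes=tuple(Gstd) if config.snp_main_effects else None,
                    )
                    y = pheno.Y

                # S_G: best combined tag per locus at the base sample size
                tag_cols = []
                for locus in (0, 1):
                    d = seg_data[locus]
                    cand = np.nonzero(d["poly"])[0]
                    if not config.tags_include_causals:
                        cand = np.setdiff1d(cand, picks[locus])
                    scores = np.abs(d["corr"][np.ix_(cand, picks[locus])] @ (
                        betas[locus] * signs[locus]))
                    tag_cols.append(d["Gs"][:, cand[int(np.argmax(scores))]])
                try:
                    res = fit_interaction(y[:n_base], tag_cols[0][:n_base],
                                          tag_cols[1][:n_base], model_kind="gwas")
                    p_g[rep] = res.p_value
                except (ValueError, np.linalg.LinAlgError):
                    pass
                for f in folds:
                    nf = n_base * f
                    try:
                        res = fit_interaction(
                            y[:nf], seg_data[0]["L"][:nf], seg_data[1]["L"][:nf],
                            model_kind="ancestry")
                        p_l[f][rep] = res.p_value
                    except (ValueError, np.linalg.LinAlgError):
                        pass

            def _row(test, fold, pvals, alpha, N):
                ok = pvals[~np.isnan(pvals)]
                est = empirical_power(ok, alpha)
                return dict(K=K, threshold=thr, test=test, fold=fold, N=N,
                            alpha=alpha, replicates=len(ok), power=est.power,
                            ci_low=est.ci_low, ci_high=est.ci_high, note="")

            rows.append(_row("S_G", 1, p_g, alpha_g, n_base))
            for f in folds:
                rows.append(_row("S_L", f, p_l[f], alpha_l, n_base * f))
            logger.info("finished cell %s", cell)
    return pd.DataFrame(rows)


_FIXTURE_SCALES = {
    "tiny": dict(n_snps=300, n_founders_per_pop=30, n_individuals=40,
                 n_segments=10, chrom_length=5_000_000),
    "small": dict(n_snps=1000, n_founders_per_pop=60, n_individuals=200,
                  n_segments=20, chrom_length=20_000_000),
}


def make_fixture(scale: str = "tiny", out_dir: str = "fixture", seed: int = 0) -> dict[str, Path]:
    """Write a small, seconds-scale on-disk demo dataset.

    Produces a founder frequency panel and haplotype TSVs, a cohort
    (phased VCF, LAMP-LD-style ancestry TSV, BED-like ancestry tracks),
    a phenotype TSV from a K=1 interaction architecture, and a matching
    YAML config.  Returns the paths keyed by artifact name.
    """
    if scale not in _FIXTURE_SCALES:
        raise ValueError(f"scale must be one of {sorted(_FIXTURE_SCALES)}")
    sizes = _FIXTURE_SCALES[scale]
    out = aio.ensure_dir(out_dir)
    config = ExperimentConfig(seed=seed, replicates=10, folds=(1,),
                              K_values=(1,), differentiation_thresholds=(0.0,),
                              **sizes)

    freqs = draw_ancestral_frequencies(
        config.n_snps, config.fst, config.ancestral_freq_range,
        seed=substream(seed, "frequencies", 0), chrom_length=config.chrom_length)
    founders = sample_founder_haplotypes(
        freqs, config.n_founders_per_pop, seed=substream(seed, "founders", 0))
    cohort = build_cohort(
        founders, config.n_individuals, config.chrom_length, config.recomb_rate,
        config.admix_props, config.n_segments, seed=substream(seed, "cohort", 0))

    # K=1 trait across two well-separated segments of the fixture chromosome
    seg1, seg2 = 1, config.n_segments - 2
    rng = substream(seed, "trait")
    model = TraitModel(target_interaction_variance=0.05)
    latents = []
    for locus, seg in enumerate((seg1, seg2)):
        sel = select_causals(cohort, seg, K=1, differentiation_threshold=0.0,
                             maf_min=0.05, seed=rng)
        latents.append(build_latent(cohort, sel.indices,
                                    draw_effects(EffectSpec(K=1), rng),
                                    sel.flip, locus=locus))
    pheno = simulate_phenotype(latents[0].Z, latents[1].Z, model, rng)

    paths = {
        "frequency_panel": out / "founder_frequencies.tsv",
        "founder_haplotypes": out / "founder_haplotypes.tsv",
        "cohort_vcf": out / "cohort.vcf",
        "ancestry": out / "local_ancestry.tsv",
        "tracks": out / "ancestry_tracks.bed",
        "phenotypes": out / "phenotypes.tsv",
        "config": out / "config.yaml",
    }
    aio.write_frequency_panel(freqs, paths["frequency_panel"], founders.chromosome)
    aio.write_haplotypes_tsv(founders, paths["founder_haplotypes"])
    aio.write_phased_vcf(cohort.positions, cohort.haplotypes, paths["cohort_vcf"],
                         chromosome=cohort.chromosome)
    aio.write_ancestry_tsv(cohort.local_ancestry, paths["ancestry"])
    aio.write_tracks_bed(cohort.tracks, paths["tracks"], cohort.chromosome)
    aio.write_phenotypes_tsv(pheno.Y, pheno.Z1, pheno.Z2, paths["phenotypes"])
    config.to_yaml(paths["config"])
    return paths


def cohort_from_files(
    vcf_path: str,
    ancestry_path: str,
    chrom_length: int,
    reference_pop: int = 2,
) -> AdmixedCohort:
    """Assemble a cohort from a phased VCF and an ancestry-dosage TSV.

    True ancestry tracks are not recoverable from dosage files, so the
    returned cohort carries constant placeholder tracks; everything that
    operates on genotype and ancestry dosage matrices works as usual.
    """
    from .founders import import_vcf
    from .admixture import AncestryTrack

    # samples split 50/50 across labels only to satisfy panel invariants;
    # the labels are unused downstream
    from cyvcf2 import VCF
    samples = VCF(vcf_path).samples
    half = max(len(samples) // 2, 1)
    mapping = {s: (1 if i < half else 2) for i, s in enumerate(samples)}
    panel = import_vcf(vcf_path, mapping)
    local_anc = aio.read_ancestry_tsv(ancestry_path)
    n = panel.n_haplotypes // 2
    if local_anc.shape[0] != n:
        raise ValueError("VCF and ancestry TSV disagree on the number of individuals")
    seg_map = SegmentMap(n_segments=local_anc.shape[1], chrom_length=chrom_length)
    tracks = [
        AncestryTrack(boundaries=np.array([0, chrom_length]),
                      interval_pop=np.array([reference_pop]))
        for _ in range(2 * n)
    ]
    genotypes = panel.haplotypes[0::2] + panel.haplotypes[1::2]
    return AdmixedCohort(
        genotypes=genotypes, local_ancestry=local_anc, tracks=tracks,
        segment_map=seg_map, positions=panel.positions,
        chromosome=panel.chromosome, reference_pop=reference_pop,
        haplotypes=panel.haplotypes,
    )
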