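"""Founder haplotype panels for two ancestral populations.

A founder panel stands in for reference haplotypes of the two ancestral
populations of a two-way admixed cohort (e.g. European-like and
African-like).  Allele-frequency differentiation between the two
populations is controlled with a Balding-Nichols Beta model: each SNP has
a shared ancestral frequency ``p`` and each population's frequency is an
independent draw from ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, so that the
expected Wright-style differentiation across SNPs equals ``F``.

Panels can also be imported from phased VCF files for use with real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Population frequencies outside this open interval are resampled so the
#: panel contains no (nearly) monomorphic sites.
_POLYMORPHIC_RANGE = (0.01, 0.99)


@dataclass
class PopulationFrequencies:
    """Per-SNP alternate-allele frequencies in two ancestral populations.

    Attributes
    ----------
    positions : array of int
        Base-pair coordinates, 0-based, strictly increasing.
    freq_pop1, freq_pop2 : array of float
        Alternate-allele frequency of each SNP in populations 1 and 2.
    fst : float
        Differentiation parameter used to generate the frequencies.
    """

    positions: np.ndarray
    freq_pop1: np.ndarray
    freq_pop2: np.ndarray
    fst: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.freq_pop1 = np.asarray(self.freq_pop1, dtype=float)
        self.freq_pop2 = np.asarray(self.freq_pop2, dtype=float)
        if not (len(self.positions) == len(self.freq_pop1) == len(self.freq_pop2)):
            raise ValueError("positions and frequency arrays must have equal length")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        for name, f in (("freq_pop1", self.freq_pop1), ("freq_pop2", self.freq_pop2)):
            if not np.all(np.isfinite(f)) or f.min() < 0 or f.max() > 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return len(self.positions)

    def frequencies(self, pop: int) -> np.ndarray:
        if pop == 1:
            return self.freq_pop1
        if pop == 2:
            return self.freq_pop2
        raise ValueError("population label must be 1 or 2")


@dataclass
class FounderHaplotypes:
    """Phased binary haplotypes for the two ancestral populations.

    ``haplotypes`` is an ``H x M`` matrix of 0/1 alleles; ``pop_label``
    assigns each haplotype row to population 1 or 2.
    """

    haplotypes: np.ndarray
    pop_label: np.ndarray
    positions: np.ndarray
    chromosome: str = "chrS"
    ld_blocks: list[tuple[int, int]] | None = None
    model_frequencies: PopulationFrequencies | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.pop_label = np.asarray(self.pop_label, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] != len(self.pop_label):
            raise ValueError("one population label per haplotype required")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("one position per SNP column required")
        uniq = set(np.unique(self.haplotypes).tolist())
        if not uniq <= {0, 1}:
            raise ValueError("haplotype alleles must be 0/1")
        if set(np.unique(self.pop_label).tolist()) - {1, 2}:
            raise ValueError("population labels must be 1 or 2")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def population(self, pop: int) -> np.ndarray:
        """Haplotype sub-matrix for one population."""
        return self.haplotypes[self.pop_label == pop]

    def empirical_frequencies(self, pop: int) -> np.ndarray:
        """Observed alternate-allele frequency per SNP in one population."""
        sub = self.population(pop)
        if sub.shape[0] == 0:
            raise ValueError(f"no haplotypes labelled population {pop}")
        return sub.mean(axis=0)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_ancestral_frequencies(
    n_snps: int,
    fst: float,
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9),
    seed: int | np.random.Generator = 0,
    chrom_length: int = 50_000_000,
) -> PopulationFrequencies:
    """Draw per-SNP population frequencies under a Balding-Nichols model.

    Each SNP gets an ancestral frequency ``p`` uniform on
    ``ancestral_freq_range`` and two independent population frequencies
    from ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with ``F = fst``.  Draws falling
    outside (0.01, 0.99) are resampled so no site is effectively
    monomorphic.  SNP positions are evenly spaced over ``chrom_length``.
    """
    if not np.isfinite(fst) or not (0 < fst < 1):
        raise ValueError(f"fst must lie strictly in (0, 1), got {fst!r}")
    lo, hi = ancestral_freq_range
    if not (0 < lo < hi < 1):
        raise ValueError("ancestral_freq_range must satisfy 0 < lo < hi < 1")
    if n_snps < 1:
        raise ValueError("n_snps must be positive")
    rng = _as_rng(seed)

    anc = rng.uniform(lo, hi, size=n_snps)
    a = anc * (1.0 - fst) / fst
    b = (1.0 - anc) * (1.0 - fst) / fst

    def _draw(mask: np.ndarray, out: np.ndarray) -> None:
        # resample out-of-range draws until every site is polymorphic
        while mask.any():
            out[mask] = rng.beta(a[mask], b[mask])
            mask = (out <= _POLYMORPHIC_RANGE[0]) | (out >= _POLYMORPHIC_RANGE[1])

    f1 = np.empty(n_snps)
    f2 = np.empty(n_snps)
    _draw(np.ones(n_snps, dtype=bool), f1)
    _draw(np.ones(n_snps, dtype=bool), f2)

    step = max(chrom_length // (n_snps + 1), 1)
    positions = step * np.arange(1, n_snps + 1, dtype=np.int64)
    return PopulationFrequencies(positions=positions, freq_pop1=f1, freq_pop2=f2, fst=fst)


def sample_founder_haplotypes(
    freqs: PopulationFrequencies,
    n_per_pop: int,
    ld_templates: int | None = None,
    seed: int | np.random.Generator = 0,
    block_size: int = 25,
    chromosome: str = "chrS",
) -> FounderHaplotypes:
    """Sample phased founder haplotypes from population frequencies.

    With ``ld_templates=None`` every site is an independent Bernoulli draw
    given its population frequency.  With ``ld_templates=T`` each
    population first receives ``T`` template haplotypes; every founder is
    then a block mosaic of those templates (one template drawn per block
    of ``block_size`` SNPs), which induces within-block linkage
    disequilibrium so that non-causal SNPs can tag causal ones.
    """
    if n_per_pop < 2:
        raise ValueError("n_per_pop must be at least 2")
    if ld_templates is not None:
        if ld_templates < 1:
            raise ValueError("ld_templates must be positive")
        if ld_templates > n_per_pop:
            raise ValueError(
                f"ld_templates ({ld_templates}) may not exceed n_per_pop ({n_per_pop})"
            )
    rng = _as_rng(seed)
    m = freqs.n_snps

    blocks: list[tuple[int, int]] | None = None
    rows = []
    labels = []
    for pop in (1, 2):
        p = freqs.frequencies(pop)
        if ld_templates is None:
            rows.append((rng.random((n_per_pop, m)) < p).astype(np.int8))
        else:
            templates = (rng.random((ld_templates, m)) < p).astype(np.int8)
            starts = np.arange(0, m, block_size)
            blocks = [(int(s), int(min(s + block_size, m))) for s in starts]
            hap = np.empty((n_per_pop, m), dtype=np.int8)
            choice = rng.integers(0, ld_templates, size=(n_per_pop, len(starts)))
            for bi, (s, e) in enumerate(blocks):
                hap[:, s:e] = templates[choice[:, bi], s:e]
            rows.append(hap)
        labels.append(np.full(n_per_pop, pop, dtype=np.int8))

    return FounderHaplotypes(
        haplotypes=np.vstack(rows),
        pop_label=np.concatenate(labels),
        positions=freqs.positions,
        chromosome=chromosome,
        ld_blocks=blocks,
        model_frequencies=freqs,
    )


def import_vcf(
    path: str,
    sample_to_pop: dict[str, int],
    region: str | None = None,
) -> FounderHaplotypes:
    """Import phased founder haplotypes from a VCF file.

    Only phased, biallelic SNP records are used; multi-allelic and
    unphased records are skipped with a logged count.  VCF coordinates
    (1-based) are converted to the package's 0-based convention.

    Parameters
    ----------
    path : str
        Path to a (possibly bgzipped) VCF with phased genotypes.
    sample_to_pop : dict
        Maps VCF sample names to population labels 1 or 2.  Every mapped
        sample must exist in the file; unmapped samples are ignored.
    region : str, optional
        samtools-style 1-based region string, e.g. ``"20:1-50000"``
        (requires an indexed VCF when used).
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    if set(sample_to_pop.values()) - {1, 2}:
        raise ValueError("population labels must be 1 or 2")
    vcf = VCF(path)
    samples = list(sample_to_pop)
    missing = [s for s in samples if s not in vcf.samples]
    if missing:
        raise KeyError(f"samples absent from VCF: {missing}")
    col = [vcf.samples.index(s) for s in samples]

    positions: list[int] = []
    hap_cols: list[np.ndarray] = []
    chrom = None
    n_skipped = 0
    for var in (vcf(region) if region else vcf):
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gts = [var.genotypes[c] for c in col]
        if any(len(g) < 3 or not g[2] for g in gts) or any(
            g[0] < 0 or g[1] < 0 for g in gts
        ):
            n_skipped += 1  # unphased or missing genotype
            continue
        chrom = var.CHROM
        positions.append(var.POS - 1)
        hap_cols.append(np.array([[g[0], g[1]] for g in gts], dtype=np.int8).ravel())
    if n_skipped:
        logger.info("import_vcf: skipped %d non-biallelic/unphased records", n_skipped)
    if not positions:
        raise ValueError("no phased biallelic SNP records found")

    haplotypes = np.column_stack(hap_cols)
    pop_label = np.repeat([sample_to_pop[s] for s in samples], 2).astype(np.int8)
    return FounderHaplotypes(
        haplotypes=haplotypes,
        pop_label=pop_label,
        positions=np.array(positions, dtype=np.int64),
        chromosome=str(chrom),
    )
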