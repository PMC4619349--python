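"""Random-walk simulation of admixed chromosomes with true local ancestry.

Each admixed haplotype is built as a mosaic over founder haplotypes:
crossover breakpoints arrive along the chromosome with a small per-base-pair
probability (sampled as exponential inter-arrival distances, which is
equivalent at rates of order 1e-8 and vastly faster than per-base Bernoulli
trials), and at every breakpoint a new founder haplotype is drawn with
replacement, its population chosen according to the admixture proportions.
Two haplotypes are paired into an unphased individual; local ancestry is
summarized over equal-width segments as a 0/1/2 dosage counting the copies
of the reference ancestry, matching the coding used for two-way admixed
cohorts such as African Americans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .founders import FounderHaplotypes, PopulationFrequencies, _as_rng


@dataclass
class AncestryTrack:
    """Ancestry intervals of one haplotype, tiling ``[0, chrom_length)``.

    ``boundaries`` has length ``n_intervals + 1`` and starts at 0;
    ``interval_pop[i]`` is the population (1 or 2) of
    ``[boundaries[i], boundaries[i+1])``.  Adjacent intervals of the same
    population are merged on construction.
    """

    boundaries: np.ndarray
    interval_pop: np.ndarray

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=np.int64)
        self.interval_pop = np.asarray(self.interval_pop, dtype=np.int8)
        if len(self.boundaries) != len(self.interval_pop) + 1:
            raise ValueError("need exactly one more boundary than intervals")
        if self.boundaries[0] != 0:
            raise ValueError("track must start at coordinate 0")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        # merge runs of identical ancestry so the representation is canonical
        keep = np.concatenate([[True], np.diff(self.interval_pop) != 0])
        if not keep.all():
            self.interval_pop = self.interval_pop[keep]
            self.boundaries = np.concatenate(
                [self.boundaries[:-1][keep], self.boundaries[-1:]]
            )

    @property
    def chrom_length(self) -> int:
        return int(self.boundaries[-1])

    @property
    def n_switches(self) -> int:
        """Number of ancestry switch points (after merging)."""
        return len(self.interval_pop) - 1

    def ancestry_at(self, pos: int) -> int:
        """Population label at a base-pair position."""
        if not (0 <= pos < self.chrom_length):
            raise ValueError(f"position {pos} outside [0, {self.chrom_length})")
        i = int(np.searchsorted(self.boundaries, pos, side="right")) - 1
        return int(self.interval_pop[i])

    def fraction(self, pop: int) -> float:
        """Fraction of the chromosome carried on ``pop`` ancestry."""
        lengths = np.diff(self.boundaries)
        return float(lengths[self.interval_pop == pop].sum() / self.chrom_length)


@dataclass
class SegmentMap:
    """Equal-width local-ancestry segments tiling a chromosome."""

    n_segments: int
    chrom_length: int

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise ValueError("need at least 2 segments")
        if self.chrom_length < self.n_segments:
            raise ValueError("chromosome shorter than the number of segments")

    @property
    def boundaries(self) -> np.ndarray:
        return np.linspace(0, self.chrom_length, self.n_segments + 1).astype(np.int64)

    @property
    def starts(self) -> np.ndarray:
        return self.boundaries[:-1]

    @property
    def ends(self) -> np.ndarray:
        return self.boundaries[1:]

    def segment_of(self, pos: int) -> int:
        """Index of the segment containing a base-pair position."""
        if not (0 <= pos < self.chrom_length):
            raise ValueError("position outside chromosome")
        return int(np.searchsorted(self.boundaries, pos, side="right")) - 1


@dataclass
class AdmixedCohort:
    """Unphased genotypes with true local-ancestry dosages.

    Attributes
    ----------
    genotypes : (N, M) int8
        Genotype dosages in {0, 1, 2}, the sum of the two haplotypes.
    local_ancestry : (N, S) int8
        Per-segment count of the individual's chromosomes whose majority
        ancestry in the segment is ``reference_pop``.
    tracks : list of AncestryTrack
        2N tracks; individual ``i`` owns tracks ``2i`` and ``2i+1``.
    """

    genotypes: np.ndarray
    local_ancestry: np.ndarray
    tracks: list[AncestryTrack]
    segment_map: SegmentMap
    positions: np.ndarray
    chromosome: str = "chrS"
    reference_pop: int = 2
    haplotypes: np.ndarray | None = field(default=None, repr=False)
    model_frequencies: PopulationFrequencies | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.local_ancestry = np.asarray(self.local_ancestry, dtype=np.int8)
        if self.genotypes.shape[0] != self.local_ancestry.shape[0]:
            raise ValueError("genotype and ancestry matrices disagree on N")
        if len(self.tracks) != 2 * self.genotypes.shape[0]:
            raise ValueError("expected two ancestry tracks per individual")
        if self.local_ancestry.shape[1] != self.segment_map.n_segments:
            raise ValueError("ancestry matrix disagrees with segment map")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_segments(self) -> int:
        return self.segment_map.n_segments

    def snps_in_segment(self, segment: int) -> np.ndarray:
        """Indices of SNPs whose position falls in a segment."""
        s, e = self.segment_map.starts[segment], self.segment_map.ends[segment]
        return np.nonzero((self.positions >= s) & (self.positions < e))[0]


def simulate_haplotype(
    founders: FounderHaplotypes,
    chrom_length: int,
    recomb_rate: float = 1e-8,
    admix_props: tuple[float, float] = (0.2, 0.8),
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, AncestryTrack]:
    """Simulate one admixed haplotype as a random walk over founders.

    Crossover positions are sampled with exponential inter-arrival
    distances at ``recomb_rate`` per base pair.  The founder copied in
    each inter-crossover interval is drawn with replacement: population 1
    with probability ``admix_props[0]``, population 2 otherwise, then a
    uniform haplotype within that population.  Re-drawing a founder of the
    same population produces no ancestry switch (runs are merged).

    Returns the allele vector over ``founders.positions`` and the true
    ancestry track.
    """
    if founders.n_haplotypes == 0:
        raise ValueError("founder panel is empty")
    if recomb_rate < 0:
        raise ValueError("recomb_rate must be non-negative")
    if abs(sum(admix_props) - 1.0) > 1e-9 or min(admix_props) < 0:
        raise ValueError("admix_props must be non-negative and sum to 1")
    rng = _as_rng(seed)

    # crossover breakpoints: exponential gaps, truncated at chromosome end
    cuts = [0]
    if recomb_rate > 0:
        pos = 0.0
        while True:
            pos += rng.exponential(1.0 / recomb_rate)
            if pos >= chrom_length:
                break
            cuts.append(int(np.ceil(pos)))
    boundaries = np.array(cuts + [chrom_length], dtype=np.int64)
    n_int = len(boundaries) - 1

    pops = np.where(rng.random(n_int) < admix_props[0], 1, 2).astype(np.int8)
    idx_by_pop = {p: np.nonzero(founders.pop_label == p)[0] for p in (1, 2)}
    for p in (1, 2):
        if admix_props[p - 1] > 0 and len(idx_by_pop[p]) == 0:
            raise ValueError(f"founder panel has no population-{p} haplotypes")

    allele = np.empty(founders.n_snps, dtype=np.int8)
    snp_cut = np.searchsorted(founders.positions, boundaries)
    for i in range(n_int):
        pool = idx_by_pop[pops[i]]
        donor = pool[rng.integers(len(pool))]
        allele[snp_cut[i]:snp_cut[i + 1]] = founders.haplotypes[donor, snp_cut[i]:snp_cut[i + 1]]

    return allele, AncestryTrack(boundaries=boundaries, interval_pop=pops)


def segment_ancestry_dosage(
    tracks: tuple[AncestryTrack, AncestryTrack] | list[AncestryTrack],
    segment_map: SegmentMap,
    reference_pop: int = 2,
) -> np.ndarray:
    """Per-segment 0/1/2 dosage of the reference ancestry for one individual.

    Each haplotype contributes 1 to a segment when the reference
    population covers the majority of the segment's base pairs; an exact
    tie is broken by the ancestry at the segment midpoint.
    """
    if len(tracks) != 2:
        raise ValueError("an individual has exactly two ancestry tracks")
    dosage = np.zeros(segment_map.n_segments, dtype=np.int8)
    starts, ends = segment_map.starts, segment_map.ends
    for track in tracks:
        if track.chrom_length < segment_map.chrom_length:
            raise ValueError("track does not span the segment map")
        cover = np.zeros(segment_map.n_segments, dtype=np.int64)
        for i, pop in enumerate(track.interval_pop):
            if pop != reference_pop:
                continue
            lo, hi = track.boundaries[i], track.boundaries[i + 1]
            overlap = np.minimum(ends, hi) - np.maximum(starts, lo)
            cover += np.maximum(overlap, 0)
        width = ends - starts
        is_ref = cover * 2 > width
        tie = cover * 2 == width
        if tie.any():
            mids = (starts[tie] + ends[tie]) // 2
            is_ref[tie] = [track.ancestry_at(int(m)) == reference_pop for m in mids]
        dosage += is_ref.astype(np.int8)
    return dosage


def build_cohort(
    founders: FounderHaplotypes,
    n_individuals: int,
    chrom_length: int,
    recomb_rate: float = 1e-8,
    admix_props: tuple[float, float] = (0.2, 0.8),
    n_segments: int = 10,
    seed: int | np.random.Generator = 0,
    reference_pop: int = 2,
) -> AdmixedCohort:
    """Simulate an admixed cohort of unphased individuals.

    Simulates ``2 * n_individuals`` haplotypes with :func:`simulate_haplotype`,
    pairs consecutive haplotypes into individuals, and populates genotype
    dosages (haplotype sums) and true local-ancestry dosages over
    ``n_segments`` equal-width segments.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if n_segments > founders.n_snps:
        raise ValueError("more segments than SNPs in the founder panel")
    rng = _as_rng(seed)
    segment_map = SegmentMap(n_segments=n_segments, chrom_length=chrom_length)

    haplotypes = np.empty((2 * n_individuals, founders.n_snps), dtype=np.int8)
    tracks: list[AncestryTrack] = []
    for h in range(2 * n_individuals):
        allele, track = simulate_haplotype(
            founders, chrom_length, recomb_rate, admix_props, rng
        )
        haplotypes[h] = allele
        tracks.append(track)

    genotypes = haplotypes[0::2] + haplotypes[1::2]
    local_anc = np.empty((n_individuals, n_segments), dtype=np.int8)
    for i in range(n_individuals):
        local_anc[i] = segment_ancestry_dosage(
            tracks[2 * i : 2 * i + 2], segment_map, reference_pop
        )

    return AdmixedCohort(
        genotypes=genotypes,
        local_ancestry=local_anc,
        tracks=tracks,
        segment_map=segment_map,
        positions=founders.positions,
        chromosome=founders.chromosome,
        reference_pop=reference_pop,
        haplotypes=haplotypes,
        model_frequencies=founders.model_frequencies,
    )


def _expected_dosage_r(q: float, p1: float, p2: float, c12: float) -> float:
    """Expected corr(D, D') when each haplotype label is flipped with prob q.

    ``p1``/``p2`` are the means of the two per-haplotype reference
    indicators and ``c12`` their covariance; flipping attenuates every
    label (co)variance by ``1 - 2q`` and shifts means toward 1/2.
    """
    v1, v2 = p1 * (1 - p1), p2 * (1 - p2)
    var_d = v1 + v2 + 2 * c12
    k = 1.0 - 2.0 * q
    p1o, p2o = p1 + q * (1 - 2 * p1), p2 + q * (1 - 2 * p2)
    var_out = p1o * (1 - p1o) + p2o * (1 - p2o) + 2 * k * k * c12
    return k * var_d / np.sqrt(var_d * var_out)


def degrade_ancestry(
    local_ancestry: np.ndarray,
    target_r2: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Emulate local-ancestry inference error at a chosen accuracy.

    The 0/1/2 dosage matrix is decomposed into two per-haplotype reference
    indicators; each indicator is flipped independently with a
    misclassification probability ``q`` calibrated by root search so that
    the expected squared correlation between input and output dosages
    equals ``target_r2``.  ``target_r2=1`` returns the input unchanged.
    Typical published accuracies are ~0.99 for African Americans and
    0.63-0.81 for Latino populations.
    """
    if not (0 < target_r2 <= 1):
        raise ValueError(f"target_r2 must lie in (0, 1], got {target_r2!r}")
    d = np.asarray(local_ancestry, dtype=np.int8)
    if target_r2 == 1.0:
        return d.copy()
    if d.min() == d.max():
        raise ValueError("ancestry matrix is constant; nothing to degrade")
    lab1 = (d >= 1).astype(np.int8)  # het individuals carry their single copy here
    lab2 = (d == 2).astype(np.int8)
    p1, p2 = float(lab1.mean()), float(lab2.mean())
    c12 = float(np.mean(lab1 * lab2)) - p1 * p2
    q = optimize.brentq(
        lambda x: _expected_dosage_r(x, p1, p2, c12) ** 2 - target_r2,
        1e-12,
        0.5 - 1e-12,
    )
    rng = _as_rng(seed)
    out = np.zeros_like(d)
    for lab in (lab1, lab2):
        flip = rng.random(d.shape) < q
        out += np.where(flip, 1 - lab, lab).astype(np.int8)
    return out
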