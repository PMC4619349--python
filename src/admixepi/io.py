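"""Plain-text interchange: TSV tables, BED-like tracks, and simple VCF export.

TSV (tab-separated, header row, '.' for missing) is the interchange
dialect throughout; local-ancestry dosages follow the LAMP-LD-style
convention of one row per individual and one integer 0/1/2 column per
segment.  Tracks are written 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .admixture import AdmixedCohort, AncestryTrack
from .founders import FounderHaplotypes, PopulationFrequencies


def write_frequency_panel(freqs: PopulationFrequencies, path: str, chromosome: str = "chrS") -> None:
    """One row per SNP: chrom, pos, freq_pop1, freq_pop2."""
    pd.DataFrame({
        "chrom": chromosome,
        "pos": freqs.positions,
        "freq_pop1": freqs.freq_pop1,
        "freq_pop2": freqs.freq_pop2,
    }).to_csv(path, sep="\t", index=False)


def read_frequency_panel(path: str, fst: float) -> PopulationFrequencies:
    df = pd.read_csv(path, sep="\t")
    return PopulationFrequencies(
        positions=df["pos"].to_numpy(),
        freq_pop1=df["freq_pop1"].to_numpy(),
        freq_pop2=df["freq_pop2"].to_numpy(),
        fst=fst,
    )


def write_haplotypes_tsv(founders: FounderHaplotypes, path: str) -> None:
    """Haplotype matrix with a leading population-label column."""
    df = pd.DataFrame(founders.haplotypes,
                      columns=[f"pos{p}" for p in founders.positions])
    df.insert(0, "pop", founders.pop_label)
    df.to_csv(path, sep="\t", index=False)


def write_ancestry_tsv(local_ancestry: np.ndarray, path: str,
                       individual_ids: list[str] | None = None) -> None:
    """LAMP-LD-style dosages: one row per individual, one 0/1/2 column per segment."""
    la = np.asarray(local_ancestry)
    ids = individual_ids or [f"ind{i}" for i in range(la.shape[0])]
    df = pd.DataFrame(la, columns=[f"seg{s}" for s in range(la.shape[1])])
    df.insert(0, "individual", ids)
    df.to_csv(path, sep="\t", index=False)


def read_ancestry_tsv(path: str) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.drop(columns=["individual"]).to_numpy(dtype=np.int8)


def write_tracks_bed(tracks: list[AncestryTrack], path: str, chromosome: str = "chrS") -> None:
    """BED-like, 0-based half-open: chrom, start, end, hap_id, pop."""
    rows = []
    for h, track in enumerate(tracks):
        for i, pop in enumerate(track.interval_pop):
            rows.append((chromosome, int(track.boundaries[i]),
                         int(track.boundaries[i + 1]), f"hap{h}", int(pop)))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "hap_id", "pop"]).to_csv(
        path, sep="\t", index=False, header=False)


def write_phenotypes_tsv(Y: np.ndarray, Z1: np.ndarray, Z2: np.ndarray, path: str,
                         individual_ids: list[str] | None = None) -> None:
    ids = individual_ids or [f"ind{i}" for i in range(len(Y))]
    pd.DataFrame({"individual": ids, "Y": Y, "Z1": Z1, "Z2": Z2}).to_csv(
        path, sep="\t", index=False)


def read_phenotypes_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phased_vcf(
    positions: np.ndarray,
    haplotypes: np.ndarray,
    path: str,
    chromosome: str = "chrS",
    sample_ids: list[str] | None = None,
) -> None:
    """Write phased haplotypes (2N x M, 0/1) as a minimal VCF 4.2 file.

    Positions are converted from the package's 0-based convention to
    VCF's 1-based coordinates.  Consecutive haplotype rows are paired
    into samples.
    """
    hap = np.asarray(haplotypes)
    if hap.shape[0] % 2:
        raise ValueError("need an even number of haplotype rows")
    n = hap.shape[0] // 2
    ids = sample_ids or [f"ind{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chromosome}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        for m, pos in enumerate(positions):
            gts = "\t".join(f"{hap[2*i, m]}|{hap[2*i+1, m]}" for i in range(n))
            fh.write(f"{chromosome}\t{int(pos)+1}\tsnp{m}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_genotype_tsv(cohort: AdmixedCohort, path: str,
                       individual_ids: list[str] | None = None) -> None:
    ids = individual_ids or [f"ind{i}" for i in range(cohort.n_individuals)]
    df = pd.DataFrame(cohort.genotypes,
                      columns=[f"pos{p}" for p in cohort.positions])
    df.insert(0, "individual", ids)
    df.to_csv(path, sep="\t", index=False)


def write_results_tsv(results: pd.DataFrame, path: str) -> None:
    results.to_csv(path, sep="\t", index=False, na_rep=".")


def ensure_dir(path: str) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
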