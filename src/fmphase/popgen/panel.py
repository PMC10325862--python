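"""Phased biallelic haplotype panel: the in-memory unit of the sweep scan.

Backed by a haplotypes-by-sites 0/1 matrix (two rows per diploid sample,
phased), with reference positions and a sample -> population map.  Reading
and writing go through pysam's VCF machinery (plain-text VCF 4.2, phased GT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam


@dataclass
class HaplotypePanel:
    chrom: str
    positions: np.ndarray  # (S,) 1-based, strictly increasing
    haplotypes: np.ndarray  # (2N, S) int8 in {0, 1}
    samples: list[str]  # length N; haplotype rows 2i, 2i+1 belong to sample i
    populations: dict[str, str]  # sample -> population label

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (2 * len(self.samples), self.positions.size):
            raise ValueError("haplotype matrix shape mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.positions.size

    def pop_labels(self) -> list[str]:
        seen = []
        for s in self.samples:
            p = self.populations[s]
            if p not in seen:
                seen.append(p)
        return seen

    def haplotype_rows(self, population: str) -> np.ndarray:
        rows = []
        for i, s in enumerate(self.samples):
            if self.populations[s] == population:
                rows.extend((2 * i, 2 * i + 1))
        return np.asarray(rows, dtype=np.int64)

    def subset_sites(self, mask: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(
            self.chrom,
            self.positions[mask],
            self.haplotypes[:, mask],
            self.samples,
            self.populations,
        )

    # -- VCF round trip ----------------------------------------------------

    def to_vcf(self, path: str, chrom_length: int | None = None) -> None:
        header = pysam.VariantHeader()
        length = int(chrom_length or (int(self.positions[-1]) + 1000))
        header.contigs.add(self.chrom, length=length)
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
        for s in self.samples:
            header.add_sample(s)
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for j, pos in enumerate(self.positions.tolist()):
                rec = vcf.new_record(
                    contig=self.chrom, start=pos - 1, stop=pos, alleles=("A", "T")
                )
                for i, s in enumerate(self.samples):
                    rec.samples[s]["GT"] = (
                        int(self.haplotypes[2 * i, j]),
                        int(self.haplotypes[2 * i + 1, j]),
                    )
                    rec.samples[s].phased = True
                    rec.samples[s]["PS"] = 1
                vcf.write(rec)

    @classmethod
    def from_vcf(cls, path: str, populations: dict[str, str]) -> "HaplotypePanel":
        """Load a phased, biallelic VCF; sites failing either are skipped."""
        with pysam.VariantFile(str(path)) as vcf:
            samples = [s for s in vcf.header.samples if s in populations]
            if not samples:
                raise ValueError("no VCF sample appears in the population map")
            chrom = None
            positions, columns = [], []
            for rec in vcf:
                if rec.alts is None or len(rec.alts) != 1:
                    continue
                chrom = rec.chrom if chrom is None else chrom
                if rec.chrom != chrom:
                    raise ValueError("panel must be single-chromosome")
                col = np.empty(2 * len(samples), dtype=np.int8)
                ok = True
                for i, s in enumerate(samples):
                    gt = rec.samples[s]["GT"]
                    if gt is None or None in gt or len(gt) != 2:
                        ok = False
                        break
                    col[2 * i], col[2 * i + 1] = gt
                if ok:
                    positions.append(rec.pos)
                    columns.append(col)
        if not positions:
            raise ValueError("no usable sites in VCF")
        return cls(
            chrom=chrom,
            positions=np.asarray(positions),
            haplotypes=np.stack(columns, axis=1),
            samples=samples,
            populations={s: populations[s] for s in samples},
        )


def read_population_map(path: str) -> dict[str, str]:
    """TSV of (sample, population); comment lines start with '#'."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split()[:2]
            out[sample] = pop
    return out


def write_population_map(populations: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for sample, pop in populations.items():
            fh.write(f"{sample}\t{pop}\n")
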