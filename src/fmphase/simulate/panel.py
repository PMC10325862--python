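"""Multi-population haplotype panel simulator for the sweep scan.

Neutral variants are drawn from the standard neutral site-frequency spectrum
(derived-allele count k with probability proportional to 1/k, whose folded
form is proportional to 1/i + 1/(n-i)).  Population differentiation is
induced Balding-Nichols style: each population's allele frequency is a Beta
draw around the ancestral frequency with a per-population drift parameter F,
so a pair of populations with equal drift F has expected Hudson F_ST of
about F.  An optional planted sweep sets a configurable fraction of one
population's haplotypes to a shared template over a window, producing the
diversity loss and long-range haplotype homozygosity of a selective sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..popgen.panel import HaplotypePanel


@dataclass(frozen=True)
class SweepConfig:
    population: str
    center: int
    width: int
    frequency: float  # swept-haplotype frequency in the target population

    def __post_init__(self) -> None:
        if not 0.0 < self.frequency <= 1.0:
            raise ValueError("sweep frequency must be in (0, 1]")

    @property
    def window(self) -> tuple[int, int]:
        half = self.width // 2
        return self.center - half, self.center + half


@dataclass(frozen=True)
class PanelConfig:
    """Conditions for the synthetic panel (defaults mirror a two-breed contrast

    of nine diploids per population, the sampling depth of the focal
    comparison the scan is designed for).
    """

    seed: int = 0
    chrom: str = "20"
    chrom_length: int = 1_000_000
    n_sites: int = 10_000
    populations: tuple[str, ...] = ("KADK", "CHIN")
    n_diploids: tuple[int, ...] = (9, 9)
    #: per-population Balding-Nichols drift parameter (0 = panmictic null)
    drift: tuple[float, ...] = (0.0, 0.0)
    sweep: SweepConfig | None = None

    def validate(self) -> None:
        if len(self.populations) < 2:
            raise ValueError("need >= 2 populations")
        if not (len(self.populations) == len(self.n_diploids) == len(self.drift)):
            raise ValueError("populations / n_diploids / drift length mismatch")
        for n in self.n_diploids:
            if 2 * n < 4:
                raise ValueError("need >= 4 haplotypes per population")
        for f in self.drift:
            if not 0.0 <= f < 1.0:
                raise ValueError("drift parameter must be in [0, 1)")
        if self.sweep and self.sweep.population not in self.populations:
            raise ValueError("sweep population not in panel")


def _neutral_counts(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    """Derived-allele counts k in 1..n-1 with P(k) proportional to 1/k."""
    k = np.arange(1, n)
    p = 1.0 / k
    p /= p.sum()
    return rng.choice(k, size=size, p=p)


def simulate_panel(cfg: PanelConfig) -> HaplotypePanel:
    """Generate a phased panel; sites monomorphic across the panel are dropped."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    positions = np.sort(rng.choice(cfg.chrom_length, size=cfg.n_sites, replace=False)) + 1

    samples, populations = [], {}
    for pop, n in zip(cfg.populations, cfg.n_diploids):
        for i in range(n):
            name = f"{pop}_{i}"
            samples.append(name)
            populations[name] = pop
    n_total_h = 2 * sum(cfg.n_diploids)

    H = np.zeros((n_total_h, cfg.n_sites), dtype=np.int8)
    if all(f == 0.0 for f in cfg.drift):
        # single panmictic pool: place k derived copies on random haplotypes
        counts = _neutral_counts(rng, n_total_h, cfg.n_sites)
        for j, k in enumerate(counts):
            rows = rng.choice(n_total_h, size=int(k), replace=False)
            H[rows, j] = 1
    else:
        anc = _neutral_counts(rng, n_total_h, cfg.n_sites) / n_total_h
        row = 0
        for pop, n, F in zip(cfg.populations, cfg.n_diploids, cfg.drift):
            nh = 2 * n
            if F > 0.0:
                a = anc * (1.0 - F) / F
                b = (1.0 - anc) * (1.0 - F) / F
                freqs = rng.beta(a, b)
            else:
                freqs = anc
            H[row : row + nh, :] = rng.random((nh, cfg.n_sites)) < freqs
            row += nh

    if cfg.sweep is not None:
        sw = cfg.sweep
        lo, hi = sw.window
        in_win = (positions >= lo) & (positions <= hi)
        pop_rows = []
        r = 0
        for pop, n in zip(cfg.populations, cfg.n_diploids):
            if pop == sw.population:
                pop_rows = list(range(r, r + 2 * n))
            r += 2 * n
        template = H[pop_rows[0], in_win].copy()
        carriers = [row for row in pop_rows if rng.random() < sw.frequency]
        for row in carriers:
            H[row, in_win] = template

    poly = (H.sum(axis=0) > 0) & (H.sum(axis=0) < n_total_h)
    return HaplotypePanel(
        chrom=cfg.chrom,
        positions=positions[poly],
        haplotypes=H[:, poly],
        samples=samples,
        populations=populations,
    )


# --------------------------------------------------------------------------
# Masks


@dataclass(frozen=True)
class MaskConfig:
    """Callability / repeat mask patches to emit alongside the panel."""

    n_low_callable_patches: int = 0
    low_callable_len: int = 30_000
    n_repeat_patches: int = 0
    repeat_len: int = 30_000


def simulate_masks(
    cfg: PanelConfig, masks: MaskConfig, rng: np.random.Generator | None = None
) -> tuple[list[tuple[str, int, int]], list[tuple[str, int, int]]]:
    """(callable intervals, repeat intervals), both BED-style 0-based half-open.

    The callable mask covers the chromosome minus the low-callability
    patches; the repeat mask lists the repeat patches themselves.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 9])
    holes = sorted(
        int(rng.integers(0, max(1, cfg.chrom_length - masks.low_callable_len)))
        for _ in range(masks.n_low_callable_patches)
    )
    callable_iv: list[tuple[str, int, int]] = []
    cursor = 0
    for h in holes:
        h_end = min(cfg.chrom_length, h + masks.low_callable_len)
        if h > cursor:
            callable_iv.append((cfg.chrom, cursor, h))
        cursor = max(cursor, h_end)
    if cursor < cfg.chrom_length:
        callable_iv.append((cfg.chrom, cursor, cfg.chrom_length))
    repeats = []
    for _ in range(masks.n_repeat_patches):
        s = int(rng.integers(0, max(1, cfg.chrom_length - masks.repeat_len)))
        repeats.append((cfg.chrom, s, s + masks.repeat_len))
    repeats.sort()
    return callable_iv, repeats


def write_bed(intervals: list[tuple[str, int, int]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")
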