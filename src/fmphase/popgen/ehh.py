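"""Extended haplotype homozygosity: EHH decay, iHH, iHS and XP-EHH.

EHH at distance d from a core site is the probability that two randomly
drawn carrier haplotypes are identical over the whole interval between the
core and d.  iHH integrates the decay curve over physical distance
(trapezoid rule) until EHH falls below a truncation threshold.  Scores are
unpolarised: the majority allele plays the "ancestral" role, so the
unstandardised iHS is ln(iHH_major / iHH_minor), later standardised to zero
mean and unit variance within minor-allele-frequency bins.  XP-EHH compares
pooled-core iHH between two populations and is standardised genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import HaplotypePanel


@dataclass
class EHHDecay:
    """Decay curves and integrals at one core site."""

    core_pos: int
    #: allele code -> (distances from core, EHH values), both starting at (0, 1)
    curves: dict = field(default_factory=dict)
    ihh: dict = field(default_factory=dict)
    freq: dict = field(default_factory=dict)

    def unstandardized_ihs(self) -> float | None:
        """ln(iHH of majority allele / iHH of minority allele)."""
        if len(self.ihh) != 2:
            return None
        (a1, f1), (a2, f2) = sorted(self.freq.items())
        major, minor = (a1, a2) if f1 >= f2 else (a2, a1)
        if self.ihh[major] <= 0 or self.ihh[minor] <= 0:
            return None
        return float(np.log(self.ihh[major] / self.ihh[minor]))


def _ehh_curve(
    h: np.ndarray,
    positions: np.ndarray,
    core_idx: int,
    min_ehh: float,
    max_gap: int,
) -> tuple[np.ndarray, np.ndarray]:
    """EHH curve for one haplotype group, both sides merged onto |distance|.

    ``h`` is the (carriers x sites) matrix.  Returns (distances, ehh) with
    the core at distance 0, each side truncated at ``min_ehh`` or at a gap
    larger than ``max_gap``.
    """
    n = h.shape[0]
    if n < 2:
        raise ValueError("need >= 2 carrier haplotypes")
    denom = n * (n - 1)
    dists = [0.0]
    ehhs = [1.0]
    for step in (1, -1):
        ids = np.zeros(n, dtype=np.int64)
        k = core_idx
        prev_pos = positions[core_idx]
        while True:
            k += step
            if k < 0 or k >= positions.size:
                break
            if abs(int(positions[k]) - int(prev_pos)) > max_gap:
                break
            prev_pos = positions[k]
            ids = ids * 2 + h[:, k]
            _, ids = np.unique(ids, return_inverse=True)
            counts = np.bincount(ids)
            ehh = float((counts * (counts - 1)).sum() / denom)
            dists.append(abs(int(positions[k]) - int(positions[core_idx])))
            ehhs.append(ehh)
            if ehh < min_ehh:
                break
    order = np.argsort(dists, kind="stable")
    return np.asarray(dists, dtype=float)[order], np.asarray(ehhs, dtype=float)[order]


def _ihh_one_side(
    h: np.ndarray, positions: np.ndarray, core_idx: int, step: int, min_ehh: float, max_gap: int
) -> float:
    """Trapezoid integral of EHH over one side, truncated below ``min_ehh``."""
    n = h.shape[0]
    denom = n * (n - 1)
    ids = np.zeros(n, dtype=np.int64)
    total = 0.0
    prev_pos = int(positions[core_idx])
    prev_ehh = 1.0
    k = core_idx
    while True:
        k += step
        if k < 0 or k >= positions.size:
            break
        pos = int(positions[k])
        if abs(pos - prev_pos) > max_gap:
            break
        ids = ids * 2 + h[:, k]
        _, ids = np.unique(ids, return_inverse=True)
        counts = np.bincount(ids)
        ehh = float((counts * (counts - 1)).sum() / denom)
        total += 0.5 * (prev_ehh + ehh) * abs(pos - prev_pos)
        prev_pos, prev_ehh = pos, ehh
        if ehh < min_ehh:
            break
    return total


def ehh_scan(
    panel: HaplotypePanel,
    core_pos: int,
    population: str,
    min_ehh: float = 0.05,
    max_gap: int = 200_000,
) -> EHHDecay | None:
    """Allele-specific EHH decay and iHH at one core site in one population.

    Returns None when the core is not biallelic with >= 2 carriers per
    allele in that population.
    """
    rows = panel.haplotype_rows(population)
    H = panel.haplotypes[rows]
    idx = int(np.searchsorted(panel.positions, core_pos))
    if idx >= panel.positions.size or panel.positions[idx] != core_pos:
        raise ValueError(f"no site at position {core_pos}")
    out = EHHDecay(core_pos=core_pos)
    n = H.shape[0]
    for allele in (0, 1):
        carriers = H[:, idx] == allele
        nc = int(carriers.sum())
        if nc < 2:
            return None
        sub = H[carriers]
        d, e = _ehh_curve(sub, panel.positions, idx, min_ehh, max_gap)
        ihh = _ihh_one_side(sub, panel.positions, idx, +1, min_ehh, max_gap) + _ihh_one_side(
            sub, panel.positions, idx, -1, min_ehh, max_gap
        )
        out.curves[allele] = (d, e)
        out.ihh[allele] = ihh
        out.freq[allele] = nc / n
    return out


def ihs_scan(
    panel: HaplotypePanel,
    population: str,
    min_maf: float = 0.05,
    min_ehh: float = 0.05,
    max_gap: int = 200_000,
    n_bins: int = 20,
) -> "np.recarray":
    """Standardised iHS for every eligible site of one population.

    Unstandardised scores are z-scored within ``n_bins`` equal-occupancy
    minor-allele-frequency bins, the usual correction for the frequency
    dependence of haplotype homozygosity.
    """
    rows = panel.haplotype_rows(population)
    H = panel.haplotypes[rows]
    n = H.shape[0]
    freqs = H.mean(axis=0)
    maf = np.minimum(freqs, 1 - freqs)
    positions, raw, mafs = [], [], []
    for idx in range(panel.positions.size):
        if maf[idx] < min_maf:
            continue
        major = 1 if freqs[idx] >= 0.5 else 0
        ihh = {}
        ok = True
        for allele in (major, 1 - major):
            sub = H[H[:, idx] == allele]
            if sub.shape[0] < 2:
                ok = False
                break
            ihh[allele] = _ihh_one_side(
                sub, panel.positions, idx, +1, min_ehh, max_gap
            ) + _ihh_one_side(sub, panel.positions, idx, -1, min_ehh, max_gap)
        if not ok or ihh[major] <= 0 or ihh[1 - major] <= 0:
            continue
        positions.append(int(panel.positions[idx]))
        raw.append(float(np.log(ihh[major] / ihh[1 - major])))
        mafs.append(float(maf[idx]))
    positions = np.asarray(positions)
    raw = np.asarray(raw)
    mafs = np.asarray(mafs)
    std = standardize_in_bins(raw, mafs, n_bins)
    rec = np.rec.fromarrays(
        [positions, raw, mafs, std], names=["pos", "ihs_raw", "maf", "ihs"]
    )
    return rec


def standardize_in_bins(values: np.ndarray, by: np.ndarray, n_bins: int) -> np.ndarray:
    """Z-score values within equal-occupancy bins of the ``by`` variable."""
    out = np.full_like(values, np.nan, dtype=float)
    if values.size == 0:
        return out
    qs = np.quantile(by, np.linspace(0, 1, n_bins + 1))
    qs[0] -= 1e-12
    bins = np.clip(np.searchsorted(qs, by, side="right") - 1, 0, n_bins - 1)
    for b in range(n_bins):
        sel = bins == b
        if sel.sum() < 2:
            continue
        mu, sd = values[sel].mean(), values[sel].std()
        if sd > 0:
            out[sel] = (values[sel] - mu) / sd
        else:
            out[sel] = 0.0
    return out


def xpehh_scan(
    panel: HaplotypePanel,
    pop_pair: tuple[str, str],
    min_ehh: float = 0.05,
    max_gap: int = 200_000,
) -> "np.recarray":
    """Genome-standardised XP-EHH (pop1 vs pop2) at every site.

    Pooled-core iHH (all haplotypes of a population, no allele split) per
    population; positive standardised values mean longer haplotype
    homozygosity in pop1.
    """
    out_pos, out_raw = [], []
    rows1 = panel.haplotype_rows(pop_pair[0])
    rows2 = panel.haplotype_rows(pop_pair[1])
    H1 = panel.haplotypes[rows1]
    H2 = panel.haplotypes[rows2]
    for idx in range(panel.positions.size):
        vals = []
        for H in (H1, H2):
            ihh = _ihh_one_side(H, panel.positions, idx, +1, min_ehh, max_gap) + _ihh_one_side(
                H, panel.positions, idx, -1, min_ehh, max_gap
            )
            vals.append(ihh)
        if vals[0] <= 0 or vals[1] <= 0:
            continue
        out_pos.append(int(panel.positions[idx]))
        out_raw.append(float(np.log(vals[0] / vals[1])))
    raw = np.asarray(out_raw)
    std = (raw - raw.mean()) / raw.std() if raw.size > 1 and raw.std() > 0 else raw * 0.0
    return np.rec.fromarrays(
        [np.asarray(out_pos), raw, std], names=["pos", "xpehh_raw", "xpehh"]
    )
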