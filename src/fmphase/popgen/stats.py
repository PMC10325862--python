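"""Diversity and differentiation estimators on phased haplotype panels.

All estimators work from the folded frequency spectrum (no ancestral
polarisation): per-window nucleotide diversity (pi), Watterson's theta,
Tajima's D, the outgroup-free Fu & Li D* (singletons counted as
minor-allele-count-1 sites), Hudson's F_ST as a ratio of averages, and
absolute divergence D_xy.  Formula conventions follow Tajima (1989),
Fu & Li (1993) and Bhatia et al. (2013).
"""

from __future__ import annotations

import numpy as np


def harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i**power))


# --------------------------------------------------------------------------
# Within-population diversity


def pairwise_diversity(counts: np.ndarray, n: int) -> float:
    """Sum over sites of mean pairwise differences, 2c(n-c)/(n(n-1))."""
    c = counts.astype(float)
    return float(np.sum(2.0 * c * (n - c) / (n * (n - 1))))


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator (per locus, divide by effective sites for per-bp)."""
    return S / harmonic(n)


def tajimas_d(counts: np.ndarray, n: int) -> float:
    """Tajima's D from derived/minor allele counts of segregating sites."""
    S = int(np.sum((counts > 0) & (counts < n)))
    if S == 0:
        return float("nan")
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = pairwise_diversity(counts, n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((pi - S / a1) / np.sqrt(var))


def fu_li_d_star(counts: np.ndarray, n: int) -> float:
    """Fu & Li's D* -- the outgroup-free form contrasting singletons with S.

    Folded data cannot distinguish a derived singleton from count n-1, so a
    singleton is any site with minor allele count 1, exactly the quantity
    D* was designed around.
    """
    if n < 3:
        return float("nan")
    seg = (counts > 0) & (counts < n)
    S = int(np.sum(seg))
    if S == 0:
        return float("nan")
    minor = np.minimum(counts, n - counts)
    eta_s = int(np.sum(seg & (minor == 1)))
    an = harmonic(n)
    bn = harmonic(n, 2)
    an1 = an + 1.0 / n
    cn = 2.0 * (n * an - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / ((n - 1) ** 2)
        + (2.0 / (n - 1)) * (1.5 - (2.0 * an1 - 3.0) / (n - 2) - 1.0 / n)
    )
    nn = float(n)
    v = ((nn / (nn - 1)) ** 2 * bn + an**2 * dn - 2.0 * nn * an * (an + 1) / ((nn - 1) ** 2)) / (
        an**2 + bn
    )
    u = (nn / (nn - 1)) * (an - nn / (nn - 1)) - v
    var = u * S + v * S**2
    if var <= 0:
        return float("nan")
    return float((nn / (nn - 1) * S - an * eta_s) / np.sqrt(var))


def diversity_stats(
    haplotypes: np.ndarray, effective_sites: float
) -> dict[str, float]:
    """pi, theta_W (both per effective site), Tajima's D and Fu & Li's D*.

    ``haplotypes`` is an (n, S) 0/1 matrix of one population's phased
    haplotypes over the window's sites; ``effective_sites`` is the number
    of callable bases in the window.
    """
    n = haplotypes.shape[0]
    if n < 4:
        raise ValueError("need >= 4 haplotypes")
    counts = haplotypes.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    eff = max(float(effective_sites), 1.0)
    return {
        "n": n,
        "S": S,
        "pi": pairwise_diversity(counts, n) / eff,
        "theta_w": watterson_theta(S, n) / eff,
        "tajimas_d": tajimas_d(counts, n),
        "fu_li_d_star": fu_li_d_star(counts, n),
    }


# --------------------------------------------------------------------------
# Between-population differentiation


def hudson_fst_components(
    h1: np.ndarray, h2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Hudson numerator/denominator (Bhatia et al. 2013, eq. 10).

    Returns (N, D, polymorphic-in-pair mask).  N and D are defined at every
    site; the mask marks sites segregating in the pooled pair, the site set
    the windowed ratio-of-averages runs over.
    """
    n1, n2 = h1.shape[0], h2.shape[0]
    p1 = h1.mean(axis=0)
    p2 = h2.mean(axis=0)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    pooled = h1.sum(axis=0) + h2.sum(axis=0)
    poly = (pooled > 0) & (pooled < n1 + n2)
    return num, den, poly


def hudson_fst(h1: np.ndarray, h2: np.ndarray) -> float:
    """Windowed Hudson F_ST as a ratio of averages over polymorphic sites."""
    num, den, poly = hudson_fst_components(h1, h2)
    if not poly.any() or den[poly].sum() <= 0:
        return float("nan")
    return float(num[poly].sum() / den[poly].sum())


def per_site_fst(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Per-site Hudson F_ST (nan where the denominator vanishes)."""
    num, den, _ = hudson_fst_components(h1, h2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


def dxy(h1: np.ndarray, h2: np.ndarray, effective_sites: float) -> float:
    """Mean between-population pairwise difference rate per effective site."""
    p1 = h1.mean(axis=0)
    p2 = h2.mean(axis=0)
    eff = max(float(effective_sites), 1.0)
    return float(np.sum(p1 * (1 - p2) + p2 * (1 - p1)) / eff)


def fixed_sites(
    h1: np.ndarray, h2: np.ndarray, positions: np.ndarray, fst_threshold: float = 0.9
) -> np.ndarray:
    """Positions whose per-site Hudson F_ST exceeds the threshold."""
    fst = per_site_fst(h1, h2)
    with np.errstate(invalid="ignore"):
        keep = fst > fst_threshold
    return np.asarray(positions)[np.nan_to_num(keep, nan=False).astype(bool)]


def private_alleles(
    focal: np.ndarray, others: list[np.ndarray], exclude_sites: np.ndarray | None = None
) -> int:
    """Alleles present in the focal population and absent from all others.

    Each biallelic site contributes 0, 1 or 2 private alleles.  An optional
    boolean site mask excludes sites (e.g. alleles already catalogued in a
    variant database).
    """
    S = focal.shape[1]
    keep = np.ones(S, dtype=bool)
    if exclude_sites is not None:
        keep &= ~np.asarray(exclude_sites, dtype=bool)
    total = 0
    for allele in (0, 1):
        in_focal = ((focal == allele).any(axis=0)) & keep
        in_others = np.zeros(S, dtype=bool)
        for h in others:
            in_others |= (h == allele).any(axis=0)
        total += int(np.sum(in_focal & ~in_others))
    return total
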