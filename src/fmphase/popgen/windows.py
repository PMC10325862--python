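"""Windowed scan: tiling, mask-based filtering and per-window statistics.

Windows tile the chromosome from position 1 at a fixed size (50 kb by
default); the last, possibly short window is kept but flagged.  A window
passes filtering when at least 80% of it is callable and at most 10% of it
is repeat-masked; failing windows are reported but excluded from outlier
ranking.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .panel import HaplotypePanel
from .stats import diversity_stats, dxy, hudson_fst


def tile_windows(chrom_length: int, size: int = 50_000) -> pd.DataFrame:
    """1-based inclusive windows tiling [1, chrom_length]."""
    starts = np.arange(1, chrom_length + 1, size, dtype=np.int64)
    ends = np.minimum(starts + size - 1, chrom_length)
    return pd.DataFrame(
        {"start": starts, "end": ends, "partial": (ends - starts + 1) < size}
    )


def read_bed(path: str) -> list[tuple[int, int]]:
    """BED intervals (0-based half-open) for a single-chromosome mask."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
        comment="#",
    )
    return [(int(s), int(e)) for s, e in zip(df["start"], df["end"])]


def overlap_fraction(
    windows: pd.DataFrame, intervals: list[tuple[int, int]] | None
) -> np.ndarray:
    """Fraction of each (1-based) window covered by the (0-based) intervals."""
    n = len(windows)
    out = np.zeros(n)
    if not intervals:
        return out
    ivs = sorted(intervals)
    starts = windows["start"].to_numpy() - 1  # to 0-based half-open
    ends = windows["end"].to_numpy()
    for i in range(n):
        w0, w1 = starts[i], ends[i]
        cov = 0
        for s, e in ivs:
            if e <= w0:
                continue
            if s >= w1:
                break
            cov += min(e, w1) - max(s, w0)
        out[i] = cov / (w1 - w0)
    return out


def window_filters(
    windows: pd.DataFrame,
    callable_mask: list[tuple[int, int]] | None,
    repeat_mask: list[tuple[int, int]] | None,
    min_callable: float = 0.8,
    max_repeat: float = 0.1,
) -> pd.DataFrame:
    """Annotate windows with mask fractions and a pass/fail flag.

    A window fails iff its callable fraction is below ``min_callable`` or
    its repeat fraction exceeds ``max_repeat``.  Missing masks let every
    window pass, with a warning.
    """
    out = windows.copy()
    if callable_mask is None:
        warnings.warn("no callability mask: treating all windows as callable")
        out["callable_frac"] = 1.0
    else:
        out["callable_frac"] = overlap_fraction(out, callable_mask)
    if repeat_mask is None:
        warnings.warn("no repeat mask: treating all windows as repeat-free")
        out["repeat_frac"] = 0.0
    else:
        out["repeat_frac"] = overlap_fraction(out, repeat_mask)
    out["pass_filters"] = (out["callable_frac"] >= min_callable) & (
        out["repeat_frac"] <= max_repeat
    )
    return out


def scan_windows(
    panel: HaplotypePanel,
    pop_pair: tuple[str, str],
    chrom_length: int | None = None,
    window_size: int = 50_000,
    callable_mask: list[tuple[int, int]] | None = None,
    repeat_mask: list[tuple[int, int]] | None = None,
    min_callable: float = 0.8,
    max_repeat: float = 0.1,
) -> pd.DataFrame:
    """Per-window diversity and differentiation table for a population pair.

    Columns: window coordinates, per-population pi / theta_W / Tajima's D /
    Fu & Li's D*, Hudson F_ST and D_xy for the pair, segregating sites,
    mask fractions and the pass flag.  Effective sites per window are the
    callable bases within it.
    """
    pop1, pop2 = pop_pair
    rows1 = panel.haplotype_rows(pop1)
    rows2 = panel.haplotype_rows(pop2)
    if rows1.size < 2 or rows2.size < 2:
        raise ValueError("need >= 2 haplotypes in each population")
    length = int(chrom_length or int(panel.positions[-1]))
    windows = tile_windows(length, window_size)
    windows = window_filters(windows, callable_mask, repeat_mask, min_callable, max_repeat)

    records = []
    H = panel.haplotypes
    pos = panel.positions
    for _, w in windows.iterrows():
        in_w = (pos >= w["start"]) & (pos <= w["end"])
        span = w["end"] - w["start"] + 1
        eff = span * (w["callable_frac"] if callable_mask is not None else 1.0)
        rec = {
            "start": int(w["start"]),
            "end": int(w["end"]),
            "partial": bool(w["partial"]),
            "callable_frac": float(w["callable_frac"]),
            "repeat_frac": float(w["repeat_frac"]),
            "pass_filters": bool(w["pass_filters"]),
            "n_sites": int(in_w.sum()),
            "effective_sites": float(eff),
        }
        h1 = H[np.ix_(rows1, np.flatnonzero(in_w))]
        h2 = H[np.ix_(rows2, np.flatnonzero(in_w))]
        for label, h in ((pop1, h1), (pop2, h2)):
            st = diversity_stats(h, eff)
            rec[f"pi_{label}"] = st["pi"]
            rec[f"theta_{label}"] = st["theta_w"]
            rec[f"tajd_{label}"] = st["tajimas_d"]
            rec[f"fulid_{label}"] = st["fu_li_d_star"]
        rec["fst"] = hudson_fst(h1, h2)
        rec["dxy"] = dxy(h1, h2, eff)
        records.append(rec)
    return pd.DataFrame(records)


def outlier_windows(
    windows: pd.DataFrame, metric: str, top_frac: float
) -> tuple[pd.DataFrame, float]:
    """Top-quantile windows of a metric, merged when adjoining.

    Only windows passing the masks enter the quantile; adjoining outlier
    windows are merged bookended (bedtools-merge semantics).  Returns the
    merged intervals and the threshold used.  With fewer than ``1/top_frac``
    passing windows the single best window is returned, with a warning.
    """
    passing = windows[windows["pass_filters"] & windows[metric].notna()]
    if passing.empty:
        return pd.DataFrame(columns=["start", "end", "n_windows", "max_" + metric]), float("nan")
    if len(passing) < 1.0 / top_frac:
        warnings.warn(
            f"only {len(passing)} passing windows for a top-{top_frac:.0%} scan; "
            "returning the single best window"
        )
        best = passing.loc[[passing[metric].idxmax()]]
        sel = best
        thr = float(best[metric].iloc[0])
    else:
        thr = float(passing[metric].quantile(1.0 - top_frac))
        sel = passing[passing[metric] >= thr]
    merged = []
    for _, w in sel.sort_values("start").iterrows():
        if merged and w["start"] == merged[-1]["end"] + 1:
            merged[-1]["end"] = int(w["end"])
            merged[-1]["n_windows"] += 1
            merged[-1]["max_" + metric] = max(merged[-1]["max_" + metric], w[metric])
        else:
            merged.append(
                {
                    "start": int(w["start"]),
                    "end": int(w["end"]),
                    "n_windows": 1,
                    "max_" + metric: float(w[metric]),
                }
            )
    return pd.DataFrame(merged), thr
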