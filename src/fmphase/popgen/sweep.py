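"""Candidate selective-sweep regions from the combined scan evidence.

F_ST outlier windows (top 1% of passing windows, merged when adjoining) are
annotated with the corroborating statistics a sweep should show in the
focal population: reduced diversity relative to the reference population,
negative Tajima's D, elevated |iHS|, positive XP-EHH and top-decile D_xy,
plus the distance to the nearest locus region when a region map is given.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..locus import RegionMap
from .windows import outlier_windows


def _mean_in(rec, lo: int, hi: int, column: str) -> float:
    if rec is None or len(rec) == 0:
        return float("nan")
    sel = (rec.pos >= lo) & (rec.pos <= hi)
    if not sel.any():
        return float("nan")
    return float(np.nanmean(getattr(rec, column)[sel]))


def distance_to_region(start: int, end: int, region_map: RegionMap, region: str = "Dup1") -> int:
    """bp between an interval and a named region (0 when they overlap)."""
    rs, re_ = region_map.interval(region)
    if end < rs:
        return rs - end
    if start > re_:
        return start - re_
    return 0


def sweep_report(
    windows: pd.DataFrame,
    focal: str,
    reference: str,
    ihs: "np.recarray | None" = None,
    xpehh: "np.recarray | None" = None,
    region_map: RegionMap | None = None,
    fst_top_frac: float = 0.01,
    dxy_top_frac: float = 0.10,
) -> pd.DataFrame:
    """Ranked candidate sweep regions for the focal-vs-reference pair.

    Regions are merged F_ST outlier intervals; each row carries the focal /
    reference diversity ratio, focal Tajima's D, mean |iHS| (focal), mean
    XP-EHH (focal vs reference), a top-decile D_xy flag and, when a region
    map is supplied, the distance to Dup1.  Ranked by peak F_ST.
    """
    regions, fst_thr = outlier_windows(windows, "fst", fst_top_frac)
    dxy_regions, dxy_thr = outlier_windows(windows, "dxy", dxy_top_frac)
    rows = []
    for _, r in regions.iterrows():
        lo, hi = int(r["start"]), int(r["end"])
        in_r = (windows["start"] <= hi) & (windows["end"] >= lo)
        sub = windows[in_r]
        pi_f = float(np.nanmean(sub[f"pi_{focal}"]))
        pi_r = float(np.nanmean(sub[f"pi_{reference}"]))
        in_dxy_top = any(
            (d["start"] <= hi and d["end"] >= lo) for _, d in dxy_regions.iterrows()
        )
        row = {
            "start": lo,
            "end": hi,
            "size": hi - lo + 1,
            "peak_fst": float(r["max_fst"]),
            "pi_ratio": pi_f / pi_r if pi_r > 0 else float("nan"),
            "tajd_focal": float(np.nanmean(sub[f"tajd_{focal}"])),
            "mean_abs_ihs": float("nan"),
            "mean_xpehh": _mean_in(xpehh, lo, hi, "xpehh"),
            "dxy_top_decile": bool(in_dxy_top),
        }
        if ihs is not None and len(ihs):
            sel = (ihs.pos >= lo) & (ihs.pos <= hi)
            row["mean_abs_ihs"] = (
                float(np.nanmean(np.abs(ihs.ihs[sel]))) if sel.any() else float("nan")
            )
        if region_map is not None:
            row["distance_to_dup1"] = distance_to_region(lo, hi, region_map)
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values("peak_fst", ascending=False).reset_index(drop=True)
    out.attrs["fst_threshold"] = fst_thr
    out.attrs["dxy_threshold"] = dxy_thr
    return out
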