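"""Genomic context: proximity classification, nascent-signal windows,
and reciprocal-overlap agreement between assay call sets.

All coordinates follow the BED convention (0-based, half-open). Distances
are measured between closest interval edges, 0 when intervals overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import InputError, StateError
from . import io as dio

PROXIMITY_CUTOFF = 500  # bp: proximal iff distance to nearest annotation < cutoff

SIGNAL_MODES = ("total", "mean")
SIGNAL_SIDES = ("within", "flank", "within_plus_flank")
SIGNAL_EXTENSIONS = (100, 250, 500)


# ---------------------------------------------------------------------------
# proximal / distal classification
# ---------------------------------------------------------------------------

def _merge_intervals(starts: np.ndarray, ends: np.ndarray
                     ) -> Tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    ms, me = [], []
    for i in range(len(s)):
        if ms and s[i] <= me[-1]:
            me[-1] = max(me[-1], e[i])
        else:
            ms.append(s[i])
            me.append(e[i])
    return np.asarray(ms), np.asarray(me)


def distance_to_nearest(sites: pd.DataFrame, annotations: pd.DataFrame
                        ) -> pd.Series:
    """Edge distance from each site interval to the nearest annotation
    interval on the same chromosome (0 if overlapping, inf if none)."""
    for df, name in ((sites, "sites"), (annotations, "annotations")):
        if (df["start"] >= df["end"]).any():
            raise InputError(f"{name}: start must be < end")
    merged = {}
    for chrom, grp in annotations.groupby("chrom"):
        merged[chrom] = _merge_intervals(
            grp["start"].to_numpy(), grp["end"].to_numpy()
        )
    out = np.full(len(sites), np.inf)
    for i, (chrom, s, e) in enumerate(
        zip(sites["chrom"], sites["start"], sites["end"])
    ):
        if chrom not in merged:
            continue
        ms, me = merged[chrom]
        j = np.searchsorted(ms, e)  # annotations starting before site end
        d = np.inf
        if j > 0:
            if me[j - 1] > s:
                d = 0.0  # overlap
            else:
                d = s - me[j - 1]
        if j < len(ms) and d > 0:
            d = min(d, ms[j] - e)
        out[i] = max(d, 0.0)
    return pd.Series(out, index=sites.index, name="distance")


def classify_proximity(sites: pd.DataFrame, annotations: pd.DataFrame,
                       cutoff: int = PROXIMITY_CUTOFF) -> pd.DataFrame:
    """Label each site proximal (nearest annotation < ``cutoff`` bp away) or
    distal. Invariant under annotation duplication (intervals are merged
    first)."""
    dist = distance_to_nearest(sites, annotations)
    label = np.where(dist < cutoff, "proximal", "distal")
    return pd.DataFrame({"distance": dist, "proximity": label}, index=sites.index)


# ---------------------------------------------------------------------------
# signal tracks and windowed extraction
# ---------------------------------------------------------------------------

@dataclass
class SignalTrack:
    """Strand-resolved per-base signal (e.g. UMI-deduplicated read 5' ends).

    ``data`` maps (chrom, strand) to a dense non-negative array; positions
    past the stored length are 0. With only a plus track loaded, both strands
    read from it (unstranded signal)."""

    data: Dict[Tuple[str, str], np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_bedgraph(cls, plus_path, minus_path=None) -> "SignalTrack":
        track = cls()
        for strand, path in (("+", plus_path), ("-", minus_path)):
            if path is None:
                continue
            df = dio.read_bedgraph(path)
            for chrom, grp in df.groupby("chrom"):
                arr = np.zeros(int(grp["end"].max()), dtype=float)
                for s, e, v in zip(grp["start"], grp["end"], grp["value"]):
                    arr[int(s): int(e)] += abs(float(v))
                track.data[(chrom, strand)] = arr
        return track

    @classmethod
    def from_arrays(cls, plus: Dict[str, np.ndarray],
                    minus: Optional[Dict[str, np.ndarray]] = None) -> "SignalTrack":
        track = cls()
        for chrom, arr in plus.items():
            track.data[(chrom, "+")] = np.asarray(arr, dtype=float)
        for chrom, arr in (minus or {}).items():
            track.data[(chrom, "-")] = np.asarray(arr, dtype=float)
        return track

    def _array(self, chrom: str, strand: str) -> Optional[np.ndarray]:
        arr = self.data.get((chrom, strand))
        if arr is None and strand == "-":
            arr = self.data.get((chrom, "+"))  # unstranded fallback
        return arr

    def window_sum(self, chrom: str, start: int, end: int, strand: str = "+"
                   ) -> float:
        if start < 0:
            warnings.warn(
                f"window [{start}, {end}) clipped to chromosome bounds on {chrom}"
            )
            start = 0
        arr = self._array(chrom, strand)
        if arr is None or start >= end:
            return 0.0
        return float(arr[start: min(end, len(arr))].sum())


def _window_bounds(start: int, end: int, orientation: str, side: str,
                   extension: int) -> Tuple[int, int]:
    forward = orientation in ("forward", "+")
    if side == "within":
        return start, end
    if extension <= 0:
        raise InputError("flank windows require a positive extension")
    flank = (end, end + extension) if forward else (start - extension, start)
    if side == "flank":
        return flank
    if side == "within_plus_flank":
        return (start, end + extension) if forward else (start - extension, end)
    raise InputError(f"unknown side {side!r}; expected one of {SIGNAL_SIDES}")


def window_signal(
    elements: pd.DataFrame,
    track: SignalTrack,
    mode: str = "total",
    extension: int = 0,
    side: str = "within",
) -> pd.Series:
    """Windowed signal per element under one criterion.

    Windows are orientation-aware: the flank extends downstream of forward
    elements and upstream of reverse elements. ``mode='mean'`` divides the
    total by the window length in bases (so mean == total / length exactly).
    Elements need columns chrom, start, end, orientation (or strand).
    """
    if mode not in SIGNAL_MODES:
        raise InputError(f"unknown mode {mode!r}; expected one of {SIGNAL_MODES}")
    ori_col = "orientation" if "orientation" in elements.columns else "strand"
    out = np.empty(len(elements))
    for i, row in enumerate(elements.itertuples(index=False)):
        ori = getattr(row, ori_col)
        w0, w1 = _window_bounds(int(row.start), int(row.end), ori, side, extension)
        strand = "+" if ori in ("forward", "+") else "-"
        total = track.window_sum(row.chrom, w0, w1, strand)
        if mode == "mean":
            length = w1 - max(w0, 0)
            total = total / length if length > 0 else 0.0
        out[i] = total
    return pd.Series(out, index=elements.index, name=f"{side}_{mode}_{extension}")


def signal_grid(elements: pd.DataFrame, track: SignalTrack) -> pd.DataFrame:
    """All windowing criteria: the plain within-boundaries total (the capped
    5'-end case) plus the 12-way grid {flank, within_plus_flank} x {total,
    mean} x {100, 250, 500} bp used for elongating-polymerase signal."""
    cols = {"within_total_0": window_signal(elements, track, "total", 0, "within")}
    for side in ("flank", "within_plus_flank"):
        for mode in SIGNAL_MODES:
            for ext in SIGNAL_EXTENSIONS:
                name = f"{side}_{mode}_{ext}"
                cols[name] = window_signal(elements, track, mode, ext, side)
    return pd.DataFrame(cols, index=elements.index)


# ---------------------------------------------------------------------------
# reciprocal overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    pairs: pd.DataFrame    # every (a, b) pair passing the reciprocal criterion
    best: pd.DataFrame     # one row per matched a: the resolved partner


def reciprocal_overlap(set_a: pd.DataFrame, set_b: pd.DataFrame,
                       min_frac: float = 0.5) -> OverlapResult:
    """Match intervals requiring the intersection to cover at least
    ``min_frac`` of *both* intervals (symmetric criterion).

    One-to-many matches are resolved per A interval by largest intersection,
    ties broken by leftmost B start. Inputs need columns chrom, start, end.
    """
    if not (0 < min_frac <= 1):
        raise InputError(f"min_frac must lie in (0, 1], got {min_frac}")
    for df, name in ((set_a, "set_a"), (set_b, "set_b")):
        if (df["start"] >= df["end"]).any():
            raise InputError(f"{name}: start must be < end")
    rows = []
    b_by_chrom = {c: g for c, g in set_b.groupby("chrom")}
    for ai, a in zip(set_a.index, set_a.itertuples(index=False)):
        grp = b_by_chrom.get(a.chrom)
        if grp is None:
            continue
        alen = a.end - a.start
        for bi, b in zip(grp.index, grp.itertuples(index=False)):
            inter = min(a.end, b.end) - max(a.start, b.start)
            if inter <= 0:
                continue
            blen = b.end - b.start
            if inter >= min_frac * alen and inter >= min_frac * blen:
                rows.append((ai, bi, inter, b.start))
    pairs = pd.DataFrame(rows, columns=["a_index", "b_index", "intersection",
                                        "b_start"])
    if len(pairs):
        best = (
            pairs.sort_values(
                ["a_index", "intersection", "b_start"],
                ascending=[True, False, True],
            )
            .groupby("a_index", sort=True)
            .first()
            .reset_index()
        )
    else:
        best = pairs.copy()
    return OverlapResult(pairs=pairs.drop(columns="b_start"),
                         best=best.drop(columns="b_start"))


def percent_confirmed(result: OverlapResult, b_active: pd.Series) -> Dict:
    """Of the A intervals with a reciprocal match, the percent whose matched
    B interval carries an active flag."""
    best = result.best
    if len(best) == 0:
        return {"n_matched": 0, "n_confirmed": 0, "percent": float("nan")}
    flags = b_active.reindex(best["b_index"]).astype(bool).to_numpy()
    n_matched = len(best)
    n_conf = int(flags.sum())
    return {
        "n_matched": n_matched,
        "n_confirmed": n_conf,
        "percent": 100.0 * n_conf / n_matched,
    }
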