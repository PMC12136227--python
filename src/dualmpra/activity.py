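"""Element activities and active promoter/enhancer calls.

The uniform active-call pipeline: (1) a CPM pre-filter anchored to a raw
count of 10 in the smallest DNA library; (2) trimmed-mean-of-M-values (TMM)
scaling factors computed *only* on negative-control ORF rows, so libraries
are normalized to the basal transcription anchor rather than to bulk
composition; (3) per-replicate activities A = log2((RNA + c)/(DNA + c)) on
normalized counts, combined across replicates with precision weights
estimated from barcode-level scatter; (4) boost indices BI = A / mean(A over
ORF controls); (5) a Z-score test of each element against the control
distribution, Benjamini-Hochberg corrected, requiring significance in both
cloned orientations for an active call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError, StateError
from .quantify import CountMatrix

READOUTS = ("promoter", "enhancer")


# ---------------------------------------------------------------------------
# CPM pre-filter
# ---------------------------------------------------------------------------

def cpm_threshold(dna_library_sizes: Sequence[float], min_count: int = 10) -> float:
    """CPM cutoff equivalent to ``min_count`` raw reads in the smallest DNA
    library."""
    smallest = min(dna_library_sizes)
    if smallest <= 0:
        raise InputError("smallest DNA library has size 0")
    return min_count * 1e6 / smallest


def cpm_prefilter(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    min_count: int = 10,
    mode: str = "all",
) -> Tuple[pd.DataFrame, float]:
    """Retain rows whose CPM exceeds the threshold in all (or any) DNA
    libraries; returns (filtered counts, threshold)."""
    dna_cols = list(meta.loc[meta.lib_type == "DNA", "column_id"])
    if not dna_cols:
        raise InputError("no DNA library columns in metadata")
    sizes = counts[dna_cols].sum(axis=0)
    if (sizes <= 0).any():
        raise InputError(f"zero-size DNA libraries: {list(sizes[sizes <= 0].index)}")
    t = cpm_threshold(sizes, min_count)
    cpm = counts[dna_cols] * 1e6 / sizes
    passed = (cpm > t).all(axis=1) if mode == "all" else (cpm > t).any(axis=1)
    return counts.loc[passed], t


# ---------------------------------------------------------------------------
# control-anchored TMM normalization
# ---------------------------------------------------------------------------

def control_anchored_tmm(
    counts: pd.DataFrame,
    control_ids: Iterable[str],
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """TMM scaling factors with M/A statistics restricted to control rows.

    Standard TMM machinery (reference selection, double trimming by M and A,
    precision-weighted mean of M values) but every statistic is computed only
    on negative-control ORF rows, so active elements cannot drag the scale.
    Factors are normalized to geometric mean 1; normalized counts are
    ``count / (library_size * factor)`` (x1e6 for CPM).
    """
    control_ids = set(control_ids)
    ctrl = counts.loc[counts.index.get_level_values("element_id").isin(control_ids)]
    if len(ctrl) < 2:
        raise StateError(
            f"need >= 2 control rows surviving the pre-filter, got {len(ctrl)}"
        )
    libsize = counts.sum(axis=0).astype(float)
    if (libsize <= 0).any():
        raise InputError("library with zero total count")

    # reference: column whose control upper-quartile (of CPM) is closest to
    # the mean upper-quartile
    uq = (ctrl * 1e6 / libsize).quantile(0.75, axis=0)
    ref_col = (uq - uq.mean()).abs().idxmin()
    r = ctrl[ref_col].to_numpy(float)
    nr = libsize[ref_col]

    factors = {}
    for col in counts.columns:
        if col == ref_col:
            factors[col] = 1.0
            continue
        x = ctrl[col].to_numpy(float)
        n = libsize[col]
        ok = (x > 0) & (r > 0)
        if ok.sum() == 0:
            factors[col] = 1.0
            continue
        xf, rf = x[ok] / n, r[ok] / nr
        m = np.log2(xf / rf)
        a = 0.5 * np.log2(xf * rf)
        w = 1.0 / ((n - x[ok]) / (n * x[ok]) + (nr - r[ok]) / (nr * r[ok]))
        k = len(m)
        rank_m = sps.rankdata(m)
        rank_a = sps.rankdata(a)
        lo_m, hi_m = np.floor(k * trim_m) + 1, k - np.floor(k * trim_m)
        lo_a, hi_a = np.floor(k * trim_a) + 1, k - np.floor(k * trim_a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0 or not np.isfinite(m[keep]).all():
            factors[col] = 1.0
        else:
            factors[col] = float(2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))

    f = pd.Series(factors)[counts.columns]
    f /= np.exp(np.mean(np.log(f)))  # geometric mean 1
    return f


def normalized_cpm(counts: pd.DataFrame, factors: pd.Series,
                   libsize: Optional[pd.Series] = None) -> pd.DataFrame:
    if libsize is None:
        libsize = counts.sum(axis=0).astype(float)
    return counts * 1e6 / (libsize * factors)


# ---------------------------------------------------------------------------
# activity computation
# ---------------------------------------------------------------------------

def compute_activity(
    cm: CountMatrix,
    factors: pd.Series,
    pseudocount: float = 0.5,
    var_floor: float = 0.05,
) -> pd.DataFrame:
    """Per-construct activity A = log2((RNA + c)/(DNA + c)) on normalized
    counts, averaged across replicates.

    Replicates are combined with precision weights proportional to
    n_barcodes / var(barcode-level log-ratios), a simplified stand-in for
    full mean-variance modelling; with no barcode-level matrix the mean is
    unweighted. Returns a tidy frame (element_id, orientation, readout,
    minp, A).
    """
    counts = cm.elements
    meta = cm.meta
    libsize = counts.sum(axis=0).astype(float)
    norm = normalized_cpm(counts, factors, libsize)
    bc_norm = None
    if cm.barcodes is not None and len(cm.barcodes):
        bc = cm.barcodes.reindex(columns=counts.columns, fill_value=0)
        bc_norm = normalized_cpm(bc, factors, libsize)

    out = []
    for (readout, minp), grp in meta.groupby(["readout", "minp"]):
        reps = sorted(grp["replicate"].unique())
        a_reps, w_reps = [], []
        for rep in reps:
            sub = grp[grp.replicate == rep]
            rna = sub.loc[sub.lib_type == "RNA", "column_id"]
            dna = sub.loc[sub.lib_type == "DNA", "column_id"]
            if len(dna) == 0:
                raise InputError(
                    f"no paired DNA column for readout={readout} minp={minp} "
                    f"replicate={rep}"
                )
            if len(rna) == 0:
                raise InputError(
                    f"no RNA column for readout={readout} minp={minp} rep={rep}"
                )
            rna_col, dna_col = rna.iloc[0], dna.iloc[0]
            a = np.log2((norm[rna_col] + pseudocount) / (norm[dna_col] + pseudocount))
            a_reps.append(a)
            if bc_norm is not None:
                lr = np.log2(
                    (bc_norm[rna_col] + pseudocount) / (bc_norm[dna_col] + pseudocount)
                )
                g = lr.groupby(level=["element_id", "orientation"])
                nbc = g.size()
                var = g.var(ddof=1).fillna(var_floor)
                w = (nbc / var.clip(lower=var_floor)).reindex(a.index).fillna(1.0)
            else:
                w = pd.Series(1.0, index=a.index)
            w_reps.append(w)
        A = sum(w * a for w, a in zip(w_reps, a_reps)) / sum(w_reps)
        df = A.rename("A").reset_index()
        df["readout"] = readout
        df["minp"] = minp
        out.append(df)
    table = pd.concat(out, ignore_index=True)
    return table[["element_id", "orientation", "readout", "minp", "A"]]


# ---------------------------------------------------------------------------
# negative-control statistics, boost index, active calls
# ---------------------------------------------------------------------------

@dataclass
class NegativeControlStats:
    """Mean/SD of activity over negative-control ORFs, per readout and minP
    set (orientations pooled: ORFs have no orientation-specific activity)."""

    table: pd.DataFrame  # index (readout, minp); columns mu, sigma, n

    @classmethod
    def from_activity(cls, act: pd.DataFrame, control_ids: Iterable[str]
                      ) -> "NegativeControlStats":
        control_ids = set(control_ids)
        ctrl = act[act.element_id.isin(control_ids)]
        if ctrl.empty:
            raise StateError("no control elements present in the activity table")
        rows = []
        for (readout, minp), grp in ctrl.groupby(["readout", "minp"]):
            vals = grp["A"].to_numpy(float)
            if len(vals) < 2:
                raise StateError(
                    f"need >= 2 control measurements for {readout}/{minp}, "
                    f"got {len(vals)}"
                )
            rows.append((readout, minp, vals.mean(), vals.std(ddof=1), len(vals)))
        table = pd.DataFrame(
            rows, columns=["readout", "minp", "mu", "sigma", "n"]
        ).set_index(["readout", "minp"])
        return cls(table=table)

    def get(self, readout: str, minp: str) -> Tuple[float, float, int]:
        row = self.table.loc[(readout, minp)]
        return float(row.mu), float(row.sigma), int(row.n)


#: below this |mean control activity| the boost-index division is unstable
BOOST_MU_FLOOR = 0.05


def boost_index(act: pd.DataFrame, controls: NegativeControlStats,
                mu_floor: float = BOOST_MU_FLOOR) -> pd.Series:
    """BI = A / mean(A over ORF controls), per readout (and minP set).

    Refuses when the control mean is within ``mu_floor`` of zero: dividing by
    a near-zero basal mean is numerically unstable (and flips sign semantics
    when negative) — use the z-scores from :func:`call_active` instead.
    """
    bi = pd.Series(np.nan, index=act.index, name="BI")
    for (readout, minp), grp in act.groupby(["readout", "minp"]):
        mu, _sigma, _n = controls.get(readout, minp)
        if abs(mu) < mu_floor:
            raise StateError(
                f"mean control activity for {readout}/{minp} is {mu:.4g}, within "
                f"{mu_floor} of zero; boost indices are unstable here — compare "
                f"elements with z-scores instead"
            )
        bi.loc[grp.index] = grp["A"] / mu
    return bi


def call_active(
    act: pd.DataFrame,
    control_ids: Iterable[str],
    alpha: float = 0.05,
    controls: Optional[NegativeControlStats] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score each element against the negative-control distribution and
    call elements active when BH-adjusted one-sided p < alpha in *both*
    cloned orientations.

    Controls define the null and are excluded from the tested set. Returns
    ``(per_orientation, combined)`` tables.
    """
    control_ids = set(control_ids)
    if controls is None:
        controls = NegativeControlStats.from_activity(act, control_ids)
    table = act.copy()
    table["z"] = np.nan
    table["p"] = np.nan
    for (readout, minp), grp in table.groupby(["readout", "minp"]):
        mu, sigma, _n = controls.get(readout, minp)
        if sigma == 0:
            raise StateError(f"control SD is zero for {readout}/{minp}")
        z = (grp["A"] - mu) / sigma
        table.loc[grp.index, "z"] = z
        table.loc[grp.index, "p"] = sps.norm.sf(z)

    is_ctrl = table.element_id.isin(control_ids)
    table["padj"] = np.nan
    tested = table[~is_ctrl]
    for (_readout, _minp, _ori), grp in tested.groupby(
        ["readout", "minp", "orientation"]
    ):
        if len(grp) == 0:
            continue
        _rej, padj, _a, _b = multipletests(grp["p"], method="fdr_bh")
        table.loc[grp.index, "padj"] = padj
    table["active"] = table["padj"] < alpha

    comb = (
        table[~is_ctrl]
        .groupby(["element_id", "readout", "minp"])
        .agg(n_orientations=("active", "size"), n_active=("active", "sum"))
        .reset_index()
    )
    comb["active"] = (comb.n_orientations >= 2) & (comb.n_active == comb.n_orientations)
    return table, comb[["element_id", "readout", "minp", "active"]]


# ---------------------------------------------------------------------------
# pipeline wrapper
# ---------------------------------------------------------------------------

@dataclass
class ActivityResult:
    table: pd.DataFrame        # per element/orientation/readout/minp: A, z, p, padj, active
    combined: pd.DataFrame     # per element/readout/minp: active (both orientations)
    controls: NegativeControlStats
    factors: pd.Series
    cpm_cutoff: float
    params: Dict = field(default_factory=dict)


def run_activity(
    cm: CountMatrix,
    control_ids: Iterable[str],
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    min_count: int = 10,
    filter_mode: str = "all",
    with_boost: bool = False,
) -> ActivityResult:
    """Full uniform active-call pipeline on a count matrix."""
    control_ids = list(control_ids)
    kept, cutoff = cpm_prefilter(cm.elements, cm.meta, min_count=min_count,
                                 mode=filter_mode)
    cm2 = CountMatrix(
        elements=kept,
        meta=cm.meta,
        barcodes=(
            cm.barcodes.loc[cm.barcodes.index.droplevel("aBC_rep").isin(kept.index)]
            if cm.barcodes is not None and len(cm.barcodes)
            else cm.barcodes
        ),
        stats=cm.stats,
    )
    factors = control_anchored_tmm(kept, control_ids)
    act = compute_activity(cm2, factors, pseudocount=pseudocount)
    controls = NegativeControlStats.from_activity(act, control_ids)
    table, combined = call_active(act, control_ids, alpha=alpha, controls=controls)
    if with_boost:
        table["BI"] = boost_index(table, controls)
    return ActivityResult(
        table=table,
        combined=combined,
        controls=controls,
        factors=factors,
        cpm_cutoff=cutoff,
        params={
            "alpha": alpha,
            "pseudocount": pseudocount,
            "min_count": min_count,
            "filter_mode": filter_mode,
        },
    )
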