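"""Functional-duality analytics over paired promoter/enhancer measurements.

Given per-element promoter and enhancer boost indices measured on the same
constructs, these routines quantify how the two activities relate: the
activity balance index (difference of Z-standardized boost indices, with
+/-1 SD cutoffs splitting elements into promoter-dominant / enhancer-dominant
/ balanced), the activity ratio with ranks and tertiles, variant delta boost
indices, active-call concordance, Bland-Altman agreement between paired
assays, and GC content.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, StateError

CATEGORIES = ("promoter-dominant", "enhancer-dominant", "balanced")


def round_half_up(x: float, digits: int = 1) -> float:
    """Decimal half-up rounding for reported percentages."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# balance index
# ---------------------------------------------------------------------------

def balance_classify(bi_p: pd.Series, bi_e: pd.Series, cutoff: float = 1.0
                     ) -> pd.DataFrame:
    """Z-standardize both boost-index vectors over the scored element set,
    take Bal = Z_P - Z_E, and classify with the +/-``cutoff``-SD rule:
    promoter-dominant (Bal > cutoff), enhancer-dominant (Bal < -cutoff),
    balanced otherwise."""
    if not bi_p.index.equals(bi_e.index):
        bi_e = bi_e.reindex(bi_p.index)
    if bi_p.isna().any() or bi_e.isna().any():
        raise InputError("boost indices must be finite over the same elements")
    n = len(bi_p)
    if n < 2:
        raise StateError(f"need >= 2 elements to standardize, got {n}")
    sd_p, sd_e = bi_p.std(ddof=1), bi_e.std(ddof=1)
    if sd_p == 0 or sd_e == 0:
        raise StateError("zero standard deviation in a boost-index vector")
    z_p = (bi_p - bi_p.mean()) / sd_p
    z_e = (bi_e - bi_e.mean()) / sd_e
    bal = z_p - z_e
    category = np.where(
        bal > cutoff, "promoter-dominant",
        np.where(bal < -cutoff, "enhancer-dominant", "balanced"),
    )
    return pd.DataFrame(
        {"Z_P": z_p, "Z_E": z_e, "bal": bal, "category": category}, index=bi_p.index
    )


def category_fractions(records: pd.DataFrame) -> Dict[str, float]:
    """Percent of elements per balance category (sums to 100)."""
    frac = records["category"].value_counts(normalize=True) * 100.0
    return {c: float(frac.get(c, 0.0)) for c in CATEGORIES}


# ---------------------------------------------------------------------------
# activity ratio
# ---------------------------------------------------------------------------

def activity_ratio(bi_p: pd.Series, bi_e: pd.Series) -> pd.DataFrame:
    """R = BI_P - BI_E per element, with descending ranks (ties averaged) and
    tertiles split at the 33.3/66.7 percentiles of R (boundary elements fall
    to the lower tertile)."""
    if not bi_p.index.equals(bi_e.index):
        bi_e = bi_e.reindex(bi_p.index)
    r = (bi_p - bi_e).astype(float)
    if r.isna().any():
        raise InputError("boost indices must be paired and finite")
    rank = pd.Series(sps.rankdata(-r.to_numpy(), method="average"), index=r.index)
    q33, q67 = np.percentile(r, [100.0 / 3.0, 200.0 / 3.0])
    tertile = np.where(r > q67, "high", np.where(r > q33, "mid", "low"))
    return pd.DataFrame({"R": r, "rank": rank, "tertile": tertile}, index=r.index)


# ---------------------------------------------------------------------------
# variant effects
# ---------------------------------------------------------------------------

@dataclass
class DeltaBoostResult:
    effects: pd.DataFrame          # per variant: dBI_promoter, dBI_enhancer
    tests: pd.DataFrame            # per readout: t, p (one-sample vs 0), n
    spearman_rho: float
    spearman_p: float
    n_dropped_incomplete: int


def delta_boost(paired: pd.DataFrame) -> DeltaBoostResult:
    """Delta boost indices for wild-type/mutant allele pairs.

    ``paired`` needs columns BI_wt_promoter, BI_mut_promoter, BI_wt_enhancer,
    BI_mut_enhancer (one row per variant; rows with a missing allele in
    either readout are dropped — both alleles must be scored in the same
    experiment). dBI = BI_mut - BI_wt per readout; a one-sample t-test of
    dBI against 0 is run per readout, plus the Spearman correlation between
    the promoter and enhancer deltas."""
    need = [f"BI_{a}_{r}" for r in ("promoter", "enhancer") for a in ("wt", "mut")]
    missing = [c for c in need if c not in paired.columns]
    if missing:
        raise InputError(f"missing columns {missing}")
    complete = paired.dropna(subset=need)
    n_dropped = len(paired) - len(complete)
    eff = pd.DataFrame(index=complete.index)
    tests = []
    for readout in ("promoter", "enhancer"):
        d = complete[f"BI_mut_{readout}"] - complete[f"BI_wt_{readout}"]
        eff[f"dBI_{readout}"] = d
        if len(d) >= 2 and d.std(ddof=1) > 0:
            t, p = sps.ttest_1samp(d, 0.0)
        else:
            t, p = np.nan, np.nan
        tests.append((readout, float(t), float(p), len(d)))
    if len(eff) >= 2:
        rho, rho_p = sps.spearmanr(eff["dBI_promoter"], eff["dBI_enhancer"])
    else:
        rho, rho_p = np.nan, np.nan
    return DeltaBoostResult(
        effects=eff,
        tests=pd.DataFrame(tests, columns=["readout", "t", "p", "n"]),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        n_dropped_incomplete=n_dropped,
    )


# ---------------------------------------------------------------------------
# concordance of active calls
# ---------------------------------------------------------------------------

def concordance(active_p: pd.Series, active_e: pd.Series) -> Dict:
    """2x2 contingency of paired promoter/enhancer active calls plus the
    conditional rates, e.g. rate(E|P) = |P and E| / |P| as a percent.

    Both flag vectors must cover the same elements (paired measurements from
    the same experiment)."""
    if not active_p.index.equals(active_e.index):
        active_e = active_e.reindex(active_p.index)
        if active_e.isna().any():
            raise InputError("active flags must be paired over the same elements")
    p = active_p.astype(bool)
    e = active_e.astype(bool)
    n_p, n_e = int(p.sum()), int(e.sum())
    n_both = int((p & e).sum())
    table = pd.DataFrame(
        [[n_both, n_p - n_both], [n_e - n_both, int((~p & ~e).sum())]],
        index=["P_active", "P_inactive"],
        columns=["E_active", "E_inactive"],
    )
    rate_e_given_p = 100.0 * n_both / n_p if n_p else float("nan")
    rate_p_given_e = 100.0 * n_both / n_e if n_e else float("nan")
    return {
        "table": table,
        "n_promoter_active": n_p,
        "n_enhancer_active": n_e,
        "n_both": n_both,
        "rate_e_given_p": rate_e_given_p,
        "rate_p_given_e": rate_p_given_e,
        "rate_e_given_p_rounded": round_half_up(rate_e_given_p, 1) if n_p else float("nan"),
        "rate_p_given_e_rounded": round_half_up(rate_p_given_e, 1) if n_e else float("nan"),
    }


def concordance_from_counts(n_p: int, n_e: int, n_both: int) -> Dict:
    """Conditional concordance rates from summary counts alone."""
    if n_both > min(n_p, n_e):
        raise InputError("intersection exceeds a marginal count")
    rate_e_given_p = 100.0 * n_both / n_p if n_p else float("nan")
    rate_p_given_e = 100.0 * n_both / n_e if n_e else float("nan")
    return {
        "rate_e_given_p": rate_e_given_p,
        "rate_p_given_e": rate_p_given_e,
        "rate_e_given_p_rounded": round_half_up(rate_e_given_p, 1),
        "rate_p_given_e_rounded": round_half_up(rate_p_given_e, 1),
    }


# ---------------------------------------------------------------------------
# Bland-Altman agreement
# ---------------------------------------------------------------------------

def bland_altman(x: pd.Series, y: pd.Series) -> Dict:
    """Bland-Altman agreement between paired measurements: per-element
    differences d = x - y against means (x + y)/2, the bias mean(d), the
    1.96-SD limits of agreement, and the fraction of points within them."""
    x = pd.Series(x, dtype=float)
    y = pd.Series(y, dtype=float).reindex(x.index)
    if x.isna().any() or y.isna().any():
        raise InputError("paired finite measurements required")
    d = x - y
    m = (x + y) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(((d >= lo) & (d <= hi)).mean()) if len(d) else float("nan")
    return {
        "bias": bias,
        "sd": sd,
        "loa_low": lo,
        "loa_high": hi,
        "frac_within": within,
        "points": pd.DataFrame({"mean": m, "diff": d}),
    }


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def gc_content(sequence: str) -> float:
    """Percent G+C over the full sequence length. N bases count toward the
    length but not toward G+C."""
    seq = sequence.upper()
    if not seq:
        raise InputError("empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise InputError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def gc_table(sequences: Dict[str, str]) -> pd.DataFrame:
    """GC percent per named sequence; sequences containing N are flagged."""
    rows = [
        (name, gc_content(seq), "N" in seq.upper()) for name, seq in sequences.items()
    ]
    return pd.DataFrame(rows, columns=["name", "gc_pct", "has_n"]).set_index("name")
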