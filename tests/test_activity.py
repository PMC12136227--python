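"""CPM pre-filter, control-anchored TMM, activities, boost indices, calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dualmpra import InputError, StateError
from dualmpra.activity import (
    NegativeControlStats,
    boost_index,
    call_active,
    compute_activity,
    control_anchored_tmm,
    cpm_prefilter,
    cpm_threshold,
    normalized_cpm,
    run_activity,
)
from dualmpra.quantify import CountMatrix


def _mk_counts(data, elements=None):
    """Element x column count frame with the (element_id, orientation) index."""
    n = len(next(iter(data.values())))
    if elements is None:
        elements = [(f"E{i}", "forward") for i in range(n)]
    idx = pd.MultiIndex.from_tuples(elements, names=["element_id", "orientation"])
    return pd.DataFrame(data, index=idx)


def _meta(columns):
    rows = []
    for c in columns:
        lib, minp = c.split("|")
        lib_type, readout, rep = lib.split("_")
        rows.append((c, lib_type, readout, int(rep.replace("rep", "")), minp))
    return pd.DataFrame(
        rows, columns=["column_id", "lib_type", "readout", "replicate", "minp"]
    )


# ---------------------------------------------------------------------------
# CPM pre-filter
# ---------------------------------------------------------------------------

def test_cpm_threshold_definition():
    assert cpm_threshold([1_000_000, 5_000_000]) == 10.0


def test_prefilter_matches_hand_computation():
    cols = ["DNA_promoter_rep1|m", "DNA_promoter_rep2|m"]
    counts = _mk_counts(
        {cols[0]: [50, 12, 0, 400, 538], cols[1]: [60, 5, 0, 380, 555]}
    )
    meta = _meta(cols)
    kept, t = cpm_prefilter(counts, meta, min_count=10)
    # smallest DNA library: 1000 reads -> threshold 10 * 1e6 / 1000 = 10,000 CPM
    assert t == pytest.approx(10 * 1e6 / 1000)
    # CPM: E0 (50000, 60000), E1 (12000, 5000), E2 zero, E3/E4 large:
    # only rows above 10,000 CPM in ALL DNA libraries survive
    assert list(kept.index.get_level_values("element_id")) == ["E0", "E3", "E4"]


def test_prefilter_rejects_zero_size_library():
    cols = ["DNA_promoter_rep1|m"]
    counts = _mk_counts({cols[0]: [0, 0]})
    with pytest.raises(InputError):
        cpm_prefilter(counts, _meta(cols))


# ---------------------------------------------------------------------------
# control-anchored TMM
# ---------------------------------------------------------------------------

def _control_matrix(rng, n_ctrl=50, n_lib=4, scale=None):
    mu = rng.lognormal(4.0, 1.0, size=n_ctrl)
    cols = {}
    for j in range(n_lib):
        s = 1.0 if scale is None else scale[j]
        cols[f"DNA_promoter_rep{j+1}|m"] = rng.poisson(mu * s)
    elements = [(f"ORF{i}", "forward") for i in range(n_ctrl)]
    return _mk_counts(cols, elements), [f"ORF{i}" for i in range(n_ctrl)]


def test_identical_libraries_give_unit_factors():
    counts = _mk_counts(
        {"DNA_promoter_rep1|m": [100, 200, 50], "DNA_promoter_rep2|m": [100, 200, 50]},
        elements=[("ORF0", "forward"), ("ORF1", "forward"), ("E0", "forward")],
    )
    f = control_anchored_tmm(counts, ["ORF0", "ORF1"])
    assert np.allclose(f.to_numpy(), 1.0)


def test_doubled_library_fully_absorbed():
    rng = np.random.default_rng(0)
    counts, ctrl = _control_matrix(rng, n_ctrl=40, n_lib=2)
    counts.iloc[:, 1] = counts.iloc[:, 0] * 2  # library B = 2 x library A
    f = control_anchored_tmm(counts, ctrl)
    norm = normalized_cpm(counts, f)
    pd.testing.assert_series_equal(
        norm.iloc[:, 0], norm.iloc[:, 1], check_names=False
    )


def test_too_few_controls_is_state_error():
    counts = _mk_counts({"DNA_promoter_rep1|m": [5, 5]},
                        elements=[("ORF0", "forward"), ("E0", "forward")])
    with pytest.raises(StateError):
        control_anchored_tmm(counts, ["ORF0"])


def _oracle_tmm(counts, control_ids, trim_m=0.30, trim_a=0.05):
    """Plain-loop reimplementation of trimmed weighted mean of M values over
    control rows, with the same trim fractions and reference rule."""
    ctrl = counts.loc[[i for i in counts.index if i[0] in set(control_ids)]]
    libsize = {c: float(counts[c].sum()) for c in counts.columns}
    uq = {c: np.quantile(ctrl[c] * 1e6 / libsize[c], 0.75) for c in counts.columns}
    mean_uq = np.mean(list(uq.values()))
    ref = min(counts.columns, key=lambda c: (abs(uq[c] - mean_uq), list(counts.columns).index(c)))
    factors = {}
    for col in counts.columns:
        if col == ref:
            factors[col] = 1.0
            continue
        ms, aa, ws = [], [], []
        for i in range(len(ctrl)):
            x, r = float(ctrl[col].iloc[i]), float(ctrl[ref].iloc[i])
            if x <= 0 or r <= 0:
                continue
            n, nr = libsize[col], libsize[ref]
            ms.append(np.log2((x / n) / (r / nr)))
            aa.append(0.5 * np.log2((x / n) * (r / nr)))
            ws.append(1.0 / ((n - x) / (n * x) + (nr - r) / (nr * r)))
        ms, aa, ws = map(np.asarray, (ms, aa, ws))
        k = len(ms)
        rm, ra = sps.rankdata(ms), sps.rankdata(aa)
        keep = (
            (rm >= np.floor(k * trim_m) + 1) & (rm <= k - np.floor(k * trim_m))
            & (ra >= np.floor(k * trim_a) + 1) & (ra <= k - np.floor(k * trim_a))
        )
        factors[col] = 2 ** (np.sum(ws[keep] * ms[keep]) / np.sum(ws[keep]))
    vals = np.array([factors[c] for c in counts.columns])
    vals = vals / np.exp(np.mean(np.log(vals)))
    return pd.Series(vals, index=counts.columns)


def test_tmm_matches_brute_force_oracle():
    rng = np.random.default_rng(21)
    counts, ctrl = _control_matrix(rng, n_ctrl=50, n_lib=4,
                                   scale=[1.0, 0.6, 1.7, 2.5])
    # add non-control rows that must NOT influence the factors
    extra = _mk_counts(
        {c: rng.poisson(3000, size=30) for c in counts.columns},
        elements=[(f"E{i}", "forward") for i in range(30)],
    )
    full = pd.concat([counts, extra])
    got = control_anchored_tmm(full, ctrl)
    want = _oracle_tmm(full, ctrl)
    assert np.allclose(got.to_numpy(), want.to_numpy(), rtol=0.01)


def test_factors_ignore_non_control_rows():
    rng = np.random.default_rng(22)
    counts, ctrl = _control_matrix(rng, n_ctrl=50, n_lib=3)
    base = control_anchored_tmm(counts, ctrl)
    # pile reads onto one library's non-control rows: control-anchored factors
    # must keep normalized control counts aligned (libsize shift absorbed)
    extra = _mk_counts(
        {c: ([100000, 200, 300] if c == counts.columns[0] else [100, 200, 300])
         for c in counts.columns},
        elements=[(f"E{i}", "forward") for i in range(3)],
    )
    full = pd.concat([counts, extra])
    f = control_anchored_tmm(full, ctrl)
    n_base = normalized_cpm(counts, base)
    n_full = normalized_cpm(full, f).loc[counts.index]
    # cross-library alignment of control rows is what the factors guarantee;
    # approximate only: the libsize shift can move the reference column and
    # TMM is not exactly transitive across references (few-percent effect)
    ref = counts.columns[1]
    m_base = np.log2(n_base.div(n_base[ref], axis=0))
    m_full = np.log2(n_full.div(n_full[ref], axis=0))
    assert np.allclose(m_base, m_full, atol=0.05)


# ---------------------------------------------------------------------------
# activity
# ---------------------------------------------------------------------------

def _activity_cm(rna, dna):
    cols = ["RNA_promoter_rep1|m", "DNA_promoter_rep1|m"]
    counts = _mk_counts({cols[0]: rna, cols[1]: dna})
    return CountMatrix(elements=counts, meta=_meta(cols))


def test_activity_zero_when_rna_equals_dna():
    cm = _activity_cm([100, 50], [100, 50])
    f = pd.Series(1.0, index=cm.elements.columns)
    act = compute_activity(cm, f, pseudocount=0.5)
    assert np.allclose(act["A"], 0.0)


def test_activity_two_when_rna_is_4x_dna():
    # equal library sizes so CPM scaling cancels; no pseudocount distortion
    cm = _activity_cm([400, 100], [100, 400])
    f = pd.Series(1.0, index=cm.elements.columns)
    act = compute_activity(cm, f, pseudocount=0.0).set_index("element_id")
    assert act.loc["E0", "A"] == pytest.approx(2.0)
    assert act.loc["E1", "A"] == pytest.approx(-2.0)


def test_missing_dna_column_is_input_error():
    cols = ["RNA_promoter_rep1|m"]
    counts = _mk_counts({cols[0]: [10]})
    cm = CountMatrix(elements=counts, meta=_meta(cols))
    with pytest.raises(InputError):
        compute_activity(cm, pd.Series(1.0, index=cols))


def test_library_scaling_leaves_activity_unchanged():
    rng = np.random.default_rng(8)
    cols = ["RNA_promoter_rep1|m", "DNA_promoter_rep1|m",
            "RNA_promoter_rep2|m", "DNA_promoter_rep2|m"]
    vals = {c: rng.poisson(800, size=40) + 1 for c in cols}
    elements = [(f"ORF{i}" if i < 20 else f"E{i}", "forward") for i in range(40)]
    counts = _mk_counts(vals, elements)
    ctrl = [f"ORF{i}" for i in range(20)]
    cm = CountMatrix(elements=counts, meta=_meta(cols))
    a0 = compute_activity(cm, control_anchored_tmm(counts, ctrl))
    scaled = counts.copy()
    scaled[cols[2]] = scaled[cols[2]] * 7
    cm7 = CountMatrix(elements=scaled, meta=_meta(cols))
    a7 = compute_activity(cm7, control_anchored_tmm(scaled, ctrl))
    # scale cancels in the M statistics; only TMM precision weights move,
    # leaving activities unchanged to well below measurement resolution
    assert np.allclose(a0["A"], a7["A"], atol=5e-3)


# ---------------------------------------------------------------------------
# boost index and calls
# ---------------------------------------------------------------------------

def _act_table(a_values, ids=None, orientation="forward"):
    n = len(a_values)
    ids = ids or [f"E{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "element_id": ids,
            "orientation": orientation,
            "readout": "promoter",
            "minp": "m",
            "A": a_values,
        }
    )


def test_boost_index_printed_formula():
    act = _act_table([1.5, 1.5, 3.0, 0.0], ids=["ORF1", "ORF2", "E1", "E2"])
    controls = NegativeControlStats.from_activity(act, ["ORF1", "ORF2"])
    with pytest.raises(StateError):
        # degenerate sigma is fine for BI but mu floor applies to near-zero mean
        boost_index(act, NegativeControlStats.from_activity(
            _act_table([0.01, -0.01], ids=["ORF1", "ORF2"]), ["ORF1", "ORF2"]))
    bi = boost_index(act, controls)
    assert bi.tolist() == pytest.approx([1.0, 1.0, 2.0, 0.0])


def test_mean_control_boost_index_is_one():
    rng = np.random.default_rng(3)
    ids = [f"ORF{i}" for i in range(30)] + [f"E{i}" for i in range(100)]
    act = _act_table(list(rng.normal(-1.2, 0.4, 130)), ids=ids)
    controls = NegativeControlStats.from_activity(act, ids[:30])
    bi = boost_index(act, controls)
    assert bi[:30].mean() == pytest.approx(1.0, abs=1e-9)


def test_element_at_control_mean_is_inactive():
    rng = np.random.default_rng(14)
    rows = []
    for ori in ("forward", "reverse"):
        rows.append(_act_table(list(rng.normal(0, 0.3, 20)),
                               ids=[f"ORF{i}" for i in range(20)],
                               orientation=ori))
    mu = pd.concat(rows)["A"].mean()
    for ori in ("forward", "reverse"):
        rows.append(_act_table([mu], ids=["E0"], orientation=ori))
    act = pd.concat(rows, ignore_index=True)
    table, comb = call_active(act, [f"ORF{i}" for i in range(20)], alpha=0.05)
    assert not comb["active"].iloc[0]


def test_combined_call_requires_both_orientations():
    rng = np.random.default_rng(15)
    ctrl = [f"ORF{i}" for i in range(30)]
    frames = []
    for ori in ("forward", "reverse"):
        frames.append(_act_table(list(rng.normal(0, 0.2, 30)), ids=ctrl,
                                 orientation=ori))
    # E_hi active in both orientations; E_one only scored forward
    frames.append(_act_table([5.0], ids=["E_hi"], orientation="forward"))
    frames.append(_act_table([5.0], ids=["E_hi"], orientation="reverse"))
    frames.append(_act_table([5.0], ids=["E_one"], orientation="forward"))
    act = pd.concat(frames, ignore_index=True)
    table, comb = call_active(act, ctrl, alpha=0.05)
    comb = comb.set_index("element_id")
    assert bool(comb.loc["E_hi", "active"])
    assert not bool(comb.loc["E_one", "active"])
    # conjunction: combined-active element is active in each orientation
    per = table[table.element_id == "E_hi"]
    assert per["active"].all()


def test_call_is_monotone_in_rna_counts():
    rng = np.random.default_rng(16)
    cols = ["RNA_promoter_rep1|m", "DNA_promoter_rep1|m"]
    elements = (
        [(f"ORF{i}", o) for i in range(25) for o in ("forward", "reverse")]
        + [("E0", "forward"), ("E0", "reverse")]
    )
    vals = {c: rng.poisson(500, size=len(elements)) + 1 for c in cols}
    counts = _mk_counts(vals, elements)
    ctrl = [f"ORF{i}" for i in range(25)]

    def padj_of(counts):
        cm = CountMatrix(elements=counts, meta=_meta(cols))
        res = run_activity(cm, ctrl, alpha=0.05)
        sub = res.table[res.table.element_id == "E0"]
        return sub.set_index("orientation")["padj"]

    base = padj_of(counts)
    boosted = counts.copy()
    boosted.loc[("E0", "forward"), cols[0]] += 2000
    boosted.loc[("E0", "reverse"), cols[0]] += 2000
    upper = padj_of(boosted)
    assert (upper <= base + 1e-12).all()


def test_sigma_zero_is_state_error():
    act = pd.concat(
        [_act_table([1.0, 1.0], ids=["ORF1", "ORF2"]),
         _act_table([2.0], ids=["E1"])],
        ignore_index=True,
    )
    with pytest.raises(StateError):
        call_active(act, ["ORF1", "ORF2"])
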