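"""Barcode clustering, element matching, triplet assignment, minP demux."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dualmpra import InputError, StateError
from dualmpra.barcode_index import (
    BarcodeCluster,
    assign_triplets,
    build_index,
    cluster_barcodes,
    demux_minp,
    ElementMatcher,
    hamming,
    map_element_sequence,
)
from dualmpra.simulate import revcomp


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _brute_force_greedy(observed, max_dist=1):
    """Independent O(n^2) oracle: same greedy order, pairwise Hamming."""
    items = sorted(
        ((bc, c) for bc, c in observed.items() if "N" not in bc),
        key=lambda kv: (-kv[1], kv[0]),
    )
    clusters = []
    for bc, count in items:
        for rep, members in clusters:
            if sum(a != b for a, b in zip(bc, rep)) <= max_dist:
                members[bc] = members.get(bc, 0) + count
                break
        else:
            clusters.append((bc, {bc: count}))
    return clusters


def test_single_mismatch_merges_into_dominant():
    a = "ACGTACGTACGTACGTACGA"
    b = "ACGTACGTACGTACGTACGC"
    clusters = cluster_barcodes({a: 100, b: 3})
    assert len(clusters) == 1
    assert clusters[0].representative == a
    assert clusters[0].total_count == 103


def test_singleton_cluster():
    clusters = cluster_barcodes({"AAAAAAAA": 5})
    assert len(clusters) == 1
    assert clusters[0].members == {"AAAAAAAA": 5}


def test_mixed_lengths_rejected_with_offenders():
    with pytest.raises(InputError) as err:
        cluster_barcodes({"AAAAAAAA": 1, "AAAAAAAAA": 2})
    assert "AAAAAAAAA" in str(err.value)


def test_n_barcodes_dropped_before_clustering():
    clusters = cluster_barcodes({"AANAAAAA": 9, "AAAAAAAA": 1})
    assert len(clusters) == 1
    assert clusters[0].representative == "AAAAAAAA"


def test_clustering_matches_brute_force_oracle():
    rng = np.random.default_rng(123)
    bases = np.array(list("ACGT"))
    barcodes = {"".join(rng.choice(bases, 12)): int(rng.integers(1, 51))
                for _ in range(30)}
    got = cluster_barcodes(barcodes)
    expected = _brute_force_greedy(barcodes)
    assert [(c.representative, c.members) for c in got] == expected


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.dictionaries(
        st.text(alphabet="ACGT", min_size=8, max_size=8),
        st.integers(min_value=1, max_value=100),
        min_size=1,
        max_size=25,
    )
)
def test_clustering_invariants(observed):
    clusters = cluster_barcodes(observed)
    # reads conserved
    assert sum(c.total_count for c in clusters) == sum(observed.values())
    # distance-1 guarantee member -> representative; representative dominates
    for c in clusters:
        for m in c.members:
            assert hamming(m, c.representative) <= 1
        assert c.members[c.representative] == max(c.members.values())
    # deterministic under dict-order permutation
    again = cluster_barcodes(dict(reversed(list(observed.items()))))
    assert [(c.representative, c.members) for c in again] == [
        (c.representative, c.members) for c in clusters
    ]


# ---------------------------------------------------------------------------
# element matching
# ---------------------------------------------------------------------------

def _mismatches(a, b):
    return sum(x != y for x, y in zip(a, b))


def _oracle_match(query, catalog, plen, budget):
    best, best_d, tied = None, budget + 1, False
    for eid, seq in zip(catalog.element_id, catalog.sequence):
        for ori, pref in (("forward", seq[:plen]), ("reverse", revcomp(seq)[:plen])):
            d = _mismatches(query, pref)
            if d < best_d:
                best, best_d, tied = (eid, ori), d, False
            elif d == best_d and (eid, ori) != best:
                tied = True
    return best if (best_d <= budget and not tied) else None


def test_exact_forward_and_reverse_prefixes(toy_catalog):
    seq = toy_catalog.sequence[7]
    assert map_element_sequence(seq[:40], toy_catalog) == ("E7", "forward")
    assert map_element_sequence(revcomp(seq)[:40], toy_catalog) == ("E7", "reverse")


def test_mismatch_budget_and_ambiguity(toy_catalog):
    seq = toy_catalog.sequence[3]
    sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
    q = sub[seq[0]] + seq[1:20] + sub[seq[20]] + seq[21:40]
    matcher = ElementMatcher(toy_catalog, prefix_length=40, max_mismatch=3)
    assert _mismatches(q, seq[:40]) == 2
    assert matcher.match(q) == ("E3", "forward")
    # a shared prefix between two catalog entries is unresolvable
    dup = pd.concat(
        [toy_catalog, toy_catalog.iloc[[3]].assign(element_id="E99")],
        ignore_index=True,
    )
    assert map_element_sequence(seq[:40], dup) is None


def test_matcher_agrees_with_exhaustive_oracle(toy_catalog):
    rng = np.random.default_rng(7)
    bases = "ACGT"
    matcher = ElementMatcher(toy_catalog, prefix_length=40, max_mismatch=3)
    queries = []
    for _ in range(150):
        row = rng.integers(0, len(toy_catalog))
        seq = toy_catalog.sequence[row]
        pref = seq[:40] if rng.random() < 0.5 else revcomp(seq)[:40]
        k = int(rng.integers(0, 5))
        q = list(pref)
        for pos in rng.choice(40, size=k, replace=False):
            q[pos] = bases[(bases.index(q[pos]) + int(rng.integers(1, 4))) % 4]
        queries.append("".join(q))
    for q in queries:
        assert matcher.match(q) == _oracle_match(q, toy_catalog, 40, 3), q


def test_empty_catalog_is_state_error():
    with pytest.raises(StateError):
        ElementMatcher({}, prefix_length=40)


# ---------------------------------------------------------------------------
# triplet assignment
# ---------------------------------------------------------------------------

def test_clear_dominance_assigned():
    counts = {("EA" * 10, "CT" * 10): {("A", "forward"): 50, ("B", "forward"): 1}}
    idx = assign_triplets(counts, dominance_ratio=5, min_support=3)
    assert len(idx.entries) == 1
    assert idx.entries.element_id[0] == "A"
    assert idx.entries.support[0] == 50


def test_ambiguous_pair_discarded():
    counts = {("EA" * 10, "CT" * 10): {("A", "forward"): 4, ("B", "forward"): 3}}
    idx = assign_triplets(counts, dominance_ratio=5, min_support=3)
    assert len(idx.entries) == 0
    assert list(idx.discards.reason) == ["ambiguous"]


def test_low_support_discarded():
    counts = {("EA" * 10, "CT" * 10): {("A", "forward"): 2}}
    idx = assign_triplets(counts, min_support=3)
    assert len(idx.entries) == 0
    assert list(idx.discards.reason) == ["low_support"]


def test_assignment_is_a_function():
    rng = np.random.default_rng(5)
    counts = {}
    for i in range(200):
        pair = (f"A{i:019d}", f"B{i:019d}")
        counts[pair] = {
            (f"E{rng.integers(0, 20)}", "forward"): int(rng.integers(1, 40))
            for _ in range(rng.integers(1, 4))
        }
    idx = assign_triplets(counts)
    keys = idx.entries[["eaBC_rep", "paBC_rep"]].apply(tuple, axis=1)
    assert keys.is_unique


def test_noiseless_index_equals_ground_truth(noiseless_run):
    truth = noiseless_run["truth"]
    idx = noiseless_run["index"]
    got = (
        idx.entries[["eaBC_rep", "paBC_rep", "element_id", "orientation", "minp"]]
        .sort_values(["eaBC_rep", "paBC_rep"])
        .reset_index(drop=True)
    )
    want = (
        truth.barcodes.rename(columns={"eaBC": "eaBC_rep", "paBC": "paBC_rep"})[
            ["eaBC_rep", "paBC_rep", "element_id", "orientation", "minp"]
        ]
        .sort_values(["eaBC_rep", "paBC_rep"])
        .reset_index(drop=True)
    )
    pd.testing.assert_frame_equal(got, want)


def test_complexity_report_flags_thin_elements(noiseless_run):
    comp = noiseless_run["index"].complexity(min_barcodes_per_element=10)
    # fixture uses 5 pairs per construct: everything is low-complexity at 10
    assert comp["low_complexity"].all()
    assert (comp["n_pairs"] == 5).all()
    assert not noiseless_run["index"].complexity(5)["low_complexity"].any()


def test_recovery_with_1pct_sequencing_error():
    from conftest import noiseless_config
    from dualmpra.simulate import simulate_elements, simulate_index_reads

    cfg = noiseless_config(n_proximal=10, n_distal=20, n_orf_controls=10,
                           barcodes_per_element=10, seq_error_rate=0.01, seed=29)
    catalog, truth = simulate_elements(cfg)
    reads = simulate_index_reads(catalog, truth, cfg)
    idx = build_index(reads.r1, reads.r2, catalog, cfg)
    want = {
        (r.eaBC, r.paBC, r.element_id, r.orientation)
        for r in truth.barcodes.itertuples(index=False)
    }
    got = {
        (r.eaBC_rep, r.paBC_rep, r.element_id, r.orientation)
        for r in idx.entries.itertuples(index=False)
    }
    assert len(want & got) / len(want) >= 0.99


# ---------------------------------------------------------------------------
# minP demux
# ---------------------------------------------------------------------------

def test_minp_demux_exact_match_only():
    table = {"ACT": "pMYC", "GAA": "pGAPDH", "TTC": "pAPOBEC3F"}
    assert demux_minp("ACT", table) == "pMYC"
    assert demux_minp("AAA", table) is None
    assert demux_minp("ACU", table) is None
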