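"""Build the eaBC-element-paBC index from index-mapping reads.

Barcodes are error-corrected by greedy abundance-ordered clustering with a
Hamming-distance-1 tolerance; partial element sequences are matched against
the reference catalog in both orientations; each (eaBC, paBC) pair is
assigned to the element it dominantly co-occurs with, discarding chimeric or
ambiguous pairs; a 3-bp tag demultiplexes minimal-promoter library sets.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .config import BASES, SimulationConfig
from .errors import InputError, StateError
from .simulate import revcomp
from . import io as dio


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise InputError(f"length mismatch: {a!r} vs {b!r}")
    return sum(x != y for x, y in zip(a, b))


def _variants1(seq: str) -> Iterable[str]:
    """The sequence itself plus every Hamming-distance-1 substitution."""
    yield seq
    for i, c in enumerate(seq):
        for b in BASES:
            if b != c:
                yield seq[:i] + b + seq[i + 1 :]


def required_colonies(n_elements: int, barcodes_per_element: int) -> int:
    """Minimum colony count for the target index complexity.

    The number of colonies must exceed the product of the number of elements
    surveyed and the desired number of uniquely assigned barcode pairs per
    element (e.g. 100 elements x 100 pairs -> 10,000 colonies)."""
    return int(n_elements) * int(barcodes_per_element)


# ---------------------------------------------------------------------------
# barcode clustering
# ---------------------------------------------------------------------------

@dataclass
class BarcodeCluster:
    """One error-corrected barcode: highest-count member is the representative;
    every member lies within Hamming distance 1 of it."""

    representative: str
    members: Dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.members.values())


def cluster_barcodes(observed: Mapping[str, int], max_dist: int = 1
                     ) -> List[BarcodeCluster]:
    """Greedy abundance-ordered clustering with member-to-representative
    distance <= ``max_dist``.

    Barcodes are processed by descending count (ties broken lexicographically);
    each joins the earliest-founded cluster whose representative is within
    ``max_dist``, else founds a new cluster. Barcodes containing N are dropped
    up front. Chains A-B-C at pairwise distance 1 but end-to-end distance 2
    therefore split into two clusters, keeping the distance guarantee exact.
    """
    items = [(bc, int(c)) for bc, c in observed.items() if "N" not in bc]
    if not items:
        return []
    lengths = {len(bc) for bc, _ in items}
    if len(lengths) != 1:
        shortest = min(lengths)
        bad = sorted(bc for bc, _ in items if len(bc) != shortest)
        raise InputError(f"mixed barcode lengths {sorted(lengths)}: {bad[:10]}")
    if any(c < 1 for _, c in items):
        raise InputError("all barcode counts must be >= 1")

    items.sort(key=lambda kv: (-kv[1], kv[0]))
    clusters: List[BarcodeCluster] = []

    if max_dist == 1:
        variant_owner: Dict[str, int] = {}
        for bc, count in items:
            idx = variant_owner.get(bc)
            if idx is None:
                idx = len(clusters)
                clusters.append(BarcodeCluster(representative=bc))
                for v in _variants1(bc):
                    variant_owner.setdefault(v, idx)
            clusters[idx].members[bc] = clusters[idx].members.get(bc, 0) + count
    else:
        for bc, count in items:
            for cl in clusters:
                if hamming(bc, cl.representative) <= max_dist:
                    cl.members[bc] = cl.members.get(bc, 0) + count
                    break
            else:
                clusters.append(BarcodeCluster(representative=bc, members={bc: count}))
    return clusters


def member_to_representative(clusters: List[BarcodeCluster]) -> Dict[str, str]:
    return {m: cl.representative for cl in clusters for m in cl.members}


# ---------------------------------------------------------------------------
# element sequence matching
# ---------------------------------------------------------------------------

_AMBIG = ("__ambiguous__", "")


class ElementMatcher:
    """Orientation-aware prefix matcher against the reference catalog.

    Matches a partial element sequence to the unique catalog entry (forward
    sequence prefix, or reverse-complement prefix for reverse-cloned inserts)
    within a mismatch budget; equal-best ties and over-budget queries return
    no-hit. Mismatch-only: indels are not tolerated.
    """

    def __init__(self, catalog, prefix_length: int = 40, max_mismatch: int = 3):
        if isinstance(catalog, pd.DataFrame):
            seqs = dict(zip(catalog["element_id"], catalog["sequence"]))
        else:
            seqs = dict(catalog)
        if not seqs:
            raise StateError("catalog is empty")
        self.prefix_length = prefix_length
        self.max_mismatch = max_mismatch
        self._entries: List[Tuple[str, str, str]] = []  # (prefix, id, orientation)
        exact: Dict[str, Tuple[str, str]] = {}
        for eid, seq in seqs.items():
            for ori, pref in (
                ("forward", seq[:prefix_length]),
                ("reverse", revcomp(seq)[:prefix_length]),
            ):
                self._entries.append((pref, eid, ori))
                if pref in exact and exact[pref] != (eid, ori):
                    exact[pref] = _AMBIG
                else:
                    exact.setdefault(pref, (eid, ori))
        self._exact = exact
        self._cache: Dict[str, Optional[Tuple[str, str]]] = {}

    def match(self, partial: str) -> Optional[Tuple[str, str]]:
        if partial in self._cache:
            return self._cache[partial]
        hit = self._match_uncached(partial)
        self._cache[partial] = hit
        return hit

    def _match_uncached(self, partial: str) -> Optional[Tuple[str, str]]:
        if len(partial) != self.prefix_length:
            return None
        hit = self._exact.get(partial)
        if hit is not None:
            return None if hit == _AMBIG else hit
        if self.max_mismatch < 1:
            return None
        # distance-1 neighbourhood lookup
        hits = set()
        for v in _variants1(partial):
            h = self._exact.get(v)
            if h is not None:
                hits.add(h)
        hits.discard(_AMBIG)
        if len(hits) == 1:
            return hits.pop()
        if len(hits) > 1:
            return None
        if self.max_mismatch < 2:
            return None
        # rare multi-error reads: full scan for the unique minimum-distance hit
        best, best_d, tied = None, self.max_mismatch + 1, False
        for pref, eid, ori in self._entries:
            d = 0
            for x, y in zip(partial, pref):
                if x != y:
                    d += 1
                    if d >= best_d + 1:
                        break
            if d < best_d:
                best, best_d, tied = (eid, ori), d, False
            elif d == best_d and (eid, ori) != best:
                tied = True
        if best is not None and best_d <= self.max_mismatch and not tied:
            return best
        return None


def map_element_sequence(partial_seq: str, catalog, max_mismatch: int = 3
                         ) -> Optional[Tuple[str, str]]:
    """One-shot wrapper around :class:`ElementMatcher` (build the matcher
    directly when matching many reads)."""
    return ElementMatcher(
        catalog, prefix_length=len(partial_seq), max_mismatch=max_mismatch
    ).match(partial_seq)


# ---------------------------------------------------------------------------
# minP demultiplexing
# ---------------------------------------------------------------------------

def demux_minp(tag: str, tag_table: Mapping[str, str]) -> Optional[str]:
    """Exact-match lookup of the 3-bp minimal-promoter tag; 3-mers are too
    short to absorb sequencing errors safely, so no mismatch tolerance."""
    return tag_table.get(tag)


# ---------------------------------------------------------------------------
# triplet assignment
# ---------------------------------------------------------------------------

@dataclass
class BarcodeIndex:
    """Assigned (eaBC, paBC) -> (element, orientation, minP) mapping.

    ``entries`` has columns eaBC_rep, paBC_rep, element_id, orientation,
    minp, support; each pair maps to at most one element by construction.
    """

    entries: pd.DataFrame
    discards: pd.DataFrame = None
    stats: Dict[str, int] = field(default_factory=dict)

    def complexity(self, min_barcodes_per_element: int = 10) -> pd.DataFrame:
        """Barcode pairs per construct; constructs under the design minimum
        (>= 10 uniquely assigned pairs) are flagged low-complexity."""
        tally = (
            self.entries.groupby(["element_id", "orientation"])
            .size()
            .rename("n_pairs")
            .reset_index()
        )
        tally["low_complexity"] = tally["n_pairs"] < min_barcodes_per_element
        return tally

    def readout_lookup(self, readout: str) -> Dict[str, Tuple[str, str, str]]:
        """Map each activity barcode (paBC for the promoter readout, eaBC for
        the enhancer readout) to (element_id, orientation, minp); barcodes
        appearing in entries for more than one construct are dropped as
        ambiguous."""
        col = "paBC_rep" if readout == "promoter" else "eaBC_rep"
        out: Dict[str, Tuple[str, str, str]] = {}
        bad = set()
        for row in self.entries.itertuples(index=False):
            bc = getattr(row, col)
            tgt = (row.element_id, row.orientation, row.minp)
            if bc in out and out[bc] != tgt:
                bad.add(bc)
            else:
                out[bc] = tgt
        for bc in bad:
            del out[bc]
        return out

    def to_tsv(self, path) -> None:
        dio.write_tsv(path, self.entries)

    @classmethod
    def from_tsv(cls, path) -> "BarcodeIndex":
        return cls(entries=dio.read_tsv(path))


def assign_triplets(
    triplet_counts: Mapping[Tuple[str, str], Mapping[Tuple[str, str], int]],
    dominance_ratio: float = 5.0,
    min_support: int = 3,
    minp_votes: Optional[Mapping[Tuple[str, str], Mapping[str, int]]] = None,
) -> BarcodeIndex:
    """Assign each (eaBC, paBC) pair to its dominant element.

    A pair is assigned to element A iff its support count(A) >= ``min_support``
    and count(A) >= ``dominance_ratio`` times the count of every other element
    seen with the pair; otherwise the pair is discarded as chimeric/ambiguous.
    The pair's minP label is the majority vote (ties to the lexicographically
    smallest label).
    """
    rows, discards = [], []
    for pair, per_element in triplet_counts.items():
        ranked = sorted(per_element.items(), key=lambda kv: (-kv[1], kv[0]))
        (eid, ori), top = ranked[0]
        runner = ranked[1][1] if len(ranked) > 1 else 0
        if top < min_support:
            discards.append((*pair, "low_support", top))
            continue
        if runner > 0 and top < dominance_ratio * runner:
            discards.append((*pair, "ambiguous", top))
            continue
        if minp_votes and pair in minp_votes and minp_votes[pair]:
            votes = minp_votes[pair]
            minp = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        else:
            minp = "NA"
        rows.append((pair[0], pair[1], eid, ori, minp, top))

    entries = pd.DataFrame(
        rows,
        columns=["eaBC_rep", "paBC_rep", "element_id", "orientation", "minp", "support"],
    ).sort_values(["element_id", "orientation", "eaBC_rep"], ignore_index=True)
    disc = pd.DataFrame(
        discards, columns=["eaBC_rep", "paBC_rep", "reason", "support"]
    )
    stats = {
        "assigned_pairs": len(entries),
        "discarded_pairs": len(disc),
    }
    return BarcodeIndex(entries=entries, discards=disc, stats=stats)


# ---------------------------------------------------------------------------
# orchestration: reads -> index
# ---------------------------------------------------------------------------

def build_index(
    r1_seqs: Iterable[str],
    r2_seqs: Iterable[str],
    catalog,
    config: SimulationConfig,
    dominance_ratio: float = 5.0,
    min_support: int = 3,
    max_mismatch: int = 3,
) -> BarcodeIndex:
    """Full index-mapping stage: extract fields, cluster barcodes, match
    element prefixes, demultiplex minP tags, and assign dominant triplets.

    Triplet support is counted as distinct UMIs per (pair, element) so PCR
    jackpots cannot manufacture dominance.
    """
    lay1 = config.index_layout_r1()
    lay2 = config.index_layout_r2()
    b = config.barcode_length
    p = config.element_prefix_length
    u = config.umi_length
    ea_s, ea_e = lay1.fields["eaBC"]
    umi_s = lay1.fields["umi"][0]
    el_s = lay2.fields["element"][0]
    pa_s = lay2.fields["paBC"][0]
    mp_s = lay2.fields["minp"][0]

    reads = []
    n_short = 0
    span1, span2 = lay1.span, lay2.span
    for s1, s2 in zip(r1_seqs, r2_seqs):
        if len(s1) < span1 or len(s2) < span2:
            n_short += 1
            continue
        reads.append(
            (
                s1[ea_s : ea_s + b],
                s1[umi_s : umi_s + u],
                s2[el_s : el_s + p],
                s2[pa_s : pa_s + b],
                s2[mp_s : mp_s + 3],
            )
        )

    ea_counts = Counter(r[0] for r in reads)
    pa_counts = Counter(r[3] for r in reads)
    ea_clusters = cluster_barcodes(ea_counts)
    pa_clusters = cluster_barcodes(pa_counts)
    ea_rep = member_to_representative(ea_clusters)
    pa_rep = member_to_representative(pa_clusters)

    matcher = ElementMatcher(catalog, prefix_length=p, max_mismatch=max_mismatch)
    tag_table = config.minp_tags

    triplet_umis: Dict = defaultdict(lambda: defaultdict(set))
    minp_votes: Dict = defaultdict(Counter)
    n_nohit = n_bad_tag = n_dropped_bc = 0
    for ea, umi, prefix, pa, tag in reads:
        er, pr = ea_rep.get(ea), pa_rep.get(pa)
        if er is None or pr is None or "N" in umi:
            n_dropped_bc += 1
            continue
        hit = matcher.match(prefix)
        if hit is None:
            n_nohit += 1
            continue
        label = demux_minp(tag, tag_table)
        if label is None:
            n_bad_tag += 1
            continue
        triplet_umis[(er, pr)][hit].add(umi)
        minp_votes[(er, pr)][label] += 1

    triplet_counts = {
        pair: {hit: len(umis) for hit, umis in per.items()}
        for pair, per in triplet_umis.items()
    }
    index = assign_triplets(
        triplet_counts,
        dominance_ratio=dominance_ratio,
        min_support=min_support,
        minp_votes=minp_votes,
    )
    index.stats.update(
        {
            "reads": len(reads),
            "reads_too_short": n_short,
            "reads_no_element_hit": n_nohit,
            "reads_bad_minp_tag": n_bad_tag,
            "reads_dropped_barcode": n_dropped_bc,
            "ea_clusters": len(ea_clusters),
            "pa_clusters": len(pa_clusters),
        }
    )
    return index
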