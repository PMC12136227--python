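"""Activity-measurement quantification: reads -> UMI-collapsed count matrices.

Each RNA/DNA library read carries one activity barcode (paBC for the promoter
readout, eaBC for the enhancer readout), the 3-bp minP tag, and a UMI.
Barcodes are matched to the clustered index with Hamming-distance-1 tolerance
to the cluster representative (the same tolerance the index clustering used);
identical (barcode, UMI) copies collapse to a single molecule; counts are
aggregated per element x library column, with barcode-level matrices retained
for QC and replicate-precision estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .barcode_index import BarcodeIndex, _variants1, demux_minp
from .config import ReadLayout, SimulationConfig
from .errors import InputError
from . import io as dio

_CONFLICT = object()


@dataclass
class CountMatrix:
    """UMI-collapsed counts.

    elements : DataFrame indexed by (element_id, orientation); one column per
               (library, minP) combination
    barcodes : same columns, indexed by (element_id, orientation, aBC_rep)
    meta     : one row per column: column_id, lib_type, readout, replicate, minp
    """

    elements: pd.DataFrame
    meta: pd.DataFrame
    barcodes: Optional[pd.DataFrame] = None
    stats: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def to_tsv(self, prefix) -> None:
        dio.write_tsv(f"{prefix}_elements.tsv", self.elements.reset_index())
        dio.write_tsv(f"{prefix}_meta.tsv", self.meta)
        if self.barcodes is not None:
            dio.write_tsv(f"{prefix}_barcodes.tsv", self.barcodes.reset_index())

    @classmethod
    def from_tsv(cls, prefix) -> "CountMatrix":
        el = dio.read_tsv(f"{prefix}_elements.tsv").set_index(
            ["element_id", "orientation"]
        )
        meta = dio.read_tsv(f"{prefix}_meta.tsv")
        try:
            bc = dio.read_tsv(f"{prefix}_barcodes.tsv").set_index(
                ["element_id", "orientation", "aBC_rep"]
            )
        except FileNotFoundError:
            bc = None
        return cls(elements=el, meta=meta, barcodes=bc)


# ---------------------------------------------------------------------------
# per-read operations
# ---------------------------------------------------------------------------

def extract_readout(seq: str, layout: ReadLayout) -> Optional[Dict[str, str]]:
    """Slice the activity barcode / minP tag / UMI out of one read.

    Rejects (returns None) reads shorter than the layout span or with N in
    the barcode or UMI fields."""
    fields = layout.extract(seq)
    if fields is None:
        return None
    if "N" in fields["aBC"] or "N" in fields["umi"]:
        return None
    return fields


def build_match_lookup(index: BarcodeIndex, readout: str) -> Dict[str, tuple]:
    """Variant table mapping any sequence within Hamming distance 1 of an
    indexed barcode representative to (element_id, orientation, minp).

    Variants reachable from two different constructs are dropped as
    unresolvable."""
    base = index.readout_lookup(readout)
    lut: Dict[str, tuple] = {}
    for rep, tgt in base.items():
        for v in _variants1(rep):
            prev = lut.get(v)
            if prev is None:
                lut[v] = tgt
            elif prev is not _CONFLICT and prev != tgt:
                lut[v] = _CONFLICT
    return {v: t for v, t in lut.items() if t is not _CONFLICT}


def match_barcode(abc: str, lookup: Mapping[str, tuple]) -> Optional[tuple]:
    """Match an observed activity barcode to its construct, tolerating one
    substitution relative to the cluster representative."""
    return lookup.get(abc)


# ---------------------------------------------------------------------------
# UMI collapse
# ---------------------------------------------------------------------------

def umi_collapse(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse identical (barcode, UMI) copies to single molecules.

    ``records`` needs columns element_id, orientation, column, aBC, umi; the
    result counts distinct (aBC, umi) pairs per (element_id, orientation,
    column). Idempotent and order-independent by construction.
    """
    required = {"element_id", "orientation", "column", "aBC", "umi"}
    missing = required - set(records.columns)
    if missing:
        raise InputError(f"records missing columns {sorted(missing)}")
    if len(records) == 0:
        return pd.DataFrame(
            columns=["element_id", "orientation", "column", "aBC", "count"]
        )
    dedup = records.drop_duplicates(
        subset=["element_id", "orientation", "column", "aBC", "umi"]
    )
    return (
        dedup.groupby(["element_id", "orientation", "column", "aBC"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def quantify_libraries(
    libraries: Mapping[str, Iterable[str]],
    metadata: pd.DataFrame,
    index: BarcodeIndex,
    config: SimulationConfig,
) -> CountMatrix:
    """Quantify every RNA/DNA library against the barcode index.

    ``libraries`` maps library id to read sequences (or a FASTQ path);
    ``metadata`` needs columns library_id, lib_type, readout, replicate.
    Reads whose observed minP tag conflicts with the index entry for their
    barcode are dropped as index violations.
    """
    layout = config.quant_layout()
    tag_table = config.minp_tags
    lookups = {r: build_match_lookup(index, r) for r in ("promoter", "enhancer")}

    frames = []
    stats: Dict[str, Dict[str, int]] = {}
    meta_rows = []
    for row in metadata.itertuples(index=False):
        lib_id = row.library_id
        reads = libraries[lib_id]
        if isinstance(reads, (str,)) or hasattr(reads, "__fspath__"):
            reads = (seq for _name, seq in dio.read_fastq(reads))
        lut = lookups[row.readout]
        recs = []
        c = {"reads": 0, "rejected": 0, "unmatched": 0, "index_violation": 0,
             "matched": 0}
        abc_s, abc_l = layout.fields["aBC"]
        mp_s = layout.fields["minp"][0]
        umi_s, umi_l = layout.fields["umi"]
        span = layout.span
        for seq in reads:
            c["reads"] += 1
            if len(seq) < span:
                c["rejected"] += 1
                continue
            abc = seq[abc_s : abc_s + abc_l]
            umi = seq[umi_s : umi_s + umi_l]
            if "N" in abc or "N" in umi:
                c["rejected"] += 1
                continue
            tgt = lut.get(abc)
            if tgt is None:
                c["unmatched"] += 1
                continue
            eid, ori, minp = tgt
            tag_label = demux_minp(seq[mp_s : mp_s + 3], tag_table)
            if tag_label is not None and minp != "NA" and tag_label != minp:
                c["index_violation"] += 1
                continue
            c["matched"] += 1
            recs.append((eid, ori, f"{lib_id}|{minp}", abc, umi))
        stats[lib_id] = c
        if recs:
            frames.append(
                pd.DataFrame(
                    recs, columns=["element_id", "orientation", "column", "aBC", "umi"]
                )
            )
        for minp in sorted(set(index.entries["minp"])):
            meta_rows.append(
                (f"{lib_id}|{minp}", row.lib_type, row.readout, row.replicate, minp)
            )

    meta = pd.DataFrame(
        meta_rows, columns=["column_id", "lib_type", "readout", "replicate", "minp"]
    ).drop_duplicates(ignore_index=True)

    if frames:
        records = pd.concat(frames, ignore_index=True)
        collapsed = umi_collapse(records)
    else:
        collapsed = umi_collapse(
            pd.DataFrame(columns=["element_id", "orientation", "column", "aBC", "umi"])
        )

    bc_level = collapsed.rename(columns={"aBC": "aBC_rep"}).pivot_table(
        index=["element_id", "orientation", "aBC_rep"],
        columns="column",
        values="count",
        fill_value=0,
        aggfunc="sum",
    )
    el_level = bc_level.groupby(level=["element_id", "orientation"]).sum()
    # make every declared column present even if no read matched it
    for col in meta["column_id"]:
        if col not in el_level.columns:
            el_level[col] = 0
            bc_level[col] = 0
    el_level = el_level[sorted(el_level.columns)].astype(np.int64)
    bc_level = bc_level[sorted(bc_level.columns)].astype(np.int64)
    el_level.columns.name = None
    bc_level.columns.name = None
    meta = meta[meta["column_id"].isin(el_level.columns)].reset_index(drop=True)
    return CountMatrix(elements=el_level, meta=meta, barcodes=bc_level, stats=stats)
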