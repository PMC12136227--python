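"""Ground-truth simulator for the dual-readout reporter assay.

Generates an element catalog (proximal/distal candidates plus negative-control
ORFs with class-dependent GC content), a barcode index with collision and
chimera noise, and raw index-mapping and activity-measurement read sets with
per-base substitution errors and UMI-tagged PCR duplication — everything the
downstream pipeline consumes, with the generative truth retained so recovery
can be scored.

Latent activity model: each element carries a (promoter, enhancer) activity
pair in log2 units drawn from a bivariate normal with class-specific mean/SD
and a configurable correlation; negative-control ORFs sit at the basal level
(class SD 0 by default). Molecule counts follow a log-normal-Poisson
hierarchy: per-barcode DNA abundance lambda ~ log-normal, DNA ~ Poisson(lambda),
RNA ~ Poisson(lambda * 2^activity * log-normal noise). This RNA noise model is a
stand-in for the (unspecified) noise of real reporter libraries; it matches
the overdispersion of typical MPRA counts but is not derived from data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .config import BASES, SimulationConfig
from .errors import StateError
from . import io as dio

_BASE_S1 = np.frombuffer(b"ACGT", dtype="S1")
_IDX_OF = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _IDX_OF[_b] = _i

READOUTS = ("promoter", "enhancer")

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# vectorised sequence helpers
# ---------------------------------------------------------------------------

def _seq_matrix(seqs, length: int) -> np.ndarray:
    """Pack equal-length sequences into an (n, length) S1 matrix."""
    joined = "".join(seqs).encode()
    return np.frombuffer(joined, dtype="S1").reshape(-1, length).copy()


def _mat_to_seqs(mat: np.ndarray) -> np.ndarray:
    n, length = mat.shape
    return np.char.decode(np.ascontiguousarray(mat).view(f"S{length}").ravel())


def _random_mat(rng: np.random.Generator, n: int, length: int,
                p=None) -> np.ndarray:
    if p is None:
        idx = rng.integers(0, 4, size=(n, length))
    else:
        idx = rng.choice(4, size=(n, length), p=p)
    return _BASE_S1[idx]


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    return _mat_to_seqs(_random_mat(rng, n, k))


def _unique_kmers(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """n distinct random k-mers (rejection sampling; collisions are rare for
    k >= 8)."""
    out: list = []
    seen: set = set()
    while len(out) < n:
        batch = _random_kmers(rng, n - len(out), k)
        for s in batch:
            if s not in seen:
                seen.add(s)
                out.append(s)
    return np.array(out)


def _apply_errors(mat: np.ndarray, rng: np.random.Generator, rate: float) -> int:
    """In-place iid per-base substitutions at ``rate``; returns #substitutions."""
    if rate <= 0 or mat.size == 0:
        return 0
    total = mat.size
    k = rng.binomial(total, rate)
    if k == 0:
        return 0
    pos = rng.choice(total, size=k, replace=False)
    flat = mat.reshape(-1)
    old = _IDX_OF[flat[pos].view(np.uint8)]
    new = (old + rng.integers(1, 4, size=k)) % 4
    flat[pos] = _BASE_S1[new]
    return int(k)


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # independent stream per stage so stages are reproducible in isolation
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Generative truth retained alongside the simulated raw data.

    elements   : element_id, el_class, chrom, start, end, gc, sequence
    activities : element_id, orientation, latent_promoter, latent_enhancer
    barcodes   : eaBC, paBC, element_id, orientation, minp, collided
    molecules  : per (barcode pair, readout, replicate) DNA/RNA molecule
                 counts (filled by :func:`simulate_counts`)
    """

    elements: pd.DataFrame
    activities: pd.DataFrame
    barcodes: pd.DataFrame
    molecules: Optional[pd.DataFrame] = None
    index_stats: Dict[str, int] = field(default_factory=dict)

    @property
    def control_ids(self) -> list:
        els = self.elements
        return sorted(els.loc[els.el_class == "orf_control", "element_id"])


@dataclass
class IndexReads:
    """Paired index-mapping reads plus emission statistics."""

    r1: np.ndarray
    r2: np.ndarray
    stats: Dict[str, int]


# ---------------------------------------------------------------------------
# element catalog
# ---------------------------------------------------------------------------

def simulate_elements(config: SimulationConfig) -> Tuple[pd.DataFrame, GroundTruth]:
    """Draw the element catalog, latent activities, and the true barcode index.

    Elements are laid out on a toy chromosome ``chrS``; per-class GC content
    is controlled through base-composition sampling. Each element is cloned
    in both orientations, sharing its element id; reverse-orientation latent
    activities equal the forward ones plus optional asymmetry noise.
    """
    rng = _stage_rng(config, 0)
    classes = (
        ["proximal"] * config.n_proximal
        + ["distal"] * config.n_distal
        + ["orf_control"] * config.n_orf_controls
    )
    n = len(classes)
    if n == 0:
        raise StateError("catalog would be empty: all element counts are zero")

    ids = [f"E{i:05d}" for i in range(n)]
    length = config.element_length
    seqs = np.empty(n, dtype=object)
    cls_arr = np.array(classes)
    for cls in set(classes):
        sel = np.flatnonzero(cls_arr == cls)
        gc = config.gc_by_class[cls]
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
        mat = _random_mat(rng, len(sel), length, p=p)
        seqs[sel] = _mat_to_seqs(mat)
    gc_frac = np.array([(s.count("G") + s.count("C")) / length for s in seqs])

    # latent (P, E): bivariate normal with correlation rho, class mean/SD
    rho = config.true_activity_corr
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)
    mu = np.array([config.activity_means_by_class[c] for c in classes])
    sd = np.array([config.activity_sds_by_class[c] for c in classes])
    lat_p = mu + sd * z1
    lat_e = mu + sd * z2

    gap = 800
    starts = 1000 + np.arange(n) * (length + gap)
    elements = pd.DataFrame(
        {
            "element_id": ids,
            "el_class": classes,
            "chrom": "chrS",
            "start": starts,
            "end": starts + length,
            "gc": gc_frac,
            "sequence": seqs,
        }
    )

    rows = []
    asym = config.orientation_asymmetry_sd
    for i, eid in enumerate(ids):
        rows.append((eid, "forward", lat_p[i], lat_e[i]))
        dp = asym * rng.standard_normal() if asym > 0 else 0.0
        de = asym * rng.standard_normal() if asym > 0 else 0.0
        rows.append((eid, "reverse", lat_p[i] + dp, lat_e[i] + de))
    activities = pd.DataFrame(
        rows, columns=["element_id", "orientation", "latent_promoter", "latent_enhancer"]
    )

    barcodes = _assign_barcodes(config, activities, rng)
    truth = GroundTruth(elements=elements, activities=activities, barcodes=barcodes)
    return elements, truth


def _assign_barcodes(config: SimulationConfig, activities: pd.DataFrame,
                     rng: np.random.Generator) -> pd.DataFrame:
    n_constructs = len(activities)
    bpe = config.barcodes_per_element
    n_pairs = n_constructs * bpe
    ea = _unique_kmers(rng, n_pairs, config.barcode_length)
    pa = _unique_kmers(rng, n_pairs, config.barcode_length)

    construct_idx = np.repeat(np.arange(n_constructs), bpe)
    labels = list(config.minp_tags.values())
    if config.minp_mix is None:
        probs = np.full(len(labels), 1.0 / len(labels))
    else:
        w = np.array([config.minp_mix[l] for l in labels], dtype=float)
        probs = w / w.sum()
    minp = rng.choice(labels, size=n_pairs, p=probs)

    collided = np.zeros(n_pairs, dtype=bool)
    if config.collision_rate > 0 and n_constructs > 1:
        k = rng.binomial(n_pairs, config.collision_rate)
        if k:
            victims = rng.choice(n_pairs, size=k, replace=False)
            for v in victims:
                others = np.flatnonzero(construct_idx != construct_idx[v])
                src = rng.choice(others)
                ea[v] = ea[src]  # barcode collision: eaBC shared across elements
                collided[v] = collided[src] = True

    return pd.DataFrame(
        {
            "eaBC": ea,
            "paBC": pa,
            "element_id": activities["element_id"].to_numpy()[construct_idx],
            "orientation": activities["orientation"].to_numpy()[construct_idx],
            "minp": minp,
            "collided": collided,
        }
    )


# ---------------------------------------------------------------------------
# index-mapping reads
# ---------------------------------------------------------------------------

#: read-count floor per barcode pair, reflecting colony-level amplification of
#: the pre-transfection index library (every cloned pair is deeply covered)
INDEX_READ_FLOOR = 3


def simulate_index_reads(catalog: pd.DataFrame, truth: GroundTruth,
                         config: SimulationConfig,
                         chimera_rate: Optional[float] = None) -> IndexReads:
    """Emit paired index-mapping reads for every true barcode pair.

    R1 = eaBC + UMI; R2 = element-sequence prefix + paBC + minP tag. A
    ``chimera_rate`` fraction of reads carries the element prefix of a
    *different* construct, mimicking template switching during amplification.
    """
    if catalog is None or len(catalog) == 0:
        raise StateError("catalog is empty")
    rng = _stage_rng(config, 1)
    rate = config.chimera_rate if chimera_rate is None else chimera_rate
    bc = truth.barcodes
    n_pairs = len(bc)

    plen = config.element_prefix_length
    seq_by_id = dict(zip(catalog["element_id"], catalog["sequence"]))
    constructs = truth.activities[["element_id", "orientation"]]
    prefixes = [
        seq_by_id[eid][:plen] if ori == "forward" else revcomp(seq_by_id[eid])[:plen]
        for eid, ori in constructs.itertuples(index=False)
    ]
    prefix_mat = _seq_matrix(prefixes, plen)
    construct_key = {
        (eid, ori): i for i, (eid, ori) in enumerate(constructs.itertuples(index=False))
    }
    pair_construct = np.array(
        [construct_key[(e, o)] for e, o in zip(bc["element_id"], bc["orientation"])]
    )

    mean = config.index_reads_per_pair
    extra = max(mean - INDEX_READ_FLOOR, 0.0)
    reads_per_pair = INDEX_READ_FLOOR + rng.poisson(extra, size=n_pairs)
    read_pair = np.repeat(np.arange(n_pairs), reads_per_pair)
    n_reads = len(read_pair)

    blen = config.barcode_length
    ea_mat = _seq_matrix(list(bc["eaBC"]), blen)[read_pair]
    pa_mat = _seq_matrix(list(bc["paBC"]), blen)[read_pair]
    tag_of = {v: k for k, v in config.minp_tags.items()}
    tag_mat = _seq_matrix([tag_of[m] for m in bc["minp"]], 3)[read_pair]
    umi_mat = _random_mat(rng, n_reads, config.umi_length)

    src = pair_construct[read_pair].copy()
    n_chim = 0
    if rate > 0 and len(prefix_mat) > 1:
        chim = rng.random(n_reads) < rate
        n_chim = int(chim.sum())
        if n_chim:
            shift = rng.integers(1, len(prefix_mat), size=n_chim)
            src[chim] = (src[chim] + shift) % len(prefix_mat)
    pre_mat = prefix_mat[src]

    r1 = np.hstack([ea_mat, umi_mat])
    r2 = np.hstack([pre_mat, pa_mat, tag_mat])
    nsub = _apply_errors(r1, rng, config.seq_error_rate)
    nsub += _apply_errors(r2, rng, config.seq_error_rate)
    stats = {
        "reads": n_reads,
        "chimeric_reads": n_chim,
        "substitutions": nsub,
        "pairs": n_pairs,
    }
    truth.index_stats.update(stats)
    return IndexReads(r1=_mat_to_seqs(r1), r2=_mat_to_seqs(r2), stats=stats)


# ---------------------------------------------------------------------------
# molecule counts and activity-measurement reads
# ---------------------------------------------------------------------------

def simulate_counts(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Draw true DNA/RNA molecule counts per barcode pair, readout, replicate.

    The per-pair abundance lambda is shared across readouts and replicates (it
    is a property of the plasmid pool); DNA ~ Poisson(lambda), RNA ~
    Poisson(lambda * 2^activity * eps) with log-normal eps per observation.
    """
    if truth.barcodes is None or len(truth.barcodes) == 0:
        raise StateError("ground truth has no barcode pairs; run simulate_elements")
    rng = _stage_rng(config, 2)
    bc = truth.barcodes
    n_pairs = len(bc)

    lam = config.mean_molecules_per_barcode * rng.lognormal(
        mean=0.0, sigma=config.dna_abundance_sdlog, size=n_pairs
    )
    act = truth.activities.set_index(["element_id", "orientation"])
    key = list(zip(bc["element_id"], bc["orientation"]))
    lat = {
        "promoter": act["latent_promoter"].loc[key].to_numpy(),
        "enhancer": act["latent_enhancer"].loc[key].to_numpy(),
    }

    frames = []
    ln2sd = config.rna_noise_sdlog
    for readout in READOUTS:
        gain = np.exp2(lat[readout])
        for rep in range(1, config.n_replicates + 1):
            dna = rng.poisson(lam)
            eps = rng.lognormal(0.0, ln2sd, size=n_pairs) if ln2sd > 0 else 1.0
            rna = rng.poisson(lam * gain * eps)
            frames.append(
                pd.DataFrame(
                    {
                        "eaBC": bc["eaBC"],
                        "paBC": bc["paBC"],
                        "element_id": bc["element_id"],
                        "orientation": bc["orientation"],
                        "minp": bc["minp"],
                        "readout": readout,
                        "replicate": rep,
                        "dna_molecules": dna,
                        "rna_molecules": rna,
                    }
                )
            )
    molecules = pd.concat(frames, ignore_index=True)
    truth.molecules = molecules
    return molecules


def simulate_quant_reads(
    truth: GroundTruth, config: SimulationConfig
) -> Tuple[Dict[str, np.ndarray], pd.DataFrame]:
    """Emit activity-measurement reads for every RNA/DNA library.

    Returns ``(libraries, metadata)`` where ``libraries`` maps library id to
    an array of read sequences (aBC + minP tag + UMI) and ``metadata`` has one
    row per library (lib_type, readout, replicate). Each molecule receives a
    UMI and is observed ``1 + Poisson(pcr_duplication_mean)`` times.
    """
    if truth.molecules is None:
        simulate_counts(truth, config)
    rng = _stage_rng(config, 3)
    mol = truth.molecules
    blen = config.barcode_length
    tag_of = {v: k for k, v in config.minp_tags.items()}

    bc = truth.barcodes
    ea_mat = _seq_matrix(list(bc["eaBC"]), blen)
    pa_mat = _seq_matrix(list(bc["paBC"]), blen)
    tag_mat = _seq_matrix([tag_of[m] for m in bc["minp"]], 3)
    pair_of_row = {}  # (eaBC, paBC) -> row in bc
    for i, (e, p) in enumerate(zip(bc["eaBC"], bc["paBC"])):
        pair_of_row[(e, p)] = i

    libraries: Dict[str, np.ndarray] = {}
    meta_rows = []
    for readout in READOUTS:
        abc_mat = pa_mat if readout == "promoter" else ea_mat
        for rep in range(1, config.n_replicates + 1):
            sub = mol[(mol.readout == readout) & (mol.replicate == rep)]
            rows = np.array(
                [pair_of_row[(e, p)] for e, p in zip(sub["eaBC"], sub["paBC"])]
            )
            for lib_type, col in (("DNA", "dna_molecules"), ("RNA", "rna_molecules")):
                lib_id = f"{lib_type}_{readout}_rep{rep}"
                counts = sub[col].to_numpy()
                mol_rows = np.repeat(rows, counts)
                n_mol = len(mol_rows)
                umi_mat = _random_mat(rng, n_mol, config.umi_length)
                if config.pcr_duplication_mean > 0:
                    copies = 1 + rng.poisson(config.pcr_duplication_mean, size=n_mol)
                else:
                    copies = np.ones(n_mol, dtype=np.int64)
                ridx = np.repeat(np.arange(n_mol), copies)
                mat = np.hstack(
                    [abc_mat[mol_rows], tag_mat[mol_rows], umi_mat]
                )[ridx]
                _apply_errors(mat, rng, config.seq_error_rate)
                libraries[lib_id] = _mat_to_seqs(mat)
                meta_rows.append((lib_id, lib_type, readout, rep))
    metadata = pd.DataFrame(
        meta_rows, columns=["library_id", "lib_type", "readout", "replicate"]
    )
    return libraries, metadata


# ---------------------------------------------------------------------------
# full run to disk
# ---------------------------------------------------------------------------

def run_simulation(config: SimulationConfig, outdir) -> GroundTruth:
    """Simulate everything and write the standard file set under ``outdir``.

    Files: catalog.bed / catalog.fasta, truth_*.tsv, index_R1.fastq /
    index_R2.fastq, libraries/<lib>.fastq, library_metadata.tsv, config.yaml.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog, truth = simulate_elements(config)
    reads = simulate_index_reads(catalog, truth, config)
    simulate_counts(truth, config)
    libs, meta = simulate_quant_reads(truth, config)

    bed = catalog.rename(columns={"element_id": "name"})[
        ["chrom", "start", "end", "name"]
    ]
    dio.write_bed6(outdir / "catalog.bed", bed)
    dio.write_fasta(
        outdir / "catalog.fasta", zip(catalog["element_id"], catalog["sequence"])
    )
    dio.write_tsv(outdir / "truth_elements.tsv", catalog.drop(columns=["sequence"]))
    dio.write_tsv(outdir / "truth_activities.tsv", truth.activities)
    dio.write_tsv(outdir / "truth_barcodes.tsv", truth.barcodes)
    dio.write_tsv(outdir / "truth_molecules.tsv", truth.molecules)
    dio.write_fastq(outdir / "index_R1.fastq", reads.r1, prefix="idx")
    dio.write_fastq(outdir / "index_R2.fastq", reads.r2, prefix="idx")
    libdir = outdir / "libraries"
    libdir.mkdir(exist_ok=True)
    for lib_id, seqs in libs.items():
        dio.write_fastq(libdir / f"{lib_id}.fastq", seqs, prefix=lib_id)
    dio.write_tsv(outdir / "library_metadata.tsv", meta)
    config.to_yaml(outdir / "config.yaml")
    return truth
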