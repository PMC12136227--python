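"""Configuration objects for the simulator and pipeline stages.

The read layouts are declared as named fields with explicit offsets so that
real sequencing layouts (which differ between vector designs) can be supplied
without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional

import yaml

from .errors import ConfigurationError

BASES = "ACGT"

#: Default minimal-promoter demultiplexing table: 3-bp tag -> minP label.
DEFAULT_MINP_TAGS: Dict[str, str] = {"ACT": "pMYC"}

#: The three-minP library set used for promoter-swap experiments.
TRIPLE_MINP_TAGS: Dict[str, str] = {"ACT": "pMYC", "GAA": "pGAPDH", "TTC": "pAPOBEC3F"}

ELEMENT_CLASSES = ("proximal", "distal", "orf_control")


@dataclass(frozen=True)
class ReadLayout:
    """Fixed-offset field map for one read of a library.

    ``fields`` maps a field name to ``(start, length)`` in 0-based
    coordinates on the read sequence.
    """

    fields: Dict[str, tuple]

    @property
    def span(self) -> int:
        return max(start + length for start, length in self.fields.values())

    def extract(self, seq: str) -> Optional[Dict[str, str]]:
        """Slice all declared fields out of ``seq``.

        Returns ``None`` when the read is shorter than the layout span.
        Raises :class:`ConfigurationError` on a zero/negative field length.
        """
        if len(seq) < self.span:
            return None
        out = {}
        for name, (start, length) in self.fields.items():
            if length <= 0 or start < 0:
                raise ConfigurationError(
                    f"layout.{name}", f"invalid field geometry ({start}, {length})"
                )
            out[name] = seq[start : start + length]
        return out


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(fieldname, msg)


@dataclass
class SimulationConfig:
    """Ground-truth generator settings.

    Latent activities are in log2 units relative to the basal transcription
    level defined by negative-control ORFs (class mean 0). Elements are
    emitted in both forward and reverse cloned orientations; the reverse
    latent activity equals the forward one plus Gaussian noise of SD
    ``orientation_asymmetry_sd``.
    """

    n_proximal: int = 50
    n_distal: int = 100
    n_orf_controls: int = 20
    # index complexity: the design rule requires >= 10 uniquely assigned
    # barcode pairs per element
    barcodes_per_element: int = 10
    barcode_length: int = 20
    umi_length: int = 10
    element_length: int = 200
    element_prefix_length: int = 40
    minp_tags: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MINP_TAGS))
    minp_mix: Optional[Dict[str, float]] = None  # label -> proportion; None = uniform
    true_activity_corr: float = 0.8
    activity_means_by_class: Dict[str, float] = field(
        default_factory=lambda: {"proximal": 2.0, "distal": 1.0, "orf_control": 0.0}
    )
    activity_sds_by_class: Dict[str, float] = field(
        default_factory=lambda: {"proximal": 1.0, "distal": 1.0, "orf_control": 0.0}
    )
    gc_by_class: Dict[str, float] = field(
        default_factory=lambda: {"proximal": 0.60, "distal": 0.45, "orf_control": 0.52}
    )
    orientation_asymmetry_sd: float = 0.0
    dna_abundance_sdlog: float = 0.5
    rna_noise_sdlog: float = 0.3
    mean_molecules_per_barcode: float = 5.0
    n_replicates: int = 2
    index_reads_per_pair: float = 12.0
    seq_error_rate: float = 0.001
    chimera_rate: float = 0.01
    collision_rate: float = 0.002
    pcr_duplication_mean: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proximal", "n_distal", "n_orf_controls", "barcodes_per_element"):
            _require(int(getattr(self, name)) >= 0, name, "must be >= 0")
        _require(self.barcode_length >= 8, "barcode_length", "must be >= 8")
        _require(self.umi_length >= 4, "umi_length", "must be >= 4")
        _require(
            abs(self.true_activity_corr) <= 1.0,
            "true_activity_corr",
            "must lie in [-1, 1]",
        )
        _require(len(self.minp_tags) >= 1, "minp_tags", "need at least one tag")
        for tag in self.minp_tags:
            _require(
                len(tag) == 3 and set(tag) <= set(BASES),
                "minp_tags",
                f"tag {tag!r} is not a 3-mer over ACGT",
            )
        labels = list(self.minp_tags.values())
        _require(len(set(labels)) == len(labels), "minp_tags", "labels must be distinct")
        if self.minp_mix is not None:
            _require(
                set(self.minp_mix) == set(labels),
                "minp_mix",
                "proportions must cover exactly the minP labels",
            )
            _require(
                all(p >= 0 for p in self.minp_mix.values())
                and sum(self.minp_mix.values()) > 0,
                "minp_mix",
                "proportions must be non-negative and sum > 0",
            )
        for name in ("seq_error_rate", "chimera_rate", "collision_rate"):
            _require(0.0 <= getattr(self, name) <= 1.0, name, "must lie in [0, 1]")
        for name, table in (
            ("activity_means_by_class", self.activity_means_by_class),
            ("activity_sds_by_class", self.activity_sds_by_class),
            ("gc_by_class", self.gc_by_class),
        ):
            missing = [c for c in ELEMENT_CLASSES if c not in table]
            _require(not missing, name, f"missing classes {missing}")
        for cls, gc in self.gc_by_class.items():
            _require(0.0 <= gc <= 1.0, "gc_by_class", f"{cls}: GC must lie in [0, 1]")
        _require(self.element_prefix_length <= self.element_length,
                 "element_prefix_length", "cannot exceed element_length")
        _require(self.pcr_duplication_mean >= 0, "pcr_duplication_mean", "must be >= 0")
        _require(self.mean_molecules_per_barcode > 0,
                 "mean_molecules_per_barcode", "must be > 0")
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _require(self.index_reads_per_pair > 0, "index_reads_per_pair", "must be > 0")

    # -- read layouts -------------------------------------------------------

    def index_layout_r1(self) -> ReadLayout:
        """Index-mapping read 1: enhancer-activity barcode then UMI."""
        return ReadLayout(
            {"eaBC": (0, self.barcode_length),
             "umi": (self.barcode_length, self.umi_length)}
        )

    def index_layout_r2(self) -> ReadLayout:
        """Index-mapping read 2: partial element sequence, paBC, minP tag."""
        p = self.element_prefix_length
        return ReadLayout(
            {"element": (0, p),
             "paBC": (p, self.barcode_length),
             "minp": (p + self.barcode_length, 3)}
        )

    def quant_layout(self) -> ReadLayout:
        """Activity-measurement read: activity barcode, minP tag, UMI."""
        b = self.barcode_length
        return ReadLayout(
            {"aBC": (0, b), "minp": (b, 3), "umi": (b + 3, self.umi_length)}
        )

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(sorted(unknown)[0], "unknown configuration field")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
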