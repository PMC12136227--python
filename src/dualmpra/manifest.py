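"""Run manifests: parameter sets, seeds, and content hashes per stage."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every stage's outputs."""

    stage: str
    params: Dict = field(default_factory=dict)
    seed: Optional[int] = None
    inputs: Dict[str, str] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    version: str = ""

    def add_inputs(self, *paths) -> None:
        for p in paths:
            self.inputs[str(p)] = sha256_file(p)

    def add_outputs(self, *paths) -> None:
        for p in paths:
            self.outputs[str(p)] = sha256_file(p)

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def now_iso() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S%z")


def manifest_diff(a: RunManifest, b: RunManifest) -> List[str]:
    """Names of parameters that differ between two manifests."""
    keys = set(a.params) | set(b.params)
    return sorted(
        k for k in keys if a.params.get(k, object()) != b.params.get(k, object())
    )
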