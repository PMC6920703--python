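"""Run manifests: one JSON record per CLI run for reproducibility."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import Any, Dict, List

import fluxlens


def _canonical(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _canonical(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    return obj


def config_hash(config: Any) -> str:
    """Stable SHA-256 over the canonical JSON form of a configuration."""
    payload = json.dumps(_canonical(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """What ran, with what, on what: enough to replay a run exactly."""

    command: str
    seed: int
    config_hash: str
    inputs: List[str] = field(default_factory=list)
    outputs: List[str] = field(default_factory=list)
    exclusion_counts: Dict[str, int] = field(default_factory=dict)
    package_version: str = fluxlens.__version__

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
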