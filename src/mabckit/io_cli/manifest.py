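"""Run manifests: enough provenance to rerun a CLI invocation."""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path


@dataclass
class RunManifest:
    command: str
    seed: int | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    tool_version: str = ""
    config_digest: str = ""
    created: str = ""

    def __post_init__(self) -> None:
        if not self.tool_version:
            from mabckit import __version__

            self.tool_version = __version__
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()
        if not self.config_digest:
            payload = json.dumps(
                {"seed": self.seed, "parameters": self.parameters},
                sort_keys=True,
            )
            self.config_digest = hashlib.sha256(payload.encode()).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def for_argv(cls, seed: int | None = None, **kwargs) -> "RunManifest":
        return cls(command=" ".join(sys.argv), seed=seed, **kwargs)
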