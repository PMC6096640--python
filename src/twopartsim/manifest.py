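"""Run manifests: a small JSON record that pins a run before it starts.

The manifest carries the configuration hash, the root seed and the
planned outputs, so any run can be reproduced bit-for-bit by re-running
with the same manifest.  All randomness in the package flows from the
root seed: replicate ``i`` uses ``root_seed + i`` and per-module streams
are spawned from that replicate seed with ``numpy`` seed sequences.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone

from . import __version__


def config_hash(config_dict: dict) -> str:
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    root_seed: int
    scenarios: list
    outputs: list
    version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)
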