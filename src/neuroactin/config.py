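"""Run configuration: one JSON-round-trippable record per pipeline run.

Every exporter writes a companion ``<output>.config.json`` carrying the
exact :class:`RunConfig` that produced the file, so any artifact can be
regenerated from its sidecar alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    """Full description of one run: command, parameters, strategies, output."""

    command: str = ""
    params: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    path: dict = field(default_factory=dict)
    variant: str = "gradient"
    parse: str = "reciprocal"
    outdir: str = "."

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))
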