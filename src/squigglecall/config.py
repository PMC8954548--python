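"""Run configuration with pipeline-wide defaults.

Defaults mirror the published processing parameters: rawmax 200, eventmax
30, batch size 128, latent dimension 128, gradient clip norm 1, scheduled
sampling ratio 0.5.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    # sample pipeline
    rawmax: int = 200
    eventmax: int = 30
    eventoffset: int = 1
    batch_size: int = 128
    split_fractions: tuple[float, float, float] = (0.15, 0.15, 0.70)
    # event detection
    window: int = 7
    threshold: float = 4.0
    # simulation
    num_basic: int = 12
    ref_length: int = 75_000
    n_reads: int = 10
    dwell_mean: float = 8.0
    noise_sd: float = 2.0
    # model / training
    mode: str = "joint"
    latent_dim: int = 128
    epochs: int = 10
    learning_rate: float = 1e-3
    clip_norm: float = 1.0
    sampling_ratio: float = 0.5
    beam_width: int = 1
    decode_cap: int = 40
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh) if str(path).endswith(".json") else _load_yaml(fh)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "split_fractions" in data:
            data["split_fractions"] = tuple(data["split_fractions"])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def write_manifest(self, out_dir, stage: str) -> None:
        import squigglecall

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {"stage": stage, "config": self.to_dict(),
                    "config_digest": self.digest(),
                    "version": squigglecall.__version__}
        with open(out_dir / f"manifest_{stage}.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def _load_yaml(fh):
    import yaml

    return yaml.safe_load(fh)
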