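"""Run configuration: YAML loading, content digests, and seed fan-out."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "stage_seed"]


@dataclass
class RunConfig:
    """Configuration for the end-to-end pipeline.

    At the defaults, ``resolution * window_size`` covers 2.56 Mbp per
    window.  One top-level ``seed`` is fanned out into per-stage seeds by
    hashing, so partial re-runs stay reproducible.
    """

    out_dir: str = "run"
    seed: int = 0
    resolution: int = 10_000
    window_size: int = 256
    stride_bins: int = 30
    k: int = 8
    use_pe: bool = True
    use_tracks: bool = True
    expected_map_mode: bool = False
    dense_attention: bool = False

    # synthetic-data stage
    n_chroms: int = 20
    n_bins: int = 256
    total_reads: int = 300_000
    sparsity: float = 0.02

    # optional external inputs (bypass the simulate stage)
    hic_path: str | None = None
    target_path: str | None = None
    track_paths: list[str] = field(default_factory=list)

    # model
    hidden: int = 32
    n_heads: int = 4
    n_layers: int = 2
    unet_channels: list[int] = field(default_factory=lambda: [64, 128, 256])
    max_attn_tokens: int = 1024

    # training
    learning_rate: float = 1e-4
    epochs: int = 10
    train_chroms: list[str] | None = None
    val_chroms: list[str] | None = None
    test_chroms: list[str] | None = None

    # evaluation
    loop_kernel: int = 7
    loop_threshold: float = 1.5
    loop_tol_bins: int = 1

    def __post_init__(self) -> None:
        if self.window_size % 8:
            raise ValueError("window_size must be divisible by 8")
        if self.train_chroms is None:
            n = self.n_chroms
            self.train_chroms = [f"chr{i}" for i in
                                 range(1, max(int(n * 0.6), 1) + 1)]
        if self.val_chroms is None:
            lo = len(self.train_chroms) + 1
            hi = lo + max(int(self.n_chroms * 0.2), 1)
            self.val_chroms = [f"chr{i}" for i in range(lo, hi)]
        if self.test_chroms is None:
            lo = len(self.train_chroms) + len(self.val_chroms) + 1
            self.test_chroms = [f"chr{i}" for i in
                                range(lo, self.n_chroms + 1)]

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable content hash of the configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the top-level seed by hashing."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)
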