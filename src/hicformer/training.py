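"""Joint training of the graph encoder and UNet decoder with MSE loss.

The loss is the plain sum of squared entry differences between the target
and imputed windows (a mean-reduction flag is available; the two differ
only by a scale absorbed into the learning rate).  Optimization uses Adam
at learning rate 1e-4 by default.  Chromosome splits keep train /
validation / test disjoint; the defaults follow the common autosome split
(chr1-7 and chr12-18 train, chr8/10/19/22 validation, chr9/11/20/21 test).

Everything is seeded: parameter initialisation, per-epoch shuffling, and
the synthetic data upstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .evaluation import ssim
from .graphs import create_graph
from .hic_io import BinnedTrack, ContactMap, Window, assemble, sample_windows
from .model import HiCAutoencoder, ModelConfig
from .nn import Tensor

__all__ = [
    "TrainConfig",
    "Sample",
    "Checkpoint",
    "mse_loss",
    "train",
    "impute_chromosome",
    "save_checkpoint",
    "load_checkpoint",
]

TRAIN_CHROMS = [f"chr{i}" for i in list(range(1, 8)) + list(range(12, 19))]
VAL_CHROMS = ["chr8", "chr10", "chr19", "chr22"]
TEST_CHROMS = ["chr9", "chr11", "chr20", "chr21"]


@dataclass
class TrainConfig:
    """Optimization and pipeline settings for one training run."""

    learning_rate: float = 1e-4
    epochs: int = 10
    batch_size: int = 1            # windows per optimizer step (accumulated)
    seed: int = 0
    window_size: int = 256
    stride_bins: int = 30
    k: int = 8
    use_pe: bool = True
    use_tracks: bool = True
    expected_map_mode: bool = False
    mean_loss: bool = False
    patience: int = 10
    val_every: int = 1
    train_chroms: list[str] = field(default_factory=lambda: list(TRAIN_CHROMS))
    val_chroms: list[str] = field(default_factory=lambda: list(VAL_CHROMS))
    test_chroms: list[str] = field(default_factory=lambda: list(TEST_CHROMS))

    def validate(self) -> None:
        sets = [set(self.train_chroms), set(self.val_chroms),
                set(self.test_chroms)]
        for a in range(3):
            for b in range(a + 1, 3):
                overlap = sets[a] & sets[b]
                if overlap:
                    raise ValueError(f"split lists overlap: {sorted(overlap)}")


@dataclass
class Sample:
    """One chromosome's worth of training material (all clip-normalized)."""

    chrom: str
    input_map: ContactMap          # sparse LRC map or expected-map prior
    target_map: ContactMap
    tracks: list[BinnedTrack]


@dataclass
class Checkpoint:
    """Trained parameters plus the flags needed to rebuild matching graphs."""

    state: dict[str, np.ndarray]
    model_config: ModelConfig
    train_config: TrainConfig
    history: list[dict] = field(default_factory=list)

    def build_model(self) -> HiCAutoencoder:
        model = HiCAutoencoder(self.model_config)
        model.load_state_dict(self.state)
        return model


def mse_loss(target: Tensor | np.ndarray, imputed: Tensor,
             mean: bool = False) -> Tensor:
    """Sum (or mean) of squared entry differences between two windows."""
    target = target if isinstance(target, Tensor) else Tensor(target)
    if target.shape != imputed.shape:
        raise ValueError(
            f"shape mismatch: target {target.shape} vs imputed {imputed.shape}")
    sq = (target - imputed) ** 2
    return sq.mean() if mean else sq.sum()


def _feature_width(config: TrainConfig, n_tracks: int) -> int:
    width = 0
    if config.use_pe:
        width += config.k
    if config.use_tracks:
        width += n_tracks
    return width if width else 1


def _window_pairs(sample: Sample, config: TrainConfig
                  ) -> list[tuple[Window, np.ndarray]]:
    tracks = sample.tracks if config.use_tracks else []
    in_windows = sample_windows(sample.input_map, tracks,
                                size=config.window_size,
                                stride_bins=config.stride_bins)
    tgt_windows = sample_windows(sample.target_map, [],
                                 size=config.window_size,
                                 stride_bins=config.stride_bins)
    tgt_by_start = {w.start_bin: w.submatrix for w in tgt_windows}
    return [(w, tgt_by_start[w.start_bin]) for w in in_windows]


def train(dataset: list[Sample], config: TrainConfig,
          model_config: ModelConfig | None = None,
          log: list | None = None) -> Checkpoint:
    """Train on the windows of the train-split chromosomes.

    Returns the checkpoint with the best validation SSIM (falling back to
    the final state when no validation chromosomes are present).  Aborts
    with a diagnostic on NaN loss.
    """
    config.validate()
    by_chrom = {s.chrom: s for s in dataset}
    train_samples = [by_chrom[c] for c in config.train_chroms if c in by_chrom]
    val_samples = [by_chrom[c] for c in config.val_chroms if c in by_chrom]
    if not train_samples:
        raise ValueError("no training chromosomes present in the dataset")
    n_tracks = len(train_samples[0].tracks) if config.use_tracks else 0
    width = _feature_width(config, n_tracks)
    if model_config is None:
        model_config = ModelConfig(in_features=width, seed=config.seed,
                                   window_size=config.window_size)
    if model_config.in_features != width:
        raise ValueError(
            f"model expects {model_config.in_features} node features but the "
            f"graph flags (use_pe={config.use_pe}, k={config.k}, "
            f"use_tracks={config.use_tracks}, n_tracks={n_tracks}) "
            f"produce {width}")

    pairs: list[tuple[Window, np.ndarray]] = []
    for s in train_samples:
        pairs.extend(_window_pairs(s, config))

    model = HiCAutoencoder(model_config)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    best_state = model.state_dict()
    best_val = -np.inf
    stale = 0
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        total = 0.0
        opt.zero_grad()
        in_batch = 0
        for idx in order:
            window, target = pairs[idx]
            graph = create_graph(window, k=config.k,
                                 use_tracks=config.use_tracks,
                                 use_pe=config.use_pe)
            pred = model(graph)
            loss = mse_loss(target, pred, mean=config.mean_loss)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, window "
                    f"{window.chrom}:{window.start_bin} — aborting")
            loss.backward()
            total += loss.item()
            in_batch += 1
            if in_batch >= config.batch_size:
                opt.step()
                opt.zero_grad()
                in_batch = 0
        if in_batch:
            opt.step()
            opt.zero_grad()
        record = {"epoch": epoch, "train_loss": total / max(len(pairs), 1)}
        validate_now = val_samples and (
            (epoch + 1) % config.val_every == 0
            or epoch == config.epochs - 1)
        if validate_now:
            val_scores = []
            for s in val_samples:
                imputed = impute_chromosome(model, s.input_map, s.tracks,
                                            config)
                val_scores.append(ssim(imputed, s.target_map))
            record["val_ssim"] = float(np.mean(val_scores))
            if record["val_ssim"] > best_val:
                best_val = record["val_ssim"]
                best_state = model.state_dict()
                stale = 0
            else:
                stale += 1
        history.append(record)
        if log is not None:
            log.append(record)
        if val_samples and stale > config.patience:
            break
    if not val_samples:
        best_state = model.state_dict()
    return Checkpoint(state=best_state, model_config=model_config,
                      train_config=config, history=history)


def impute_chromosome(model_or_ckpt: HiCAutoencoder | Checkpoint,
                      input_map: ContactMap,
                      tracks: list[BinnedTrack],
                      config: TrainConfig | None = None) -> ContactMap:
    """Window -> graph -> forward -> assemble with overlap averaging.

    ``input_map`` may be an observed (clip-normalized) sparse map or an
    expected-contact prior; in the latter case edges and positional
    encodings come from the prior (the no-Hi-C mode).
    """
    if isinstance(model_or_ckpt, Checkpoint):
        if config is None:
            config = model_or_ckpt.train_config
        model = model_or_ckpt.build_model()
    else:
        model = model_or_ckpt
        if config is None:
            raise ValueError("config required when passing a bare model")
    n_tracks = len(tracks) if config.use_tracks else 0
    width = _feature_width(config, n_tracks)
    if model.config.in_features != width:
        raise ValueError(
            f"checkpoint/model expects {model.config.in_features} node "
            f"features but flags (use_pe={config.use_pe}, k={config.k}, "
            f"use_tracks={config.use_tracks}, n_tracks={n_tracks}) "
            f"produce {width}")
    windows = sample_windows(input_map,
                             tracks if config.use_tracks else [],
                             size=config.window_size,
                             stride_bins=config.stride_bins)
    preds = []
    for w in windows:
        graph = create_graph(w, k=config.k, use_tracks=config.use_tracks,
                             use_pe=config.use_pe)
        preds.append((w, model.predict(graph)))
    out = assemble(preds, input_map.n_bins, chrom=input_map.chrom,
                   resolution=input_map.resolution)
    return ContactMap(matrix=np.clip(out.matrix, 0.0, 1.0), chrom=out.chrom,
                      resolution=out.resolution, norm_state="clipped")


def save_checkpoint(ckpt: Checkpoint, path: str | Path) -> None:
    """Persist parameters and configs to a single .npz archive."""
    meta = {
        "model_config": ckpt.model_config.to_dict(),
        "train_config": {k: v for k, v in ckpt.train_config.__dict__.items()},
        "history": ckpt.history,
    }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **ckpt.state)


def load_checkpoint(path: str | Path) -> Checkpoint:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    tc = TrainConfig(**meta["train_config"])
    return Checkpoint(state=state,
                      model_config=ModelConfig.from_dict(meta["model_config"]),
                      train_config=tc, history=meta["history"])
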