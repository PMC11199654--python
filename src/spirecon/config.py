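"""Run configuration, scale presets, and the end-to-end pipeline.

Two presets bundle the problem sizes: ``desk`` (32x32 scenes, M=200
patterns, a K=3 / C=16 network, 200 pairs) runs end to end on one CPU in
minutes and is the default everywhere; ``paper`` (128x128, M=5000, K=9,
C=128, 1200 pairs) is the full-scale configuration and is guarded behind an
explicit flag because training it is a GPU-scale job.

One global seed fans out to per-stage substreams by stable names, so adding
a stage never perturbs the randomness of earlier ones, and every artifact
is stamped with the configuration hash and seed that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._rng import derive_seed

__all__ = ["RunConfig", "PRESETS", "run_pipeline", "load_config"]

logger = logging.getLogger("spirecon")

PRESETS = {
    "desk": dict(side=32, n_patterns=200, stage_count=3, channels=16,
                 n_pairs=200, epochs=30, pattern_steps=600, batch_size=16),
    "paper": dict(side=128, n_patterns=5000, stage_count=9, channels=128,
                  n_pairs=1200, epochs=2000, pattern_steps=1_500_000,
                  batch_size=16),
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; preset values can be overridden."""

    preset: str = "desk"
    seed: int = 0
    out_dir: str = "runs/out"
    scene_kind: str = "nucleus"
    noise_model: str = "none"
    noise_param: float = 0.0
    photon_scale: float = 1.0
    test_size: int | None = None
    log_level: str = "INFO"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")

    def resolved(self) -> dict:
        vals = dict(PRESETS[self.preset])
        vals.update(self.overrides)
        return vals

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration with schema validation."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def run_pipeline(config: RunConfig, allow_large: bool = False) -> dict:
    """generate -> learn patterns -> simulate -> train -> evaluate.

    Writes patterns, a model checkpoint, a ratio sweep CSV, and a provenance
    stamp to ``config.out_dir``; returns the artifact paths.  Deterministic:
    rerunning an identical config reproduces identical artifacts.
    """
    from .evaluation import ratio_sweep
    from .patterns import learn_patterns
    from .recon_classical import ReconSpec
    from .recon_net import build_network, train
    from .synthetic_data import default_spec, gen_scene, make_dataset

    if config.preset == "paper" and not allow_large:
        raise RuntimeError(
            "the 'paper' preset is a full-scale (GPU-class) job; "
            "pass allow_large=True / --allow-large to run it anyway"
        )
    logging.basicConfig(level=config.log_level)
    vals = config.resolved()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "generate"
    try:
        side = vals["side"]
        spec = default_spec(config.scene_kind, side=side)
        # a handful of training scenes drive pattern learning
        train_imgs = [
            gen_scene(dataclasses.replace(
                spec, seed=derive_seed(config.seed, "pattern-scene", i)))
            for i in range(min(50, vals["n_pairs"]))
        ]

        stage = "patterns"
        op, pat_log = learn_patterns(
            train_imgs, vals["n_patterns"], vals["pattern_steps"],
            seed=derive_seed(config.seed, "patterns"),
            batch_size=vals["batch_size"],
        )
        op.save(out / "patterns.npz")
        artifacts["patterns"] = str(out / "patterns.npz")

        stage = "simulate"
        train_pairs, test_pairs = make_dataset(
            spec, op, vals["n_pairs"], seed=derive_seed(config.seed, "dataset"),
            noise_model=config.noise_model, noise_param=config.noise_param,
            photon_scale=config.photon_scale, test_size=config.test_size,
        )

        stage = "train"
        recon_spec = ReconSpec(stage_count=vals["stage_count"],
                               channels=vals["channels"],
                               ratio=op.n_rows / op.n_cols)
        net = build_network(recon_spec, seed=derive_seed(config.seed, "net"))
        train_log = train(net, train_pairs, op, epochs=vals["epochs"],
                          batch_size=vals["batch_size"],
                          seed=derive_seed(config.seed, "train"))
        net.save(out / "checkpoint.npz",
                 pattern_fingerprint=hashlib.sha256(op.values.tobytes()).hexdigest()[:16])
        artifacts["checkpoint"] = str(out / "checkpoint.npz")

        stage = "evaluate"
        m_list = sorted({max(1, op.n_rows // 32), op.n_rows // 8,
                         op.n_rows // 2, op.n_rows})
        sweep = ratio_sweep(lambda rec, o: net.reconstruct(rec, o), test_pairs,
                            m_list, seeds=(derive_seed(config.seed, "sweep"),))
        sweep.to_csv(out / "sweep.csv", index=False)
        artifacts["sweep"] = str(out / "sweep.csv")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    stamp = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "pattern_loss": pat_log["final_loss"],
        "train_loss": train_log["epoch_losses"],
        "artifacts": artifacts,
    }
    (out / "provenance.json").write_text(json.dumps(stamp, indent=2))
    artifacts["provenance"] = str(out / "provenance.json")
    return artifacts
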