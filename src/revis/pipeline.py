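"""Reproducible end-to-end pipeline: config, staging, manifests, reports.

The pipeline composes the package's stages -- synthetic silhouettes and
scenes -> 17-condition stimuli -> simulated human trials -> (optional)
model fine-tuning -> Top-1 evaluation -> behavioural benchmark -- under a
single validated configuration.  Every source of randomness derives from
the master seed through stable per-stage hashing, so stages can be re-run
independently without perturbing each other; a manifest of content digests
makes re-runs idempotent (unchanged stages are skipped).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import behaviour, models, stimuli, synthetic, training
from .stimuli import ConfigurationError


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class StimulusConfig:
    size: int = 128
    n_categories: int = 2
    n_exemplars: int = 2
    n_scenes: int = 8
    tolerance: float = 0.01
    threshold_cpd: float = 1.5
    visual_angle: float = 10.0
    conditions: list[str] | None = None  # None = all 17


@dataclass
class HumanConfig:
    n_subjects: int = 6
    trials_per_cell: int = 20


@dataclass
class ModelConfig:
    variants: list[str] = field(default_factory=lambda: ["B", "CLT"])
    seeds: list[int] = field(default_factory=lambda: [0, 1])
    timesteps: int = 2
    width_scale: float = 0.125
    pretrain_classes: int = 16
    finetune: bool = True
    images_per_category: int = 16
    n_cycles: int = 2
    epochs_per_cycle: int = 6
    head_only_epochs: int = 3
    full_epochs: int = 3
    batch_size: int = 16
    base_lr: float = 3e-3


@dataclass
class AnalysisConfig:
    reliability_iters: int = 25
    exclusion_threshold: float = 0.7


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "runs/demo"
    stimuli: StimulusConfig = field(default_factory=StimulusConfig)
    humans: HumanConfig = field(default_factory=HumanConfig)
    models: ModelConfig = field(default_factory=ModelConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def _from_dict(cls, payload: dict, path: str = "") -> object:
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in payload.items():
        if key not in fields:
            raise ConfigurationError(f"unknown config key {path + key!r}")
        ftype = fields[key].type
        if dataclasses.is_dataclass(_CONFIG_SECTIONS.get(key)) and isinstance(value, dict):
            kwargs[key] = _from_dict(_CONFIG_SECTIONS[key], value, path + key + ".")
        else:
            kwargs[key] = value
    return cls(**kwargs)


_CONFIG_SECTIONS = {"stimuli": StimulusConfig, "humans": HumanConfig,
                    "models": ModelConfig, "analysis": AnalysisConfig}


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected
    by name, missing keys fall back to defaults."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(payload, dict):
        raise ConfigurationError("config root must be a mapping")
    return _from_dict(PipelineConfig, payload)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def config_hash(config) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# File helpers
# ---------------------------------------------------------------------------


def save_png(path: Path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image, dtype=float), 0, 1)
    Image.fromarray((arr * 255).round().astype(np.uint8)).save(path)


def load_png(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Manifest and stage running
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    config_hash: str
    stages: dict = field(default_factory=dict)
    created: str = ""

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def load(cls, path: Path) -> "RunManifest | None":
        if not path.exists():
            return None
        payload = json.loads(path.read_text())
        return cls(config_hash=payload["config_hash"],
                   stages=payload["stages"], created=payload.get("created", ""))


class PipelineRunner:
    """Execute the staged pipeline under one config, skipping stages whose
    config and on-disk outputs are unchanged."""

    STAGES = ("stimuli", "humans", "models", "analysis")

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.previous = RunManifest.load(self.manifest_path)
        self.manifest = RunManifest(config_hash=config_hash(config),
                                    created=time.strftime("%Y-%m-%dT%H:%M:%S"))

    # -- stage bookkeeping -------------------------------------------------
    def _stage_hash(self, name: str, section) -> str:
        upstream = [self.manifest.stages[s]["hash"]
                    for s in self.STAGES[: self.STAGES.index(name)]
                    if s in self.manifest.stages]
        raw = json.dumps([self.config.seed, asdict(section), upstream],
                         sort_keys=True, default=str)
        return hashlib.sha256(raw.encode()).hexdigest()[:16]

    def _can_skip(self, name: str, stage_hash: str) -> bool:
        if self.previous is None or name not in self.previous.stages:
            return False
        prev = self.previous.stages[name]
        if prev["hash"] != stage_hash:
            return False
        for rel, digest in prev["outputs"].items():
            p = self.out / rel
            if not p.exists() or _digest_file(p) != digest:
                return False
        return True

    def _record(self, name: str, stage_hash: str, outputs: list[Path],
                skipped: bool) -> None:
        self.manifest.stages[name] = {
            "hash": stage_hash,
            "status": "skipped" if skipped else "computed",
            "outputs": {str(p.relative_to(self.out)): _digest_file(p)
                        for p in outputs},
        }

    # -- stages ------------------------------------------------------------
    def run(self) -> RunManifest:
        try:
            self._stage_stimuli()
            self._stage_humans()
            self._stage_models()
            self._stage_analysis()
        finally:
            self.manifest_path.write_text(
                json.dumps(self.manifest.to_json(), indent=2))
        return self.manifest

    def _conditions(self) -> list[stimuli.ManipulationSpec]:
        specs = stimuli.enumerate_conditions()
        wanted = self.config.stimuli.conditions
        if wanted:
            specs = [s for s in specs if s.label in wanted]
        return specs

    def _stage_stimuli(self) -> None:
        cfg = self.config.stimuli
        h = self._stage_hash("stimuli", cfg)
        stim_dir = self.out / "stimuli"
        manifest_csv = stim_dir / "stimuli.csv"
        if self._can_skip("stimuli", h):
            rows = pd.read_csv(manifest_csv)
            outs = [stim_dir / p for p in rows["path"]] + [manifest_csv]
            self._record("stimuli", h, outs, skipped=True)
            return
        stim_dir.mkdir(parents=True, exist_ok=True)
        seed = derive_seed(self.config.seed, "stimuli")
        sils = synthetic.generate_category_shapes(
            cfg.n_categories, cfg.n_exemplars, cfg.size, seed)
        scenes = synthetic.generate_scene_surrogates(
            cfg.n_scenes, cfg.size, derive_seed(self.config.seed, "scenes"))
        resources = {"scenes": scenes}
        rows, outputs = [], []
        for spec in self._conditions():
            cdir = stim_dir / spec.label
            cdir.mkdir(exist_ok=True)
            for i, sil in enumerate(sils):
                s = derive_seed(seed, f"{spec.label}:{sil.category}:{sil.exemplar_id}")
                stim = stimuli.generate_stimulus(sil, spec, resources, seed=s)
                rel = f"{spec.label}/{sil.category}_{sil.exemplar_id}.png"
                save_png(stim_dir / rel, stim.pixels)
                outputs.append(stim_dir / rel)
                rows.append({"path": rel, "category": sil.category,
                             "exemplar": sil.exemplar_id,
                             "condition": spec.label, "seed": s,
                             "achieved_coverage":
                                 stim.provenance.get("achieved_coverage", np.nan)})
        pd.DataFrame(rows).to_csv(manifest_csv, index=False)
        outputs.append(manifest_csv)
        self._record("stimuli", h, outputs, skipped=False)

    def _stage_humans(self) -> None:
        cfg = self.config.humans
        h = self._stage_hash("humans", cfg)
        path = self.out / "human_trials.csv"
        if self._can_skip("humans", h):
            self._record("humans", h, [path], skipped=True)
            return
        model = synthetic.default_response_model()
        trials = synthetic.simulate_trials(
            model, cfg.n_subjects, cfg.trials_per_cell,
            seed=derive_seed(self.config.seed, "humans"))
        labels = [s.label for s in self._conditions()]
        trials = trials[trials["condition"].isin(labels)]
        trials.to_csv(path, index=False)
        self._record("humans", h, [path], skipped=False)

    def _model_spec(self, variant: str, seed: int) -> models.ModelSpec:
        cfg = self.config.models
        variant = models.canonical_variant(variant)
        size = 32 if variant.startswith("B") else 64
        return models.ModelSpec(variant=variant, timesteps=cfg.timesteps,
                                n_classes=cfg.pretrain_classes,
                                input_size=size,
                                width_scale=cfg.width_scale, seed=seed)

    def _stage_models(self) -> None:
        cfg = self.config.models
        h = self._stage_hash("models", cfg)
        mdir = self.out / "model_trials"
        expected = [mdir / f"{models.canonical_variant(v)}_{s}.csv"
                    for v in cfg.variants for s in cfg.seeds]
        info_path = self.out / "model_info.json"
        if self._can_skip("models", h):
            self._record("models", h, expected + [info_path], skipped=True)
            return
        mdir.mkdir(parents=True, exist_ok=True)
        stim_rows = pd.read_csv(self.out / "stimuli" / "stimuli.csv")
        categories = sorted(stim_rows["category"].unique())
        master = derive_seed(self.config.seed, "models")
        scfg = self.config.stimuli
        sils = synthetic.generate_category_shapes(
            scfg.n_categories, scfg.n_exemplars, scfg.size,
            derive_seed(self.config.seed, "stimuli"))
        scenes = synthetic.generate_scene_surrogates(
            scfg.n_scenes, scfg.size, derive_seed(self.config.seed, "scenes"))
        info = {}
        for variant in cfg.variants:
            canon = models.canonical_variant(variant)
            for seed in cfg.seeds:
                spec = self._model_spec(canon, derive_seed(master, f"{canon}:{seed}"))
                model = models.build_model(spec)
                models.swap_head(model, len(categories), seed=spec.seed)
                if cfg.finetune:
                    dataset = training.realize_finetune_dataset(
                        sils, scenes, cfg.images_per_category,
                        spec.resolved_input_size, seed=spec.seed)
                    base_lr = cfg.base_lr
                    schedule = training.FinetuneSchedule(
                        n_cycles=cfg.n_cycles,
                        epochs_per_cycle=cfg.epochs_per_cycle,
                        head_only_epochs=cfg.head_only_epochs,
                        full_epochs=cfg.full_epochs,
                        lr_policy=lambda c: base_lr * (0.5 ** c),
                        batch_size=cfg.batch_size, seed=spec.seed)
                    training.run_finetune(model, dataset, schedule)
                imgs = np.stack([
                    training.to_model_input(
                        load_png(self.out / "stimuli" / rel),
                        spec.resolved_input_size)
                    for rel in stim_rows["path"]])
                labels = np.array([categories.index(c)
                                   for c in stim_rows["category"]])
                pred_idx = training.predict_top1(model, imgs,
                                                 timesteps=spec.timesteps)
                pred_names = [categories[i] for i in pred_idx]
                table = training.model_trial_table(
                    canon, seed, stim_rows["condition"], stim_rows["category"],
                    pred_idx == labels, pred_names)
                table.to_csv(mdir / f"{canon}_{seed}.csv", index=False)
            info[canon] = {
                "n_parameters": models.count_parameters(model),
                "recurrent": canon in models.RECURRENT,
                "seeds": list(cfg.seeds),
            }
        info_path.write_text(json.dumps(info, indent=2))
        self._record("models", h, expected + [info_path], skipped=False)

    def _stage_analysis(self) -> None:
        cfg = self.config.analysis
        h = self._stage_hash("analysis", cfg)
        report_json = self.out / "report.json"
        report_csv = self.out / "report_tidy.csv"
        if self._can_skip("analysis", h):
            self._record("analysis", h, [report_json, report_csv], skipped=True)
            return
        human = pd.read_csv(self.out / "human_trials.csv")
        human, _ = behaviour.exclude_participants(human, cfg.exclusion_threshold)
        info = json.loads((self.out / "model_info.json").read_text())
        tables: dict[str, list[pd.DataFrame]] = {}
        for name, entry in info.items():
            tables[name] = [
                pd.read_csv(self.out / "model_trials" / f"{name}_{s}.csv")
                for s in entry["seeds"]]
        labels = [s.label for s in self._conditions()]
        categories = sorted(set(human["true"]) | set(human["response"]))
        report = behaviour.build_benchmark_report(
            human, tables, info, conditions=labels, categories=categories,
            reliability_seed=derive_seed(self.config.seed, "analysis"))
        write_report(report, self.out)
        self._record("analysis", h, [report_json, report_csv], skipped=False)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute synthetic-data -> stimuli -> models -> analysis end to end."""
    return PipelineRunner(config).run()


def write_report(report: behaviour.BenchmarkReport, outdir: str | Path,
                 ) -> list[Path]:
    """Write the benchmark report as JSON plus a tidy per-seed CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    jpath = outdir / "report.json"
    cpath = outdir / "report_tidy.csv"
    jpath.write_text(json.dumps(report.to_json(), indent=2, default=float))
    report.tidy().to_csv(cpath, index=False)
    return [jpath, cpath]
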