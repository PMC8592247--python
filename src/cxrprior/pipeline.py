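"""End-to-end pipeline: phantom -> prep -> train -> eval -> attend.

A single YAML-serializable :class:`RunConfig` drives the whole chain.
Each stage records a checksum of the configuration slice it depends on
(chained to its upstream stage) in ``stage_state.json``; re-running
with ``resume=True`` skips any stage whose checksum matches and whose
output files still exist — the train stage then reloads its checkpoint
instead of retraining.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from PIL import Image

from cxrprior import attention, manifest, metrics, preprocess, training
from cxrprior.model import DualStreamModel, ModelConfig
from cxrprior.phantom import PhantomConfig, generate_phantom
from cxrprior.preprocess import CLAHEConfig, NMFConfig

log = logging.getLogger("cxrprior")


@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    nmf: NMFConfig = field(default_factory=NMFConfig)
    clahe: CLAHEConfig = field(default_factory=CLAHEConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    variant: str = "GD_NMF => AD_NMF => DD_ORG"
    fast: bool = True
    augment_max_angle_deg: float = 30.0
    split_fractions: tuple[float, float, float] = (0.80, 0.10, 0.10)
    seed: int = 0
    out_dir: str = "runs/demo"
    save_images: bool = False
    disease_classes: tuple[str, ...] | None = None
    #: Per-task PhaseConfig overrides, e.g. {"disease": {"epochs": 12}}.
    phase_overrides: dict | None = None

    def to_yaml(self) -> str:
        d = asdict(self)
        d["phantom"]["age_geometry_effect"] = list(self.phantom.age_geometry_effect)
        d["phantom"]["disease_classes"] = list(self.phantom.disease_classes)
        d["clahe"]["nt"] = list(self.clahe.nt)
        d["model"]["filters_per_block"] = list(self.model.filters_per_block)
        d["split_fractions"] = list(self.split_fractions)
        if self.disease_classes is not None:
            d["disease_classes"] = list(self.disease_classes)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        d.pop("loss_params", None)
        kwargs = {
            k: v for k, v in d.items()
            if k not in ("phantom", "nmf", "clahe", "model",
                         "split_fractions", "disease_classes")
        }
        if "split_fractions" in d:
            kwargs["split_fractions"] = tuple(d["split_fractions"])
        if d.get("disease_classes") is not None:
            kwargs["disease_classes"] = tuple(d["disease_classes"])
        return cls(
            phantom=PhantomConfig(**_tupled(d.get("phantom", {}),
                                            "age_geometry_effect", "disease_classes")),
            nmf=NMFConfig(**d.get("nmf", {})),
            clahe=CLAHEConfig(**_tupled(d.get("clahe", {}), "nt")),
            model=ModelConfig(**_tupled(d.get("model", {}), "filters_per_block")),
            **kwargs,
        )

    def apply_overrides(self, overrides: dict[str, str]) -> "RunConfig":
        """Apply dotted-key overrides like ``{"nmf.kappa": "12"}``."""
        d = yaml.safe_load(self.to_yaml())
        for key, raw in overrides.items():
            parts = key.split(".")
            node = d
            for p in parts[:-1]:
                node = node[p]
            if parts[-1] not in node and parts[-1] not in RunConfig.__dataclass_fields__:
                raise KeyError(f"unknown config key {key!r}")
            node[parts[-1]] = yaml.safe_load(raw)
        return RunConfig.from_yaml(yaml.safe_dump(d))


def _tupled(d: dict, *keys: str) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    return d


def _checksum(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


class PipelineRun:
    """Executes the stage chain into ``cfg.out_dir``."""

    def __init__(self, cfg: RunConfig, resume: bool = False):
        self.cfg = cfg
        self.resume = resume
        self.dir = Path(cfg.out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self._handler = logging.FileHandler(self.dir / "run.log")
        self._handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        log.addHandler(self._handler)
        log.setLevel(logging.INFO)
        state_path = self.dir / "stage_state.json"
        self.state = json.loads(state_path.read_text()) if state_path.exists() else {}
        self._state_path = state_path
        self.records = None
        self.versions = None
        self.model: DualStreamModel | None = None
        self.phase_logs: list[pd.DataFrame] = []
        self.report: pd.DataFrame | None = None

    # -- stage plumbing ----------------------------------------------------

    def _fresh(self, name: str, checksum: str, outputs: list[Path]) -> bool:
        entry = self.state.get(name)
        ok = (
            self.resume
            and entry is not None
            and entry["checksum"] == checksum
            and all(o.exists() for o in outputs)
        )
        if ok:
            log.info("stage %s: up to date, skipped", name)
        return ok

    def _done(self, name: str, checksum: str, outputs: list[Path]) -> None:
        self.state[name] = {
            "checksum": checksum,
            "outputs": [str(o) for o in outputs],
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self._state_path.write_text(json.dumps(self.state, indent=2))

    def _checksums(self) -> dict[str, str]:
        c = self.cfg
        ck = {}
        ck["phantom"] = _checksum(asdict(c.phantom))
        ck["prep"] = _checksum(
            [ck["phantom"], asdict(c.nmf), asdict(c.clahe),
             c.augment_max_angle_deg, list(c.split_fractions), c.seed]
        )
        ck["train"] = _checksum(
            [ck["prep"], c.variant, c.fast, asdict(c.model), c.seed,
             list(c.disease_classes or []), c.phase_overrides or {}]
        )
        ck["eval"] = _checksum([ck["train"], "eval"])
        ck["attend"] = _checksum([ck["train"], "attend"])
        return ck

    # -- stages ------------------------------------------------------------

    def stage_phantom(self, ck: str):
        man = self.dir / "manifest.csv"
        self.records = generate_phantom(self.cfg.phantom)
        if self._fresh("phantom", ck, [man]):
            return
        manifest.write_manifest(self.records, man)
        if self.cfg.save_images:
            img_dir = self.dir / "images" / "org"
            img_dir.mkdir(parents=True, exist_ok=True)
            for rec in self.records:
                Image.fromarray(rec.pixels).save(img_dir / rec.image_id)
        self._done("phantom", ck, [man])

    def stage_prep(self, ck: str):
        c = self.cfg
        split = preprocess.split_dataset(
            self.records, c.split_fractions, seed=c.seed, by="disease"
        )
        train_pool = [r for r in split if r.role == "train"]
        rest = [r for r in split if r.role != "train"]
        augmented = preprocess.augment_balance(
            train_pool, c.augment_max_angle_deg, by="disease", seed=c.seed
        )
        all_recs = augmented + rest
        self.versions = {
            "Ver_ORG": preprocess.make_version_org(all_recs),
            "Ver_NMF": preprocess.make_version_nmf(all_recs, c.nmf, c.clahe),
        }
        roles_path = self.dir / "roles.csv"
        if self._fresh("prep", ck, [roles_path]):
            return
        if c.save_images:
            img_dir = self.dir / "images" / "nmf"
            img_dir.mkdir(parents=True, exist_ok=True)
            for rec in self.versions["Ver_NMF"].records:
                Image.fromarray(rec.pixels).save(img_dir / rec.image_id)
        pd.DataFrame(
            {"image_id": [r.image_id for r in all_recs],
             "role": [r.role for r in all_recs]}
        ).to_csv(roles_path, index=False)
        self._done("prep", ck, [roles_path])

    def stage_train(self, ck: str):
        c = self.cfg
        chain = training.parse_variant(c.variant)
        ckpt_dir = self.dir / "checkpoints"
        last = ckpt_dir / f"phase{len(chain)}_{chain[-1][0]}.npz"
        if self._fresh("train", ck, [last]):
            self.model = DualStreamModel.load(last)
            return
        run = training.run_protocol(
            c.variant,
            self.versions,
            seed=c.seed,
            model_cfg=dataclasses.replace(c.model, input_size=c.phantom.image_size),
            fast=c.fast,
            out_dir=ckpt_dir,
            disease_classes=c.disease_classes,
            phase_overrides=c.phase_overrides,
        )
        self.model = run.model
        for k, phase in enumerate(run.phases, start=1):
            phase.log.to_csv(
                self.dir / f"phase{k}_{phase.config.task}_log.csv", index=False
            )
            self.phase_logs.append(phase.log)
        self._done("train", ck, [last])

    def _final_task(self):
        task, version = training.parse_variant(self.cfg.variant)[-1]
        if task == "disease" and self.cfg.disease_classes:
            classes = tuple(self.cfg.disease_classes)
        else:
            classes = training.task_classes(task)
        return task, version, classes

    def stage_eval(self, ck: str):
        path = self.dir / "metrics.csv"
        if self._fresh("eval", ck, [path]):
            self.report = pd.read_csv(path)
            return
        task, version, classes = self._final_task()
        scores, targets = training.evaluate_split(
            self.model, self.versions[version], task, classes=classes
        )
        rule = "threshold" if task == "disease" else "argmax"
        self.report = metrics.metrics_report(scores, targets, list(classes), rule=rule)
        self.report.to_csv(path, index=False)
        self._done("eval", ck, [path])

    def stage_attend(self, ck: str):
        path = self.dir / "profiles.csv"
        if self._fresh("attend", ck, [path]):
            return
        task, version, classes = self._final_task()
        test_recs = self.versions[version].subset("test")
        profiles = [
            attention.zone_profile(self.model, test_recs, label, task, classes=classes)
            for label in classes
        ]
        attention.profiles_frame(profiles).to_csv(path, index=False)
        self._done("attend", ck, [path])

    def execute(self) -> Path:
        (self.dir / "resolved_config.yaml").write_text(self.cfg.to_yaml())
        ck = self._checksums()
        stages = [
            ("phantom", self.stage_phantom),
            ("prep", self.stage_prep),
            ("train", self.stage_train),
            ("eval", self.stage_eval),
            ("attend", self.stage_attend),
        ]
        try:
            for name, fn in stages:
                log.info("stage %s: start", name)
                t0 = time.time()
                fn(ck[name])
                log.info("stage %s: end (%.1fs)", name, time.time() - t0)
        except Exception as exc:
            log.error("pipeline halted at a stage: %s", exc)
            raise
        finally:
            log.removeHandler(self._handler)
            self._handler.close()
        return self.dir


def run_all(cfg: RunConfig, resume: bool = False) -> Path:
    """Run the whole pipeline; returns the run directory."""
    return PipelineRun(cfg, resume=resume).execute()
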