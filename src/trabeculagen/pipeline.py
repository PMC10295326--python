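"""End-to-end study pipeline: simulate -> pair -> train -> translate ->
measure -> evaluate, driven by one YAML config and a single master seed.

Each stage writes its outputs plus a stage marker (config hash and input
checksums) under the run directory; re-running a completed stage with
unchanged configuration is a no-op.  A manifest records seeds, per-stage
timings and the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import VoxelVolume, read_stack, write_stack
from .evaluate import (RandomConvProjector, SimilarityReport, compare_methods,
                       embed, fid, full_report, icc, regress_metrics, ssim)
from .morphometry import CylindricalVOI, measure_stack, position_voi_from_body_mask
from .pairing import pair_stacks
from .phantom import PhantomSpec, make_study_set
from . import translate as tr

log = logging.getLogger("trabeculagen")

STAGES = ("simulate", "pair", "train", "translate", "measure", "evaluate")


@dataclass
class RunConfig:
    output_dir: str = "run"
    seed: int = 0
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    n_train: int = 2
    n_test: int = 1
    pairing: dict = field(default_factory=lambda: {"lowe_ratio": 0.75})
    training: dict = field(default_factory=dict)  # TrainConfig overrides
    voi: dict = field(default_factory=lambda: {"mode": "center", "diameter_mm": 15.0,
                                               "height_mm": 5.0})
    evaluation: dict = field(default_factory=lambda: {"scopes": ["overall"],
                                                      "extractor_seed": 0})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(config) -> list[str]:
    """Schema and invariant checks; returns a list of problems (no side
    effects, empty list means valid)."""
    problems = []
    if isinstance(config, dict):
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(config) - known
        if unknown:
            problems.append(f"unknown config keys: {sorted(unknown)}")
        if not config:
            problems.append("empty config")
        try:
            config = RunConfig(**{k: v for k, v in config.items() if k in known})
        except (TypeError, ValueError) as e:
            problems.append(f"malformed config: {e}")
            return problems
    if config.n_train < 1 or config.n_test < 1:
        problems.append("need at least one training and one test vertebra")
    if config.n_train + config.n_test < 2:
        problems.append("cohort too small")
    # train/test split is by construction disjoint (leading vs trailing ids),
    # but explicit id lists may be supplied in the phantom section
    ids_tr = set(config.phantom.get("train_ids", range(config.n_train)))
    ids_te = set(config.phantom.get("test_ids",
                                    range(config.n_train, config.n_train + config.n_test)))
    if ids_tr & ids_te:
        problems.append(f"train and test vertebra ids overlap: {sorted(ids_tr & ids_te)}")
    try:
        phantom_spec(config)
    except (TypeError, ValueError) as e:
        problems.append(f"invalid phantom spec: {e}")
    tr_over = dict(config.training)
    tr_over.pop("reference_slices", None)
    try:
        tr.TrainConfig(**tr_over)
    except TypeError as e:
        problems.append(f"invalid training section: {e}")
    if config.voi.get("mode", "center") not in ("center", "auto"):
        problems.append("voi.mode must be 'center' or 'auto'")
    return problems


def phantom_spec(config: RunConfig) -> PhantomSpec:
    over = {k: v for k, v in config.phantom.items()
            if k not in ("train_ids", "test_ids")}
    for key in ("extent_mm", "body_semiaxes_mm", "gt_region_mm", "anisotropy",
                "mdct_psf_fwhm_mm"):
        if key in over:
            over[key] = tuple(over[key])
    return PhantomSpec(**over)


# ---------------------------------------------------------------------------
# stage bookkeeping
# ---------------------------------------------------------------------------

def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _marker(run: Path, stage: str) -> Path:
    return run / f".{stage}.done.json"


def _stage_fresh(run: Path, stage: str, key: str) -> bool:
    m = _marker(run, stage)
    if not m.exists():
        return False
    try:
        return json.loads(m.read_text()).get("key") == key
    except json.JSONDecodeError:
        return False


def _mark(run: Path, stage: str, key: str, dt: float) -> None:
    _marker(run, stage).write_text(json.dumps({"key": key, "seconds": round(dt, 2)}))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, run: Path) -> None:
    spec = phantom_spec(config)
    n = config.n_train + config.n_test
    items = make_study_set(n, spec, seed=config.seed)
    stacks = run / "stacks"
    stacks.mkdir(parents=True, exist_ok=True)
    for i, (gt, micro, mdct) in enumerate(items):
        write_stack(stacks / f"v{i:03d}_micro.tif", micro)
        write_stack(stacks / f"v{i:03d}_mdct.tif", mdct)
        write_stack(stacks / f"v{i:03d}_body.tif", gt.body_mask.astype_u8())
        sidecar = {
            "spec": dataclasses.asdict(gt.spec),
            "bvtv_true": gt.bvtv_true,
            "tbth_true_mm": gt.tbth_true_mm,
            "tbsp_true_mm": gt.tbsp_true_mm,
            "computed_by": gt.computed_by,
            "split": "train" if i < config.n_train else "test",
        }
        (stacks / f"v{i:03d}.json").write_text(json.dumps(sidecar, indent=1))


def _load_item(stacks: Path, i: int):
    gt_meta = json.loads((stacks / f"v{i:03d}.json").read_text())
    micro = read_stack(stacks / f"v{i:03d}_micro.tif")
    mdct = read_stack(stacks / f"v{i:03d}_mdct.tif")
    body = read_stack(stacks / f"v{i:03d}_body.tif")
    return gt_meta, micro, mdct, body


def stage_pair(config: RunConfig, run: Path) -> None:
    stacks = run / "stacks"
    rows = []
    for i in range(config.n_train, config.n_train + config.n_test):
        _, micro, mdct, _ = _load_item(stacks, i)
        res = pair_stacks(mdct, micro, ratio=config.pairing.get("lowe_ratio", 0.75))
        np.savetxt(run / f"pair_matrix_v{i:03d}.csv", res.distance_matrix,
                   delimiter=",", fmt="%.4f")
        for mi, mj in res.pairs:
            rows.append({"vertebra": i, "mdct_index": mi, "micro_index": mj,
                         "distance": res.distance_matrix[mi, mj]})
    pd.DataFrame(rows).to_csv(run / "pairs.csv", index=False)


class _GTStub:
    def __init__(self, meta):
        self.__dict__.update(meta)


def _dataset(config: RunConfig, run: Path, split: str) -> tr.TranslationDataset:
    stacks = run / "stacks"
    lo, hi = ((0, config.n_train) if split == "train"
              else (config.n_train, config.n_train + config.n_test))
    items = []
    for i in range(lo, hi):
        meta, micro, mdct, _ = _load_item(stacks, i)
        items.append((_GTStub(meta), micro, mdct))
    size = config.training.get("image_size", 64)
    return tr.build_slice_dataset(items, image_size=size)


def stage_train(config: RunConfig, run: Path) -> None:
    ds = _dataset(config, run, "train")
    over = dict(config.training)
    over.pop("reference_slices", None)
    over.setdefault("seed", config.seed)
    cfg = tr.TrainConfig(**over)
    state = tr.new_model(cfg)
    state = tr.train(state, ds, callback=lambda h: log.info("train %s", h))
    tr.save_checkpoint(state, run / "checkpoint.npz")
    pd.DataFrame(state.history).to_csv(run / "losses.csv", index=False)


def stage_translate(config: RunConfig, run: Path) -> None:
    stacks = run / "stacks"
    state = tr.load_checkpoint(run / "checkpoint.npz")
    ds_train = _dataset(config, run, "train")
    n_ref = config.training.get("reference_slices", 4)
    refs = ds_train.micro[:n_ref]
    for i in range(config.n_train, config.n_train + config.n_test):
        _, micro, mdct, _ = _load_item(stacks, i)
        size = config.training.get("image_size", 64)
        # translate the physically matching central window of each slice
        win_mm = size * micro.voxel_size[1]
        c = mdct.shape[1] / 2.0
        half = win_mm / 2.0 / mdct.voxel_size[1]
        a, b = int(round(c - half)), int(round(c + half))
        sub = VoxelVolume(mdct.data[:, a:b, a:b], mdct.voxel_size, mdct.origin)
        out = tr.translate_stack(state, sub, refs)
        write_stack(run / f"v{i:03d}_translated.tif", out.astype_u8())


def _voi_for(config: RunConfig, volume: VoxelVolume, body: VoxelVolume) -> CylindricalVOI:
    v = config.voi
    if v.get("mode", "center") == "auto":
        voi, _ = position_voi_from_body_mask(
            body, diameter_mm=v.get("diameter_mm", 15.0),
            height_mm=v.get("height_mm", 5.0))
        return voi
    ext = volume.extent_mm
    return CylindricalVOI(center=(ext[0] / 2, ext[1] / 2, ext[2] / 2),
                          diameter_mm=v.get("diameter_mm", 15.0),
                          height_mm=v.get("height_mm", 5.0))


def stage_measure(config: RunConfig, run: Path) -> None:
    stacks = run / "stacks"
    rows = []
    for i in range(config.n_train, config.n_train + config.n_test):
        meta, micro, mdct, body = _load_item(stacks, i)
        volumes = {"micro": micro, "mdct": mdct}
        tpath = run / f"v{i:03d}_translated.tif"
        if tpath.exists():
            volumes["translated"] = read_stack(tpath)
        for modality, vol in volumes.items():
            voi = _voi_for(config, vol, body)
            try:
                r = measure_stack(vol, voi)
            except ValueError as e:
                log.warning("measure %s v%03d failed: %s", modality, i, e)
                continue
            rows.append({
                "id": i, "modality": modality, "bvtv": r.bvtv,
                "tbth_mm": r.tbth_mm, "tbsp_mm": r.tbsp_mm,
                "threshold": r.threshold_used, "n_fg": r.n_foreground,
                "n_total": r.n_total, "bvtv_true": meta["bvtv_true"],
                "tbth_true_mm": meta["tbth_true_mm"],
            })
    pd.DataFrame(rows).to_csv(run / "morphometry.csv", index=False)


def stage_evaluate(config: RunConfig, run: Path) -> None:
    ds = _dataset(config, run, "test")
    state = tr.load_checkpoint(run / "checkpoint.npz")
    proj = RandomConvProjector(seed=config.evaluation.get("extractor_seed", 0))
    translated = []
    for i in range(0, len(ds.mdct), 8):
        x = tr.Tensor(tr._normalize(ds.mdct[i:i + 8]))
        y = tr.Tensor(tr._normalize(ds.micro[:1]))
        translated.append(tr._denormalize(state.generator(x, [y]).data[:, 0]))
    translated = np.concatenate(translated)
    f_micro = embed(ds.micro, proj)
    sims = {}
    for name, imgs in (("mdct-bicubic", ds.mdct),
                       ("translated", translated)):
        vals = np.array([ssim(imgs[i_], ds.micro[j]) for i_, j in ds.true_pairs])
        sims[name] = SimilarityReport(
            scope="overall", ssim_values=vals,
            fid_value=fid(embed(imgs, proj), f_micro),
            extractor=proj.name,
        )
    statistics = compare_methods(
        sims["mdct-bicubic"].ssim_values,
        {"translated": np.array([ssim(translated[i_], ds.micro[j])
                                 for i_, j in ds.true_pairs])},
    )
    morpho = run / "morphometry.csv"
    if morpho.exists():
        df = pd.read_csv(morpho)
        ref = df[df.modality == "micro"].sort_values("id")
        gen = df[df.modality == "translated"].sort_values("id")
        if len(ref) >= 3 and len(ref) == len(gen):
            for metric in ("bvtv", "tbth_mm", "tbsp_mm"):
                try:
                    statistics.append(regress_metrics(ref[metric], gen[metric]))
                except ValueError as e:
                    log.warning("regression on %s skipped: %s", metric, e)
        if len(ref) >= 5 and len(ref) == len(gen):
            for metric in ("bvtv", "tbth_mm"):
                try:
                    statistics.append(icc(np.column_stack([ref[metric], gen[metric]])))
                except ValueError as e:
                    log.warning("icc on %s skipped: %s", metric, e)
    full_report(sims, statistics, run / "report")


STAGE_FNS = {
    "simulate": stage_simulate,
    "pair": stage_pair,
    "train": stage_train,
    "translate": stage_translate,
    "measure": stage_measure,
    "evaluate": stage_evaluate,
}


def run_pipeline(config: RunConfig, stages=STAGES, force: bool = False) -> Path:
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    run = Path(config.output_dir)
    run.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "config": config.to_dict(), "config_hash": _hash(config.to_dict()),
                "stages": {}}
    for stage in stages:
        key = _hash({"config": config.to_dict(), "stage": stage})
        if not force and _stage_fresh(run, stage, key):
            log.info("stage %s up to date, skipping", stage)
            manifest["stages"][stage] = {"skipped": True}
            continue
        log.info("stage %s ...", stage)
        t0 = time.time()
        try:
            STAGE_FNS[stage](config, run)
        except Exception:
            log.exception("stage %s failed", stage)
            raise
        dt = time.time() - t0
        _mark(run, stage, key, dt)
        manifest["stages"][stage] = {"seconds": round(dt, 2)}
        log.info("stage %s done in %.1fs", stage, dt)
    (run / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return run
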