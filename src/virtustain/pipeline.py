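"""End-to-end pipeline orchestration: simulate -> register -> denoise ->
train -> stain -> quantify -> evaluate, with a run manifest and stage
resumption.

Each stage is a pure function of (inputs, config, seed) writing its outputs
under the run directory; re-running with the same config and seeds
reproduces them.  The evaluation follows the donor-holdout protocol: the
configured test donors are excluded from GAN training and reported
separately.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import denoising, quantify, registration, staining, synthetic
from .io import read_image, write_image, write_report

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_pairs", "evaluate_run"]

MODALITIES = ("dsdna", "ssdna")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.  Unknown keys in a config file are
    rejected; command-line overrides take precedence over file values."""

    # paths
    workdir: str = "virtustain_run"
    dataset_root: str | None = None  # existing dataset; None -> simulate
    # simulate
    n_donors: int = 2
    cells_per_donor: int = 55
    bg_level_ds: int = 10
    bg_level_ss: int = 14
    bg_jitter: int = 1
    frame_size: int = 192
    # registration
    ratio: float = registration.DEFAULT_RATIO
    ransac_px: float = registration.DEFAULT_RANSAC_PX
    min_inliers: int = registration.DEFAULT_MIN_INLIERS
    patch_size: int = 32
    # denoising
    exclude_zeros: bool = False
    # model
    arch: str = "pix2pix"
    epochs: int = 50
    batch_size: int = 8
    lambda_l1: float = 100.0
    lambda_gan: float = 1.0
    lr: float = 2e-4
    # evaluation
    area_mode: str = "intensity_sum"
    test_donors: tuple[str, ...] = ("donor_1",)
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.patch_size < 16:
            raise ValueError("patch_size must be >= 16")
        if self.arch not in ("pix2pix", "pix2pixpp"):
            raise ValueError("arch must be 'pix2pix' or 'pix2pixpp'")
        if not 0 < self.ratio < 1:
            raise ValueError("ratio must be in (0, 1)")
        if isinstance(self.test_donors, list):
            self.test_donors = tuple(self.test_donors)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)

    def record(self, name: str, **info) -> None:
        self.stages[name] = dict(completed_at=time.strftime("%Y-%m-%dT%H:%M:%S"), **info)

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        tmp.replace(path)  # atomic on POSIX


def load_pairs(
    pairs_root: str | Path, manifest: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Read a paired patch dataset into arrays.

    Returns (index frame with donor/frame/cell, bfi stack, dsdna stack,
    ssdna stack), sorted by (donor, frame, cell) for determinism.
    """
    root = Path(pairs_root)
    if manifest is None:
        manifest = pd.read_csv(root / "manifest.csv")
    ok = manifest[manifest["status"] == "ok"].sort_values(["donor", "frame", "cell"])
    idx_rows, bfi, ds, ss = [], [], [], []
    for r in ok.itertuples():
        pair_dir = root / r.donor / f"pair_{r.frame}_{r.cell}"
        bfi.append(read_image(pair_dir / "bfi.tiff"))
        ds.append(read_image(pair_dir / "dsdna.tiff"))
        ss.append(read_image(pair_dir / "ssdna.tiff"))
        idx_rows.append(dict(donor=r.donor, frame=int(r.frame), cell=int(r.cell)))
    if not idx_rows:
        raise ValueError(f"no usable pairs under {root}")
    index = pd.DataFrame(idx_rows)
    return index, np.stack(bfi), np.stack(ds), np.stack(ss)


def _denoise_stack(ds: np.ndarray, ss: np.ndarray, exclude_zeros: bool) -> tuple:
    ds_c = np.empty_like(ds)
    ss_c = np.empty_like(ss)
    noise_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-patch warnings are expected
        for i in range(ds.shape[0]):
            ds_c[i], ss_c[i], nd, ns = denoising.denoise_pair(
                ds[i], ss[i], exclude_zeros=exclude_zeros
            )
            noise_rows.append(dict(pair=i, ds_noise=nd, ss_noise=ns))
    return ds_c, ss_c, pd.DataFrame(noise_rows)


def _predict_dfi(
    index: pd.DataFrame, gen_ds: np.ndarray, gen_ss: np.ndarray, area_mode: str
) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(index.itertuples()):
        res = quantify.compute_dfi(gen_ds[i], gen_ss[i], area_mode=area_mode, cell_id=i)
        rows.append(
            dict(donor=r.donor, frame=r.frame, cell=r.cell, pred_dfi=res.dfi)
        )
    return pd.DataFrame(rows)


def evaluate_run(
    truth: pd.DataFrame, pred: pd.DataFrame, test_donors=()
) -> tuple[pd.DataFrame, quantify.EvalReport]:
    """Per-donor MAE/MAPE against ground truth plus the aggregate report."""
    per_donor = quantify.evaluate_per_donor(truth, pred)
    report = quantify.aggregate_report(per_donor, test_donors=test_donors)
    return report.to_frame(), report


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> RunManifest:
    """Execute all stages; each stage is skipped under ``resume`` when its
    outputs already exist.  Failures halt with the stage name; completed
    outputs are preserved."""
    work = Path(cfg.workdir)
    work.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=cfg.config_hash(), seed=cfg.seed)
    manifest_path = work / "run_manifest.json"

    def stage_done(output: Path) -> bool:
        return resume and output.exists()

    # 1. simulate (or use an existing dataset)
    dataset_root = Path(cfg.dataset_root) if cfg.dataset_root else work / "dataset"
    if cfg.dataset_root is None and not stage_done(dataset_root / "truth.csv"):
        template = synthetic.SceneSpec(
            frame_size=(cfg.frame_size, cfg.frame_size),
            bg_level_ds=cfg.bg_level_ds,
            bg_level_ss=cfg.bg_level_ss,
            bg_jitter=cfg.bg_jitter,
        )
        truth = synthetic.generate_donor_dataset(
            dataset_root,
            n_donors=cfg.n_donors,
            cells_per_donor=cfg.cells_per_donor,
            spec_template=template,
            seed=cfg.seed,
            force=True,
        )
        manifest.record("simulate", rows=len(truth), output=str(dataset_root))
    else:
        manifest.record("simulate", skipped=True, output=str(dataset_root))
    truth = pd.read_csv(dataset_root / "truth.csv")

    # 2. registration / paired patch extraction
    pairs_root = work / "pairs"
    if not stage_done(pairs_root / "manifest.csv"):
        reg_manifest = registration.build_paired_dataset(
            dataset_root,
            pairs_root,
            size=cfg.patch_size,
            ratio=cfg.ratio,
            ransac_threshold_px=cfg.ransac_px,
            min_inliers=cfg.min_inliers,
            seed=cfg.seed,
        )
    else:
        reg_manifest = pd.read_csv(pairs_root / "manifest.csv")
    n_ok = int((reg_manifest["status"] == "ok").sum())
    if n_ok == 0:
        raise RuntimeError("stage 'register' produced no usable pairs")
    manifest.record(
        "register",
        pairs=n_ok,
        failed=int((reg_manifest["status"] == "failed").sum()),
        mean_rmse=float(reg_manifest.loc[reg_manifest["status"] == "ok", "rmse"].mean()),
        output=str(pairs_root),
    )

    index, bfi, ds, ss = load_pairs(pairs_root, reg_manifest)

    # 3. denoise
    ds_clean, ss_clean, noise_log = _denoise_stack(ds, ss, cfg.exclude_zeros)
    write_report(noise_log, work / "noise_log.csv")
    manifest.record("denoise", pairs=len(noise_log), output=str(work / "noise_log.csv"))

    # 4-5. train one generator per fluorescence modality (test donors held out)
    is_train = ~index["donor"].isin(cfg.test_donors)
    if not is_train.any():
        raise RuntimeError("stage 'train': no training donors left after holdout")
    generators = {}
    for modality, target in (("dsdna", ds_clean), ("ssdna", ss_clean)):
        ckpt = work / f"generator_{modality}.npz"
        if stage_done(Path(str(ckpt))):
            generators[modality] = staining.load_checkpoint(ckpt)
            manifest.record(f"train_{modality}", skipped=True, output=str(ckpt))
            continue
        tcfg = staining.TrainConfig(
            epochs=cfg.epochs,
            image_size=cfg.patch_size,
            batch_size=cfg.batch_size,
            lr=cfg.lr,
            seed=cfg.seed,
            modality=modality,
        )
        dcfg = staining.DiscriminatorConfig(spectral_norm=(cfg.arch == "pix2pixpp"))
        lcfg = staining.LossConfig(lambda_l1=cfg.lambda_l1, lambda_gan=cfg.lambda_gan)
        gen, log = staining.train(
            bfi[is_train.to_numpy()], target[is_train.to_numpy()],
            dcfg=dcfg, lcfg=lcfg, tcfg=tcfg, checkpoint_path=ckpt,
        )
        write_report(log, work / f"train_log_{modality}.csv")
        generators[modality] = gen
        manifest.record(
            f"train_{modality}",
            epochs=cfg.epochs,
            final_l1=float(log["g_l1_loss"].iloc[-1]),
            output=str(ckpt),
        )

    # 6. stain all pairs (train and held-out donors)
    gen_ds = staining.stain(generators["dsdna"], bfi)
    gen_ss = staining.stain(generators["ssdna"], bfi)
    gen_dir = work / "generated"
    for i, r in enumerate(index.itertuples()):
        pair_dir = gen_dir / r.donor / f"pair_{r.frame}_{r.cell}"
        pair_dir.mkdir(parents=True, exist_ok=True)
        write_image(pair_dir / "dsdna.tiff", np.round(gen_ds[i] * 65535).astype(np.uint16))
        write_image(pair_dir / "ssdna.tiff", np.round(gen_ss[i] * 65535).astype(np.uint16))
    manifest.record("stain", pairs=int(bfi.shape[0]), output=str(gen_dir))

    # 7. quantify + evaluate
    pred = _predict_dfi(index, gen_ds, gen_ss, cfg.area_mode)
    write_report(pred, work / "pred_dfi.csv")
    report_frame, report = evaluate_run(truth, pred, test_donors=cfg.test_donors)
    write_report(report_frame, work / "report.csv")
    manifest.record(
        "evaluate",
        donors=len(report.per_donor),
        mean_mae=report.mean.get("mae"),
        output=str(work / "report.csv"),
    )

    manifest.write(manifest_path)
    return manifest
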