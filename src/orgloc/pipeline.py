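"""End-to-end orchestration: phantoms -> dataset -> training -> ROI ->
segmentation -> evaluation, with reproducible seeding and hashed configs."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import phantom as phantom_mod
from .clustering import ClusterConfig, segment_organ
from .metrics import evaluate_cohort
from .models import AxisClassifier, NetConfig, build_network, save_classifier, train_classifier
from .roi_search import RoiBox, SearchConfig, find_roi, side_box
from .sampling import SIDE_FOR_LABEL, SamplingConfig, build_dataset
from .volume_io import ORGAN_LABELS, write_mask

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "train_axis_nets"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run (serializable, hashed)."""

    organ: str = "kidney_right"
    n_cases: int = 10
    seed: int = 7
    out_dir: str | None = None
    demo: bool = True  # phantom cohort; False would require external NIfTI inputs
    sampling: SamplingConfig = field(default_factory=lambda: SamplingConfig(slice_stride=3))
    net: NetConfig = field(default_factory=lambda: NetConfig.fast(minibatch=16))
    search: SearchConfig = field(default_factory=SearchConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    z_stride: int = 6  # stride of axial slices entering the Z training set
    dedupe: bool = True
    ablation: bool = False  # additionally segment without ROI (whole image half)

    def validate(self) -> None:
        if self.organ not in ORGAN_LABELS or self.organ == "background":
            raise ValueError(f"organ must be one of {ORGAN_LABELS[:-1]}, got {self.organ!r}")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not self.demo:
            raise NotImplementedError("only phantom (demo) cohorts are wired up")

    def config_hash(self) -> str:
        payload = asdict(self)
        # artifact location and the optional extra ablation report do not
        # change the main pipeline outputs
        payload.pop("out_dir", None)
        payload.pop("ablation", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    report: "pd.DataFrame"  # noqa: F821 - per-case metrics + mean row
    rois: list[RoiBox]
    nets: dict[str, AxisClassifier]
    cohort: list
    pred_masks: list
    ablation_report: "pd.DataFrame | None" = None  # noqa: F821
    timings: dict[str, float] = field(default_factory=dict)
    config_hash: str = ""


def train_axis_nets(dataset, net_cfg: NetConfig, seed: int) -> dict[str, AxisClassifier]:
    """Build and train the three axis classifiers from a dataset bundle."""
    nets: dict[str, AxisClassifier] = {}
    for i, axis in enumerate(("X", "Y", "Z")):
        images = dataset.images[axis]
        shape = tuple(images.shape[1:3])
        cfg = replace(net_cfg, input_shape=shape, seed=seed + i)
        net = build_network(cfg, axis=axis)
        train_classifier(net, images, dataset.labels[axis])
        nets[axis] = net
    return nets


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full localization/segmentation pipeline.

    Re-running with the same config and seed reproduces every output
    bit-for-bit.  Artifacts (models, ROI JSONs, mask NIfTIs, the report
    CSV and a run manifest) are written when ``cfg.out_dir`` is set.
    """
    cfg.validate()
    chash = cfg.config_hash()
    timings: dict[str, float] = {}
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    cohort = phantom_mod.make_cohort(cfg.n_cases, seed=cfg.seed)
    timings["phantom"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    dataset = build_dataset(
        cohort, cfg.organ, cfg.sampling, z_stride=cfg.z_stride, dedupe=cfg.dedupe
    )
    timings["dataset"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    nets = train_axis_nets(dataset, cfg.net, cfg.seed)
    timings["train"] = time.perf_counter() - t0
    if out:
        for axis, net in nets.items():
            save_classifier(net, out / f"roinet_{axis.lower()}")

    search = replace(cfg.search, side=SIDE_FOR_LABEL.get(cfg.organ, "full"))
    rois: list[RoiBox] = []
    preds = []
    refs = []
    t0 = time.perf_counter()
    for i, (vol, masks) in enumerate(cohort):
        try:
            roi = find_roi(vol, nets, search, organ=cfg.organ)
        except Exception as exc:
            raise RuntimeError(f"stage=locate case={i}: {exc}") from exc
        rois.append(roi)
        if out:
            roi.to_json(out / f"roi_case{i}.json", extra={"config_hash": chash})
    timings["locate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    for i, (vol, masks) in enumerate(cohort):
        try:
            pred = segment_organ(vol, rois[i], cfg.cluster, label=cfg.organ)
        except Exception as exc:
            raise RuntimeError(f"stage=segment case={i}: {exc}") from exc
        preds.append(pred)
        refs.append(masks[cfg.organ])
        if out:
            write_mask(pred, out / f"mask_case{i}.nii.gz")
    timings["segment"] = time.perf_counter() - t0

    report = evaluate_cohort(list(zip(preds, refs)))
    ablation_report = None
    if cfg.ablation:
        t0 = time.perf_counter()
        ab_preds = []
        for vol, masks in cohort:
            box = side_box(vol.shape, side=search.side)
            ab_preds.append(segment_organ(vol, box, cfg.cluster, label=cfg.organ))
        ablation_report = evaluate_cohort(list(zip(ab_preds, refs)))
        timings["ablation"] = time.perf_counter() - t0

    if out:
        _write_csv(report, out / "report.csv", chash)
        if ablation_report is not None:
            _write_csv(ablation_report, out / "report_no_roi.csv", chash)
        (out / "run.json").write_text(
            json.dumps(
                {"config": asdict(cfg), "config_hash": chash, "timings": timings},
                indent=2,
                default=str,
            )
        )
    for stage, dt in timings.items():
        log.info("stage %-8s %6.1f s", stage, dt)
    return PipelineResult(
        report=report,
        rois=rois,
        nets=nets,
        cohort=cohort,
        pred_masks=preds,
        ablation_report=ablation_report,
        timings=timings,
        config_hash=chash,
    )


def _write_csv(df, path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=False, float_format="%.6f")
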