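"""End-to-end missing-seedling counting runs.

Workflow per image: segment green plants (ExG -> Otsu -> closing), extract
filtered blobs and their centroids (the default emergence detector — an
external detector's boxes can be substituted), group centroids into rows,
fit row lines, estimate the average plant spacing by the mode search, and
report detected vs expected counts with localized gaps.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import metrics as mt
from . import rows as rg
from . import segmentation as seg
from . import synthetic as syn
from . import voc

logger = logging.getLogger("maizegap")

__all__ = ["RunConfig", "count_image", "run_count", "run_simulate", "run_eval"]


@dataclass
class RunConfig:
    """Agronomy, segmentation and spacing parameters of a counting run.

    ``min_area_px`` defaults to ``min_area_frac`` x (plant spacing in
    pixels) squared. ``spacing_source`` selects Eq.-of-count spacing:
    ``estimated`` (from the image, the default) or ``rated`` (the nominal
    agronomic plant spacing x GSD). ``tolerance`` of the mode search
    defaults to 0.2 x median consecutive distance.
    """

    row_spacing_cm: float = 65.0
    plant_spacing_cm: float = 25.0
    gsd_px_per_cm: float = syn.GSD_PRESETS["default"]
    kernel_px: int = 5
    min_area_frac: float = 0.02
    min_area_px: int | None = None
    step_px: float = 10.0
    tolerance: float | None = None
    spacing_source: str = "estimated"
    refine_spacing: bool = True
    gap_factor: float = 1.5
    min_row_members: int = 4
    seed: int = 0

    @property
    def plant_spacing_px(self) -> float:
        return self.plant_spacing_cm * self.gsd_px_per_cm

    @property
    def row_spacing_px(self) -> float:
        return self.row_spacing_cm * self.gsd_px_per_cm

    def resolved_min_area(self) -> int:
        if self.min_area_px is not None:
            return int(self.min_area_px)
        return max(1, int(round(self.min_area_frac * self.plant_spacing_px**2)))

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class CountArtifacts:
    """Intermediate results kept for overlays and debugging."""

    centroids: np.ndarray
    row_groups: list[np.ndarray] = field(default_factory=list)
    row_lines: list[rg.RowLine] = field(default_factory=list)
    n_blobs: int = 0


def count_image(
    image: np.ndarray,
    config: RunConfig,
    boxes: list[mt.DetectionBox] | None = None,
) -> tuple[rg.CountReport, CountArtifacts]:
    """Run the counting chain on one RGB image.

    ``boxes`` substitutes an external emergence detector: box centers are
    used as plant centroids instead of the segmentation blobs. Detected
    totals count the centroids assigned to kept rows; clutter that does
    not align into a row (e.g. weeds between rows) is excluded.
    """
    if boxes is not None:
        centroids = np.array([b.center for b in boxes], dtype=float).reshape(-1, 2)
        n_blobs = len(boxes)
    else:
        exg = seg.excess_green(image)
        try:
            _, mask = seg.otsu_binarize(exg)
        except ValueError:  # constant index map: bare frame
            centroids = np.empty((0, 2))
            report = _empty_report(["no rows: constant excess-green map"])
            return report, CountArtifacts(centroids)
        closed = seg.close_mask(mask, config.kernel_px)
        blobs = seg.extract_blobs(closed, config.resolved_min_area())
        centroids = np.array([b.centroid for b in blobs], dtype=float).reshape(-1, 2)
        n_blobs = len(blobs)

    if centroids.shape[0] == 0:
        return _empty_report(["no rows: no plant blobs detected"]), CountArtifacts(centroids, n_blobs=n_blobs)

    groups = rg.group_rows(centroids, config.row_spacing_px)
    kept = [g for g in groups if g.shape[0] >= max(2, config.min_row_members)]
    if not kept:
        return (
            _empty_report(["no rows: no cluster reached min_row_members"]),
            CountArtifacts(centroids, groups, n_blobs=n_blobs),
        )
    lines = [rg.fit_row_line(g) for g in kept]

    pooled = np.concatenate([rg.consecutive_distances(line) for line in lines])
    spacing = None
    if config.spacing_source == "rated":
        dt = config.plant_spacing_px
    else:
        spacing = rg.estimate_spacing(pooled, config.step_px, config.tolerance)
        dt = spacing.refined_Dt if config.refine_spacing else spacing.chosen_Dt
    detected = int(sum(line.members.shape[0] for line in lines))
    report = rg.build_count_report(lines, dt, detected, config.gap_factor, spacing)
    return report, CountArtifacts(centroids, kept, lines, n_blobs=n_blobs)


def _empty_report(flags: list[str]) -> rg.CountReport:
    return rg.CountReport(
        per_row=[],
        detected_total=0,
        expected_total=0,
        missing_total=0,
        per_row_missing_total=0,
        dt_used=float("nan"),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# batch runs


def _overlay(image: np.ndarray, report: rg.CountReport, art: CountArtifacts, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(image.shape[1] / 100, image.shape[0] / 100), dpi=100)
    ax.imshow(image)
    if art.centroids.size:
        ax.plot(art.centroids[:, 0], art.centroids[:, 1], "r+", ms=8, mew=1.5)
    for line in art.row_lines:
        t = line.member_coordinates()
        p0 = line.anchor + t.min() * line.direction
        p1 = line.anchor + t.max() * line.direction
        ax.plot([p0[0], p1[0]], [p0[1], p1[1]], "c-", lw=1)
    for rc in report.per_row:
        for _, _, positions in rc.gaps:
            for x, y in positions:
                ax.plot(x, y, "yo", ms=10, mfc="none", mew=2)
    ax.set_axis_off()
    ax.set_title(
        f"detected {report.detected_total} / expected {report.expected_total} "
        f"/ missing {report.missing_total}"
    )
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def run_count(
    image_paths: list[str | Path],
    config: RunConfig,
    out_dir: str | Path,
    boxes_dir: str | Path | None = None,
    strict: bool = False,
    overlays: bool = True,
) -> dict:
    """Count every image, write per-image JSON (+ overlay PNG) and an
    aggregate CSV; returns a summary dict with per-image rows and the
    number of skipped inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    skipped = []
    t_start = time.time()
    for path in image_paths:
        path = Path(path)
        try:
            image = iio.imread(path)
        except Exception as exc:  # unreadable input
            if strict:
                raise
            logger.warning("skipping unreadable image %s: %s", path, exc)
            skipped.append(str(path))
            continue
        boxes = None
        if boxes_dir is not None:
            cand = Path(boxes_dir) / (path.stem + ".xml")
            if cand.exists():
                boxes = voc.read_voc_xml(cand)
        t0 = time.time()
        report, art = count_image(np.asarray(image)[..., :3], config, boxes)
        payload = {
            "image": path.name,
            "report": report.to_dict(),
            "config": config.to_dict(),
            "config_hash": config.content_hash(),
        }
        (out / f"{path.stem}.count.json").write_text(json.dumps(payload, sort_keys=True, indent=1))
        if overlays:
            _overlay(np.asarray(image)[..., :3], report, art, out / f"{path.stem}.overlay.png")
        records.append(
            {
                "image": path.name,
                "detected": report.detected_total,
                "expected": report.expected_total,
                "missing": report.missing_total,
                "dt": report.dt_used,
                "seconds": round(time.time() - t0, 3),
            }
        )
    pd.DataFrame(
        records, columns=["image", "detected", "expected", "missing", "dt", "seconds"]
    ).to_csv(out / "summary.csv", index=False)
    (out / "run.log").write_text(
        "\n".join(
            [
                "maizegap count run",
                f"config_hash: {config.content_hash()}",
                f"images: {len(records)} processed, {len(skipped)} skipped",
                f"total_seconds: {round(time.time() - t_start, 3)}",
            ]
            + [f"skipped: {s}" for s in skipped]
        )
    )
    return {"records": records, "skipped": skipped}


def run_simulate(spec: syn.FieldSpec, n_images: int, seed: int, out_dir: str | Path) -> pd.DataFrame:
    """Generate a synthetic dataset on disk: PNG images, Pascal-VOC XML for
    the emerged plants, a JSON sidecar with the full ground truth, and a
    manifest CSV (image, seed, spec hash)."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec_i in enumerate(syn.make_image_specs(spec, n_images, seed)):
        img, truth = syn.generate_field(spec_i)
        name = f"field_{i:04d}"
        iio.imwrite(out / "images" / f"{name}.png", img)
        boxes = [tuple(b) for b in truth.emerged_boxes]
        voc.write_voc_xml(
            out / "annotations" / f"{name}.xml",
            f"{name}.png",
            (img.shape[1], img.shape[0]),
            boxes,
        )
        (out / "annotations" / f"{name}.truth.json").write_text(
            json.dumps(truth.to_json_dict(), sort_keys=True)
        )
        rows.append({"image": f"{name}.png", "seed": spec_i.seed, "spec_hash": spec_i.content_hash()})
    manifest = pd.DataFrame(rows, columns=["image", "seed", "spec_hash"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def run_eval(pred_dir: str | Path, truth_dir: str | Path, iou_thr: float = 0.5, out_path: str | Path | None = None) -> dict:
    """Score predictions against Pascal-VOC ground truth.

    Predictions are matched per image (files paired by stem; ``.xml`` VOC
    or ``.json`` ``[[x0, y0, x1, y1, score], ...]`` are accepted), pooled
    into one PR curve, and summarized as P/R/F1 at the IoU threshold plus
    all-points AP (mAP == AP for the single class).
    """
    truth_dir, pred_dir = Path(truth_dir), Path(pred_dir)
    scores, flags = [], []
    tp = fp = fn = 0
    n_truth = 0
    for truth_path in sorted(truth_dir.glob("*.xml")):
        if truth_path.name.endswith(".truth.xml"):
            continue
        truths = voc.read_voc_xml(truth_path)
        preds = _load_predictions(pred_dir, truth_path.stem)
        n_truth += len(truths)
        match = mt.match_boxes(preds, truths, iou_thr)
        tp += match.tp
        fp += match.fp
        fn += match.fn
        scores.extend(preds[i].score for i in match.pred_order)
        flags.extend(match.pred_is_tp)
    pooled = mt.MatchResult(tp=tp, fp=fp, fn=fn)
    precision, recall, f1 = mt.precision_recall_f1(pooled)
    ap = mt.ap_from_scored_flags(np.array(scores), np.array(flags, dtype=bool), n_truth) if n_truth else 0.0
    result = {
        "iou_threshold": iou_thr,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "ap": ap,
        "map": ap,
        "ap_interpolation": "all-points",
        "n_truth": n_truth,
        "tp": tp,
        "fp": fp,
        "fn": fn,
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(result, sort_keys=True, indent=1))
    return result


def _load_predictions(pred_dir: Path, stem: str) -> list[mt.DetectionBox]:
    xml = pred_dir / f"{stem}.xml"
    if xml.exists():
        return voc.read_voc_xml(xml)
    js = pred_dir / f"{stem}.json"
    if js.exists():
        data = json.loads(js.read_text())
        return [mt.DetectionBox(*row[:4], score=(row[4] if len(row) > 4 else 1.0)) for row in data]
    return []


def simulate_and_count(spec: syn.FieldSpec, config: RunConfig | None = None):
    """Convenience: generate one field and run the counting chain on it."""
    config = config or replace_config_for(spec)
    img, truth = syn.generate_field(spec)
    report, art = count_image(img, config)
    return img, truth, report, art


def replace_config_for(spec: syn.FieldSpec, **overrides) -> RunConfig:
    """A RunConfig whose agronomy matches a FieldSpec."""
    cfg = RunConfig(
        row_spacing_cm=spec.row_spacing_cm,
        plant_spacing_cm=spec.plant_spacing_cm,
        gsd_px_per_cm=spec.gsd_px_per_cm,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
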