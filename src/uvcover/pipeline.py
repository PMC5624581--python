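"""Batch orchestration: simulate -> score -> analyze.

One flat configuration drives all three stages; every parameter has a
default, the file round-trips unchanged through load/save, and one seed
makes the whole chain byte-for-byte reproducible.  Images are 8-bit
greyscale PNG, truth masks 0/255 PNG, landmarks JSON sidecars, tables CSV
with fixed float formatting.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .geometry import (
    GeometryConfig,
    MalformedLandmarksError,
    NoFaceError,
    SidecarProvider,
    get_landmarks,
)
from .phantom import CohortModel, PhantomSpec, generate_cohort
from .preprocess import EqualizationConfig, GaussianKernelSpec
from .scoring import ScoringConfig, score_image
from .stats import full_report

log = logging.getLogger("uvcover")

__all__ = ["PipelineConfig", "simulate", "run_scoring", "run_analysis", "run_all"]

FLOAT_FMT = "%.6f"


@dataclass
class PipelineConfig:
    """Flat key-value pipeline configuration; defaults are the frozen
    study conditions."""

    # cohort simulation
    n_participants: int = 57
    letterbox_median: float = 0.14
    rest_median: float = 0.07
    log_sd: float = 0.35
    skill_correlation: float = 0.84
    visit2_improvement_letterbox: float = 0.30
    visit2_improvement_rest: float = 0.15
    canthus_miss_probability_v1: float = 44 / 57
    canthus_miss_probability_v2: float = 37 / 57
    with_artifacts: bool = False
    image_width: int = 256
    image_height: int = 320
    # scoring
    threshold: float = 0.52
    min_missed_pixels: int = 1
    block_rows: int = 8
    block_cols: int = 8
    clip_limit: float = 2.0
    blur_theta: float = 1.0
    landmark_provider: str = "sidecar"
    # geometry
    letterbox_hpad: float = 0.10
    letterbox_top_pad: float = 0.15
    letterbox_bottom_frac: float = 0.60
    canthus_frac: float = 0.25
    # run control
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    def cohort_model(self, seed: int | None = None) -> CohortModel:
        return CohortModel(
            n_participants=self.n_participants,
            letterbox_median=self.letterbox_median,
            rest_median=self.rest_median,
            log_sd=self.log_sd,
            skill_correlation=self.skill_correlation,
            visit2_improvement_letterbox=self.visit2_improvement_letterbox,
            visit2_improvement_rest=self.visit2_improvement_rest,
            canthus_miss_probability=(
                self.canthus_miss_probability_v1,
                self.canthus_miss_probability_v2,
            ),
            seed=self.seed if seed is None else seed,
        )

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(image_width=self.image_width, image_height=self.image_height)

    def geometry_config(self) -> GeometryConfig:
        return GeometryConfig(
            letterbox_hpad=self.letterbox_hpad,
            letterbox_top_pad=self.letterbox_top_pad,
            letterbox_bottom_frac=self.letterbox_bottom_frac,
            canthus_frac=self.canthus_frac,
        )

    def scoring_config(self) -> ScoringConfig:
        return ScoringConfig(
            threshold=self.threshold,
            min_missed_pixels=self.min_missed_pixels,
            equalization=EqualizationConfig(
                block_rows=self.block_rows,
                block_cols=self.block_cols,
                clip_limit=self.clip_limit or None,
            ),
            blur=GaussianKernelSpec(theta_x=self.blur_theta, theta_y=self.blur_theta),
            geometry=self.geometry_config(),
        )


def _save_png(arr: np.ndarray, path: Path) -> None:
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def simulate(config: PipelineConfig, out_dir, seed: int | None = None) -> pd.DataFrame:
    """Generate the phantom cohort on disk: PNGs, masks, sidecars, cohort.csv."""
    out = Path(out_dir)
    for sub in ("images", "masks", "landmarks"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    model = config.cohort_model(seed)
    bundles, table = generate_cohort(
        model,
        config.phantom_spec(),
        with_artifacts=config.with_artifacts,
        geometry=config.geometry_config(),
    )
    for b in bundles:
        image_id = b.metadata["image_id"]
        _save_png(b.image, out / "images" / f"{image_id}.png")
        _save_png(b.truth_mask.astype(np.uint8) * 255, out / "masks" / f"{image_id}.png")
        b.landmarks.to_json(out / "landmarks" / f"{image_id}.json")
    table.to_csv(out / "cohort.csv", index=False, float_format=FLOAT_FMT)
    log.info("simulated %d bundles into %s", len(bundles), out)
    return table


def run_scoring(
    config: PipelineConfig, input_dir, out_csv
) -> pd.DataFrame:
    """Score every image in ``input_dir/images`` against its landmark sidecar.

    Unreadable images or missing/malformed sidecars are skipped and logged;
    a missing input directory is a hard error.
    """
    root = Path(input_dir)
    img_dir = root / "images"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"missing input image directory {img_dir}")
    if config.landmark_provider != "sidecar":
        raise ValueError(
            f"unknown landmark provider {config.landmark_provider!r}; "
            "only the ground-truth 'sidecar' provider is bundled"
        )
    scoring = config.scoring_config()
    rows, skipped = [], 0
    for path in sorted(img_dir.glob("*.png")):
        image_id = path.stem
        t0 = time.perf_counter()
        try:
            with Image.open(path) as im:
                arr = np.asarray(im.convert("L"))
            provider = SidecarProvider(root / "landmarks" / f"{image_id}.json")
            landmarks = get_landmarks(arr, provider)
            result = score_image(arr, landmarks, scoring, image_id=image_id)
        except (OSError, NoFaceError, MalformedLandmarksError, ValueError) as exc:
            skipped += 1
            log.warning("skipping %s: %s", image_id, exc)
            continue
        log.info("scored %s in %.3fs", image_id, time.perf_counter() - t0)
        rows.append(result.as_row())
    if not rows:
        raise RuntimeError(f"no image in {img_dir} could be scored")
    df = pd.DataFrame(rows)
    df.attrs["skipped"] = skipped
    Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_csv, index=False, float_format=FLOAT_FMT)
    log.info("wrote %d coverage rows (%d skipped) to %s", len(df), skipped, out_csv)
    return df


def join_coverage(coverage: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Join scored coverage rows to cohort metadata on image_id."""
    meta_cols = ["image_id", "participant_id", "visit", "gender", "skin_type",
                 "formulation"]
    missing = set(meta_cols) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    unknown = sorted(set(coverage["image_id"]) - set(cohort["image_id"]))
    if unknown:
        raise ValueError(f"coverage rows with unknown image ids: {unknown}")
    return coverage.merge(cohort[meta_cols], on="image_id", how="left")


def run_analysis(coverage_csv, cohort_csv, out_dir) -> Path:
    """Compute the full statistics report from the scored coverage table."""
    coverage = pd.read_csv(coverage_csv)
    if coverage.empty:
        raise ValueError(f"coverage table {coverage_csv} is empty")
    cohort = pd.read_csv(cohort_csv)
    joined = join_coverage(coverage, cohort)
    report = full_report(joined)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json() + "\n")
    (out / "report.md").write_text(report.to_markdown())
    for w in report.warnings:
        log.warning("%s", w)
    log.info("wrote report to %s", out)
    return out / "report.json"


def run_all(config: PipelineConfig, out_dir, seed: int | None = None) -> Path:
    """simulate -> score -> analyze from one config and one seed."""
    out = Path(out_dir)
    simulate(config, out, seed)
    run_scoring(config, out, out / "coverage.csv")
    return run_analysis(out / "coverage.csv", out / "cohort.csv", out)
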