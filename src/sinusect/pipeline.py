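"""End-to-end pipeline: reorient -> reconstruct/clip -> measure -> stats.

Input layout: a directory of ``<subject>_<side>.nii.gz`` cavity masks with
matching ``<subject>_<side>.landmarks.json`` files, plus an optional
``meta.csv`` (columns ``subject,sex[,age]``); without it the sex is
inferred from the subject prefix (``m``/``f``). Per-sinus failures are
logged and skipped; the run summary carries a non-zero failure count.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import load_mask, save_profiles
from .morphometry import profile_sinus
from .orientation import (
    HeadLandmarks,
    aggregate_misorientation,
    apply_transform,
    compute_reorientation,
)
from .reconstruct import BoundarySpec, clip_by_boundary, extract_isosurface
from .stats import cohort_report

logger = logging.getLogger("sinusect")


@dataclass
class PipelineConfig:
    input_dir: str = "."
    output_dir: str = "out"
    boundary: str | None = None
    fraction_step: int = 10
    smoothing: float = 0.0
    largest_loop_only: bool = False
    welch: bool = False
    holm: bool = False
    subject_level: bool = False
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fraction_step <= 0 or 100 % self.fraction_step:
            raise ValueError("fraction_step must divide 100")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in payload.items() if k in known}
        kwargs["extra"] = {k: v for k, v in payload.items() if k not in known}
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _discover_inputs(input_dir: Path) -> list[tuple[str, str, Path, Path]]:
    masks = sorted(input_dir.glob("*.nii.gz")) + sorted(input_dir.glob("*.nii"))
    items = []
    for mask_path in masks:
        stem = mask_path.name.removesuffix(".nii.gz").removesuffix(".nii")
        lm_path = input_dir / f"{stem}.landmarks.json"
        if not lm_path.exists():
            logger.warning("no landmarks for %s; skipping", mask_path.name)
            continue
        subject, _, side = stem.rpartition("_")
        items.append((subject, side, mask_path, lm_path))
    return items


def _sex_lookup(input_dir: Path) -> dict[str, str]:
    meta_path = input_dir / "meta.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, dtype=str)
        return dict(zip(meta["subject"], meta["sex"]))
    return {}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full measurement pipeline over an input directory.

    Returns a summary dict with the output paths, per-sinus failures and
    the provenance record. Deterministic stages are bit-reproducible for a
    fixed config.
    """
    input_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    items = _discover_inputs(input_dir)
    if not items:
        raise FileNotFoundError(f"no mask/landmark pairs found in {input_dir}")
    sexes = _sex_lookup(input_dir)
    boundary = (
        BoundarySpec.from_json(config.boundary) if config.boundary else None
    )

    profiles, transforms, failures = [], [], []
    for subject, side, mask_path, lm_path in items:
        try:
            volume = load_mask(mask_path)
            landmarks = HeadLandmarks.from_json(lm_path)
            mis = compute_reorientation(landmarks)
            aligned = apply_transform(volume, mis.inverse())
            transforms.append(mis)
            mesh = extract_isosurface(aligned, side=side)
            if boundary is not None:
                mesh = clip_by_boundary(mesh, boundary)
            sex = sexes.get(subject) or (
                "male" if subject.startswith("m") else "female"
            )
            profile = profile_sinus(
                mesh,
                subject=subject,
                sex=sex,
                side=side,
                fraction_step=config.fraction_step,
                smoothing=config.smoothing,
                largest_loop_only=config.largest_loop_only,
            )
            profiles.append(profile)
        except Exception as exc:  # noqa: BLE001 - per-sinus isolation
            logger.error("sinus %s_%s failed: %s", subject, side, exc)
            failures.append({"subject": subject, "side": side, "error": str(exc)})

    if not profiles:
        raise RuntimeError("every sinus failed; see log")

    table = pd.concat([p.to_frame() for p in profiles], ignore_index=True)
    profiles_path = out_dir / "profiles.csv"
    save_profiles(table, profiles_path)

    report = {
        "misorientation": aggregate_misorientation(transforms),
        "stats": cohort_report(
            table[table["fraction"].isin(range(10, 100, 10))],
            welch=config.welch,
            holm=config.holm,
        ),
    }
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=1))

    provenance = {
        "sinusect_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "config": {k: v for k, v in asdict(config).items()},
        "n_sinuses": len(profiles),
        "n_failures": len(failures),
        "failures": failures,
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))

    return {
        "profiles_csv": str(profiles_path),
        "report_json": str(report_path),
        "n_sinuses": len(profiles),
        "failures": failures,
    }
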