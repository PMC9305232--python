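"""End-to-end pipelines: configuration, provenance, tidy tabular outputs.

``run_architecture_pipeline`` takes micrographs (files or a synthetic
preset) through binarize → clean → skeletonize → box-count/density and
emits one tidy row per (image, ROI).  ``run_assay_pipeline`` fits the
copy-number calibrations and computes per-replicate transfer efficiencies.
Every output table carries the config hash and package version; a fixed
config + seed reproduces tables byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
import yaml

from . import __version__
from .assays import copies_to_biomass, fit_calibration, transfer_efficiency
from .images import NetworkImage, read_images
from .metrics import (
    DEFAULT_GRID_SIZES,
    BoxCountFractalEstimator,
    surface_density,
)
from .preprocess import binarize, clean_mask, skeletonize
from .synthetic import (
    FIXTURE_NAMES,
    SyntheticNetworkParams,
    generate_gradient_series,
    generate_network,
    make_fixture,
)

__all__ = ["PipelineConfig", "run_architecture_pipeline", "run_assay_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the architecture and assay pipelines.

    Round-trips losslessly through YAML (``to_yaml``/``from_yaml``); the
    first 12 hex digits of the SHA-256 of its canonical JSON form are the
    provenance hash stamped into every output table.
    """

    # binarization
    binarize_method: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: float | None = None
    invert: bool = False
    # cleaning
    min_cluster_px: int = 20
    connectivity: int = 8
    smoothing_radius_px: int = 1
    # metrics
    grid_sizes_px: tuple[int, ...] = DEFAULT_GRID_SIZES
    anchoring: Literal["topleft", "average4"] = "topleft"
    source: Literal["skeleton", "clean_mask"] = "skeleton"
    # ROI / synthesis
    roi_side_px: int = 640
    gradient_coverages: tuple[float, ...] = (0.04, 0.06, 0.08)
    rng_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_sizes_px"] = list(self.grid_sizes_px)
        d["gradient_coverages"] = list(self.gradient_coverages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("grid_sizes_px", "gradient_coverages"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _load_preset(preset: str, config: PipelineConfig) -> list[NetworkImage]:
    params = SyntheticNetworkParams(
        image_size_px=config.roi_side_px, rng_seed=config.rng_seed
    )
    if preset == "fixtures":
        out = []
        for i, name in enumerate(FIXTURE_NAMES):
            size = 729 if name == "sierpinski_carpet" else config.roi_side_px
            fx = make_fixture(name, size)
            # analytic rasters are measured as-is (no cleaning/thinning) and
            # the carpet needs power-of-3 grids aligned with its construction
            meta = {"label": i + 1, "raw_metrics": True, "true_dimension": fx.true_dimension}
            if name == "sierpinski_carpet":
                meta["grid_sizes_px"] = (3, 9, 27, 81)
            out.append(NetworkImage(fx.image, provenance=f"fixture:{name}", metadata=meta))
        return out
    if preset == "gradient":
        return generate_gradient_series(
            params, len(config.gradient_coverages), list(config.gradient_coverages)
        )
    if preset == "network":
        img = generate_network(params)
        img.metadata["label"] = 1
        return [img]
    raise ValueError(f"unknown preset {preset!r}; supported: fixtures, gradient, network")


def run_architecture_pipeline(
    images: Sequence[str | Path | NetworkImage] | str,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Quantify network architecture for a set of images or a synth preset.

    ``images`` is a list of file paths / :class:`NetworkImage` objects, or a
    preset name (``"fixtures"``, ``"gradient"``, ``"network"``).  Unreadable
    image files are skipped with a logged error; if every input fails, a
    ``RuntimeError`` is raised.  Returns one row per image with D_m, r²,
    coverage percent, the N(s) counts, and provenance columns.
    """
    if isinstance(images, str) and not Path(images).exists():
        inputs: list[tuple[str, NetworkImage]] = [
            (img.provenance, img) for img in _load_preset(images, config)
        ]
    else:
        if isinstance(images, str):
            images = [images]
        if len(images) == 0:
            raise ValueError("no input images given")
        inputs = []
        for item in images:
            if isinstance(item, NetworkImage):
                inputs.append((item.provenance or "in-memory", item))
                continue
            try:
                for img in read_images(item):
                    inputs.append((img.provenance, img))
            except Exception as exc:  # unreadable file: skip, keep going
                logger.error("skipping unreadable image %s: %s", item, exc)
        if not inputs:
            raise RuntimeError("all input images failed to load")

    rows = []
    for name, img in inputs:
        binary = binarize(img, config.binarize_method, config.fixed_threshold, config.invert)
        if img.metadata.get("raw_metrics"):
            clean = counted = binary  # analytic fixture: measure the raster as-is
        else:
            clean = clean_mask(
                binary, config.min_cluster_px, config.connectivity, config.smoothing_radius_px
            )
            counted = skeletonize(clean) if config.source == "skeleton" else clean
        grids = img.metadata.get("grid_sizes_px", config.grid_sizes_px)
        est = BoxCountFractalEstimator(grids, config.anchoring).fit(counted)
        den = surface_density(clean)
        row = {
            "image": name,
            "label": img.metadata.get("label", 0),
            "D_m": est.dimension_,
            "r_squared": est.r_squared_,
            "coverage_percent": den.coverage_percent,
        }
        for s, c in zip(est.curve_.grid_sizes_px, est.curve_.occupied_counts):
            row[f"N_s{s}"] = c
        row["config_hash"] = config.config_hash
        row["version"] = __version__
        rows.append(row)
    return pd.DataFrame(rows)


def run_assay_pipeline(
    calibration_table: str | Path | pd.DataFrame,
    assay_table: str | Path | pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    fit_intercept: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fit calibrations and compute transfer efficiencies from CSV tables.

    The calibration table needs columns ``strain, copy_number, biomass_mg``.
    The assay table needs ``replicate_id, qd_signal_focal_root`` plus either
    biomass columns (``biomass_focal_comp_mg, biomass_focal_in_central_mg``)
    or raw copy-number columns (``strain, copies_focal_comp,
    copies_focal_in_central``), which are converted through the per-strain
    calibration.  When qPCR cannot distinguish the focal strain from its
    partner, all central-compartment copies are attributed to the focal
    strain (logged prominently); pre-split biomass columns override this.

    Returns ``(models, efficiencies, excluded)`` DataFrames, each stamped
    with the config hash and version.
    """
    calib = (
        calibration_table
        if isinstance(calibration_table, pd.DataFrame)
        else pd.read_csv(calibration_table)
    )
    assay = assay_table if isinstance(assay_table, pd.DataFrame) else pd.read_csv(assay_table)

    models, failures = fit_calibration(calib, per_strain=True, fit_intercept=fit_intercept)
    models_df = pd.DataFrame([dataclasses.asdict(m) for m in models])
    for strain, reason in failures.items():
        models_df = pd.concat(
            [
                models_df,
                pd.DataFrame(
                    [{"strain": strain, "slope": float("nan"), "intercept": float("nan"),
                      "r_squared": float("nan"), "n_samples": 0, "error": reason}]
                ),
            ],
            ignore_index=True,
        )
    by_strain = {m.strain: m for m in models}

    has_biomass = {"biomass_focal_comp_mg", "biomass_focal_in_central_mg"} <= set(assay.columns)
    if not has_biomass:
        needed = {"strain", "copies_focal_comp", "copies_focal_in_central"}
        missing = needed - set(assay.columns)
        if missing:
            raise ValueError(
                "assay table needs biomass columns "
                "(biomass_focal_comp_mg, biomass_focal_in_central_mg) or copy-number "
                f"columns; missing: {sorted(missing)}"
            )
        logger.warning(
            "deriving biomass from copy numbers; all central-compartment copies "
            "are attributed to the focal strain"
        )
        assay = assay.copy()
        for copy_col, mass_col in (
            ("copies_focal_comp", "biomass_focal_comp_mg"),
            ("copies_focal_in_central", "biomass_focal_in_central_mg"),
        ):
            assay[mass_col] = [
                copies_to_biomass(by_strain[str(s)], c)
                for s, c in zip(assay["strain"], assay[copy_col])
            ]

    eff, excluded = transfer_efficiency(assay)
    for df in (models_df, eff, excluded):
        df["config_hash"] = config.config_hash
        df["version"] = __version__
    return models_df, eff, excluded
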