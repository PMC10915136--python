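"""Shared I/O, configuration and the end-to-end pipeline.

Volumes travel as multi-page TIFF (one page per z-section; 32-bit float
for phase/intensity, 16-bit for labels), feature and spectrum tables as
CSV, grades and summaries as JSON, configuration as YAML.  The pipeline
chains segmentation → feature extraction → scattering spectrum → health
grading for one embryo and writes every artifact with pinned float
formatting so re-runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import features as feat
from . import scatter as scat
from .glim import PhaseVolume
from .grading import FBMModel, GradeResult, max_vote, nucleus_feature_rows, predict_items
from .link3d import LabelVolume, Link3DParams, count_map, resample_isotropic, segment_nucleus_stack
from .seg2d import Seg2DParams

logger = logging.getLogger(__name__)

CSV_FLOAT_FORMAT = "%.8g"


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF into a (z, y, x) array."""
    try:
        vol = tifffile.imread(str(path))
    except Exception as exc:  # corrupt / unreadable file
        raise IOError(f"cannot read TIFF stack {path}: {exc}") from exc
    vol = np.asarray(vol)
    if vol.ndim == 2:
        vol = vol[None]
    if vol.ndim != 3:
        raise IOError(f"{path}: expected a z-stack, got shape {vol.shape}")
    return vol


def write_stack(volume: np.ndarray, path, labels: bool = False) -> None:
    """Write a (z, y, x) array as multi-page TIFF.

    Phase/intensity volumes are stored as 32-bit float, label volumes as
    16-bit unsigned integers.
    """
    vol = np.asarray(volume)
    if labels:
        if vol.max() > np.iinfo(np.uint16).max:
            raise ValueError("more than 65535 labels do not fit a 16-bit TIFF")
        vol = vol.astype(np.uint16)
    else:
        vol = vol.astype(np.float32)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), vol)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Calibration + per-stage parameters for the full pipeline.

    Pixel-domain segmentation defaults correspond to the reference
    calibration (11 px/µm, 1 µm z-step) and are rescaled automatically
    when the calibration differs.
    """

    lateral_px_per_um: float = 11.0
    z_step_um: float = 1.0
    wavelength_um: float = 0.488
    gamma_um3_per_pg: float = 0.2
    seg2d: Seg2DParams = field(default_factory=Seg2DParams)
    link3d: Link3DParams = field(default_factory=Link3DParams)
    scatter_grid: int = 256
    te_radius_threshold: float = 0.7
    seed: int = 0
    output_dir: str = "embryoqpi_out"

    def scaled_params(self) -> tuple[Seg2DParams, Link3DParams]:
        return (
            self.seg2d.scaled(self.lateral_px_per_um),
            self.link3d.scaled(self.lateral_px_per_um, self.z_step_um),
        )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "seg2d" in d:
            d["seg2d"] = Seg2DParams(**d["seg2d"])
        if "link3d" in d:
            d["link3d"] = Link3DParams(**d["link3d"])
        return cls(**d)


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

@dataclass
class EmbryoResult:
    """Everything the pipeline computes for one embryo."""

    records: pd.DataFrame
    labels: LabelVolume  # anisotropic pixel-domain labels
    labels_iso: LabelVolume
    spectrum: scat.ScatteringSpectrum
    nuc_count: int
    bw3db: float
    count_map: np.ndarray
    grade: GradeResult | None = None
    dmd_map: np.ndarray | None = None
    stage_counts: dict = field(default_factory=dict)


def process_embryo(
    phase: PhaseVolume,
    nucleus_channel: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
    model: FBMModel | None = None,
    compute_dmd_map: bool = False,
    embryo_id: str | int = 0,
) -> EmbryoResult:
    """Segment → extract features → scattering spectrum → (optional) grade."""
    t0 = time.perf_counter()
    seg_params, link_params = config.scaled_params()

    labels, trajectories = segment_nucleus_stack(nucleus_channel, seg_params, link_params)
    t_seg = time.perf_counter()
    cmap = count_map(labels)

    labels_iso, phase_iso = resample_isotropic(labels, phase, link_params)
    records = feat.build_records(labels_iso, phase_iso)
    if len(records):
        records = feat.assign_compartment(records, config.te_radius_threshold)
    t_feat = time.perf_counter()

    if len(records):
        cents = records[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy()
        extent = tuple(
            n * v for n, v in zip(labels_iso.labels.shape, labels_iso.voxel_size_um)
        )
        spectrum = scat.spectrum_from_centroids(cents, extent, config.scatter_grid)
        bw3db = spectrum.bw3db
    else:
        spectrum = None
        bw3db = float("nan")
    t_scat = time.perf_counter()

    grade = None
    if model is not None and len(records):
        rows = nucleus_feature_rows(records, len(records), bw3db, embryo_id)
        grade = max_vote(predict_items(model, rows), embryo_id)

    dmd = None
    if compute_dmd_map and len(records):
        dmd, _ = feat.dmd_map(labels_iso, records)

    stage_counts = dict(
        trajectories=len(trajectories),
        nuclei_3d=labels.n_objects,
        records=len(records),
        t_segment_s=round(t_seg - t0, 3),
        t_features_s=round(t_feat - t_seg, 3),
        t_scatter_s=round(t_scat - t_feat, 3),
    )
    logger.info("embryo %s: %s", embryo_id, stage_counts)
    return EmbryoResult(
        records=records,
        labels=labels,
        labels_iso=labels_iso,
        spectrum=spectrum,
        nuc_count=len(records),
        bw3db=bw3db,
        count_map=cmap,
        grade=grade,
        dmd_map=dmd,
        stage_counts=stage_counts,
    )


def write_embryo_outputs(result: EmbryoResult, out_dir, embryo_id="embryo") -> dict:
    """Write the per-embryo artifacts; returns the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = out / str(embryo_id)

    result.records.to_csv(
        f"{prefix}_features.csv", index=False, float_format=CSV_FLOAT_FORMAT
    )
    result.labels.table.to_csv(
        f"{prefix}_objects.csv", index=False, float_format=CSV_FLOAT_FORMAT
    )
    write_stack(result.labels.labels, f"{prefix}_labels.tif", labels=True)
    tifffile.imwrite(
        f"{prefix}_count_map.tif", result.count_map.astype(np.uint16)
    )
    if result.spectrum is not None:
        pd.DataFrame(dict(k=result.spectrum.k, power=result.spectrum.power)).to_csv(
            f"{prefix}_spectrum.csv", index=False, float_format=CSV_FLOAT_FORMAT
        )
    if result.dmd_map is not None:
        write_stack(result.dmd_map, f"{prefix}_dmd_map.tif")

    summary = dict(
        embryo_id=str(embryo_id),
        nuc_count=result.nuc_count,
        bw3dB=None if np.isnan(result.bw3db) else round(result.bw3db, 6),
        stage_counts=result.stage_counts,
    )
    if result.grade is not None:
        summary["grade"] = dict(
            predicted_class=result.grade.predicted_class,
            cp=round(result.grade.cp, 6),
            majority_fraction=round(result.grade.majority_fraction, 6),
            tie=result.grade.tie,
        )
    Path(f"{prefix}_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_pipeline(
    config: PipelineConfig,
    phase_path,
    nucleus_path,
    model_path=None,
    embryo_id: str = "embryo",
) -> dict:
    """File-based pipeline entry point: read stacks, process, write outputs."""
    phase_vol = read_stack(phase_path)
    channel = read_stack(nucleus_path)
    if phase_vol.shape != channel.shape:
        raise IOError(
            f"phase {phase_vol.shape} and nucleus {channel.shape} stacks disagree"
        )
    phase = PhaseVolume(
        phase_vol,
        dx_um=1.0 / config.lateral_px_per_um,
        dz_um=config.z_step_um,
        wavelength_um=config.wavelength_um,
        gamma_um3_per_pg=config.gamma_um3_per_pg,
    )
    model = None
    if model_path is not None:
        model = FBMModel.from_json(Path(model_path).read_text())
    result = process_embryo(
        phase, channel, config, model=model, compute_dmd_map=True, embryo_id=embryo_id
    )
    return write_embryo_outputs(result, config.output_dir, embryo_id)
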