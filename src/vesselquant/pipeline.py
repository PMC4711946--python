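"""End-to-end orchestration: pre-process, segment, quantify, compare.

One image in, one sample record out; a manifest of images in, a records
table plus a pairwise permutation-test report out.  Every record carries
the config hash and the per-image seed, so reruns are reproducible and
adding samples never perturbs existing results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .config import KmeansConfig, PipelineConfig
from .permstats import compare_groups, derive_seed
from .preprocess import preprocess_image
from .segment import ECM, SMF, segment_image

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("sample_id", "group", "path")


@dataclass(frozen=True)
class SampleRecord:
    """Per-image quantification result with full provenance."""

    sample_id: str
    group: str
    path: str
    a_smf: int
    a_ecm: int
    a_tot: int
    ratio_SMF: float
    ratio_ECM: float
    fold_t: float
    otsu_T: float
    seed: int
    config_hash: str
    version: str = __version__


def _save_mask(mask: np.ndarray, path: Path) -> None:
    Image.fromarray(mask.astype(bool)).convert("1").save(path)


def process_image(
    source,
    config: PipelineConfig | None = None,
    sample_id: str = "sample",
    group: str = "",
    seed: int | None = None,
    save_intermediates: Path | str | None = None,
) -> SampleRecord:
    """Quantify one stained-section image.

    ``source`` is a path to an 8-bit RGB PNG/TIFF or an RGB array.  The
    image is pre-processed (defect removal, contrast stretch, Otsu,
    wall-mask cleanup), then the contrast-enhanced color image is clustered
    with k-means and the SMF/ECM areas are normalized by the wall area.
    """
    config = config or PipelineConfig()
    if isinstance(source, (str, Path)):
        path = str(source)
        rgb = np.asarray(iio.imread(path))[..., :3]
    else:
        path = ""
        rgb = np.asarray(source)
    if seed is None:
        seed = config.kmeans.seed

    pre = preprocess_image(rgb, config)
    # feature extraction runs on the contrast-enhanced color image
    lab_enhanced = np.dstack([pre.L_stretched, pre.lab[..., 1], pre.lab[..., 2]])
    km = dataclasses.replace(config.kmeans, seed=seed)
    model, roles, quant = segment_image(lab_enhanced, pre.wall, km, valid=pre.valid)

    if save_intermediates is not None:
        out = Path(save_intermediates)
        out.mkdir(parents=True, exist_ok=True)
        from skimage.color import lab2rgb

        enhanced_rgb = np.rint(lab2rgb(lab_enhanced) * 255).astype(np.uint8)
        iio.imwrite(out / f"{sample_id}_enhanced.png", enhanced_rgb)
        _save_mask(pre.wall.mask, out / f"{sample_id}_wall.png")
        assignment = model.assignment.reshape(pre.wall.mask.shape)
        _save_mask((assignment == roles[SMF]) & pre.wall.mask,
                   out / f"{sample_id}_smf.png")
        _save_mask((assignment == roles[ECM]) & pre.wall.mask,
                   out / f"{sample_id}_ecm.png")

    return SampleRecord(
        sample_id=sample_id,
        group=group,
        path=path,
        a_smf=quant.a_smf,
        a_ecm=quant.a_ecm,
        a_tot=quant.a_tot,
        ratio_SMF=quant.ratio_smf,
        ratio_ECM=quant.ratio_ecm,
        fold_t=pre.fold_t,
        otsu_T=pre.otsu_T,
        seed=seed,
        config_hash=config.config_hash(),
    )


def run_study(
    manifest: pd.DataFrame | str | Path,
    config: PipelineConfig | None = None,
    out_dir: Path | str | None = None,
    seed: int = 0,
    save_intermediates: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Batch-process a manifest of images and compare the groups.

    The manifest is a CSV (or DataFrame) with columns sample_id, group,
    path.  Per-image seeds derive from (seed, sample_id), so adding samples
    never changes existing records.  Per-image failures are logged and the
    batch continues.  Returns (records, pairwise report); the report is
    None when fewer than two groups are usable.
    """
    config = config or PipelineConfig()
    if isinstance(manifest, (str, Path)):
        manifest = pd.read_csv(manifest)
    for col in MANIFEST_COLUMNS:
        if col not in manifest.columns:
            raise ValueError(f"manifest is missing column {col!r}")
    if len(manifest) == 0:
        raise ValueError("empty manifest")

    records, errors = [], []
    for row in manifest.itertuples(index=False):
        img_seed = derive_seed(seed, row.sample_id)
        inter = (
            Path(out_dir) / "intermediates"
            if (save_intermediates and out_dir is not None)
            else None
        )
        try:
            rec = process_image(
                row.path, config, sample_id=str(row.sample_id),
                group=str(row.group), seed=img_seed, save_intermediates=inter,
            )
            records.append(dataclasses.asdict(rec))
        except Exception as exc:  # record and continue with the batch
            logger.error("sample %s failed: %s", row.sample_id, exc)
            errors.append({"sample_id": row.sample_id, "error": str(exc)})

    records_df = pd.DataFrame(records)
    report = None
    if len(records_df):
        usable = records_df.groupby("group").size()
        if (usable >= 2).sum() >= 2:
            stats_cfg = dataclasses.replace(config.permutation, seed=seed)
            report = compare_groups(records_df, stats_cfg)
        else:
            logger.warning("fewer than two usable groups; statistics skipped")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records_df.to_csv(out / "records.csv", index=False)
        if errors:
            pd.DataFrame(errors).to_csv(out / "errors.csv", index=False)
        if report is not None:
            report.to_csv(out / "pvalues.csv", index=False)
            (out / "report.json").write_text(
                json.dumps(
                    {
                        "seed": seed,
                        "config_hash": config.config_hash(),
                        "version": __version__,
                        "cells": report.to_dict(orient="records"),
                    },
                    indent=2,
                )
            )
    return records_df, report


def pvalue_matrix(report: pd.DataFrame, component: str) -> pd.DataFrame:
    """Pivot one component's pairwise p-values into a lower-triangle matrix."""
    sub = report[report["component"] == component]
    groups = sorted(set(sub["group_1"]) | set(sub["group_2"]))
    mat = pd.DataFrame(index=groups, columns=groups, dtype=float)
    for row in sub.itertuples(index=False):
        mat.loc[row.group_2, row.group_1] = row.p_value
    return mat
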