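"""Batch pipeline: images + annotations + metadata in, tables + tests out.

Ties the stages together: segmentation of droplets and edge, radial
mapping against the edge contour, nine-class profiles and densities,
factor summaries and the statistical battery. Deterministic given inputs
and configuration; per-slice failures are logged and skipped, and a
manifest records the configuration hash and per-slice status.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import geometry, profiles, segmentation, stats
from .errors import MetadataError, OleomapError, UsageError

__all__ = ["PipelineConfig", "validate_metadata", "analyze_slice", "run_pipeline"]

log = logging.getLogger("oleomap")

META_COLUMNS = (
    "slice_id",
    "image_path",
    "center_path",
    "clone",
    "fraction",
    "horizon",
    "scale_um_per_px",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs besides the data itself."""

    segmentation: segmentation.SegmentationParams = field(
        default_factory=segmentation.SegmentationParams
    )
    tissue_threshold: float | None = None  # None: automatic low-histogram Otsu
    clamp_max: float = geometry.CLAMP_MAX_DEFAULT
    n_angles: int = 2048  # angular resolution of the pp map
    wilcoxon_variant: str = "signed_rank"
    welch: bool = False
    alpha: float = 0.05
    seed: int = 0
    write_masks: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seg = segmentation.SegmentationParams(**raw.pop("segmentation", {}))
        return cls(segmentation=seg, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segmentation"]["max_area"] = (
            None if math.isinf(self.segmentation.max_area) else self.segmentation.max_area
        )
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_metadata(metadata: pd.DataFrame | str | Path) -> dict[str, profiles.SliceMeta]:
    """Check the metadata table and build SliceMeta records.

    Required columns: slice_id, image_path, center_path, clone, fraction,
    horizon, scale_um_per_px. Unknown factor levels are errors (all
    offenders listed); a clone paired with a fraction it does not form
    (e.g. a thin clone with RF4) is a warning, since the assignment may be
    deliberate. Classification (thin/thick) is derived from the clone.
    """
    df = (
        pd.read_csv(metadata, dtype={"slice_id": str})
        if not isinstance(metadata, pd.DataFrame)
        else metadata
    )
    if df.empty:
        raise UsageError("metadata table is empty")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata lacks columns: {', '.join(missing)}")
    if df["slice_id"].duplicated().any():
        dupes = df.loc[df["slice_id"].duplicated(), "slice_id"].tolist()
        raise MetadataError(f"duplicate slice ids: {dupes}")

    offenders = []
    metas: dict[str, profiles.SliceMeta] = {}
    for _, row in df.iterrows():
        try:
            meta = profiles.SliceMeta(
                slice_id=str(row["slice_id"]),
                clone=str(row["clone"]),
                fraction=str(row["fraction"]),
                horizon=str(row["horizon"]),
                scale=float(row["scale_um_per_px"]),
            )
        except MetadataError as exc:
            offenders.append(f"{row['slice_id']}: {exc}")
            continue
        metas[meta.slice_id] = meta
    if offenders:
        raise MetadataError("invalid metadata rows:\n" + "\n".join(offenders))
    return metas


@dataclass
class SliceResult:
    slice_id: str
    detections: list[segmentation.DropletDetection]
    records: list[geometry.RadialRecord]
    geometry: geometry.SliceGeometry
    profile: profiles.ClassProfile
    class_pixel_counts: np.ndarray
    droplet_mask: np.ndarray
    edge_mask: np.ndarray


def analyze_slice(
    image: np.ndarray,
    center: tuple[float, float],
    scale: float,
    config: PipelineConfig | None = None,
    slice_id: str = "slice",
    edge_contour: np.ndarray | None = None,
) -> SliceResult:
    """Run the full per-slice chain on an in-memory image.

    ``edge_contour`` can override the segmented edge (e.g. the true
    contour of a synthetic slice) — the droplet segmentation still runs.
    """
    config = config or PipelineConfig()
    gray = segmentation.to_grayscale8(image, channel=config.segmentation.channel)
    if edge_contour is None:
        tissue = segmentation.binarize_tissue(gray, config.tissue_threshold)
        edge_contour = segmentation.extract_edge_contour(tissue)
        geom = geometry.SliceGeometry(center=center, edge=edge_contour, scale=scale)
        edge_mask = tissue.pixels
    else:
        geom = geometry.SliceGeometry(center=center, edge=edge_contour, scale=scale)
        edge_mask = geometry.rasterize(geom, gray.shape)
    # droplet threshold restricted to the tissue region: keeps the black
    # mounting frame from dominating the fuzzy-entropy criterion
    droplet_mask = segmentation.binarize_droplets(
        gray, config.segmentation, roi=edge_mask
    )
    detections = segmentation.extract_particles(droplet_mask, config.segmentation)
    pts = np.array([[d.centroid_x, d.centroid_y] for d in detections]).reshape(-1, 2)
    records = geometry.map_droplets(pts, geom, clamp_max=config.clamp_max)
    _, pix_counts, areas_mm2 = geometry.relative_distance_map(
        geom, gray.shape, n_angles=config.n_angles
    )
    profile = profiles.build_profile(records, areas_mm2, slice_id)
    return SliceResult(
        slice_id=slice_id,
        detections=detections,
        records=records,
        geometry=geom,
        profile=profile,
        class_pixel_counts=pix_counts,
        droplet_mask=droplet_mask.pixels,
        edge_mask=edge_mask,
    )


def _factor_statistics(
    profs: list[profiles.ClassProfile],
    metas: dict[str, profiles.SliceMeta],
    config: PipelineConfig,
) -> dict:
    """The full battery per factor: rank tests on the class distributions,
    ANOVA (or t test) on per-slice densities, SNK letters."""
    out: dict = {}
    for factor in profiles.FACTORS:
        entry: dict = {}
        for value in ("count", "density"):
            mat = profiles.class_distribution_matrix(profs, metas, factor, value=value)
            levels = tuple(mat.index)
            if len(levels) >= 3:
                res = stats.friedman_test(mat.to_numpy(), groups=levels)
            elif len(levels) == 2:
                res = stats.wilcoxon_paired(
                    mat.iloc[0].to_numpy(),
                    mat.iloc[1].to_numpy(),
                    variant=config.wilcoxon_variant,
                    groups=levels,
                )
            else:
                continue
            entry[f"distribution_{value}"] = {
                "test": res.name,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "levels": list(levels),
            }
        samples = {}
        for p in profs:
            samples.setdefault(metas[p.slice_id].level(factor), []).append(p.total_density)
        samples = {k: np.asarray(v) for k, v in samples.items()}
        usable = {k: v for k, v in samples.items() if v.size >= 2}
        if len(usable) >= 2:
            if len(usable) == 2:
                (na, a), (nb, b) = usable.items()
                res = stats.t_test_density(a, b, welch=config.welch, groups=(na, nb))
            else:
                res = stats.anova_density(usable)
            entry["density_anova"] = {
                "test": res.name,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "levels": list(res.groups),
            }
            try:
                mse, df_err = stats.anova_mse(usable)
                snk = stats.snk_letters(
                    means={k: float(v.mean()) for k, v in usable.items()},
                    ns={k: int(v.size) for k, v in usable.items()},
                    mse=mse,
                    df=df_err,
                    alpha=config.alpha,
                )
                entry["density_snk"] = {"letters": snk.letters}
            except UsageError:
                pass
        if entry:
            out[factor] = entry
    return out


def run_pipeline(
    metadata_csv: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Process every slice of a metadata table and write all outputs.

    Returns the manifest (also written as ``manifest.json``): config
    hash, per-slice status, and counts of processed/failed slices.
    Failures of single slices do not abort the batch.
    """
    config = config or PipelineConfig()
    metadata_csv = Path(metadata_csv)
    base = metadata_csv.parent
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(metadata_csv, dtype={"slice_id": str})
    metas = validate_metadata(df)

    droplet_rows, radial_rows, area_rows, profile_rows = [], [], [], []
    results: list[SliceResult] = []
    status: dict[str, str] = {}
    center_cache: dict[str, pd.DataFrame] = {}
    for _, row in df.iterrows():
        sid = str(row["slice_id"])
        try:
            image = iio.imread(base / str(row["image_path"]))
            cpath = str(row["center_path"])
            if cpath not in center_cache:
                center_cache[cpath] = pd.read_csv(base / cpath, dtype={"slice_id": str})
            center = segmentation.read_center_annotation(
                center_cache[cpath], sid, image.shape[:2]
            )
            res = analyze_slice(
                image, center, metas[sid].scale, config, slice_id=sid
            )
        except (OleomapError, OSError, ValueError) as exc:
            log.error("slice %s failed: %s", sid, exc)
            status[sid] = f"failed: {exc}"
            continue
        status[sid] = "ok"
        results.append(res)
        for j, (d, r) in enumerate(zip(res.detections, res.records)):
            droplet_rows.append(
                dict(slice_id=sid, droplet_id=j, x=d.centroid_x, y=d.centroid_y,
                     area_px2=d.area, circularity=d.circularity)
            )
            radial_rows.append(
                dict(slice_id=sid, droplet_id=j, x_mod=r.x_mod, y_mod=r.y_mod,
                     r_cd_px=r.r_cd, phi_rad=r.phi, r_ce_px=r.r_ce,
                     pp_percent=r.pp, class_index=r.class_index)
            )
        for k in range(9):
            area_rows.append(
                dict(slice_id=sid, class_index=k + 1,
                     area_mm2=res.profile.areas[k],
                     pixel_count=int(res.class_pixel_counts[k]))
            )
            profile_rows.append(
                dict(slice_id=sid, class_index=k + 1,
                     count=int(res.profile.counts[k]),
                     area_mm2=res.profile.areas[k],
                     density_per_mm2=res.profile.densities[k])
            )
        if config.write_masks:
            masks = out / "masks"
            masks.mkdir(exist_ok=True)
            iio.imwrite(masks / f"{sid}_droplets.png",
                        res.droplet_mask.astype(np.uint8) * 255)
            iio.imwrite(masks / f"{sid}_edge.png",
                        res.edge_mask.astype(np.uint8) * 255)

    cols = dict(
        droplets=["slice_id", "droplet_id", "x", "y", "area_px2", "circularity"],
        radial=["slice_id", "droplet_id", "x_mod", "y_mod", "r_cd_px", "phi_rad",
                "r_ce_px", "pp_percent", "class_index"],
        class_areas=["slice_id", "class_index", "area_mm2", "pixel_count"],
        profiles=["slice_id", "class_index", "count", "area_mm2", "density_per_mm2"],
    )
    for name, rows in (("droplets", droplet_rows), ("radial", radial_rows),
                       ("class_areas", area_rows), ("profiles", profile_rows)):
        pd.DataFrame(rows, columns=cols[name]).to_csv(out / f"{name}.csv", index=False)

    profs = [r.profile for r in results]
    if profs:
        totals = pd.DataFrame(
            dict(slice_id=p.slice_id, total_count=p.total_count,
                 total_area_mm2=p.total_area, total_density_per_mm2=p.total_density)
            for p in profs
        )
        totals.to_csv(out / "totals.csv", index=False)
        summary_rows = []
        for factor in profiles.FACTORS:
            for s in profiles.summarize_factor(profs, metas, factor):
                summary_rows.append(
                    dict(factor=s.factor, level=s.level, n_slices=s.n_slices,
                         sum_droplets=s.sum_droplets, mean=s.display_mean,
                         mean_exact=s.mean_per_slice, sd=s.sd_per_slice,
                         mean_density=s.mean_density, sd_density=s.sd_density)
                )
        pd.DataFrame(summary_rows).to_csv(out / "summaries.csv", index=False)
        test_json = _factor_statistics(profs, metas, config)
        (out / "stats.json").write_text(json.dumps(test_json, indent=2))

    n_failed = sum(1 for v in status.values() if v != "ok")
    manifest = {
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "n_slices": len(status),
        "n_ok": len(status) - n_failed,
        "n_failed": n_failed,
        "slices": status,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
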