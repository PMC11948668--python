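"""End-to-end analysis: slab -> threshold -> DBSCAN -> morphometrics -> alignment -> tests.

This module is the library form of the ``psdblocks analyze`` command.  All
outputs are plain CSV/JSON carrying the run-manifest hash, and the whole
run is a pure function of (inputs, config), so re-running an identical
configuration yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .align import (
    build_randomization_null,
    classify_blocks,
    fraction_within_range,
    pair_points,
    project_to_plane,
    psd_domain,
    records_to_frame,
)
from .blocks import DbscanParams, NOISE, block_distances, block_height, build_nanoblocks, dbscan
from .config import AnalyzeConfig
from .errors import PsdBlocksError
from .slab import estimate_background, extract_slab_projection, threshold_projection
from .stats import kruskal_wallis, ks_2samp, mann_whitney
from .volio import fit_membrane_plane, read_annotations, read_volume

__all__ = ["AnalysisResult", "run_analysis", "write_outputs", "manifest_hash"]


@dataclass
class AnalysisResult:
    """Everything one analysis run produced, in memory."""

    config: AnalyzeConfig
    background: float
    n_candidate_pixels: int
    n_selected_pixels: int
    n_noise_pixels: int
    blocks: list
    block_table: pd.DataFrame
    distance_table: pd.DataFrame
    alignment: pd.DataFrame
    null_ratios: np.ndarray | None
    tests: dict
    counts: dict = field(default_factory=dict)


def manifest_hash(manifest: dict) -> str:
    return hashlib.sha256(json.dumps(manifest, sort_keys=True).encode()).hexdigest()[:16]


def run_analysis(cfg: AnalyzeConfig) -> AnalysisResult:
    """Execute the full pipeline for one tomogram."""
    cfg.validate()
    volume = read_volume(cfg.volume)
    aset = read_annotations(cfg.annotations, volume=volume)
    if aset.psd_side_hint is None:
        raise PsdBlocksError("annotation sidecar must provide psd_side_hint for membrane orientation")
    membrane = fit_membrane_plane(aset.membrane_points, aset.psd_side_hint)
    projection = extract_slab_projection(volume, membrane, depth=cfg.slab_depth)

    if cfg.threshold.mode == "global_fraction":
        background = float("nan")
        bg_for_height = float(np.nanmedian(projection.values))
    else:
        if aset.empty_region is None:
            raise PsdBlocksError("below-background thresholding needs an empty_region in the sidecar")
        background = estimate_background(volume, aset.empty_region)
        bg_for_height = background
    cloud = threshold_projection(projection, background, cfg.threshold.fraction, cfg.threshold.mode)

    eps_px = cfg.dbscan.eps if cfg.dbscan.eps_units == "px" else cfg.dbscan.eps / volume.voxel_size
    labels = dbscan(cloud.pixels, DbscanParams(eps=eps_px, min_pts=cfg.dbscan.min_pts))
    blocks = build_nanoblocks(cloud, labels)
    for b in blocks:
        b.height = block_height(volume, b, membrane, bg_for_height, max_depth=cfg.slab_depth)
    dist_table = block_distances(blocks)

    # --- alignment ---------------------------------------------------------
    particles = aset.of_kind("particle_A", "particle_B", "particle_undefined")
    vesicles = [
        p
        for p in aset.of_kind("vesicle")
        if p.vesicle_state in ("docked", "tethered", "partially_fused")
    ]
    tests: dict = {}
    records = []
    null_ratios = None
    if blocks:
        if particles:
            pos2d = project_to_plane(np.array([p.position for p in particles]), membrane)
            classify_blocks(blocks, pos2d, [p.kind for p in particles])
            records.extend(
                pair_points(
                    pos2d,
                    blocks,
                    mode=cfg.pairing_mode,
                    point_ids=[p.id for p in particles],
                    point_kinds=[p.kind for p in particles],
                )
            )
        if vesicles:
            vpos2d = project_to_plane(np.array([v.position for v in vesicles]), membrane)
            ves_records = pair_points(
                vpos2d,
                blocks,
                mode=cfg.pairing_mode,
                point_ids=[v.id for v in vesicles],
                point_kinds=["vesicle"] * len(vesicles),
            )
            records.extend(ves_records)
            eligible = [b for b in blocks if b.D > 0]
            if eligible and ves_records:
                domain = psd_domain(eligible, mode=cfg.randomization.domain)
                null = build_randomization_null(
                    vpos2d,
                    domain,
                    blocks,
                    reps=cfg.randomization.reps,
                    seed=cfg.randomization.seed,
                    mode=cfg.pairing_mode,
                    pixel_size=volume.voxel_size,
                )
                null_ratios = null.ratios
                exp = np.array([r.ratio for r in ves_records])
                tests["vesicle_vs_null_ks"] = ks_2samp(exp, null.pooled(), method="auto").to_dict()
    frame = records_to_frame(records)
    tests.update(_particle_tests(frame))
    tests.update(_block_type_tests(frame, blocks))

    block_table = pd.DataFrame(
        [
            {
                "id": b.id,
                "n_pixels": b.n_pixels,
                "centroid_u_nm": b.centroid[0],
                "centroid_w_nm": b.centroid[1],
                "area_nm2": b.area,
                "width_nm": b.width,
                "D_nm": b.D,
                "height_nm": np.nan if b.height is None else b.height,
                "type_label": b.type_label,
            }
            for b in blocks
        ],
        columns=[
            "id",
            "n_pixels",
            "centroid_u_nm",
            "centroid_w_nm",
            "area_nm2",
            "width_nm",
            "D_nm",
            "height_nm",
            "type_label",
        ],
    )
    counts = {
        "n_candidate_pixels": int(np.sum(~projection.mask)),
        "n_selected_pixels": len(cloud),
        "n_noise_pixels": int(np.sum(labels == NOISE)) if len(cloud) else 0,
        "n_blocks": len(blocks),
        "n_degenerate_blocks": int(sum(1 for b in blocks if b.D <= 0)),
        "n_particles": len(particles),
        "n_vesicles_eligible": len(vesicles),
        "membrane_residual_rms_nm": membrane.residual_rms,
        "background": background,
    }
    return AnalysisResult(
        config=cfg,
        background=background,
        n_candidate_pixels=counts["n_candidate_pixels"],
        n_selected_pixels=counts["n_selected_pixels"],
        n_noise_pixels=counts["n_noise_pixels"],
        blocks=blocks,
        block_table=block_table,
        distance_table=dist_table,
        alignment=frame,
        null_ratios=null_ratios,
        tests=tests,
        counts=counts,
    )


def _particle_tests(frame: pd.DataFrame) -> dict:
    """KS / Mann-Whitney comparisons between particle-type ratio samples."""
    out: dict = {}
    if frame.empty:
        return out
    ratios = {
        k: frame.loc[frame["kind"] == k, "ratio"].to_numpy()
        for k in ("particle_A", "particle_B", "particle_undefined")
    }
    a, b, und = ratios["particle_A"], ratios["particle_B"], ratios["particle_undefined"]
    if len(a) and len(b):
        out["typeA_vs_typeB_ks"] = ks_2samp(a, b).to_dict()
        out["typeA_vs_typeB_mw"] = mann_whitney(a, b).to_dict()
        ab = np.concatenate([a, b])
        prop, n_in, n_tot = fraction_within_range(ab)
        out["typeAB_fraction_within_range"] = {"proportion": prop, "n_within": n_in, "n": n_tot}
        if len(und):
            out["typeAB_vs_undefined_ks"] = ks_2samp(ab, und).to_dict()
            out["typeAB_vs_undefined_mw"] = mann_whitney(ab, und).to_dict()
    if len(und):
        prop, n_in, n_tot = fraction_within_range(und)
        out["undefined_fraction_within_range"] = {"proportion": prop, "n_within": n_in, "n": n_tot}
    return out


def _block_type_tests(frame: pd.DataFrame, blocks) -> dict:
    """Kruskal-Wallis comparisons across nanoblock types (vesicle d2/D, areas)."""
    out: dict = {}
    if not blocks:
        return out
    type_of = {b.id: b.type_label for b in blocks}
    # vesicle all-pairs d2/D grouped by block type
    ves = frame[frame["kind"] == "vesicle"]
    if not ves.empty:
        grouped: dict[str, list] = {}
        for _, row in ves.iterrows():
            grouped.setdefault(type_of.get(row["block_id"], "unassigned"), []).append(row["ratio"])
        groups = [np.array(v) for k, v in sorted(grouped.items()) if len(v) >= 2]
        names = [k for k, v in sorted(grouped.items()) if len(v) >= 2]
        if len(groups) >= 2:
            res = kruskal_wallis(groups, pairwise=True)
            d = res.to_dict()
            d["group_names"] = names
            d["pairwise"] = res.extras["pairwise"].to_dict(orient="records")
            out["vesicle_ratio_by_block_type_kw"] = d
    # areas by block type
    by_type: dict[str, list] = {}
    for b in blocks:
        by_type.setdefault(b.type_label, []).append(b.area)
    groups = [np.array(v) for k, v in sorted(by_type.items()) if len(v) >= 2]
    names = [k for k, v in sorted(by_type.items()) if len(v) >= 2]
    if len(groups) >= 2:
        res = kruskal_wallis(groups, pairwise=True)
        d = res.to_dict()
        d["group_names"] = names
        d["pairwise"] = res.extras["pairwise"].to_dict(orient="records")
        out["area_by_block_type_kw"] = d
    return out


def write_outputs(result: AnalysisResult, out_dir) -> dict:
    """Write all analysis products; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    manifest = {
        "tool": "psdblocks",
        "version": __version__,
        "config": {
            "volume": cfg.volume,
            "annotations": cfg.annotations,
            "slab_depth": cfg.slab_depth,
            "threshold": {"fraction": cfg.threshold.fraction, "mode": cfg.threshold.mode},
            "dbscan": {
                "eps": cfg.dbscan.eps,
                "eps_units": cfg.dbscan.eps_units,
                "min_pts": cfg.dbscan.min_pts,
            },
            "pairing_mode": cfg.pairing_mode,
            "randomization": {
                "reps": cfg.randomization.reps,
                "seed": cfg.randomization.seed,
                "domain": cfg.randomization.domain,
            },
        },
        "counts": _jsonable(result.counts),
    }
    mhash = manifest_hash(manifest)
    manifest["manifest_sha256"] = mhash
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    def _csv(df: pd.DataFrame, name: str):
        with open(out / name, "w") as fh:
            fh.write(f"# manifest_sha256: {mhash}\n")
            df.to_csv(fh, index=False)

    _csv(result.block_table, "nanoblocks.csv")
    _csv(result.distance_table, "distances.csv")
    _csv(result.alignment, "alignment.csv")
    if result.null_ratios is not None:
        reps, npts = result.null_ratios.shape
        null_df = pd.DataFrame(
            {
                "replicate": np.repeat(np.arange(reps), npts),
                "ratio": result.null_ratios.reshape(-1),
            }
        )
        _csv(null_df, "null_ratios.csv")
    (out / "tests.json").write_text(
        json.dumps({"manifest_sha256": mhash, "tests": _jsonable(result.tests)}, indent=1, sort_keys=True)
    )
    (out / "report.txt").write_text(_report_text(result, mhash))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _report_text(result: AnalysisResult, mhash: str) -> str:
    lines = [
        "psdblocks analysis report",
        f"manifest: {mhash}",
        "",
        "stage counts:",
    ]
    for k, v in result.counts.items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append(f"nanoblocks detected: {len(result.blocks)}")
    if not result.block_table.empty:
        med = result.block_table[["area_nm2", "width_nm", "D_nm"]].median()
        lines.append(f"  median area  : {med['area_nm2']:.1f} nm^2")
        lines.append(f"  median width : {med['width_nm']:.1f} nm")
        lines.append(f"  median D     : {med['D_nm']:.1f} nm")
    if not result.distance_table.empty:
        lines.append(
            f"  median centroid-centroid NN: {result.distance_table['nn_centroid_nm'].median():.1f} nm"
        )
        lines.append(f"  median edge-edge NN        : {result.distance_table['nn_edge_nm'].median():.1f} nm")
    lines.append("")
    lines.append("statistical tests:")
    for name, t in sorted(result.tests.items()):
        if "p_value" in t:
            lines.append(f"  {name}: statistic={t['statistic']:.4g} p={t['p_value']:.3g} ({t['method']})")
        else:
            lines.append(f"  {name}: {json.dumps(_jsonable(t), sort_keys=True)}")
    lines.append("")
    return "\n".join(lines)
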