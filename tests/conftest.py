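"""Shared fixtures: one default synthetic tomogram, analyzed once per session."""

from dataclasses import dataclass

import numpy as np
import pytest

from psdblocks.blocks import DbscanParams, Nanoblock, build_nanoblocks, dbscan
from psdblocks.slab import (
    PixelCloud,
    estimate_background,
    extract_slab_projection,
    threshold_projection,
)
from psdblocks.synthgen import GroundTruth, SynthParams, simulate
from psdblocks.volio import MembranePlane, fit_membrane_plane


@dataclass
class SimCase:
    params: SynthParams
    truth: GroundTruth
    volume: object
    annotations: object
    membrane: MembranePlane
    projection: object
    background: float
    cloud: PixelCloud
    labels: np.ndarray
    blocks: list

    def planted_uw(self, block) -> np.ndarray:
        """Planted block centroid mapped into the analysis (u, w) frame."""
        c3 = np.array([block.centroid[0], self.params.membrane_y, block.centroid[1]])
        return self.membrane.to_plane_coords(c3)[0]


def run_case(params: SynthParams, fraction: float = 0.25) -> SimCase:
    truth, vol, aset = simulate(params)
    membrane = fit_membrane_plane(aset.membrane_points, aset.psd_side_hint)
    projection = extract_slab_projection(vol, membrane, depth=params.slab_depth)
    background = estimate_background(vol, aset.empty_region)
    cloud = threshold_projection(projection, background, fraction)
    labels = dbscan(cloud.pixels, DbscanParams(eps=6, min_pts=32))
    blocks = build_nanoblocks(cloud, labels)
    return SimCase(
        params=params,
        truth=truth,
        volume=vol,
        annotations=aset,
        membrane=membrane,
        projection=projection,
        background=background,
        cloud=cloud,
        labels=labels,
        blocks=blocks,
    )


@pytest.fixture(scope="session")
def default_case() -> SimCase:
    """Default noisy phantom analyzed with the study operating point."""
    return run_case(SynthParams(seed=11))


@pytest.fixture(scope="session")
def noisefree_case() -> SimCase:
    """Noise-free phantom; full below-background selection keeps exact footprints."""
    return run_case(SynthParams(seed=11, noise_sigma=0.0), fraction=1.0)


def blocks_from_truth(truth: GroundTruth) -> list[Nanoblock]:
    """Nanoblocks built directly from planted footprints (absolute frame)."""
    pix = np.vstack([b.pixels for b in truth.blocks])
    labels = np.concatenate([[b.id] * len(b.pixels) for b in truth.blocks])
    cloud = PixelCloud(
        pixels=pix,
        values=np.zeros(len(pix)),
        background=0.0,
        fraction=1.0,
        mode="below_background_fraction",
    )
    return build_nanoblocks(cloud, labels, voxel_size=truth.params.voxel_size)
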