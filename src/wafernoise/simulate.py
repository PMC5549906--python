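"""Virtual-wafer scan simulator.

Generates synthetic scans of the 75 mm square alumina reference wafer so
the whole pipeline can be exercised with a known ground truth. A scan is
a regular triangulated grid displaced along the surface normal by

* a deterministic low-frequency waviness bounded by the wafer's optical
  flatness spec (lambda/2 of 550 nm light, i.e. a 275 nm amplitude) --
  present so tests can confirm that nanometre-scale reference error is
  negligible against micrometre-scale scanner noise;
* zero-mean Gaussian noise of standard deviation sigma (um), multiplied
  inside a border band to emulate the edge effect real scanners show;
* sparse symmetric outliers (Bernoulli per vertex);

and finally rotated rigidly by the acquisition tilt (0/30/45 deg about an
in-plane axis, sign flipping between directions 1 and 2). Noise is drawn
in the wafer frame before tilting; by the rotation invariance of the
orthogonal-distance roughness statistic this is equivalent to drawing it
along the optical axis after tilting.

Everything is deterministic given the seed; the protocol generator derives
one child seed per (condition, replicate) from the master seed with
``numpy.random.SeedSequence(entropy=(seed, condition_index, replicate))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ParameterError
from .mesh import TriangleMesh
from .stats import AcquisitionCondition

#: The five acquisition conditions of the standard protocol.
DEFAULT_CONDITIONS = (
    AcquisitionCondition(0),
    AcquisitionCondition(30, 1),
    AcquisitionCondition(30, 2),
    AcquisitionCondition(45, 1),
    AcquisitionCondition(45, 2),
)


@dataclass(frozen=True)
class WaferScanConfig:
    """Parameters of one simulated wafer scan.

    Defaults emulate the reference protocol: a 75 mm square wafer, a
    101 x 101 vertex grid (~0.75 mm spacing; real scans are denser, but
    the noise statistics scale with vertex count only through sampling
    error), 8 um Gaussian noise -- the middle of the 5-12.5 um range
    commercial intra-oral scanners exhibit on this target -- tripled in a
    10% border band to reproduce the edge effect, and a sprinkle of
    40 um outliers.
    """

    side_mm: float = 75.0
    resolution: int = 101
    tilt_deg: float = 0.0
    direction: int = 1
    sigma_um: float = 8.0
    edge_band_fraction: float = 0.1
    edge_multiplier: float = 3.0
    outlier_rate: float = 0.002
    outlier_magnitude_um: float = 40.0
    waviness_amplitude_nm: float = 275.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side_mm <= 0:
            raise ParameterError("side_mm must be positive")
        if self.resolution < 2:
            raise ParameterError("resolution must be >= 2")
        if self.sigma_um < 0:
            raise ParameterError("sigma_um must be non-negative")
        if self.edge_multiplier < 1:
            raise ParameterError("edge_multiplier must be >= 1")
        if not 0 <= self.edge_band_fraction < 0.5:
            raise ParameterError("edge_band_fraction must be in [0, 0.5)")
        if not 0 <= self.outlier_rate < 1:
            raise ParameterError("outlier_rate must be in [0, 1)")
        if self.outlier_magnitude_um < 0:
            raise ParameterError("outlier_magnitude_um must be non-negative")
        if self.waviness_amplitude_nm < 0:
            raise ParameterError("waviness_amplitude_nm must be non-negative")
        if self.direction not in (1, 2):
            raise ParameterError("direction must be 1 or 2")
        if self.tilt_deg < 0 or self.tilt_deg >= 90:
            raise ParameterError("tilt_deg must be in [0, 90)")


def _grid_faces(res: int) -> np.ndarray:
    """Two triangles per grid cell of a res x res vertex lattice."""
    idx = np.arange(res * res).reshape(res, res)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    return np.concatenate(
        [np.stack([a, b, c], axis=1), np.stack([b, d, c], axis=1)]
    )


def simulate_wafer_scan(config: WaferScanConfig) -> TriangleMesh:
    """Generate one synthetic wafer scan as a TriangleMesh (mm units)."""
    L, res = config.side_mm, config.resolution
    coords = np.linspace(-L / 2, L / 2, res)
    gx, gy = np.meshgrid(coords, coords, indexing="ij")
    x, y = gx.ravel(), gy.ravel()
    n = x.size

    # deterministic sub-resolution waviness (amplitude in nm -> mm)
    amp_mm = config.waviness_amplitude_nm * 1e-6
    z = amp_mm * np.sin(2 * np.pi * x / L) * np.sin(2 * np.pi * y / L)

    rng = np.random.default_rng(config.seed)
    if config.sigma_um > 0:
        sigma_mm = np.full(n, config.sigma_um * 1e-3)
        band = config.edge_band_fraction * L
        on_edge = (L / 2 - np.abs(x) < band) | (L / 2 - np.abs(y) < band)
        sigma_mm[on_edge] *= config.edge_multiplier
        z = z + rng.standard_normal(n) * sigma_mm
    if config.outlier_rate > 0:
        hit = rng.random(n) < config.outlier_rate
        signs = rng.integers(0, 2, size=n) * 2 - 1
        z = z + hit * signs * config.outlier_magnitude_um * 1e-3

    vertices = np.stack([x, y, z], axis=1)
    if config.tilt_deg != 0:
        theta = math.radians(config.tilt_deg)
        if config.direction == 2:
            theta = -theta
        ct, st = math.cos(theta), math.sin(theta)
        rot = np.array([[ct, 0.0, st], [0.0, 1.0, 0.0], [-st, 0.0, ct]])
        vertices = vertices @ rot.T

    name = f"wafer_a{config.tilt_deg:g}_d{config.direction}_s{config.seed}"
    return TriangleMesh(vertices, _grid_faces(res), name=name)


def child_seed(master_seed: int, condition_index: int, replicate: int) -> int:
    """Stable per-scan seed derived from the master seed.

    Uses numpy's SeedSequence with entropy (master, condition, replicate)
    and folds the result below 2**31 so it fits any RNG seed field.
    """
    ss = np.random.SeedSequence((int(master_seed), int(condition_index),
                                 int(replicate)))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_protocol(base_config: WaferScanConfig | None = None,
                      replicates: int = 10,
                      conditions=DEFAULT_CONDITIONS,
                      seed: int = 0):
    """Simulate the full acquisition protocol.

    Returns a mapping AcquisitionCondition -> list of TriangleMesh with
    ``replicates`` independent scans per condition (5 conditions x 10
    replicates = 50 scans by default). Each scan gets its own child seed;
    the same master seed reproduces every mesh exactly.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    base_config = base_config or WaferScanConfig()
    out = {}
    for ci, cond in enumerate(conditions):
        meshes = []
        for r in range(replicates):
            cfg = replace(
                base_config,
                tilt_deg=float(cond.angulation),
                direction=cond.direction if cond.direction is not None else 1,
                seed=child_seed(seed, ci, r),
            )
            meshes.append(simulate_wafer_scan(cfg))
        out[cond] = meshes
    return out
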