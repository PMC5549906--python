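"""Pipeline configuration shared by the library and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ParameterError
from .roughness import DEFAULT_BIN_EDGES_UM, DEFAULT_KERNEL_RADIUS_MM


@dataclass
class PipelineConfig:
    """Parameters of the noise-evaluation pipeline.

    Attributes
    ----------
    kernel_radius_mm : ball-kernel radius for the local plane fits; the
        default 20 mm makes the cropped wafer mesh a single neighborhood.
    crop_margin : fraction of the in-plane bounding box removed per side
        before any roughness computation (wafer-edge elimination).
    roi_fraction : per-axis fraction of the cropped mesh kept as the
        central region of interest.
    bin_edges_um : distance-bin edges in micrometres.
    alpha : significance level for tests and confidence intervals.
    ci_method : 't' (Student CI) or 'normal'.
    holm : apply Holm correction to the pairwise condition comparisons.
    lut_range_um : symmetric color-scale half-range for distance maps.
    """

    kernel_radius_mm: float = DEFAULT_KERNEL_RADIUS_MM
    crop_margin: float = 0.05
    roi_fraction: float = 0.5
    bin_edges_um: tuple = DEFAULT_BIN_EDGES_UM
    alpha: float = 0.05
    ci_method: str = "t"
    holm: bool = False
    lut_range_um: float = 20.0

    def __post_init__(self) -> None:
        if self.kernel_radius_mm <= 0:
            raise ParameterError("kernel_radius_mm must be positive")
        if not 0 <= self.crop_margin < 0.5:
            raise ParameterError("crop_margin must be in [0, 0.5)")
        if not 0 < self.roi_fraction <= 1:
            raise ParameterError("roi_fraction must be in (0, 1]")
        edges = tuple(float(e) for e in self.bin_edges_um)
        if any(e <= 0 for e in edges) or list(edges) != sorted(set(edges)):
            raise ParameterError("bin edges must be positive, strictly increasing")
        self.bin_edges_um = edges
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if self.ci_method not in ("t", "normal"):
            raise ParameterError("ci_method must be 't' or 'normal'")
        if self.lut_range_um <= 0:
            raise ParameterError("lut_range_um must be positive")
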