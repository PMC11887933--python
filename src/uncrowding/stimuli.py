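"""Declarative geometry and rasterization of vernier/flanker/Pacman displays.

Eight named conditions are supported, all built from the same printed
geometry: a peripheral vernier (two abutting vertical segments, the lower
one displaced horizontally), optionally surrounded by three flanker lines
per side, optionally with four "Pacman" disk inducers.

Coordinate convention: degrees of visual angle measured from the stimulus
center, x increasing rightward and y increasing downward (matching pixel
row order).  Fixation is not rendered; eccentricity is carried as metadata
only.  Pixel rounding is round-half-away-from-zero and is applied once per
geometric edge so that abutting intervals tile without gaps or overlaps.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "CONDITIONS",
    "DisplayConfig",
    "VernierSpec",
    "FlankerSpec",
    "PacmanSpec",
    "StimulusSpec",
    "LuminanceImage",
    "OutOfFieldError",
    "deg_to_px",
    "make_condition_spec",
    "render",
    "count_components",
    "spec_to_yaml",
    "spec_from_yaml",
]

#: Canonical condition names, in battery order.
CONDITIONS = (
    "VERNIER_ONLY",
    "EQUAL_FLANKERS",
    "LONG",
    "GAPPED",
    "GAPPED_INWARD",
    "GAPPED_OUTWARD",
    "LONG_INWARD",
    "LONG_OUTWARD",
)

ARCSEC_PER_DEG = 3600.0


class OutOfFieldError(ValueError):
    """A coordinate or element lies outside the simulated field."""


class ConfigurationError(ValueError):
    """An invalid condition name or inconsistent specification."""


@dataclass(frozen=True)
class DisplayConfig:
    """Display geometry and luminance conventions for rasterization."""

    viewing_distance_cm: float = 55.0
    pixels_per_degree: float = 10.0
    background_luminance: float = 0.75
    element_luminance: float = 0.25
    field_width_deg: float = 16.0
    field_height_deg: float = 14.0

    def __post_init__(self) -> None:
        if self.pixels_per_degree <= 0:
            raise ConfigurationError("pixels_per_degree must be positive")
        if not (0.0 <= self.element_luminance < self.background_luminance <= 1.0):
            raise ConfigurationError(
                "luminances must satisfy 0 <= element < background <= 1"
            )
        if self.field_width_deg <= 0 or self.field_height_deg <= 0:
            raise ConfigurationError("field extent must be positive")

    @property
    def n_cols(self) -> int:
        # Odd pixel count so a true center column exists (exact mirror symmetry).
        return 2 * int(round(self.field_width_deg * self.pixels_per_degree / 2)) + 1

    @property
    def n_rows(self) -> int:
        return 2 * int(round(self.field_height_deg * self.pixels_per_degree / 2)) + 1

    @property
    def center_col(self) -> int:
        return self.n_cols // 2

    @property
    def center_row(self) -> int:
        return self.n_rows // 2


@dataclass(frozen=True)
class VernierSpec:
    """Two abutting vertical segments; the lower one displaced horizontally."""

    eccentricity_deg: float = 10.5
    length_deg: float = 1.8
    width_arcsec: float = 210.0
    offset_deg: float = 0.2
    offset_direction: str = "right"

    def __post_init__(self) -> None:
        if self.offset_direction not in ("left", "right"):
            raise ConfigurationError(
                f"offset_direction must be 'left' or 'right', got {self.offset_direction!r}"
            )

    @property
    def width_deg(self) -> float:
        return self.width_arcsec / ARCSEC_PER_DEG

    @property
    def signed_offset_deg(self) -> float:
        return self.offset_deg if self.offset_direction == "right" else -self.offset_deg


@dataclass(frozen=True)
class FlankerSpec:
    """Vertical flanker lines, three per side, symmetric about the vernier."""

    n_per_side: int = 3
    spacing_deg: float = 0.4
    height_deg: float = 8.5
    gapped: bool = False
    gap_height_deg: float = 1.25
    middle_segment_height_deg: float = 1.8

    def column_offsets_deg(self) -> np.ndarray:
        """Signed x positions of all flanker columns (left negative)."""
        k = np.arange(1, self.n_per_side + 1) * self.spacing_deg
        return np.concatenate([-k[::-1], k])

    def segment_spans_deg(self) -> list[tuple[float, float]]:
        """Vertical (y_top, y_bottom) spans of each drawn segment of one line."""
        half = self.height_deg / 2.0
        if not self.gapped:
            return [(-half, half)]
        mid = self.middle_segment_height_deg / 2.0
        gap = self.gap_height_deg
        if half <= mid + gap:
            raise ConfigurationError("gapped line too short for two gaps")
        return [(-half, -(mid + gap)), (-mid, mid), (mid + gap, half)]


@dataclass(frozen=True)
class PacmanSpec:
    """Four filled disks with a horizontal rectangular mouth cutout."""

    present: bool = True
    radius_deg: float = 1.125
    horizontal_distance_deg: float = 3.33
    mouth_direction: str = "inward"
    mouth_height_deg: float = 1.25

    def __post_init__(self) -> None:
        if self.mouth_direction not in ("inward", "outward"):
            raise ConfigurationError(
                f"mouth_direction must be 'inward' or 'outward', got {self.mouth_direction!r}"
            )

    def centers_deg(self, gap_row_center_deg: float) -> list[tuple[float, float]]:
        """Centers of the four disks: left/right x upper-gap/lower-gap rows."""
        xs = (-self.horizontal_distance_deg, self.horizontal_distance_deg)
        ys = (-gap_row_center_deg, gap_row_center_deg)
        return [(x, y) for x in xs for y in ys]


@dataclass(frozen=True)
class StimulusSpec:
    condition: str
    vernier: VernierSpec
    flankers: Optional[FlankerSpec] = None
    pacmen: Optional[PacmanSpec] = None


@dataclass(frozen=True)
class LuminanceImage:
    """Rasterized stimulus: luminance fraction per pixel plus deg<->px metadata."""

    grid: np.ndarray
    origin_deg: tuple[float, float]
    pixels_per_degree: float
    background_luminance: float = 0.75

    def x_deg(self) -> np.ndarray:
        """Degree x coordinate of each pixel-center column."""
        return self.origin_deg[0] + np.arange(self.grid.shape[1]) / self.pixels_per_degree

    def y_deg(self) -> np.ndarray:
        return self.origin_deg[1] + np.arange(self.grid.shape[0]) / self.pixels_per_degree

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.round(self.grid * 255.0), 0, 255).astype(np.uint8)


def _round_half_away(x: float) -> int:
    """Round half away from zero (symmetric rounding, unlike banker's)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def deg_to_px(x_deg: float, config: DisplayConfig, axis: str = "x") -> int:
    """Signed pixel offset of ``x_deg`` from the field center.

    Raises :class:`OutOfFieldError` if the coordinate falls outside the
    simulated field along the given axis.
    """
    extent = config.field_width_deg if axis == "x" else config.field_height_deg
    if abs(x_deg) > extent / 2.0 + 1e-12:
        raise OutOfFieldError(
            f"coordinate {x_deg}\N{DEGREE SIGN} outside the {extent}\N{DEGREE SIGN} field ({axis}-axis)"
        )
    return _round_half_away(x_deg * config.pixels_per_degree)


def make_condition_spec(condition: str, offset_direction: str = "right") -> StimulusSpec:
    """Fully populated :class:`StimulusSpec` for one of the 8 named conditions."""
    if condition not in CONDITIONS:
        raise ConfigurationError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    vernier = VernierSpec(offset_direction=offset_direction)
    flankers: Optional[FlankerSpec] = None
    pacmen: Optional[PacmanSpec] = None

    if condition != "VERNIER_ONLY":
        gapped = condition.startswith("GAPPED")
        height = vernier.length_deg if condition == "EQUAL_FLANKERS" else 8.5
        flankers = FlankerSpec(height_deg=height, gapped=gapped)
    if condition.endswith("_INWARD") or condition.endswith("_OUTWARD"):
        mouth = "inward" if condition.endswith("_INWARD") else "outward"
        pacmen = PacmanSpec(mouth_direction=mouth)
    return StimulusSpec(condition=condition, vernier=vernier, flankers=flankers, pacmen=pacmen)


def _row_span(y_top: float, y_bot: float, config: DisplayConfig, name: str) -> tuple[int, int]:
    """Half-open pixel row interval for a vertical degree span."""
    for y in (y_top, y_bot):
        if abs(y) > config.field_height_deg / 2.0 + 1e-12:
            raise OutOfFieldError(f"{name} exceeds the field vertically (y={y})")
    r0 = config.center_row + deg_to_px(y_top, config, axis="y")
    r1 = config.center_row + deg_to_px(y_bot, config, axis="y")
    return r0, r1


def _col_span(x_center: float, width_deg: float, config: DisplayConfig, name: str) -> tuple[int, int]:
    """Half-open pixel column interval for a vertical line of given width.

    Lines narrower than one pixel are rendered one pixel wide.  The center
    column snaps toward the vernier column (truncation, not nearest
    rounding): at coarse resolutions nearest rounding would push the offset
    vernier segment onto the pixel adjacent to the nearest flanker line and
    collapse the sub-pixel gap between them, changing the component
    structure of the display.  Truncation is symmetric under mirroring and
    agrees with nearest rounding whenever positions land on exact pixels
    (as they do at 10 px/deg).
    """
    half = width_deg / 2.0
    for x in (x_center - half, x_center + half):
        if abs(x) > config.field_width_deg / 2.0 + 1e-12:
            raise OutOfFieldError(f"{name} exceeds the field horizontally (x={x})")
    c = config.center_col + int(math.trunc(x_center * config.pixels_per_degree))
    w = max(1, int(round(width_deg * config.pixels_per_degree)))
    return c - (w - 1) // 2, c - (w - 1) // 2 + w


def render(spec: StimulusSpec, config: DisplayConfig = DisplayConfig()) -> LuminanceImage:
    """Rasterize a stimulus: background at 0.75, elements at 0.25 by default."""
    grid = np.full((config.n_rows, config.n_cols), config.background_luminance)
    lum = config.element_luminance
    v = spec.vernier

    # Vernier: upper segment at x=0, lower segment displaced by the offset.
    half_len = v.length_deg / 2.0
    r0, r1 = _row_span(-half_len, 0.0, config, "vernier upper segment")
    c0, c1 = _col_span(0.0, v.width_deg, config, "vernier upper segment")
    grid[r0:r1, c0:c1] = lum
    r0, r1 = _row_span(0.0, half_len, config, "vernier lower segment")
    c0, c1 = _col_span(v.signed_offset_deg, v.width_deg, config, "vernier lower segment")
    grid[r0:r1, c0:c1] = lum

    if spec.flankers is not None:
        spans = spec.flankers.segment_spans_deg()
        for x in spec.flankers.column_offsets_deg():
            c0, c1 = _col_span(float(x), v.width_deg, config, "flanker line")
            for y_top, y_bot in spans:
                r0, r1 = _row_span(y_top, y_bot, config, "flanker line")
                grid[r0:r1, c0:c1] = lum

    if spec.pacmen is not None and spec.pacmen.present:
        if spec.flankers is None:
            raise ConfigurationError("Pacman inducers require flankers (gap geometry)")
        p = spec.pacmen
        gap_center = (
            spec.flankers.middle_segment_height_deg / 2.0
            + spec.flankers.gap_height_deg / 2.0
        )
        xs = _pixel_x_deg(config)
        ys = _pixel_y_deg(config)
        X, Y = np.meshgrid(xs, ys)
        for xc, yc in p.centers_deg(gap_center):
            if abs(xc) + p.radius_deg > config.field_width_deg / 2.0 + 1e-12 or abs(
                yc
            ) + p.radius_deg > config.field_height_deg / 2.0 + 1e-12:
                raise OutOfFieldError("Pacman inducer exceeds the field")
            disk = (X - xc) ** 2 + (Y - yc) ** 2 <= p.radius_deg**2
            # Mouth: horizontal cutout from the center to the perimeter.
            toward_center = -1.0 if xc > 0 else 1.0
            sign = toward_center if p.mouth_direction == "inward" else -toward_center
            dx = (X - xc) * sign
            mouth = (dx >= 0) & (np.abs(Y - yc) <= p.mouth_height_deg / 2.0)
            grid[disk & ~mouth] = lum

    origin = (
        -config.center_col / config.pixels_per_degree,
        -config.center_row / config.pixels_per_degree,
    )
    return LuminanceImage(
        grid=grid,
        origin_deg=origin,
        pixels_per_degree=config.pixels_per_degree,
        background_luminance=config.background_luminance,
    )


def _pixel_x_deg(config: DisplayConfig) -> np.ndarray:
    return (np.arange(config.n_cols) - config.center_col) / config.pixels_per_degree


def _pixel_y_deg(config: DisplayConfig) -> np.ndarray:
    return (np.arange(config.n_rows) - config.center_row) / config.pixels_per_degree


def count_components(
    img: LuminanceImage, polarity: str = "darker_than_background"
) -> tuple[int, np.ndarray]:
    """4-connected components of pixels strictly below background luminance."""
    if polarity != "darker_than_background":
        raise ConfigurationError(f"unsupported polarity {polarity!r}")
    dark = img.grid < img.background_luminance - 1e-9
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(dark, structure=structure)
    return int(n), labels


# -- serialization ----------------------------------------------------------


def spec_to_yaml(spec: StimulusSpec, config: Optional[DisplayConfig] = None) -> str:
    doc: dict = {"stimulus": _dataclass_to_dict(spec)}
    if config is not None:
        doc["display"] = dataclasses.asdict(config)
    return yaml.safe_dump(doc, sort_keys=False)


def spec_from_yaml(text: str) -> tuple[StimulusSpec, Optional[DisplayConfig]]:
    doc = yaml.safe_load(text)
    s = doc["stimulus"]
    spec = StimulusSpec(
        condition=s["condition"],
        vernier=VernierSpec(**s["vernier"]),
        flankers=FlankerSpec(**s["flankers"]) if s.get("flankers") else None,
        pacmen=PacmanSpec(**s["pacmen"]) if s.get("pacmen") else None,
    )
    config = DisplayConfig(**doc["display"]) if "display" in doc else None
    return spec, config


def _dataclass_to_dict(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        val = getattr(obj, f.name)
        out[f.name] = _dataclass_to_dict(val) if dataclasses.is_dataclass(val) else val
    return out
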