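"""Display-window algebra for CT gray-level mapping.

A CT display window is a pair (center WC, width WW) in Hounsfield units.
Attenuation values at or below the lower gray level ``WC - WW/2`` render
black, values at or above the upper gray level ``WC + WW/2`` render white,
and the ramp in between is linear.  A zero-width window degenerates to a
binary threshold at the center; that binary display is what makes the
*half-value window* useful: with the center placed halfway between the
background attenuation and the attenuation of a dense object, the visible
white region recovers the object's true outline (the full-width-at-half-
maximum principle), eliminating the blooming artifact that low display
thresholds produce around calcifications.

Two named presets are shipped: ``soft_tissue`` (WC 50, WW 400) and
``bone`` (WC 300, WW 1120).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import InvalidContrastError

__all__ = [
    "WindowSetting",
    "gray_levels",
    "half_value_window",
    "apply_window",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class WindowSetting:
    """A display window: center and width in HU plus a free-text label.

    ``width == 0`` is legal and denotes the binary half-value display.
    """

    center: float
    width: float
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.center) or not np.isfinite(self.width):
            raise ValueError("window center/width must be finite")
        if self.width < 0:
            raise ValueError(f"window width must be >= 0, got {self.width}")

    @property
    def lower_level(self) -> float:
        """Gray level below which values display black (WC - WW/2)."""
        return self.center - self.width / 2.0

    @property
    def upper_level(self) -> float:
        """Gray level above which values display white (WC + WW/2)."""
        return self.center + self.width / 2.0


def _load_presets() -> dict[str, WindowSetting]:
    text = resources.files("stonewin.data").joinpath("presets.toml").read_text()
    raw = tomllib.loads(text)["windows"]
    return {
        name: WindowSetting(float(v["center"]), float(v["width"]), label=name)
        for name, v in raw.items()
    }


PRESETS: dict[str, WindowSetting] = _load_presets()


def preset(name: str) -> WindowSetting:
    """Return a shipped window preset (``soft_tissue`` or ``bone``)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown window preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def gray_levels(w: WindowSetting) -> tuple[float, float]:
    """Lower and upper gray levels ``(WC - WW/2, WC + WW/2)`` of a window.

    E.g. the bone window (300, 1120) has levels (-260, 860): everything
    below -260 HU displays black and everything above 860 HU white.
    """
    return (w.lower_level, w.upper_level)


def half_value_window(
    peak: float, background: float = 0.0, mode: str = "max"
) -> WindowSetting:
    """Derive the zero-width half-value window for a dense object.

    The center is placed halfway between the background attenuation and
    the object's attenuation statistic (``peak``), and the width is set
    to 0 so the display is a binary threshold.  ``mode`` records whether
    ``peak`` was the ROI *mean* or *max* attenuation and only affects the
    label.

    With the conventional background of 0 HU the center is simply
    ``peak / 2``.

    Raises
    ------
    InvalidContrastError
        If ``peak <= background`` (the object is not denser than its
        surroundings, so no half-value threshold separates it).
    """
    if mode not in ("mean", "max"):
        raise ValueError(f"mode must be 'mean' or 'max', got {mode!r}")
    if not peak > background:
        raise InvalidContrastError(
            f"object attenuation ({peak} HU) must exceed background "
            f"({background} HU) to define a half-value window"
        )
    center = background + (peak - background) / 2.0
    return WindowSetting(center, 0.0, label=f"half_value_{mode}")


def apply_window(values, w: WindowSetting) -> np.ndarray:
    """Map HU values to normalized display gray levels in [0, 1].

    Values at or below the lower level map to 0 (black), at or above the
    upper level to 1 (white), linearly in between.  For a zero-width
    window the transform is a step: values >= center display white.  The
    boundary value itself displays white (closed supra-threshold set), so
    a voxel at exactly half-max counts as object.
    """
    v = np.asarray(values, dtype=float)
    if w.width == 0:
        return (v >= w.center).astype(float)
    with np.errstate(over="ignore"):  # subnormal widths overflow before clip
        out = (v - w.lower_level) / w.width
    return np.clip(out, 0.0, 1.0)
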