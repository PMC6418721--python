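"""Condensed-domain statistics from epifluorescence micrographs.

Converts grayscale images of a compressed monolayer into a dark-domain
mask and summary statistics, and cross-checks the measured area fraction
against the coverage predicted from the isotherms.  The dark-phase
convention follows probes that are excluded from the condensed (LC) phase,
so LC domains appear dark; set ``invert=True`` for probes that accumulate
in the LC phase instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import DegenerateThresholdError, PressureOutOfRangeError
from .isotherm import IsothermCurve, area_at_pressure


@dataclass(frozen=True)
class Micrograph:
    """2-D intensity grid, at least 16x16, finite and non-negative."""

    intensities: np.ndarray
    pixel_size_um: float | None = None
    label: str = ""

    def __post_init__(self):
        img = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", img)
        if img.ndim != 2:
            raise ValueError("intensities must be a 2-D grid")
        if img.shape[0] < 16 or img.shape[1] < 16:
            raise ValueError("micrograph must be at least 16x16 pixels")
        if not np.isfinite(img).all():
            raise ValueError("non-finite intensity values")
        if (img < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class DomainStats:
    """Segmented-domain summary: exact pixel area fraction, 8-connected
    component count (border-touching components included), and mean domain
    area in pixels (None when there are no domains)."""

    area_fraction: float
    domain_count: int
    mean_domain_area_px: float | None

    def __post_init__(self):
        if not 0.0 <= self.area_fraction <= 1.0:
            raise ValueError("area fraction must lie in [0, 1]")
        if self.domain_count < 0:
            raise ValueError("domain count must be non-negative")


def segment_dark_domains(
    image: Micrograph,
    method: str = "otsu",
    level: float | None = None,
    invert: bool = False,
) -> np.ndarray:
    """Binary mask of dark (condensed-phase) pixels.

    method ``"otsu"`` picks the threshold automatically; ``"fixed"``
    requires ``level``.  The mask is True strictly below the threshold
    (strictly above it with ``invert=True``).
    """
    img = image.intensities
    if method == "otsu":
        if np.ptp(img) == 0:
            raise DegenerateThresholdError(
                "constant image: otsu threshold is undefined"
            )
        thr = float(threshold_otsu(img))
    elif method == "fixed":
        if level is None:
            raise ValueError("fixed method requires a threshold level")
        thr = float(level)
    else:
        raise ValueError(f"unknown method {method!r}")
    return img > thr if invert else img < thr


def domain_stats(mask: np.ndarray) -> DomainStats:
    """Area fraction and 8-connected component count of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    n_on = int(mask.sum())
    phi = n_on / mask.size
    _, count = label(mask, connectivity=2, return_num=True)
    mean_area = n_on / count if count else None
    return DomainStats(
        area_fraction=phi, domain_count=int(count), mean_domain_area_px=mean_area
    )


def predicted_lc_coverage(
    pressure: float,
    pure_lipid: IsothermCurve,
    mix_per_lipid: IsothermCurve,
) -> float:
    """Condensed-lipid coverage predicted from the isotherms.

    Above the LE-LC transition essentially all lipid is condensed; the
    condensed fraction of the film area is then the pure-lipid area per
    molecule over the mixed film's area per lipid at the same pressure:
    φ_pred = A_lipid(Π) / A_mix_per_lipid(Π), clamped to [0, 1].  Whether
    the transition is complete at ``pressure`` is the caller's call.
    """
    a_pure = area_at_pressure(pure_lipid, pressure)
    a_mix = area_at_pressure(mix_per_lipid, pressure)
    if a_mix <= 0:
        raise PressureOutOfRangeError("mixed-film area vanishes at this pressure")
    return float(np.clip(a_pure / a_mix, 0.0, 1.0))
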