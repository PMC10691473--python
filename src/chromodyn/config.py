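"""Shared imaging configuration.

A single :class:`ImagingConfig` is passed to both the simulator and the
inference stages so that the localization-error constant sigma, the frame
interval and the focal depth are guaranteed to be the same on both sides.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import yaml

log = logging.getLogger("chromodyn")


@dataclasses.dataclass(frozen=True)
class ImagingConfig:
    """Acquisition geometry and optics shared by simulation and inference.

    Parameters
    ----------
    pixel_size : float
        Camera pixel size in um/pixel.
    frame_interval : float
        Time between consecutive frames in seconds (exposure plus camera
        dead time, treated as one fixed sampling interval).
    focal_depth : float
        Axial extent of the detection slab in um; molecules are observed
        while their axial position is within +/- focal_depth/2.
    loc_error : float
        One-axis localization error sigma in um.
    roi_pixels : int
        Side length of the square region of interest, in pixels.
    psf_sigma : float
        Standard deviation of the (pixel-integrated) Gaussian PSF, in
        pixels.
    """

    pixel_size: float = 0.16
    frame_interval: float = 0.00748
    focal_depth: float = 0.7
    loc_error: float = 0.035
    roi_pixels: int = 100
    psf_sigma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "frame_interval", "focal_depth",
                     "psf_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.loc_error < 0:
            raise ValueError("loc_error must be nonnegative")
        if self.roi_pixels < 1:
            raise ValueError("roi_pixels must be >= 1")

    @property
    def roi_um(self) -> float:
        """Side length of the ROI in um."""
        return self.roi_pixels * self.pixel_size

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ImagingConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in fields})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
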