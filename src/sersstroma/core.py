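"""Shared containers for SERS hyperspectral imaging data.

The pipeline moves a single carrier through every stage: a hyperspectral
cube (pixel grid x wavenumber axis of SERS intensities) plus a per-pixel
annotation raster using the pathology vocabulary. Both are defined here so
that the simulation, preprocessing, annotation and statistics layers share
one set of types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = [
    "DataError",
    "ConfigError",
    "VOCABULARY",
    "STROMA_LABELS",
    "NEST_LABELS",
    "ADIPOSE_LABELS",
    "DIAGNOSES",
    "WavenumberAxis",
    "SpectralCube",
    "BandImage",
    "AnnotationMask",
]


class DataError(ValueError):
    """Raised for invalid, degenerate or inconsistent data inputs."""


class ConfigError(ValueError):
    """Raised for invalid configuration."""


DIAGNOSES = ("DCIS", "IBC")

#: Annotation vocabulary used by the pathology-style label rasters.
VOCABULARY = (
    "cancer_nest",
    "cancer_stroma",
    "dcis",
    "dcis_stroma",
    "fiber",
    "fat",
    "normal_gland",
    "background",
)

#: Stroma labels accepted per diagnosis when building ROI meshes. Invasive
#: cancer stroma is annotated ``cancer_stroma``; DCIS-associated stroma may be
#: annotated either specifically (``dcis_stroma``) or generically.
STROMA_LABELS: Mapping[str, tuple[str, ...]] = {
    "IBC": ("cancer_stroma",),
    "DCIS": ("dcis_stroma", "cancer_stroma"),
}

NEST_LABELS = ("cancer_nest", "dcis")
ADIPOSE_LABELS = ("fat",)


@dataclass(frozen=True)
class WavenumberAxis:
    """Uniform wavenumber grid in cm^-1.

    Defaults cover the fingerprint region at the instrument's ~2 cm^-1
    resolution; the lower end is 250 cm^-1 so that every reported
    differential band (the lowest sits at 256 cm^-1) is on-axis.
    """

    start: float = 250.0
    stop: float = 1800.0
    step: float = 2.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ConfigError("wavenumber step must be > 0")
        if self.stop <= self.start:
            raise ConfigError("wavenumber axis must be strictly increasing")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def contains(self, wavenumber: float) -> bool:
        return self.start <= wavenumber <= self.stop

    def nearest_channel(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.values - wavenumber)))


def _as_wavenumbers(axis: "WavenumberAxis | np.ndarray | Sequence[float]") -> np.ndarray:
    if isinstance(axis, WavenumberAxis):
        wn = axis.values
    else:
        wn = np.asarray(axis, dtype=float)
    if wn.ndim != 1 or wn.size < 2:
        raise DataError("wavenumber axis must be a 1-D array of >= 2 channels")
    if np.any(np.diff(wn) <= 0):
        raise DataError("wavenumber axis must be strictly increasing")
    return wn


@dataclass
class SpectralCube:
    """A hyperspectral SERS image: height x width x channels, plus its axis.

    ``wavenumbers`` holds channel centers in cm^-1 (a plain array rather than
    start/stop/step, because calibration may shift it off the nominal grid).
    ``pixel_pitch`` is the spatial sampling in um along the scan axis.
    ``metadata`` carries patient id, diagnosis and processing provenance.
    """

    intensities: np.ndarray
    wavenumbers: np.ndarray
    pixel_pitch: float = 11.65
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.wavenumbers = _as_wavenumbers(self.wavenumbers)
        if self.intensities.ndim != 3:
            raise DataError("cube intensities must be 3-D (height, width, channels)")
        if self.intensities.shape[2] != self.wavenumbers.size:
            raise DataError(
                f"cube has {self.intensities.shape[2]} channels but axis has "
                f"{self.wavenumbers.size}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise DataError("cube intensities must be finite")
        if self.pixel_pitch <= 0:
            raise DataError("pixel_pitch must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape[:2]  # type: ignore[return-value]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[2]

    def channel_window(self, center: float, halfwidth: float) -> np.ndarray:
        """Indices of channels whose centers lie in [center-hw, center+hw]."""
        if halfwidth < 0:
            raise DataError("halfwidth must be >= 0")
        if halfwidth == 0:
            return np.array([int(np.argmin(np.abs(self.wavenumbers - center)))])
        lo, hi = center - halfwidth, center + halfwidth
        idx = np.nonzero((self.wavenumbers >= lo) & (self.wavenumbers <= hi))[0]
        return idx

    def copy(self) -> "SpectralCube":
        return SpectralCube(
            intensities=self.intensities.copy(),
            wavenumbers=self.wavenumbers.copy(),
            pixel_pitch=self.pixel_pitch,
            metadata=dict(self.metadata),
        )


@dataclass
class BandImage:
    """Band-accumulated image: per-pixel sum over a wavenumber window."""

    values: np.ndarray
    center: float
    halfwidth: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("band image must be 2-D")


@dataclass
class AnnotationMask:
    """Per-pixel categorical raster over the cube grid.

    ``labels`` holds small-integer codes indexing into ``vocabulary``.
    """

    labels: np.ndarray
    vocabulary: tuple[str, ...] = VOCABULARY

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise DataError("annotation mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise DataError("annotation mask labels must be integer codes")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= len(self.vocabulary):
            raise DataError(
                "annotation mask contains label codes outside the declared vocabulary"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def code(self, label: str) -> int:
        try:
            return self.vocabulary.index(label)
        except ValueError:
            raise DataError(f"unknown annotation label {label!r}") from None

    def pixels_with(self, labels: Sequence[str]) -> np.ndarray:
        codes = [self.code(lab) for lab in labels]
        return np.isin(self.labels, codes)

    def label_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=len(self.vocabulary))
        return {lab: int(c) for lab, c in zip(self.vocabulary, counts)}

    @classmethod
    def from_names(cls, names: np.ndarray, vocabulary: tuple[str, ...] = VOCABULARY) -> "AnnotationMask":
        """Build a mask from a 2-D array of label strings."""
        names = np.asarray(names)
        codes = np.empty(names.shape, dtype=np.uint8)
        lut = {lab: i for i, lab in enumerate(vocabulary)}
        for lab in np.unique(names):
            if lab not in lut:
                raise DataError(f"unknown annotation label {lab!r}")
            codes[names == lab] = lut[lab]
        return cls(labels=codes, vocabulary=vocabulary)
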