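"""Joining cubes with pathology label masks.

Tags each annotated pixel's spectrum with its label, round-trips the tagged
records through the flat text export format ``(x, y, annotation tag,
spectrum)``, and builds stromal ROI meshes — one mesh cell per binned pixel
labelled as cancer-associated stroma, the unit of downstream
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import STROMA_LABELS, VOCABULARY, AnnotationMask, DataError, SpectralCube

__all__ = [
    "TaggedSpectrumTable",
    "RoiMesh",
    "tag_spectra",
    "write_tagged",
    "read_tagged",
    "stroma_mesh",
    "bin_mask",
]


@dataclass
class TaggedSpectrumTable:
    """Flat records (x, y, tag, spectrum) for one patient.

    ``x`` is the pixel column, ``y`` the pixel row (0-based, row-major,
    pixel centers); ``spectra`` has one row per record, aligned with
    ``wavenumbers``.
    """

    x: np.ndarray
    y: np.ndarray
    tags: np.ndarray
    spectra: np.ndarray
    wavenumbers: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=int)
        self.y = np.asarray(self.y, dtype=int)
        self.tags = np.asarray(self.tags, dtype=object)
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        n = self.x.size
        if not (self.y.size == n and self.tags.size == n and self.spectra.shape[0] == n):
            raise DataError("tagged table fields have inconsistent lengths")
        if n and self.spectra.shape[1] != self.wavenumbers.size:
            raise DataError("spectrum length does not match the wavenumber axis")
        coords = set(zip(self.x.tolist(), self.y.tolist()))
        if len(coords) != n:
            raise DataError("tagged table has duplicate (x, y) coordinates")
        unknown = set(self.tags.tolist()) - set(VOCABULARY)
        if unknown:
            raise DataError(f"unknown annotation tags {sorted(unknown)}")

    def __len__(self) -> int:
        return self.x.size

    def filter_tags(self, tags) -> "TaggedSpectrumTable":
        keep = np.isin(self.tags, list(tags))
        return TaggedSpectrumTable(
            x=self.x[keep], y=self.y[keep], tags=self.tags[keep],
            spectra=self.spectra[keep], wavenumbers=self.wavenumbers,
            patient_id=self.patient_id,
        )

    def tag_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.tags, return_counts=True)
        return {str(lab): int(c) for lab, c in zip(labels, counts)}


def tag_spectra(cube: SpectralCube, mask: AnnotationMask) -> TaggedSpectrumTable:
    """One record per non-background pixel, spectrum copied verbatim."""
    if mask.shape != cube.shape:
        raise DataError(
            f"mask shape {mask.shape} does not match cube grid {cube.shape}"
        )
    background = mask.code("background")
    yy, xx = np.nonzero(mask.labels != background)
    tags = np.asarray(mask.vocabulary, dtype=object)[mask.labels[yy, xx]]
    return TaggedSpectrumTable(
        x=xx, y=yy, tags=tags,
        spectra=cube.intensities[yy, xx, :].copy(),
        wavenumbers=cube.wavenumbers,
        patient_id=str(cube.metadata.get("patient_id", "")),
    )


def write_tagged(table: TaggedSpectrumTable, path) -> None:
    """Write a tagged table as TSV: header row with wavenumbers, then
    ``x<TAB>y<TAB>tag<TAB>intensity...`` rows at 6 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        header = ["x", "y", "tag"] + [f"{wn:.6g}" for wn in table.wavenumbers]
        fh.write("\t".join(header) + "\n")
        for i in range(len(table)):
            row = [str(int(table.x[i])), str(int(table.y[i])), str(table.tags[i])]
            row += [f"{v:.6g}" for v in table.spectra[i]]
            fh.write("\t".join(row) + "\n")


def read_tagged(path, patient_id: str = "") -> TaggedSpectrumTable:
    """Parse the TSV export; malformed rows raise with their line number."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 4 or header[:3] != ["x", "y", "tag"]:
            raise DataError(f"{path}: malformed header (expected x, y, tag, wavenumbers)")
        try:
            wavenumbers = np.array([float(v) for v in header[3:]])
        except ValueError as exc:
            raise DataError(f"{path}: non-numeric wavenumber in header: {exc}") from None
        ncol = len(header)
        xs: list[int] = []
        ys: list[int] = []
        tags: list[str] = []
        spectra: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise DataError(
                    f"{path}: line {lineno}: expected {ncol} columns, got {len(parts)}"
                )
            try:
                xs.append(int(parts[0]))
                ys.append(int(parts[1]))
                spectra.append([float(v) for v in parts[3:]])
            except ValueError as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from None
            tags.append(parts[2])
    return TaggedSpectrumTable(
        x=np.array(xs, dtype=int),
        y=np.array(ys, dtype=int),
        tags=np.array(tags, dtype=object),
        spectra=np.array(spectra, dtype=float).reshape(len(xs), wavenumbers.size),
        wavenumbers=wavenumbers,
        patient_id=patient_id,
    )


@dataclass
class RoiMesh:
    """Stromal region-of-interest mesh: one cell per stroma-labelled pixel."""

    x: np.ndarray
    y: np.ndarray
    patient_id: str
    diagnosis: str

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=int)
        self.y = np.asarray(self.y, dtype=int)
        if self.x.size != self.y.size:
            raise DataError("mesh x and y have different lengths")

    def __len__(self) -> int:
        return self.x.size


def stroma_mesh(mask: AnnotationMask, diagnosis: str, patient_id: str = "") -> RoiMesh:
    """Mesh cells on every pixel carrying a stroma label for this diagnosis.

    Invasive patients use ``cancer_stroma``; DCIS patients accept both
    ``dcis_stroma`` and ``cancer_stroma``.
    """
    try:
        labels = STROMA_LABELS[diagnosis]
    except KeyError:
        raise DataError(f"unknown diagnosis {diagnosis!r}") from None
    sel = mask.pixels_with(labels)
    if not sel.any():
        raise DataError(f"patient {patient_id or '<unknown>'} has no stroma ROI")
    yy, xx = np.nonzero(sel)
    return RoiMesh(x=xx, y=yy, patient_id=patient_id, diagnosis=diagnosis)


def bin_mask(mask: AnnotationMask, factor: int) -> AnnotationMask:
    """Downsample a mask with the same factor x 1 line-bin geometry as
    :func:`sersstroma.preprocess.bin_pixels`, by majority vote per bin.

    Ties resolve to the smallest label code, deterministically.
    """
    if int(factor) != factor or factor < 1:
        raise DataError(f"binning factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    if factor == 1:
        return AnnotationMask(labels=mask.labels.copy(), vocabulary=mask.vocabulary)
    h, w = mask.shape
    usable = (h // factor) * factor
    if usable == 0:
        raise DataError(f"binning factor {factor} exceeds mask height {h}")
    blocks = mask.labels[:usable].reshape(usable // factor, factor, w)
    n_lab = len(mask.vocabulary)
    counts = np.zeros((usable // factor, w, n_lab), dtype=int)
    for code in range(n_lab):
        counts[:, :, code] = (blocks == code).sum(axis=1)
    out = counts.argmax(axis=2).astype(mask.labels.dtype)
    return AnnotationMask(labels=out, vocabulary=mask.vocabulary)
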