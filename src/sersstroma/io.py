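"""On-disk formats.

One self-describing HDF5 container per patient cube (intensity array, axis
vector, silicon reference, metadata), indexed PNG label masks with a JSON
sidecar mapping index to label, and TSV for everything tabular. All writers
produce byte-stable output for a given input (HDF5 object timestamps are
disabled) so that identical configs yield hash-identical trees.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import AnnotationMask, DataError, SpectralCube

__all__ = [
    "FORMAT_VERSION",
    "write_cube",
    "read_cube",
    "write_mask",
    "read_mask",
    "write_table",
    "read_table",
    "sha256_file",
]

FORMAT_VERSION = 1


def write_cube(cube: SpectralCube, path, silicon: np.ndarray | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.attrs["pixel_pitch"] = cube.pixel_pitch
        fh.attrs["metadata"] = json.dumps(cube.metadata, sort_keys=True)
        fh.create_dataset("intensities", data=cube.intensities, track_times=False)
        fh.create_dataset("wavenumbers", data=cube.wavenumbers, track_times=False)
        if silicon is not None:
            fh.create_dataset("silicon", data=np.asarray(silicon), track_times=False)


def read_cube(path, with_silicon: bool = False):
    path = Path(path)
    with h5py.File(path, "r") as fh:
        version = int(fh.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise DataError(
                f"{path}: cube container version {version} != expected {FORMAT_VERSION}"
            )
        cube = SpectralCube(
            intensities=fh["intensities"][...],
            wavenumbers=fh["wavenumbers"][...],
            pixel_pitch=float(fh.attrs["pixel_pitch"]),
            metadata=json.loads(fh.attrs["metadata"]),
        )
        if with_silicon:
            silicon = fh["silicon"][...] if "silicon" in fh else None
            return cube, silicon
    return cube


def write_mask(mask: AnnotationMask, path) -> None:
    """Indexed PNG plus a `<stem>.labels.json` sidecar mapping index->label."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, mask.labels.astype(np.uint8), extension=".png")
    sidecar = path.with_suffix(".labels.json")
    sidecar.write_text(
        json.dumps({str(i): lab for i, lab in enumerate(mask.vocabulary)}, indent=0)
    )


def read_mask(path) -> AnnotationMask:
    path = Path(path)
    sidecar = path.with_suffix(".labels.json")
    if not sidecar.exists():
        raise DataError(f"mask sidecar {sidecar} not found")
    mapping = json.loads(sidecar.read_text())
    labels = np.asarray(iio.imread(path))
    if labels.ndim == 3:
        labels = labels[..., 0]
    labels = labels.astype(np.int64)
    declared = {int(k) for k in mapping}
    present = set(np.unique(labels).tolist())
    undeclared = present - declared
    if undeclared:
        raise DataError(
            f"{path}: mask contains undeclared label indices {sorted(undeclared)}"
        )
    vocabulary = tuple(mapping[str(i)] for i in range(len(mapping)))
    return AnnotationMask(labels=labels, vocabulary=vocabulary)


def write_table(table: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"table not found: {path}")
    return pd.read_csv(path, sep="\t")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
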