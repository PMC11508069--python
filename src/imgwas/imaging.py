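"""Middle-slice extraction and normalization of registered 3D volumes.

Volumes are assumed to be skull-stripped and registered to a common space
upstream. From each 3D scan the full middle slice (index floor(dim/2)) is
taken along each canonical axis — x = sagittal, y = coronal, z = axial —
and min-max normalized to [0, 1] per image. NIfTI volumes are reoriented to
the closest canonical (RAS) orientation on load so the axis convention holds
regardless of on-disk storage order.

A portable slice archive (one .npy per slice plus a TSV manifest) is the
on-disk exchange format between the generator/extractor and the scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLANES = ("axial", "coronal", "sagittal")


def extract_middle_slices(volume: np.ndarray) -> dict[str, np.ndarray]:
    """Middle slice along each canonical axis of a 3D volume.

    Returns a dict plane -> 2D array. For a volume of shape (nx, ny, nz) the
    sagittal slice is volume[nx//2, :, :], coronal volume[:, ny//2, :] and
    axial volume[:, :, nz//2].
    """
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got {vol.ndim} dimensions")
    mids = [d // 2 for d in vol.shape]
    return {
        "sagittal": vol[mids[0], :, :],
        "coronal": vol[:, mids[1], :],
        "axial": vol[:, :, mids[2]],
    }


def normalize01(pixels: np.ndarray) -> np.ndarray:
    """Min-max normalize a 2D image to [0, 1]; a constant image maps to zeros."""
    img = np.asarray(pixels, dtype=np.float64)
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    lo = img.min()
    hi = img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


@dataclass
class Scan:
    """One acquisition: three normalized middle slices keyed by plane."""

    subject: str
    index: int
    slices: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.slices) != set(PLANES):
            raise ValueError(f"scan must hold exactly the planes {PLANES}")


@dataclass
class ImagingDataset:
    """Per-subject ordered scan collection."""

    scans: list[Scan] = field(default_factory=list)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.scans:
            seen.setdefault(s.subject, None)
        return list(seen)

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    def scans_for(self, subject: str) -> list[Scan]:
        return [s for s in self.scans if s.subject == subject]


def volume_to_scan(volume: np.ndarray, subject: str, index: int) -> Scan:
    slices = {
        plane: normalize01(img).astype(np.float32)
        for plane, img in extract_middle_slices(volume).items()
    }
    return Scan(subject=subject, index=index, slices=slices)


def build_dataset(scan_table: list[tuple[str, str]]) -> ImagingDataset:
    """Build a dataset from (subject, NIfTI path) pairs.

    Each volume is reoriented to canonical orientation, its three middle
    slices extracted and normalized. Scan indices count acquisitions per
    subject in input order.
    """
    import nibabel as nib

    counts: dict[str, int] = {}
    scans: list[Scan] = []
    for subject, path in scan_table:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"unreadable scan file: {p}")
        img = nib.as_closest_canonical(nib.load(str(p)))
        vol = np.asarray(img.get_fdata())
        idx = counts.get(subject, 0)
        counts[subject] = idx + 1
        scans.append(volume_to_scan(vol, subject=subject, index=idx))
    return ImagingDataset(scans=scans)


def save_slice_archive(ds: ImagingDataset, directory) -> None:
    """Write slices as .npy files plus a TSV manifest (subject, scan, plane, file)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in ds.scans:
        for plane, img in scan.slices.items():
            fname = f"{scan.subject}_{scan.index}_{plane}.npy"
            np.save(d / fname, np.asarray(img, dtype=np.float32))
            rows.append([scan.subject, scan.index, plane, fname])
    pd.DataFrame(rows, columns=["subject", "scan_index", "plane", "file"]).to_csv(
        d / "manifest.tsv", sep="\t", index=False
    )


def load_slice_archive(directory) -> ImagingDataset:
    d = Path(directory)
    manifest = pd.read_csv(d / "manifest.tsv", sep="\t", dtype={"subject": str})
    scans: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    order: list[tuple[str, int]] = []
    for _, row in manifest.iterrows():
        key = (str(row["subject"]), int(row["scan_index"]))
        if key not in scans:
            scans[key] = {}
            order.append(key)
        scans[key][row["plane"]] = np.load(d / row["file"])
    out = ImagingDataset()
    for subject, idx in order:
        out.scans.append(Scan(subject=subject, index=idx, slices=scans[(subject, idx)]))
    return out
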