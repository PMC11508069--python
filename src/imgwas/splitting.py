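"""Subject-grouped train/validation/test splitting.

Every scan of a subject lands in the same part, so the three parts share no
subjects (no information leakage through repeat scans). Part sizes follow
the 7:1:2 ratio by largest-remainder rounding over a seeded shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MonomorphicTaskError
from .imaging import ImagingDataset

PARTS = ("train", "validation", "test")


@dataclass(frozen=True)
class SubjectSplit:
    assignment: dict[str, str]  # subject id -> part name
    seed: int

    def part(self, name: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == name]

    def sizes(self) -> tuple[int, int, int]:
        return tuple(len(self.part(p)) for p in PARTS)  # type: ignore[return-value]


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    exact = [n * r for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    remainder = n - sum(counts)
    # Distribute leftovers to the largest fractional parts (stable order).
    order = sorted(range(len(ratios)), key=lambda i: exact[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def subject_split(
    subjects: list[str],
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> SubjectSplit:
    """Randomly assign subjects to train/validation/test at the given ratios."""
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects to split into 3 parts")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    shuffled = [subjects[i] for i in rng.permutation(len(subjects))]
    counts = _largest_remainder(len(subjects), ratios)
    assignment: dict[str, str] = {}
    start = 0
    for part, c in zip(PARTS, counts):
        for s in shuffled[start : start + c]:
            assignment[s] = part
        start += c
    return SubjectSplit(assignment=assignment, seed=seed)


@dataclass
class LabeledSlices:
    """A stack of same-plane slices with binary labels and subject provenance."""

    images: np.ndarray  # (n, H, W) float32
    labels: np.ndarray  # (n,) int
    subjects: list[str]

    def __len__(self) -> int:
        return int(self.images.shape[0])


def materialize(
    split: SubjectSplit,
    ds: ImagingDataset,
    labels: dict[str, int],
    plane: str,
) -> tuple[LabeledSlices, LabeledSlices, LabeledSlices]:
    """Collect each part's labeled slices for one plane.

    Subjects without a label (e.g. missing genotype) are excluded. Raises
    MonomorphicTaskError when the training part ends up with a single class.
    """
    unknown = set(labels) - set(ds.subjects)
    if unknown:
        raise ValueError(f"labeled subjects absent from the imaging dataset: {sorted(unknown)}")
    parts: dict[str, list] = {p: [] for p in PARTS}
    for scan in ds.scans:
        subj = scan.subject
        if subj not in labels or subj not in split.assignment:
            continue
        parts[split.assignment[subj]].append((scan.slices[plane], labels[subj], subj))
    out = []
    for p in PARTS:
        entries = parts[p]
        if entries:
            images = np.stack([e[0] for e in entries]).astype(np.float32)
            y = np.array([e[1] for e in entries], dtype=np.int64)
            subjects = [e[2] for e in entries]
        else:
            images = np.zeros((0, 0, 0), dtype=np.float32)
            y = np.zeros(0, dtype=np.int64)
            subjects = []
        out.append(LabeledSlices(images=images, labels=y, subjects=subjects))
    train = out[0]
    if len(train) and len(np.unique(train.labels)) < 2:
        raise MonomorphicTaskError("training part contains a single class")
    return out[0], out[1], out[2]
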