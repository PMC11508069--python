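"""Synthetic imaging-genetics cohorts with known ground truth.

The generator emulates the structure of a longitudinal neuroimaging-genetics
cohort at desk scale: Hardy-Weinberg genotypes at chosen minor allele
frequencies, a shared smooth anatomy template plus a per-subject smooth
deviation field (subject identity), several repeat scans per subject with
independent acquisition noise, and genotype-dependent image effects planted
under a dominant model.

Two effect kinds are supported per causal SNP:

* ``mean_blob`` — carriers receive an additive Gaussian-shaped intensity
  bump of amplitude beta at a chosen 3-D location; a linear, mean-shift
  signal detectable by pixelwise tests.
* ``texture_variance`` — the local acquisition-noise standard deviation
  inside the blob is scaled by sqrt(1 + beta) for carriers, leaving the
  pixelwise mean unchanged; a non-linear signal that a mean-based
  univariate test cannot see but a non-linear classifier can.

Real MR slices have stable intensity extremes set by tissue classes, not by
noise; a pure smooth Gaussian field does not, and then the per-image
min-max normalization couples any planted variance effect into a global
multiplicative mean cue (the inflated noise occasionally sets the image
extremes). The template therefore carries fixed bright and dark reference
structures, placed on the central axes so every middle slice contains at
least one of each; acquisition noise is additionally drawn from a bounded
(uniform) distribution. Together these anchor each image's min and max to
anatomy, keeping texture_variance effects mean-preserving end to end.

Volumes are reduced through the imaging module (middle slices of each
plane, min-max normalized), so downstream code consumes exactly what the
real-data path would produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ._util import derive_seed
from .genotypes import MISSING, GenotypeMatrix, SNPRecord
from .imaging import ImagingDataset, volume_to_scan


@dataclass(frozen=True)
class CausalEffect:
    snp_id: str
    beta: float
    kind: str = "mean_blob"  # or "texture_variance"
    center: tuple[int, int, int] | None = None  # default: volume center
    radius: float = 8.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("effect size beta must be >= 0")
        if self.kind not in ("mean_blob", "texture_variance"):
            raise ValueError(f"unknown effect kind {self.kind!r}")


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    effects: tuple[CausalEffect, ...] = ()
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    scans_per_subject_rate: float = 1.5  # scans = 1 + Poisson(rate)
    anatomy_smoothness: float = 4.0  # gaussian sigma, voxels
    subject_sd: float = 0.2  # amplitude of per-subject anatomy deviation
    noise_sd: float = 0.05  # per-scan acquisition noise sd
    missing_rate: float = 0.02
    genetic_model: str = "dominant"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.genetic_model not in ("dominant", "recessive"):
            raise ValueError("genetic_model must be 'dominant' or 'recessive'")


@dataclass
class CohortTruth:
    """Planted effects and the 3-D region mask of each causal SNP."""

    effects: tuple[CausalEffect, ...]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def plane_mask(self, snp_id: str, plane: str) -> np.ndarray:
        """Middle-slice cut of a causal SNP's 3-D mask in one plane."""
        m = self.masks[snp_id]
        mids = [d // 2 for d in m.shape]
        if plane == "sagittal":
            return m[mids[0], :, :]
        if plane == "coronal":
            return m[:, mids[1], :]
        if plane == "axial":
            return m[:, :, mids[2]]
        raise ValueError(f"unknown plane {plane!r}")


def _snp_id(j: int) -> str:
    return f"snp{j + 1:05d}"


def _bump(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, d) for d in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    sigma = radius / 2.0
    return np.exp(-d2 / (2.0 * sigma**2))


def _smooth_field(rng, shape, sigma) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return (f - f.mean()) / (f.std() + 1e-12)


_ANCHOR_AMPLITUDE = 6.0


def _anchor_structures(shape) -> np.ndarray:
    """Fixed bright/dark reference structures anchoring image extremes.

    Three bright (+A) and three dark (-A) bumps sit on the central axes at
    ~30% of each dimension from the volume center, so each of the three
    middle planes contains at least one bright and one dark structure. Their
    amplitude dominates the smooth anatomy field and the planted effects,
    which pins every slice's min/max to these structures.
    """
    center = tuple(d // 2 for d in shape)
    radius = max(2.0, min(shape) * 0.08)
    out = np.zeros(shape)
    for axis in range(3):
        offset = int(round(shape[axis] * 0.3))
        for sign in (+1, -1):
            c = list(center)
            c[axis] += sign * offset
            out += sign * _ANCHOR_AMPLITUDE * _bump(shape, c, radius)
    return out


def generate_cohort(cfg: CohortConfig) -> tuple[GenotypeMatrix, ImagingDataset, CohortTruth]:
    """Draw a full cohort: genotype matrix, imaging dataset and ground truth.

    Fully reproducible from ``cfg.seed``; effects are applied based on the
    true genotype even when the reported call is planted as missing.
    """
    subjects = [f"S{i + 1:04d}" for i in range(cfg.n_subjects)]
    snp_ids = [_snp_id(j) for j in range(cfg.n_snps)]
    known = {e.snp_id for e in cfg.effects}
    unknown = known - set(snp_ids)
    if unknown:
        raise ValueError(f"causal SNP ids outside the cohort: {sorted(unknown)}")

    # -- genotypes ---------------------------------------------------------
    geno_rng = np.random.default_rng(derive_seed(cfg.seed, "genotypes"))
    mafs = geno_rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    true_g = np.stack(
        [geno_rng.binomial(2, p, size=cfg.n_subjects) for p in mafs]
    ).astype(np.int8)  # (n_snps, n_subjects)
    reported = true_g.copy()
    if cfg.missing_rate > 0:
        miss = geno_rng.random(reported.shape) < cfg.missing_rate
        reported[miss] = MISSING
    snps = []
    for j, sid in enumerate(snp_ids):
        snps.append(
            SNPRecord(
                id=sid,
                chrom=str(j % 22 + 1),
                pos=1000 * (j + 1),
                ref_allele="A",
                alt_allele="G",
                genotypes=reported[j],
            )
        )
    gm = GenotypeMatrix(subjects=subjects, snps=snps)

    # -- effect geometry ---------------------------------------------------
    shape = cfg.volume_shape
    truth = CohortTruth(effects=tuple(cfg.effects))
    bumps: dict[str, np.ndarray] = {}
    for e in cfg.effects:
        center = e.center if e.center is not None else tuple(d // 2 for d in shape)
        if not all(0 <= c < d for c, d in zip(center, shape)):
            raise ValueError(f"causal blob center {center} outside volume {shape}")
        grids = np.ogrid[tuple(slice(0, d) for d in shape)]
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        truth.masks[e.snp_id] = d2 <= e.radius**2
        bumps[e.snp_id] = _bump(shape, center, e.radius)

    snp_index = {sid: j for j, sid in enumerate(snp_ids)}

    def is_carrier(snp_id: str, subject_idx: int) -> bool:
        g = true_g[snp_index[snp_id], subject_idx]
        return bool(g == 2) if cfg.genetic_model == "recessive" else bool(g >= 1)

    # -- imaging -----------------------------------------------------------
    template = _smooth_field(
        np.random.default_rng(derive_seed(cfg.seed, "template")), shape, cfg.anatomy_smoothness
    ) + _anchor_structures(shape)
    ds = ImagingDataset()
    scan_rng = np.random.default_rng(derive_seed(cfg.seed, "scans"))
    for i, subject in enumerate(subjects):
        subj_rng = np.random.default_rng(derive_seed(cfg.seed, "subject", subject))
        vol = template + cfg.subject_sd * _smooth_field(subj_rng, shape, cfg.anatomy_smoothness)
        texture_masks = []
        for e in cfg.effects:
            if not is_carrier(e.snp_id, i):
                continue
            if e.kind == "mean_blob":
                vol = vol + e.beta * bumps[e.snp_id]
            else:
                texture_masks.append((truth.masks[e.snp_id], e.beta))
        n_scans = 1 + scan_rng.poisson(cfg.scans_per_subject_rate)
        half_width = cfg.noise_sd * np.sqrt(3.0)  # uniform with sd = noise_sd
        for k in range(n_scans):
            noise = scan_rng.uniform(-half_width, half_width, size=shape)
            for mask, beta in texture_masks:
                noise[mask] *= np.sqrt(1.0 + beta)
            ds.scans.append(volume_to_scan(vol + noise, subject=subject, index=k))
    return gm, ds, truth


def generate_null_labels(ds: ImagingDataset, class1_fraction: float, seed: int = 0) -> dict[str, int]:
    """Subject labels drawn independently of the images (null calibration)."""
    if not 0.0 < class1_fraction < 1.0:
        raise ValueError("class1_fraction must be in (0, 1)")
    subjects = ds.subjects
    n1 = int(round(class1_fraction * len(subjects)))
    rng = np.random.default_rng(seed)
    ones = set(rng.choice(len(subjects), size=n1, replace=False).tolist())
    return {s: (1 if i in ones else 0) for i, s in enumerate(subjects)}
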