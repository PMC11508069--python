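"""Genotype I/O, GWAS-style quality control and class-label encoding.

Genotypes are stored as counts of the alternate allele (0/1/2) with -1 for
missing calls. Quality control follows standard GWAS practice: SNPs are
excluded when call rate < 95%, exact Hardy-Weinberg p < 1e-6 or minor allele
frequency < 5%, and only autosomal SNPs are kept by default.

For classification, a SNP's genotypes are pooled into two classes under a
dominant model (AA vs Aa+aa) or a recessive model (AA+Aa vs aa); subjects
with a missing call at the SNP are dropped from that SNP's task.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
_AUTOSOMES = {str(i) for i in range(1, 23)}

TSV_META_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


class MonomorphicTaskError(ValueError):
    """Raised when a binarized genotype task has only one class."""


def normalize_chrom(chrom: str) -> str:
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


@dataclass
class SNPRecord:
    """One biallelic SNP: metadata plus per-subject alt-allele counts."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotypes: np.ndarray  # int8, values in {0, 1, 2, MISSING}

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not np.isin(self.genotypes, (0, 1, 2, MISSING)).all():
            raise ValueError(f"invalid genotype values for SNP {self.id}")

    @property
    def called(self) -> np.ndarray:
        return self.genotypes != MISSING

    @property
    def is_autosomal(self) -> bool:
        return normalize_chrom(self.chrom) in _AUTOSOMES


@dataclass
class GenotypeMatrix:
    """Ordered subjects x ordered SNPs."""

    subjects: list[str]
    snps: list[SNPRecord]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject identifiers")
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP identifiers")
        for s in self.snps:
            if s.genotypes.shape != (len(self.subjects),):
                raise ValueError(f"SNP {s.id} has wrong number of genotype values")
        self._index = {s.id: i for i, s in enumerate(self.snps)}

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def get(self, snp_id: str) -> SNPRecord:
        return self.snps[self._index[snp_id]]

    def to_tsv(self, path) -> None:
        """Write the TSV genotype dialect (metadata columns then one column
        per subject; missing encoded 'NA')."""
        rows = []
        for s in self.snps:
            g = [("NA" if v == MISSING else str(int(v))) for v in s.genotypes]
            rows.append([s.id, s.chrom, str(s.pos), s.ref_allele, s.alt_allele] + g)
        df = pd.DataFrame(rows, columns=TSV_META_COLUMNS + list(self.subjects))
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; comparisons are strict (< threshold excludes)."""

    min_call_rate: float = 0.95
    hwe_p_min: float = 1e-6
    maf_min: float = 0.05
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "hwe_p_min", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF (GT field) or the tab-separated dialect.

    Diploid biallelic calls map to {0, 1, 2}; anything else (multiallelic
    site, non-SNP alleles, half-missing call) becomes missing.
    """
    path = str(path)
    if format is None:
        format = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    subjects = list(vcf.samples)
    snps: list[SNPRecord] = []
    for i, var in enumerate(vcf):
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            logger.warning(
                "site %s has %d ALT alleles; all genotypes set to missing",
                snp_id, len(var.ALT),
            )
            g = np.full(len(subjects), MISSING, dtype=np.int8)
            alt = var.ALT[0] if var.ALT else "."
        else:
            # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown.
            g = np.asarray(var.gt_types, dtype=np.int8)
            g[g == 3] = MISSING
            alt = var.ALT[0]
        snps.append(
            SNPRecord(
                id=snp_id,
                chrom=normalize_chrom(var.CHROM),
                pos=int(var.POS),
                ref_allele=var.REF,
                alt_allele=alt,
                genotypes=g,
            )
        )
    vcf.close()
    return GenotypeMatrix(subjects=subjects, snps=snps)


def _read_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in TSV_META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"genotype TSV missing columns: {missing_cols}")
    subjects = [c for c in df.columns if c not in TSV_META_COLUMNS]
    snps = []
    for _, row in df.iterrows():
        vals = row[subjects]
        g = np.array(
            [MISSING if (pd.isna(v) or v == "NA") else int(v) for v in vals],
            dtype=np.int8,
        )
        snps.append(
            SNPRecord(
                id=row["snp_id"],
                chrom=normalize_chrom(row["chrom"]),
                pos=int(row["pos"]),
                ref_allele=row["ref"],
                alt_allele=row["alt"],
                genotypes=g,
            )
        )
    return GenotypeMatrix(subjects=subjects, snps=snps)


def call_rate(snp: SNPRecord) -> float:
    """Fraction of subjects with a non-missing call."""
    if snp.genotypes.size < 1:
        raise ValueError("SNP has no genotype values")
    return float(snp.called.mean())


def maf(snp: SNPRecord) -> float:
    """Minor allele frequency: alt-allele frequency folded to <= 0.5."""
    g = snp.genotypes[snp.called]
    if g.size == 0:
        raise ValueError(f"SNP {snp.id}: all genotypes missing")
    alt_freq = float(g.sum()) / (2.0 * g.size)
    return min(alt_freq, 1.0 - alt_freq)


def genotype_counts(snp: SNPRecord) -> tuple[int, int, int]:
    """(n_hom_ref, n_het, n_hom_alt) over called subjects."""
    g = snp.genotypes[snp.called]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def hwe_test(nAA: int, nAa: int, naa: int, method: str = "exact") -> float:
    """Hardy-Weinberg equilibrium test p-value.

    ``exact``: conditional exact test — given the allele counts, sum the
    hypergeometric-weighted probabilities of all heterozygote counts no more
    probable than the observed one. ``chisq``: 1-df asymptotic test.
    """
    if min(nAA, nAa, naa) < 0 or nAA + nAa + naa < 1:
        raise ValueError("genotype counts must be non-negative with positive total")
    if method == "chisq":
        return _hwe_chisq(nAA, nAa, naa)
    if method != "exact":
        raise ValueError("method must be 'exact' or 'chisq'")
    n = nAA + nAa + naa
    # Fold to the rarer allele so enumeration ranges over its carrier counts.
    rare = min(2 * nAA + nAa, 2 * naa + nAa)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het | allele margins) up to a constant:
    #   n! / (n_AA! n_Aa! n_aa!) * 2^het with n_rare_hom = (rare - het)/2.
    from scipy.special import gammaln

    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - n_rare_hom - hets
    logw = (
        hets * math.log(2.0)
        - gammaln(hets + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(n_common_hom + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    obs_p = probs[np.where(hets == nAa)[0][0]]
    p = float(probs[probs <= obs_p * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def _hwe_chisq(nAA: int, nAa: int, naa: int) -> float:
    from scipy.stats import chi2

    n = nAA + nAa + naa
    p = (2 * nAA + nAa) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([nAA, nAa, naa], dtype=float)
    stat = float(((obs - exp) ** 2 / exp).sum())
    return float(chi2.sf(stat, df=1))


def qc_filter(
    gm: GenotypeMatrix,
    th: QCThresholds = QCThresholds(),
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply SNP-level QC; returns the filtered matrix and an exclusion report.

    Rules are checked in order (non-autosome, call rate, MAF, HWE) and the
    report records the first failing rule per excluded SNP.
    """
    kept: list[SNPRecord] = []
    excluded: list[tuple[str, str, float]] = []
    for snp in gm.snps:
        if th.autosomes_only and not snp.is_autosomal:
            excluded.append((snp.id, "non_autosomal", float("nan")))
            continue
        cr = call_rate(snp)
        if cr < th.min_call_rate:
            excluded.append((snp.id, "call_rate", cr))
            continue
        if not snp.called.any():
            excluded.append((snp.id, "all_missing", 0.0))
            continue
        f = maf(snp)
        if f < th.maf_min:
            excluded.append((snp.id, "maf", f))
            continue
        p = hwe_test(*genotype_counts(snp), method=hwe_method)
        if p < th.hwe_p_min:
            excluded.append((snp.id, "hwe", p))
            continue
        kept.append(snp)
    if not kept:
        logger.warning("QC removed every SNP")
    report = pd.DataFrame(excluded, columns=["snp_id", "rule", "value"])
    return GenotypeMatrix(subjects=list(gm.subjects), snps=kept), report


@dataclass(frozen=True)
class BinaryTask:
    """Subjects with non-missing calls and their pooled genotype class."""

    snp_id: str
    model: str
    subjects: tuple[str, ...]
    labels: np.ndarray  # int, values in {0, 1}

    @property
    def is_monomorphic(self) -> bool:
        return len(np.unique(self.labels)) < 2

    @property
    def class_sizes(self) -> tuple[int, int]:
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())


def binarize(snp: SNPRecord, subjects: list[str], model: str = "dominant") -> BinaryTask:
    """Pool genotypes into two classes, dropping missing-call subjects.

    Dominant: AA (0) -> class 0, Aa/aa (1, 2) -> class 1.
    Recessive: AA/Aa (0, 1) -> class 0, aa (2) -> class 1.
    """
    if model not in ("dominant", "recessive"):
        raise ValueError("model must be 'dominant' or 'recessive'")
    mask = snp.called
    g = snp.genotypes[mask]
    kept = tuple(s for s, m in zip(subjects, mask) if m)
    if model == "dominant":
        labels = (g >= 1).astype(np.int64)
    else:
        labels = (g == 2).astype(np.int64)
    return BinaryTask(snp_id=snp.id, model=model, subjects=kept, labels=labels)
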