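"""Genotype I/O, QC rules, HWE exact test and class-label encoding."""

import math

import numpy as np
import pytest

from imgwas.genotypes import (
    MISSING,
    GenotypeMatrix,
    QCThresholds,
    SNPRecord,
    binarize,
    call_rate,
    genotype_counts,
    hwe_test,
    maf,
    qc_filter,
    read_genotypes,
)

VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=chr2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\tD
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.
1\t200\trs2\tC\tT,G\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0
chr2\t300\trs3\tG\tA\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0\t1/1
"""


def _snp(genos, chrom="1", snp_id="s1"):
    return SNPRecord(id=snp_id, chrom=chrom, pos=1, ref_allele="A",
                     alt_allele="G", genotypes=np.array(genos, dtype=np.int8))


@pytest.fixture()
def vcf_path(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(VCF_TEXT)
    return p


class TestReadGenotypes:
    def test_vcf_gt_mapping(self, vcf_path):
        gm = read_genotypes(vcf_path)
        assert gm.subjects == ["A", "B", "C", "D"]
        assert list(gm.get("rs1").genotypes) == [0, 1, 2, MISSING]

    def test_multiallelic_site_all_missing(self, vcf_path):
        gm = read_genotypes(vcf_path)
        assert list(gm.get("rs2").genotypes) == [MISSING] * 4

    def test_chr_prefix_normalized(self, vcf_path):
        assert read_genotypes(vcf_path).get("rs3").chrom == "2"

    def test_tsv_round_trip_matches_vcf(self, vcf_path, tmp_path):
        gm = read_genotypes(vcf_path)
        out = tmp_path / "g.tsv"
        gm.to_tsv(out)
        gm2 = read_genotypes(out)
        assert gm2.subjects == gm.subjects
        for a, b in zip(gm.snps, gm2.snps):
            assert a.id == b.id and a.chrom == b.chrom and a.pos == b.pos
            assert np.array_equal(a.genotypes, b.genotypes)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenotypeMatrix(subjects=["a", "a"], snps=[])
        with pytest.raises(ValueError, match="duplicate"):
            GenotypeMatrix(subjects=["a"], snps=[_snp([0]), _snp([1])])


@pytest.mark.parametrize(
    "genos, expected",
    [([0, 1, 2, MISSING], 0.75), ([0, 1, 2], 1.0), ([MISSING, MISSING], 0.0)],
)
def test_call_rate(genos, expected):
    assert call_rate(_snp(genos)) == pytest.approx(expected)


@pytest.mark.parametrize(
    "genos, expected",
    [([0, 0, 0, 0], 0.0), ([0, 1, 1, 2], 0.5), ([2, 2, 2, 1], 0.125)],
)
def test_maf_examples(genos, expected):
    assert maf(_snp(genos)) == pytest.approx(expected)


def test_maf_fold_symmetry():
    rng = np.random.default_rng(0)
    for _ in range(20):
        g = rng.integers(0, 3, size=30).astype(np.int8)
        assert maf(_snp(g)) == pytest.approx(maf(_snp(2 - g)))


def _hwe_bruteforce(nAA, nAa, naa):
    """Independent enumeration oracle: full trinomial configuration weights
    n! / (nAA! nAa! naa!) * 2^nAa over all tables with the observed margins."""
    n = nAA + nAa + naa
    n_alt = 2 * naa + nAa
    configs = []
    for het in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
        aa = (n_alt - het) // 2
        AA = n - aa - het
        if AA < 0:
            continue
        w = (
            math.factorial(n)
            // (math.factorial(AA) * math.factorial(het) * math.factorial(aa))
            * 2**het
        )
        configs.append((het, w))
    total = sum(w for _, w in configs)
    obs = dict(configs)[nAa]
    return sum(w for _, w in configs if w <= obs) / total


@pytest.mark.parametrize(
    "counts, expected",
    [((100, 0, 0), 1.0), ((1, 2, 1), 1.0), ((3, 0, 3), 20 / 924)],
)
def test_hwe_examples(counts, expected):
    assert hwe_test(*counts) == pytest.approx(expected)


def test_hwe_matches_enumeration_oracle_exhaustively():
    """Exact test equals brute-force enumeration for all tables with <= 30 alleles."""
    for n in range(1, 16):  # n subjects -> 2n alleles <= 30
        for nAa in range(n + 1):
            for naa in range(n - nAa + 1):
                nAA = n - nAa - naa
                got = hwe_test(nAA, nAa, naa)
                want = _hwe_bruteforce(nAA, nAa, naa)
                assert got == pytest.approx(want, rel=1e-9), (nAA, nAa, naa)


def test_hwe_calibration_under_equilibrium():
    """At MAF 0.3 and n = 10,000 the exact test rejects at ~nominal 5%."""
    rng = np.random.default_rng(42)
    p = 0.3
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
    rej = 0
    reps = 2000
    for _ in range(reps):
        c = rng.multinomial(10000, probs)
        if hwe_test(int(c[0]), int(c[1]), int(c[2])) < 0.05:
            rej += 1
    assert rej / reps == pytest.approx(0.05, abs=0.01)


def test_hwe_chisq_option_close_to_exact_at_large_n():
    assert hwe_test(500, 400, 100, method="chisq") == pytest.approx(
        hwe_test(500, 400, 100), rel=0.5
    )


class TestQCFilter:
    def _toy_matrix(self):
        n = 40
        rng = np.random.default_rng(3)
        clean = rng.binomial(2, 0.3, n).astype(np.int8)
        low_cr = clean.copy()
        low_cr[: n // 2] = MISSING  # call rate 0.5
        rare = np.zeros(n, dtype=np.int8)
        rare[0] = 1  # maf 1/80
        hwe_bad = np.array([0] * 20 + [2] * 20, dtype=np.int8)  # no hets
        snps = [
            SNPRecord("ok", "1", 10, "A", "G", clean),
            SNPRecord("cr", "2", 20, "A", "G", low_cr),
            SNPRecord("rare", "3", 30, "A", "G", rare),
            SNPRecord("hwe", "4", 40, "A", "G", hwe_bad),
            SNPRecord("sex", "X", 50, "A", "G", clean),
        ]
        return GenotypeMatrix(subjects=[f"s{i}" for i in range(n)], snps=snps)

    def test_each_rule_fires(self):
        gm = self._toy_matrix()
        filt, report = qc_filter(gm, QCThresholds(hwe_p_min=0.05))
        assert filt.snp_ids == ["ok"]
        rules = dict(zip(report["snp_id"], report["rule"]))
        assert rules == {
            "cr": "call_rate", "rare": "maf", "hwe": "hwe", "sex": "non_autosomal",
        }

    def test_permissive_thresholds_identity(self):
        gm = self._toy_matrix()
        th = QCThresholds(min_call_rate=0.0, hwe_p_min=0.0, maf_min=0.0, autosomes_only=False)
        filt, report = qc_filter(gm, th)
        assert filt.snp_ids == gm.snp_ids
        assert len(report) == 0

    def test_empty_matrix(self):
        gm = GenotypeMatrix(subjects=["a"], snps=[])
        filt, _ = qc_filter(gm)
        assert filt.n_snps == 0

    def test_idempotent(self):
        gm = self._toy_matrix()
        once, _ = qc_filter(gm, QCThresholds(hwe_p_min=0.05))
        twice, report = qc_filter(once, QCThresholds(hwe_p_min=0.05))
        assert twice.snp_ids == once.snp_ids
        assert len(report) == 0


class TestBinarize:
    subjects = ["a", "b", "c", "d"]

    def test_dominant_drops_missing(self):
        task = binarize(_snp([0, 1, 2, MISSING]), self.subjects, "dominant")
        assert task.subjects == ("a", "b", "c")
        assert list(task.labels) == [0, 1, 1]

    def test_recessive(self):
        task = binarize(_snp([0, 1, 2]), self.subjects[:3], "recessive")
        assert list(task.labels) == [0, 0, 1]

    def test_monomorphic_flag(self):
        task = binarize(_snp([0, 0, 0]), self.subjects[:3], "dominant")
        assert task.is_monomorphic

    def test_genotype_counts(self):
        assert genotype_counts(_snp([0, 1, 1, 2, MISSING])) == (1, 2, 1)
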