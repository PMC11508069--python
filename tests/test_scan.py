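"""Genome scan, ranking, overlap and the fine-tuning permutation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imgwas.cohort import CausalEffect, CohortConfig, generate_cohort
from imgwas.genotypes import MISSING, SNPRecord
from imgwas.scan import (
    STATUS_MIN_CLASS,
    STATUS_MONO,
    STATUS_SCORED,
    _permute_subject_labels,
    finetune_snp,
    genome_scan,
    plane_overlap,
    rank_top,
    scan_snp,
)


@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = CohortConfig(n_subjects=60, n_snps=6, volume_shape=(16, 16, 16),
                       missing_rate=0.0, seed=4)
    return generate_cohort(cfg)


class TestScanSnp:
    def test_planted_effect_scores_high(self, causal_cohort):
        gm, ds, _ = causal_cohort
        res = scan_snp(gm, ds, "snp00005", "axial", classifier="linear", seed=1)
        assert res.status == STATUS_SCORED
        assert res.metrics.mcc >= 0.5
        assert res.counts.total == res.counts.tp + res.counts.tn + res.counts.fp + res.counts.fn

    def test_monomorphic_snp_skipped(self, tiny_cohort):
        gm, ds, _ = tiny_cohort
        mono = SNPRecord("mono", "1", 5, "A", "G",
                         np.zeros(gm.n_subjects, dtype=np.int8))
        gm2 = type(gm)(subjects=list(gm.subjects), snps=gm.snps + [mono])
        res = scan_snp(gm2, ds, "mono", "axial", seed=0)
        assert res.status == STATUS_MONO
        assert res.metrics is None

    def test_tiny_minor_class_skipped(self, tiny_cohort):
        gm, ds, _ = tiny_cohort
        g = np.zeros(gm.n_subjects, dtype=np.int8)
        g[0] = 1
        rare = SNPRecord("rare", "1", 6, "A", "G", g)
        gm2 = type(gm)(subjects=list(gm.subjects), snps=gm.snps + [rare])
        res = scan_snp(gm2, ds, "rare", "axial", seed=0)
        assert res.status == STATUS_MIN_CLASS


class TestGenomeScan:
    def test_row_count_and_determinism(self, tiny_cohort):
        gm, ds, _ = tiny_cohort
        t1 = genome_scan(gm, ds, seed=5)
        t2 = genome_scan(gm, ds, seed=5)
        assert len(t1) == gm.n_snps * 3
        pd.testing.assert_frame_equal(t1, t2)

    def test_resumable(self, tiny_cohort, tmp_path):
        gm, ds, _ = tiny_cohort
        out = tmp_path / "scan.tsv"
        full = genome_scan(gm, ds, planes=("axial",), seed=5, out_tsv=out)
        # truncate the file to 3 rows and resume
        partial = pd.read_csv(out, sep="\t").head(3)
        partial.to_csv(out, sep="\t", index=False)
        resumed = genome_scan(gm, ds, planes=("axial",), seed=5, out_tsv=out)
        assert len(resumed) == len(full)
        assert set(resumed["snp_id"]) == set(full["snp_id"])


class TestRankTop:
    def _frame(self, entries):
        rows = []
        for snp_id, plane, m in entries:
            rows.append({"snp_id": snp_id, "plane": plane, "status": STATUS_SCORED,
                         "mcc": m, "macro_f1": m})
        return pd.DataFrame(rows)

    def test_descending_selection(self):
        df = self._frame([("a", "axial", 0.5), ("b", "axial", 0.3), ("c", "axial", 0.1)])
        assert rank_top(df, 2)["axial"] == ["a", "b"]

    def test_tie_broken_lexicographically(self):
        df = self._frame([("z", "axial", 0.3), ("a", "axial", 0.3), ("m", "axial", 0.9)])
        assert rank_top(df, 2)["axial"] == ["m", "a"]

    def test_k_exceeding_rows_returns_all(self):
        df = self._frame([("a", "axial", 0.1)])
        assert rank_top(df, 10)["axial"] == ["a"]

    def test_planted_snps_outrank_null(self, causal_rank_wins):
        assert all(causal_rank_wins)


class TestPlaneOverlap:
    def test_identical_lists(self):
        tops = {p: ["a", "b", "c", "d", "e"] for p in ("axial", "coronal", "sagittal")}
        counts = plane_overlap(tops)
        assert counts["triple"] == 5 and counts["union"] == 5

    def test_disjoint_lists(self):
        tops = {"axial": list("abcde"), "coronal": list("fghij"), "sagittal": list("klmno")}
        counts = plane_overlap(tops)
        assert counts["triple"] == 0 and counts["union"] == 15

    def test_partial_overlap_by_hand(self):
        tops = {"axial": list("abc"), "coronal": list("bcd"), "sagittal": list("cde")}
        counts = plane_overlap(tops)
        assert counts["triple"] == 1
        assert counts["union"] == 5
        assert counts["axial_only"] == 1 and counts["sagittal_only"] == 1
        assert counts["axial_coronal_only"] == 1  # {b}
        assert counts["coronal_sagittal_only"] == 1  # {d}
        assert counts["axial_sagittal_only"] == 0


class TestFineTune:
    def test_strong_effect_significant(self, causal_cohort):
        gm, ds, _ = causal_cohort
        rep = finetune_snp(gm, ds, "snp00005", "axial", classifier="linear",
                           n_real=5, n_perm=5, seed=1)
        assert len(rep.real["mcc"]) == 5 and len(rep.permuted["mcc"]) == 5
        assert rep.tests["mcc"].p_value < 0.01
        assert rep.tests["macro_f1"].p_value < 0.01

    def test_null_pvalue_fraction_near_nominal(self, finetune_null_pvalues):
        frac = float(np.mean(finetune_null_pvalues < 0.05))
        assert frac == pytest.approx(0.05, abs=0.07)

    def test_null_pvalues_not_anticonservative(self, finetune_null_pvalues):
        """p-values on null SNPs are stochastically >= uniform (KS check)."""
        ks = stats.kstest(finetune_null_pvalues, "uniform", alternative="greater")
        assert ks.pvalue > 0.05

    def test_permutation_preserves_class_proportions(self):
        labels = {f"s{i}": int(i < 7) for i in range(20)}
        rng = np.random.default_rng(0)
        for _ in range(10):
            shuffled = _permute_subject_labels(labels, rng)
            assert sorted(shuffled.values()) == sorted(labels.values())
            assert set(shuffled) == set(labels)

    def test_degenerate_metrics_give_p_one(self):
        from imgwas.metrics import two_sample_t

        res = two_sample_t([0.5] * 5, [0.5] * 5)
        assert res.p_value == 1.0 and res.degenerate

    def test_significance_monotone_in_effect_size(self):
        """Mean fine-tuning -log10(p) does not decrease with the planted
        effect size (averaged over generator seeds)."""
        levels = (0.0, 0.4, 1.0)
        means = []
        for beta in levels:
            logs = []
            for s in range(5):
                effects = () if beta == 0 else (CausalEffect("snp00002", beta=beta, radius=5.0),)
                cfg = CohortConfig(n_subjects=100, n_snps=4, volume_shape=(24, 24, 24),
                                   effects=effects, seed=200 + s)
                gm, ds, _ = generate_cohort(cfg)
                rep = finetune_snp(gm, ds, "snp00002", "axial", classifier="linear",
                                   n_real=5, n_perm=5, seed=s)
                logs.append(-np.log10(rep.tests["mcc"].p_value))
            means.append(float(np.mean(logs)))
        assert means[0] <= means[1] + 0.3  # small slack for the null level
        assert means[1] <= means[2]
        assert means[2] > means[0]

    def test_report_frame_shape(self, causal_cohort):
        gm, ds, _ = causal_cohort
        rep = finetune_snp(gm, ds, "snp00005", "axial", classifier="linear",
                           n_real=3, n_perm=3, seed=2)
        frame = rep.to_frame()
        assert len(frame) == 2 * (3 + 3)  # two metrics, real + permuted reps
        assert set(frame["run_kind"]) == {"real", "permuted"}
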