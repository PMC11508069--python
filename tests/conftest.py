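"""Shared fixtures.

Expensive end-to-end computations (cohort generation, scans, CNN training)
are session-scoped so that module tests and the acceptance suite assert on
the same results without recomputing them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from imgwas.classifier import TrainConfig
from imgwas.cohort import CausalEffect, CohortConfig, generate_cohort
from imgwas.scan import STATUS_SCORED, finetune_snp, genome_scan

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="Precision loss occurred")


@pytest.fixture(scope="session")
def causal_cohort():
    """150 subjects, 30 SNPs, one strong additive (mean_blob) causal SNP."""
    cfg = CohortConfig(
        n_subjects=150, n_snps=30, volume_shape=(32, 32, 32),
        effects=(CausalEffect("snp00005", beta=1.0, radius=6.0),), seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """120 subjects, 40 SNPs, no genotype-image association."""
    cfg = CohortConfig(n_subjects=120, n_snps=40, volume_shape=(32, 32, 32), seed=9)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def texture_cohort():
    """Mean-preserving variance effect: carriers get 3x noise sd in the blob."""
    cfg = CohortConfig(
        n_subjects=200, n_snps=10, volume_shape=(32, 32, 32), noise_sd=0.2,
        scans_per_subject_rate=0.5,
        effects=(CausalEffect("snp00003", beta=8.0, kind="texture_variance", radius=7.0),),
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_scan_big():
    """Genome scan of an association-free cohort at the default image size."""
    cfg = CohortConfig(n_subjects=200, n_snps=300, seed=1)
    gm, ds, _ = generate_cohort(cfg)
    table = genome_scan(gm, ds, planes=("axial",), classifier="linear", seed=1)
    return table


@pytest.fixture(scope="session")
def finetune_null_pvalues(null_cohort):
    """Fine-tuning MCC p-values for every SNP of the null cohort (5+5 retrains)."""
    gm, ds, _ = null_cohort
    pvals = []
    for sid in gm.snp_ids:
        rep = finetune_snp(gm, ds, sid, "axial", classifier="linear",
                           n_real=5, n_perm=5, seed=2)
        pvals.append(rep.tests["mcc"].p_value)
    return np.array(pvals)


@pytest.fixture(scope="session")
def causal_rank_wins():
    """Across generator seeds: does the planted causal SNP beat the null median?"""
    wins = []
    for s in range(8):
        cfg = CohortConfig(
            n_subjects=120, n_snps=20, volume_shape=(32, 32, 32),
            effects=(CausalEffect("snp00003", beta=1.0, radius=6.0),), seed=100 + s,
        )
        gm, ds, _ = generate_cohort(cfg)
        table = genome_scan(gm, ds, planes=("axial",), classifier="linear", seed=s)
        scored = table[table["status"] == STATUS_SCORED]
        causal = scored[scored["snp_id"] == "snp00003"]
        null_median = scored[scored["snp_id"] != "snp00003"]["mcc"].median()
        wins.append(len(causal) == 1 and float(causal["mcc"].iloc[0]) > null_median)
    return wins


@pytest.fixture(scope="session")
def saliency_setup():
    """CNN trained on a mean_blob causal SNP at the default slice size, with
    the pieces a localization check needs."""
    from imgwas.classifier import CNNSpec, fit_classifier
    from imgwas.genotypes import binarize
    from imgwas.scan import _task_split
    from imgwas.splitting import materialize

    cfg = CohortConfig(
        n_subjects=150, n_snps=5, volume_shape=(64, 64, 64),
        scans_per_subject_rate=0.5,
        effects=(CausalEffect("snp00002", beta=3.0, radius=10.0),), seed=5,
    )
    gm, ds, truth = generate_cohort(cfg)
    task = binarize(gm.get("snp00002"), gm.subjects)
    split = _task_split(task, 1)
    labels = dict(zip(task.subjects, (int(v) for v in task.labels)))
    train, val, test = materialize(split, ds, labels, "axial")
    tc = TrainConfig(max_epochs=20, early_stop_patience=20, learning_rate=3e-3, seed=2)
    model = fit_classifier("cnn", train, val, CNNSpec(), tc)
    return model, test, truth


@pytest.fixture(scope="session")
def sim_grid_default():
    """The reduced simulation grid (10 mu x 3 n x 3 prop, 3 reps, seed 1)."""
    from imgwas.simulation import run_grid

    return run_grid(seed=1)
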