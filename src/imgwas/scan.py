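"""The classification-based genome scan, ranking, plane overlap and the
fine-tuning permutation statistic.

For each (SNP, plane) pair the pipeline is: pool genotypes into two classes,
drop missing-call subjects, draw a subject-grouped 7:1:2 split (seeded per
SNP so scans are reproducible and resumable), train a classifier and score
the held-out test set with MCC and macro F1. SNPs whose pooled task is
monomorphic or whose minor class is too small are recorded with a skip
status rather than an error.

The fine-tuning step retrains the classifier n_real times on the true
labels and n_perm times after permuting subject labels (fresh permutation
per repetition, class proportions preserved), then compares the two metric
samples with a one-sided Welch t-test — "is this task classifiable beyond
chance?".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import derive_seed
from .classifier import CNNSpec, TrainConfig, evaluate, fit_classifier
from .genotypes import BinaryTask, GenotypeMatrix, MonomorphicTaskError, binarize
from .imaging import PLANES, ImagingDataset
from .metrics import ConfusionCounts, MetricPair, TestResult, two_sample_t
from .splitting import materialize, subject_split

logger = logging.getLogger(__name__)

SCAN_COLUMNS = [
    "snp_id", "chrom", "pos", "plane", "status",
    "tp", "tn", "fp", "fn", "mcc", "macro_f1", "n0", "n1",
]

STATUS_SCORED = "scored"
STATUS_MONO = "skipped_monomorphic"
STATUS_MIN_CLASS = "skipped_min_class"


@dataclass
class ScanResult:
    snp_id: str
    chrom: str
    pos: int
    plane: str
    status: str
    counts: ConfusionCounts | None = None
    metrics: MetricPair | None = None
    n0: int = 0
    n1: int = 0

    def to_row(self) -> dict:
        row = {
            "snp_id": self.snp_id, "chrom": self.chrom, "pos": self.pos,
            "plane": self.plane, "status": self.status,
            "tp": np.nan, "tn": np.nan, "fp": np.nan, "fn": np.nan,
            "mcc": np.nan, "macro_f1": np.nan, "n0": self.n0, "n1": self.n1,
        }
        if self.status == STATUS_SCORED:
            row.update(
                tp=self.counts.tp, tn=self.counts.tn,
                fp=self.counts.fp, fn=self.counts.fn,
                mcc=self.metrics.mcc, macro_f1=self.metrics.macro_f1,
            )
        return row


@dataclass
class FineTuneReport:
    snp_id: str
    plane: str
    real: dict[str, list[float]]  # metric name -> values per real retrain
    permuted: dict[str, list[float]]
    tests: dict[str, TestResult]  # metric name -> one-sided t-test result

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric in self.real:
            t = self.tests[metric]
            for kind, vals in (("real", self.real[metric]), ("permuted", self.permuted[metric])):
                for i, v in enumerate(vals):
                    rows.append(
                        {
                            "snp_id": self.snp_id, "plane": self.plane,
                            "metric": metric, "run_kind": kind, "rep": i,
                            "value": v, "t_statistic": t.statistic,
                            "p_value": t.p_value, "degenerate": t.degenerate,
                        }
                    )
        return pd.DataFrame(rows)


def _task_split(task: BinaryTask, seed: int):
    split_seed = derive_seed(seed, "split", task.snp_id)
    return subject_split(list(task.subjects), seed=split_seed)


def scan_snp(
    gm: GenotypeMatrix,
    ds: ImagingDataset,
    snp_id: str,
    plane: str,
    model: str = "dominant",
    classifier: str = "linear",
    spec: CNNSpec = CNNSpec(),
    cfg: TrainConfig = TrainConfig(),
    seed: int = 0,
    min_class_subjects: int = 5,
) -> ScanResult:
    """Score one (SNP, plane) task; failures are encoded in the status."""
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}")
    snp = gm.get(snp_id)
    result = ScanResult(snp_id=snp_id, chrom=snp.chrom, pos=snp.pos, plane=plane, status=STATUS_SCORED)
    task = binarize(snp, gm.subjects, model=model)
    result.n0, result.n1 = task.class_sizes
    if task.is_monomorphic:
        result.status = STATUS_MONO
        return result
    if min(task.class_sizes) < min_class_subjects:
        result.status = STATUS_MIN_CLASS
        return result
    split = _task_split(task, seed)
    labels = dict(zip(task.subjects, (int(v) for v in task.labels)))
    try:
        train, val, test = materialize(split, ds, labels, plane)
        run_cfg = _reseed(cfg, derive_seed(seed, "train", snp_id, plane))
        model_obj = fit_classifier(classifier, train, val, spec, run_cfg)
    except MonomorphicTaskError:
        result.status = STATUS_MIN_CLASS
        return result
    if len(test) == 0:
        result.status = STATUS_MIN_CLASS
        return result
    counts, metrics = evaluate(model_obj, test)
    result.counts, result.metrics = counts, metrics
    return result


def _reseed(cfg: TrainConfig, seed: int) -> TrainConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed)


def genome_scan(
    gm: GenotypeMatrix,
    ds: ImagingDataset,
    planes=PLANES,
    model: str = "dominant",
    classifier: str = "linear",
    spec: CNNSpec = CNNSpec(),
    cfg: TrainConfig = TrainConfig(),
    seed: int = 0,
    min_class_subjects: int = 5,
    out_tsv=None,
) -> pd.DataFrame:
    """Scan every SNP in every requested plane; one row per (SNP, plane).

    If ``out_tsv`` exists, rows already present there are not recomputed
    (resumable scans); each newly scored row is appended immediately.
    """
    done: set[tuple[str, str]] = set()
    rows: list[dict] = []
    out_path = Path(out_tsv) if out_tsv is not None else None
    if out_path is not None and out_path.exists():
        prev = pd.read_csv(out_path, sep="\t")
        rows = prev.to_dict("records")
        done = {(str(r["snp_id"]), str(r["plane"])) for r in rows}
    header_written = out_path is not None and out_path.exists()
    for snp_id in gm.snp_ids:
        for plane in planes:
            if (snp_id, plane) in done:
                continue
            res = scan_snp(
                gm, ds, snp_id, plane, model=model, classifier=classifier,
                spec=spec, cfg=cfg, seed=seed, min_class_subjects=min_class_subjects,
            )
            row = res.to_row()
            rows.append(row)
            if out_path is not None:
                pd.DataFrame([row], columns=SCAN_COLUMNS).to_csv(
                    out_path, sep="\t", index=False, mode="a" if header_written else "w",
                    header=not header_written,
                )
                header_written = True
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def rank_top(results: pd.DataFrame, k: int, metric: str = "mcc") -> dict[str, list[str]]:
    """Per-plane top-k SNP ids, descending by metric; ties broken by the
    lexicographically smaller SNP id."""
    if metric not in ("mcc", "macro_f1"):
        raise ValueError("metric must be 'mcc' or 'macro_f1'")
    scored = results[results["status"] == STATUS_SCORED]
    tops: dict[str, list[str]] = {}
    for plane, sub in scored.groupby("plane"):
        if k > len(sub):
            logger.warning("k=%d exceeds %d scored rows in plane %s; returning all", k, len(sub), plane)
        ordered = sub.sort_values([metric, "snp_id"], ascending=[False, True], kind="mergesort")
        tops[str(plane)] = ordered["snp_id"].head(k).tolist()
    return tops


def plane_overlap(tops: dict[str, list[str]]) -> dict[str, int]:
    """Three-set Venn counts over the per-plane top lists.

    Keys: '<plane>_only' per plane, '<a>_<b>_only' per pair (SNPs in exactly
    those two planes), 'triple' and 'union'.
    """
    if len(tops) != 3:
        raise ValueError("plane_overlap expects exactly three lists")
    names = list(tops)
    sets = {n: set(v) for n, v in tops.items()}
    a, b, c = (sets[n] for n in names)
    out: dict[str, int] = {}
    out[f"{names[0]}_only"] = len(a - b - c)
    out[f"{names[1]}_only"] = len(b - a - c)
    out[f"{names[2]}_only"] = len(c - a - b)
    out[f"{names[0]}_{names[1]}_only"] = len((a & b) - c)
    out[f"{names[0]}_{names[2]}_only"] = len((a & c) - b)
    out[f"{names[1]}_{names[2]}_only"] = len((b & c) - a)
    out["triple"] = len(a & b & c)
    out["union"] = len(a | b | c)
    return out


def _permute_subject_labels(labels: dict[str, int], rng) -> dict[str, int]:
    subjects = list(labels)
    values = np.array([labels[s] for s in subjects])
    return dict(zip(subjects, (int(v) for v in values[rng.permutation(len(values))])))


def finetune_snp(
    gm: GenotypeMatrix,
    ds: ImagingDataset,
    snp_id: str,
    plane: str,
    model: str = "dominant",
    classifier: str = "linear",
    spec: CNNSpec = CNNSpec(),
    cfg: TrainConfig = TrainConfig(),
    n_real: int = 20,
    n_perm: int = 20,
    seed: int = 0,
    permute_at: str = "subject",
) -> FineTuneReport:
    """Retrain-vs-permutation significance for one (SNP, plane) task.

    The original split is reused for every repetition; real repetitions vary
    only the training seed, permuted repetitions additionally shuffle the
    labels (subject-level by default so all scans of a subject move
    together; 'image' shuffles scan labels individually).
    """
    if permute_at not in ("subject", "image"):
        raise ValueError("permute_at must be 'subject' or 'image'")
    snp = gm.get(snp_id)
    task = binarize(snp, gm.subjects, model=model)
    if task.is_monomorphic:
        raise MonomorphicTaskError(f"SNP {snp_id} is monomorphic after pooling")
    split = _task_split(task, seed)
    labels = dict(zip(task.subjects, (int(v) for v in task.labels)))

    def run(run_labels: dict[str, int], run_seed: int, shuffle_images: bool = False) -> MetricPair:
        train, val, test = materialize(split, ds, run_labels, plane)
        run_cfg = _reseed(cfg, run_seed)
        if shuffle_images:
            # Shuffle scan labels within each part with the run's rng.
            rng = np.random.default_rng(derive_seed(run_seed, "imageperm"))
            for part in (train, val, test):
                part.labels = part.labels[rng.permutation(len(part.labels))]
        model_obj = fit_classifier(classifier, train, val, spec, run_cfg)
        _, metrics = evaluate(model_obj, test)
        return metrics

    real: dict[str, list[float]] = {"mcc": [], "macro_f1": []}
    perm: dict[str, list[float]] = {"mcc": [], "macro_f1": []}
    for r in range(n_real):
        m = run(labels, derive_seed(seed, "real", snp_id, plane, r))
        real["mcc"].append(m.mcc)
        real["macro_f1"].append(m.macro_f1)
    for r in range(n_perm):
        perm_rng = np.random.default_rng(derive_seed(seed, "perm", snp_id, plane, r))
        if permute_at == "subject":
            shuffled = _permute_subject_labels(labels, perm_rng)
            m = run(shuffled, derive_seed(seed, "permtrain", snp_id, plane, r))
        else:
            m = run(labels, derive_seed(seed, "permtrain", snp_id, plane, r), shuffle_images=True)
        perm["mcc"].append(m.mcc)
        perm["macro_f1"].append(m.macro_f1)
    tests = {
        metric: two_sample_t(real[metric], perm[metric], sided="one", direction="greater")
        for metric in real
    }
    return FineTuneReport(snp_id=snp_id, plane=plane, real=real, permuted=perm, tests=tests)
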