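"""Univariate testing-vs-classification simulation.

Data are drawn from two normal distributions N(0, 1) and N(mu, 1) with
0.2 <= mu <= 2, total sample size n in the thousands and a configurable
major-class proportion. On each sample both strategies are applied: a
two-sided two-sample (Welch) t-test on the full sample, and a depth-limited
decision tree trained on a stratified 70% subsample and scored with MCC and
macro F1 on the held-out 30%. The closed-form Gaussian KL divergence
(mu^2 / 2 at unit variance) accompanies each record. The grid summary
reports Spearman correlations of -log10(p) against the classification
metrics and of the KLD against both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import derive_seed
from .metrics import gaussian_kld, metric_pair, spearman_corr, two_sample_t

DEFAULT_MU = tuple(np.round(np.arange(0.2, 2.01, 0.2), 10))
DEFAULT_N = (3000, 5000, 7000)
DEFAULT_PROP = (0.5, 0.7, 0.9)

_P_FLOOR = 1e-300  # guard for -log10 of underflowed p-values


@dataclass(frozen=True)
class SimCell:
    mu: float
    n: int
    major_prop: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.major_prop < 1.0:
            raise ValueError("major_prop must be in (0, 1)")
        if self.n < 10:
            raise ValueError("n must be at least 10")


@dataclass(frozen=True)
class SimRecord:
    cell: SimCell
    p_ttest: float
    mcc: float
    macro_f1: float
    kld: float


def simulate_cell(cell: SimCell, tree_depth: int = 2, min_leaf: int = 5) -> SimRecord:
    """Run both strategies on one simulated two-class sample."""
    from sklearn.model_selection import train_test_split
    from sklearn.tree import DecisionTreeClassifier

    n_major = int(round(cell.n * cell.major_prop))
    n_minor = cell.n - n_major
    if min(n_major, n_minor) < 2:
        raise ValueError("degenerate class size < 2")
    rng = np.random.default_rng(cell.seed)
    x_major = rng.normal(0.0, 1.0, size=n_major)
    x_minor = rng.normal(cell.mu, 1.0, size=n_minor)
    t = two_sample_t(x_major, x_minor, sided="two")

    x = np.concatenate([x_major, x_minor]).reshape(-1, 1)
    y = np.concatenate([np.zeros(n_major, dtype=int), np.ones(n_minor, dtype=int)])
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=0.3, stratify=y, random_state=derive_seed(cell.seed, "holdout")
    )
    tree = DecisionTreeClassifier(
        max_depth=tree_depth,
        min_samples_leaf=min_leaf,
        random_state=derive_seed(cell.seed, "tree"),
    ).fit(x_tr, y_tr)
    m = metric_pair(y_te, tree.predict(x_te))
    return SimRecord(
        cell=cell,
        p_ttest=max(t.p_value, _P_FLOOR),
        mcc=m.mcc,
        macro_f1=m.macro_f1,
        kld=gaussian_kld(0.0, 1.0, cell.mu, 1.0),
    )


def run_grid(
    mu_values=DEFAULT_MU,
    n_values=DEFAULT_N,
    prop_values=DEFAULT_PROP,
    reps: int = 3,
    seed: int = 1,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate every (mu, n, prop) cell ``reps`` times and summarize.

    Returns the per-record table and the Spearman correlation summary:
    neglogp_vs_mcc, neglogp_vs_macro_f1, kld_vs_neglogp, kld_vs_mcc.
    """
    if not (len(mu_values) and len(n_values) and len(prop_values)):
        raise ValueError("grids must be non-empty")
    rows = []
    for mu in mu_values:
        for n in n_values:
            for prop in prop_values:
                for rep in range(reps):
                    cell = SimCell(
                        mu=float(mu), n=int(n), major_prop=float(prop),
                        seed=derive_seed(seed, "cell", mu, n, prop, rep),
                    )
                    rec = simulate_cell(cell)
                    rows.append(
                        {
                            "mu": cell.mu, "n": cell.n, "major_prop": cell.major_prop,
                            "rep": rep, "p_ttest": rec.p_ttest,
                            "neglog10_p": -np.log10(rec.p_ttest),
                            "mcc": rec.mcc, "macro_f1": rec.macro_f1, "kld": rec.kld,
                        }
                    )
    table = pd.DataFrame(rows)
    summary = {
        "neglogp_vs_mcc": spearman_corr(table["neglog10_p"], table["mcc"]),
        "neglogp_vs_macro_f1": spearman_corr(table["neglog10_p"], table["macro_f1"]),
        "kld_vs_neglogp": spearman_corr(table["kld"], table["neglog10_p"]),
        "kld_vs_mcc": spearman_corr(table["kld"], table["mcc"]),
    }
    return table, summary
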