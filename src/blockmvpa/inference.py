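"""Significance and precision of pooled decoding accuracies.

The balanced-block permutation test shuffles class labels at the block
level -- all scans of a block move together, respecting the temporal
autocorrelation of the hemodynamic response -- under the constraint that
within each grouping unit (session, session pair, or subject) the
original number of blocks per class is preserved.  For every permuted
labeling the full cross-validation is rerun, and the add-one Monte Carlo
p-value is reported:

    p = (1 + #{null >= observed}) / (1 + n_perm)

Precision of an observed accuracy with c correct and e incorrect scans
is summarized by the equal-tailed quantile interval of Beta(c+1, e+1),
the posterior of the accuracy under a uniform prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from sklearn.svm import SVC

from .decode import ClassifierResult, DecoderConfig, SymmetricMinMaxScaler, run_cv
from .features import FeatureDataset, FoldPlan


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    n_perm: int
    p_value: float
    seed: int


@dataclass
class AccuracyCI:
    c: int
    e: int
    level: float
    lower: float
    upper: float


def _blocks_by_unit(dataset: FeatureDataset) -> tuple[pd.DataFrame, np.ndarray]:
    """One row per block: (unit, block_id, label) plus scan->block index."""
    units = dataset.group_id if dataset.group_id is not None else dataset.session_id
    df = pd.DataFrame(
        {"unit": units, "block": dataset.block_id, "label": dataset.labels}
    )
    blocks = df.drop_duplicates("block").reset_index(drop=True)
    per_block_labels = df.groupby("block")["label"].nunique()
    if (per_block_labels > 1).any():
        raise ValueError("scans within a block must share one label")
    return blocks, units


def permute_block_labels(
    dataset: FeatureDataset, rng: np.random.Generator
) -> np.ndarray:
    """Random balanced relabeling of whole blocks; returns per-scan labels.

    Within each grouping unit the multiset of block labels is preserved
    (a uniform random permutation of the unit's label sequence), so the
    draw is uniform over balanced assignments.  Raises if any unit is
    unbalanced.
    """
    blocks, _ = _blocks_by_unit(dataset)
    counts = blocks.groupby(["unit", "label"]).size().unstack(fill_value=0)
    if counts.shape[1] != 2 or not (counts.iloc[:, 0] == counts.iloc[:, 1]).all():
        raise ValueError("balanced-block permutation requires balanced units")
    new_label = {}
    for _, grp in blocks.groupby("unit", sort=False):
        labels = grp["label"].to_numpy()
        shuffled = labels[rng.permutation(len(labels))]
        for b, lab in zip(grp["block"], shuffled):
            new_label[b] = lab
    return np.array([new_label[b] for b in dataset.block_id])


class _FoldKernelCache:
    """Precomputed per-fold Gram matrices for fast CV reruns.

    The [-1, 1] scaling is a function of the training *features* only,
    so under label permutations the scaled matrices -- and hence the
    linear-kernel Grams -- are unchanged.  Refitting the SVM on the
    precomputed Gram is therefore exactly equivalent to rerunning the
    full per-fold scale-fit-test chain with new labels.
    """

    def __init__(self, dataset: FeatureDataset, folds: FoldPlan, config: DecoderConfig):
        self.config = config
        self.folds = folds
        self.entries = []
        for train, test in folds.folds:
            scaler = SymmetricMinMaxScaler().fit(dataset.matrix[train])
            xtr = scaler.transform(dataset.matrix[train])
            xte = scaler.transform(dataset.matrix[test])
            self.entries.append(
                dict(train=train, test=test, gram_tr=xtr @ xtr.T, gram_te=xte @ xtr.T)
            )

    def accuracy(self, labels: np.ndarray) -> float:
        """Pooled CV accuracy for an arbitrary per-scan labeling."""
        pos = self.config.positive_class
        c = n = 0
        for entry in self.entries:
            y_tr = labels[entry["train"]]
            classes = np.unique(y_tr)
            if len(classes) != 2:
                raise ValueError("fold training labels must contain 2 classes")
            p = pos if pos in classes else classes[0]
            y_num = np.where(y_tr == p, 1, -1)
            svc = SVC(kernel="precomputed", C=self.config.penalty_C, tol=self.config.solver_tolerance)
            svc.fit(entry["gram_tr"], y_num)
            dv = svc.decision_function(entry["gram_te"])
            y_te = labels[entry["test"]]
            pred_pos = dv >= 0
            c += int(np.sum(np.where(pred_pos, p == y_te, (p != y_te))))
            n += len(y_te)
        return c / n


def permutation_test(
    dataset: FeatureDataset,
    folds: FoldPlan,
    config: DecoderConfig | None = None,
    n_perm: int = 300,
    seed: int = 0,
    observed: ClassifierResult | None = None,
) -> PermutationResult:
    """Balanced-block permutation test of the pooled CV accuracy.

    Permutations are sampled with replacement from the constrained
    assignment space; each one reruns the entire cross-validation
    (through a precomputed linear-kernel cache, which is exactly
    equivalent because the scaling step depends only on the training
    features, not the labels).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    config = config or DecoderConfig()
    rng = np.random.default_rng(seed)
    if observed is None:
        observed = run_cv(dataset, folds, config)
    cache = _FoldKernelCache(dataset, folds, config)
    null = np.empty(n_perm)
    for i in range(n_perm):
        labels = permute_block_labels(dataset, rng)
        null[i] = cache.accuracy(labels)
    p = (1.0 + np.sum(null >= observed.accuracy)) / (1.0 + n_perm)
    return PermutationResult(
        observed_accuracy=observed.accuracy,
        null_accuracies=null,
        n_perm=n_perm,
        p_value=float(p),
        seed=seed,
    )


def accuracy_ci(c: int, e: int, level: float = 0.95) -> AccuracyCI:
    """Equal-tailed Beta(c+1, e+1) interval for a pooled accuracy."""
    if c < 0 or e < 0:
        raise ValueError("c and e must be non-negative")
    if c + e < 1:
        raise ValueError("need at least one classified scan (c + e >= 1)")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = float(beta_dist.ppf(alpha / 2.0, c + 1, e + 1))
    upper = float(beta_dist.ppf(1.0 - alpha / 2.0, c + 1, e + 1))
    return AccuracyCI(c=c, e=e, level=level, lower=lower, upper=upper)
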