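"""Chronological nested cross-validation with per-electrode probability output.

The segment axis is cut into K+1 equal chronological folds, shared by all
electrodes (segment t of every electrode lands in the same fold, so a time
period can never appear in both train and test through different channels).
Split k (k = 1..K) trains on folds 1..k and tests on fold k+1; every test
segment is strictly later than every training segment.  Inside each split the
training set is again cut chronologically: the first 80% is the training
subset and the last 20% the validation set, on which a grid search selects the
hyperparameters by validation AUC (ties broken by declared grid order).  The
winning configuration is refit on the whole training set and scored on the
test fold.  For split k with fold size 30 and N_electrode electrodes this
gives N_train = k*30*N_electrode*80%, N_validation = k*30*N_electrode*20%,
N_test = 30*N_electrode.

The evaluation metric is the AUC of the ROC, computed as a rank statistic
(ties count 1/2), and the per-electrode output is the mean predicted SOZ
probability of the electrode's test segments, averaged over the K splits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .clf import FeatureMatrix, default_grid, make_model

__all__ = [
    "SplitPlan",
    "SplitResult",
    "plan_splits",
    "auc",
    "run_nested_cv",
    "electrode_probabilities",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitPlan:
    """Bookkeeping for K chronological splits over K+1 equal segment folds."""

    n_segments: int               # per electrode
    n_electrodes: int
    K: int = 5

    def __post_init__(self) -> None:
        if self.n_segments % (self.K + 1) != 0:
            raise ValueError(
                f"{self.n_segments} segments not divisible into {self.K + 1} "
                f"folds; trim the recording to a multiple of {self.K + 1} segments"
            )
        if self.n_segments < self.K + 1:
            raise ValueError("need at least one segment per fold")

    @property
    def fold_size(self) -> int:
        return self.n_segments // (self.K + 1)

    def train_segments(self, k: int) -> np.ndarray:
        """Segment ids of the training set of split k (folds 1..k)."""
        self._check_split(k)
        return np.arange(0, k * self.fold_size)

    def test_segments(self, k: int) -> np.ndarray:
        """Segment ids of the test set of split k (fold k+1)."""
        self._check_split(k)
        return np.arange(k * self.fold_size, (k + 1) * self.fold_size)

    def inner_split(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(training subset, validation set): first 80% / last 20% of the train set.

        Both parts are kept non-empty even for very small folds (the 80%
        cut is clamped to [1, size-1]).
        """
        train = self.train_segments(k)
        if train.size < 2:
            raise ValueError("training set too small for an inner 80/20 split")
        cut = int(round(0.8 * train.size))
        cut = max(1, min(train.size - 1, cut))
        return train[:cut], train[cut:]

    def sizes(self, k: int) -> dict[str, int]:
        """N_train / N_validation / N_test segment counts across all electrodes."""
        sub, val = self.inner_split(k)
        return {
            "N_train": sub.size * self.n_electrodes,
            "N_validation": val.size * self.n_electrodes,
            "N_test": self.test_segments(k).size * self.n_electrodes,
            "N_electrode": self.n_electrodes,
        }

    def _check_split(self, k: int) -> None:
        if not 1 <= k <= self.K:
            raise ValueError(f"split k must be in 1..{self.K}, got {k}")


def plan_splits(n_segments_per_electrode: int, n_electrodes: int, K: int = 5) -> SplitPlan:
    """Build the chronological split plan (errors if folds cannot be equal)."""
    return SplitPlan(n_segments=n_segments_per_electrode,
                     n_electrodes=n_electrodes, K=K)


def auc(scores, labels) -> float:
    """Area under the ROC curve as a rank statistic; ties contribute 1/2.

    Equals the Mann-Whitney U statistic of the positive group over n1*n2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n2 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


@dataclass
class SplitResult:
    """Outcome of a nested-CV run."""

    model_kind: str
    split_auc: list[float]                 # NaN where AUC was undefined
    chosen_params: list[dict]
    mean_auc: float
    std_auc: float
    electrode_probs: pd.DataFrame          # channel, label, probability
    split_sizes: list[dict] = field(default_factory=list)

    def summary(self) -> str:
        return (f"{self.model_kind}: AUC {self.mean_auc:.3f} +/- {self.std_auc:.3f} "
                f"over {len(self.split_auc)} splits")


def run_nested_cv(
    features: FeatureMatrix,
    model_kind: str,
    plan: SplitPlan,
    grid: list[dict] | None = None,
    seed: int = 0,
) -> SplitResult:
    """Nested chronological CV of one model kind over a feature matrix.

    Inner loop: every grid configuration is trained on the training subset and
    scored by AUC on the validation set; the best (first on ties, in grid
    order) is refit on the full training set with probability outputs enabled.
    Outer loop: test AUC per split, summarised as mean +/- std over the splits
    with defined AUC; splits whose validation or test set is single-class are
    recorded as NaN and excluded with a warning.
    """
    if grid is None:
        grid = default_grid(model_kind)
    X, y = np.asarray(features.X, dtype=float), features.y
    seg = features.segments
    split_aucs: list[float] = []
    chosen: list[dict] = []
    per_split_probs: list[pd.DataFrame] = []
    for k in range(1, plan.K + 1):
        sub_ids, val_ids = plan.inner_split(k)
        test_ids = plan.test_segments(k)
        sub = np.isin(seg, sub_ids)
        val = np.isin(seg, val_ids)
        train = np.isin(seg, plan.train_segments(k))
        test = np.isin(seg, test_ids)
        if np.unique(y[val]).size < 2 or np.unique(y[test]).size < 2:
            warnings.warn(
                f"split {k}: validation or test set is single-class; "
                "AUC recorded as missing"
            )
            split_aucs.append(np.nan)
            chosen.append({})
            continue
        best_auc, best_params = -np.inf, None
        for params in grid:
            m = make_model(model_kind, params, seed=seed)
            m.fit(X[sub], y[sub], X[val], y[val])
            a = auc(m.predict_score(X[val]), y[val])
            if a > best_auc:
                best_auc, best_params = a, params
        final = make_model(model_kind, best_params, seed=seed, probability=True)
        final.fit(X[train], y[train], X[val], y[val])
        test_auc = auc(final.predict_score(X[test]), y[test])
        log.info("split %d: params=%s val AUC=%.3f test AUC=%.3f",
                 k, best_params, best_auc, test_auc)
        split_aucs.append(test_auc)
        chosen.append(best_params)
        probs = final.predict_proba(X[test])
        per_split_probs.append(
            pd.DataFrame(
                {
                    "split": k,
                    "channel": features.meta.loc[test, "channel"].to_numpy(),
                    "y": y[test],
                    "prob": probs,
                }
            )
        )
    valid = [a for a in split_aucs if np.isfinite(a)]
    if not valid:
        raise ValueError("AUC undefined in every split")
    elec = electrode_probabilities(pd.concat(per_split_probs, ignore_index=True))
    return SplitResult(
        model_kind=model_kind,
        split_auc=split_aucs,
        chosen_params=chosen,
        mean_auc=float(np.mean(valid)),
        std_auc=float(np.std(valid)),
        electrode_probs=elec,
        split_sizes=[plan.sizes(k) for k in range(1, plan.K + 1)],
    )


def electrode_probabilities(per_segment: pd.DataFrame) -> pd.DataFrame:
    """Per-electrode SOZ probability: mean within each split, then across splits.

    ``per_segment`` needs columns split, channel, y, prob covering every test
    segment of every split.
    """
    if per_segment.empty:
        raise ValueError("no per-segment predictions given")
    by_split = (
        per_segment.groupby(["channel", "split"], sort=False)
        .agg(prob=("prob", "mean"), y=("y", "first"))
        .reset_index()
    )
    out = (
        by_split.groupby("channel", sort=False)
        .agg(probability=("prob", "mean"), y=("y", "first"))
        .reset_index()
    )
    out["label"] = np.where(out["y"] == 1, "SOZ", "NSOZ")
    return out[["channel", "label", "probability"]]
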