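"""Resampling-based stability feature selection.

In each of ``n_repeats x n_folds`` trials (default 100 x 5 = 500) the
training portion of a stratified split is tested per feature with the
Wilcoxon rank-sum statistic, survivors are kept at a Benjamini-Hochberg FDR
level, and redundant survivors (|Spearman rho| above a threshold against a
lower-p survivor) are discarded.  A feature's selection frequency is the
fraction of trials it survives; features above a frequency threshold form
the chosen pool.

Zone-stratified defaults: FDR 0.05 and frequency threshold 0.20 for the
all-lesion and PZ-only analyses; FDR 0.1 and frequency threshold 0.10 for
the TZ-only analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .stats import benjamini_hochberg, rank_sum_matrix, spearman_prune

logger = logging.getLogger(__name__)

ZONE_DEFAULTS = {"all": (0.05, 0.20), "PZ": (0.05, 0.20), "TZ": (0.10, 0.10)}


@dataclass
class SelectionConfig:
    n_repeats: int = 100
    n_folds: int = 5
    spearman_threshold: float = 0.5
    fdr: float = 0.05
    frequency_threshold: float = 0.20
    zone_filter: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if not 0 < self.frequency_threshold < 1:
            raise ValueError("frequency_threshold must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.zone_filter not in ("all", "PZ", "TZ"):
            raise ValueError("zone_filter must be one of all/PZ/TZ")

    @classmethod
    def for_zone(cls, zone: str, **kw) -> "SelectionConfig":
        fdr, freq = ZONE_DEFAULTS[zone]
        return cls(fdr=fdr, frequency_threshold=freq, zone_filter=zone, **kw)


@dataclass
class TrialSplit:
    repeat: int
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class SelectionResult:
    feature_names: list[str]
    frequencies: np.ndarray          # per-feature fraction of trials selected
    chosen: list[str]                # frequency > threshold
    per_trial_selected: np.ndarray   # (n_trials, n_features) bool, for audit
    n_trials: int
    config: SelectionConfig

    def frequency_table(self) -> pd.DataFrame:
        order = np.argsort(-self.frequencies, kind="stable")
        return pd.DataFrame({
            "Features": [self.feature_names[i] for i in order],
            "% Choices": [round(100 * self.frequencies[i])
                          for i in order],
        })


def partition_stratified(labels, n_folds: int, seed: int,
                         n_repeats: int = 1) -> list[TrialSplit]:
    """Repeated stratified k-fold splits preserving class balance per fold.

    Per-fold class counts are within +-1 of proportional (sklearn
    StratifiedKFold guarantee); deterministic given ``seed``.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than "
            f"n_folds={n_folds}")
    splits = []
    rng = np.random.default_rng(seed)
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        for fold, (train, test) in enumerate(skf.split(np.zeros_like(y), y)):
            splits.append(TrialSplit(rep, fold, train, test))
    return splits


class StabilitySelector(SelectorMixin, BaseEstimator):
    """Sklearn-style transformer running the full stability selection.

    Parameters mirror :class:`SelectionConfig`.  After ``fit``:

    ``frequencies_``
        per-feature selection frequency over the trials;
    ``support_``
        boolean mask of features above the frequency threshold;
    ``selected_features_``
        chosen column names (when fitted on a DataFrame);
    ``per_trial_selected_``
        (n_trials, n_features) boolean audit matrix.
    """

    def __init__(self, n_repeats=100, n_folds=5, fdr=0.05,
                 frequency_threshold=0.20, spearman_threshold=0.5,
                 random_state=0):
        self.n_repeats = n_repeats
        self.n_folds = n_folds
        self.fdr = fdr
        self.frequency_threshold = frequency_threshold
        self.spearman_threshold = spearman_threshold
        self.random_state = random_state

    def fit(self, X, y):
        names = (list(X.columns) if isinstance(X, pd.DataFrame)
                 else [f"x{i}" for i in range(np.asarray(X).shape[1])])
        Xv = np.asarray(X, dtype=float)
        yv = np.asarray(y)
        if np.isnan(Xv).any():
            raise ValueError("feature table contains missing values")
        splits = partition_stratified(yv, self.n_folds, self.random_state,
                                      n_repeats=self.n_repeats)
        n_feat = Xv.shape[1]
        trial_sel = np.zeros((len(splits), n_feat), dtype=bool)
        n_skipped = 0
        for t, split in enumerate(splits):
            tr = split.train_idx
            ytr = yv[tr]
            if np.unique(ytr).size < 2:
                n_skipped += 1
                continue
            Xtr = Xv[tr]
            p = rank_sum_matrix(Xtr, ytr == ytr.max())
            reject = benjamini_hochberg(p, self.fdr)
            if not reject.any():
                continue
            idx = np.flatnonzero(reject)
            keep = spearman_prune(Xtr[:, idx], p[idx],
                                  threshold=self.spearman_threshold)
            trial_sel[t, idx[keep]] = True
        if n_skipped:
            logger.warning("skipped %d degenerate trials", n_skipped)
        n_eff = len(splits) - n_skipped
        self.feature_names_ = names
        self.n_features_in_ = n_feat
        self.per_trial_selected_ = trial_sel
        self.n_trials_ = n_eff
        self.frequencies_ = trial_sel.sum(axis=0) / max(n_eff, 1)
        self.support_ = self.frequencies_ > self.frequency_threshold
        self.selected_features_ = [n for n, s in zip(names, self.support_) if s]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def result(self) -> SelectionResult:
        check_is_fitted(self, "support_")
        return SelectionResult(
            feature_names=self.feature_names_,
            frequencies=self.frequencies_,
            chosen=self.selected_features_,
            per_trial_selected=self.per_trial_selected_,
            n_trials=self.n_trials_,
            config=SelectionConfig(
                n_repeats=self.n_repeats, n_folds=self.n_folds,
                fdr=self.fdr, frequency_threshold=self.frequency_threshold,
                spearman_threshold=self.spearman_threshold,
                seed=self.random_state),
        )


def stability_select(feature_table: pd.DataFrame, labels,
                     config: SelectionConfig | None = None) -> SelectionResult:
    """Functional wrapper over :class:`StabilitySelector`."""
    cfg = config or SelectionConfig()
    sel = StabilitySelector(
        n_repeats=cfg.n_repeats, n_folds=cfg.n_folds, fdr=cfg.fdr,
        frequency_threshold=cfg.frequency_threshold,
        spearman_threshold=cfg.spearman_threshold, random_state=cfg.seed)
    sel.fit(feature_table, labels)
    res = sel.result()
    res.config = cfg
    return res
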