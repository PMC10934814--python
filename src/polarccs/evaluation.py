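"""Repeated-split performance protocol and comparison utilities.

The headline protocol: draw a random train/test split, tune hyperparameters
by 5-fold CV on the training part, train, predict the held-out part, record
the mean relative error (MRE, %); repeat many times with independently
derived seeds and summarise the MRE distribution.  With 88 records a 70/18
split is exactly an 80/20 split, which keeps positive- and negative-mode
evaluations on equal footing when one mode has more records.

Per-iteration seeds are derived from the master seed with a counter-based
scheme (``SeedSequence(master, spawn_key=(iteration,))``), so iteration *i*
is reproducible in isolation and a longer run extends — never resamples —
a shorter run with the same master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import PropertyDataset
from .svr import (
    DEFAULT_FEATURES,
    TUNING_MAX_ITER,
    _train_arrays,
    _tune_arrays,
)

__all__ = [
    "EvaluationResult",
    "LearningCurveResult",
    "ToolComparison",
    "mean_relative_error",
    "repeated_split_evaluation",
    "learning_curve",
    "compare_predictions",
    "cross_instrument_mre",
    "average_duplicate_ccs",
]


@dataclass
class EvaluationResult:
    """MRE distribution over repeated random splits (percentages)."""

    per_iteration_mre: np.ndarray
    n_train: int
    n_test: int
    seed: int

    @property
    def iterations(self) -> int:
        return len(self.per_iteration_mre)

    @property
    def mean_mre(self) -> float:
        return float(np.mean(self.per_iteration_mre))

    @property
    def sd_mre(self) -> float:
        """Standard deviation across iterations (ddof=1); the spread quoted
        alongside the mean, e.g. '1.7 ± 0.3%'."""
        if self.iterations < 2:
            return 0.0
        return float(np.std(self.per_iteration_mre, ddof=1))

    def to_dict(self) -> dict:
        return {
            "mean_mre_pct": self.mean_mre,
            "sd_mre_pct": self.sd_mre,
            "iterations": self.iterations,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "seed": self.seed,
        }


@dataclass
class LearningCurveResult:
    """One :class:`EvaluationResult` per training size, fixed test size."""

    results: dict[int, EvaluationResult]
    n_test: int

    def mean_mre(self) -> dict[int, float]:
        return {size: res.mean_mre for size, res in self.results.items()}


@dataclass
class ToolComparison:
    tool: str
    mre_pct: float
    n_matched: int
    unmatched: list[tuple[str, str]] = field(default_factory=list)


def mean_relative_error(predicted: Sequence[float], experimental: Sequence[float]) -> float:
    """MRE in percent: ``mean(|pred - exp| / exp) * 100``."""
    pred = np.asarray(predicted, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1 or len(pred) < 1:
        raise ValueError(f"length mismatch: {pred.shape} vs {exp.shape}")
    if np.any(exp <= 0):
        raise ValueError("experimental values must all be > 0")
    return float(np.mean(np.abs(pred - exp) / exp) * 100.0)


def _iteration_seeds(master_seed: int, iteration: int, n_streams: int = 2) -> list[int]:
    """Deterministic per-iteration integer seeds (< 2**31)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(iteration,))
    return [int(s % (2**31)) for s in ss.generate_state(n_streams, dtype=np.uint64)]


def repeated_split_evaluation(
    ds: PropertyDataset,
    n_train: int,
    n_test: int,
    iterations: int = 10_000,
    grid: dict | None = None,
    seed: int = 0,
    features: Sequence[str] = DEFAULT_FEATURES,
    folds: int = 5,
    solver_max_iter: int = TUNING_MAX_ITER,
) -> EvaluationResult:
    """Repeat: random split -> CV tuning -> train -> test MRE.

    The default iteration count of 10,000 eliminates split-sampling bias;
    pass a smaller count for scaled-down runs (the per-iteration seed scheme
    guarantees shorter runs are prefixes of longer ones).  ``solver_max_iter``
    caps SMO iterations per fit inside the protocol; -1 solves exactly.
    """
    n = len(ds)
    if n_train + n_test > n:
        raise ValueError(f"n_train + n_test = {n_train + n_test} exceeds {n} records")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    X = ds.feature_matrix(features)
    y = ds.ccs_values()
    feats = tuple(features)
    mre = np.empty(iterations)
    for i in range(iterations):
        split_seed, cv_seed = _iteration_seeds(seed, i)
        perm = np.random.default_rng(split_seed).permutation(n)
        tr = np.sort(perm[:n_train])
        te = np.sort(perm[n_train : n_train + n_test])
        hp = _tune_arrays(X[tr], y[tr], grid, folds, cv_seed, feats, max_iter=solver_max_iter)
        model = _train_arrays(X[tr], y[tr], hp, feats, max_iter=solver_max_iter)
        pred = model.decision_function(model.scaler.transform(X[te]))
        mre[i] = mean_relative_error(pred, y[te])
    return EvaluationResult(per_iteration_mre=mre, n_train=n_train, n_test=n_test, seed=seed)


def learning_curve(
    ds: PropertyDataset,
    train_sizes: Sequence[int],
    n_test: int = 20,
    iterations: int = 100,
    grid: dict | None = None,
    seed: int = 0,
    features: Sequence[str] = DEFAULT_FEATURES,
    folds: int = 5,
    solver_max_iter: int = TUNING_MAX_ITER,
) -> LearningCurveResult:
    """MRE as a function of training-set size at a fixed test size.

    The test size stays constant across training sizes so accuracies are
    comparable; each size uses its own deterministically derived seed
    stream.  Training sizes smaller than ``folds`` fall back to
    ``folds = n_train`` (leave-one-out at the smallest sizes).
    """
    sizes = list(train_sizes)
    if not sizes:
        raise ValueError("train_sizes must be non-empty")
    if max(sizes) + n_test > len(ds):
        raise ValueError(
            f"max train size {max(sizes)} + n_test {n_test} exceeds {len(ds)} records"
        )
    results: dict[int, EvaluationResult] = {}
    for k, size in enumerate(sizes):
        size_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(997, k)).generate_state(1)[0] % (2**31)
        )
        results[size] = repeated_split_evaluation(
            ds,
            n_train=size,
            n_test=n_test,
            iterations=iterations,
            grid=grid,
            seed=size_seed,
            features=features,
            folds=min(folds, size),
            solver_max_iter=solver_max_iter,
        )
    return LearningCurveResult(results=results, n_test=n_test)


def compare_predictions(ds: PropertyDataset, external: pd.DataFrame) -> list[ToolComparison]:
    """MRE of external tool predictions against experimental CCS.

    ``external`` columns: ``compound_id, adduct_type, tool, predicted_ccs``.
    Join key is (compound_id, adduct_type); unmatched external rows are
    reported, not dropped silently; duplicate predictions for one adduct use
    the first occurrence with a warning.
    """
    required = {"compound_id", "adduct_type", "tool", "predicted_ccs"}
    missing = required - set(external.columns)
    if missing:
        raise ValueError(f"external table missing columns {sorted(missing)}")
    experimental = {(rec.compound_id, rec.adduct_type): rec.ccs for rec in ds}
    comparisons: list[ToolComparison] = []
    for tool in pd.unique(external["tool"]):
        sub = external[external["tool"] == tool]
        dup = sub.duplicated(subset=["compound_id", "adduct_type"])
        if dup.any():
            warnings.warn(
                f"tool {tool!r}: {int(dup.sum())} duplicate predictions; using first occurrence"
            )
            sub = sub[~dup]
        pred, exp, unmatched = [], [], []
        for _, row in sub.iterrows():
            key = (row["compound_id"], row["adduct_type"])
            if key in experimental:
                pred.append(float(row["predicted_ccs"]))
                exp.append(experimental[key])
            else:
                unmatched.append(key)
        if not pred:
            raise ValueError(f"tool {tool!r}: no predictions match the dataset")
        comparisons.append(
            ToolComparison(
                tool=str(tool),
                mre_pct=mean_relative_error(pred, exp),
                n_matched=len(pred),
                unmatched=unmatched,
            )
        )
    return comparisons


def cross_instrument_mre(twim: PropertyDataset, dtim: PropertyDataset) -> tuple[float, int]:
    """Divergence of TWIM CCS from matched DTIM CCS.

    Inner join on (compound_id, adduct_type); the drift-tube value is the
    reference (denominator).  Returns ``(mre_pct, n_matched)``.
    """
    if len(twim) == 0 or len(dtim) == 0:
        raise ValueError("both datasets must be nonempty")
    dtim_ccs = {(rec.compound_id, rec.adduct_type): rec.ccs for rec in dtim}
    t_vals, d_vals = [], []
    for rec in twim:
        key = (rec.compound_id, rec.adduct_type)
        if key in dtim_ccs:
            t_vals.append(rec.ccs)
            d_vals.append(dtim_ccs[key])
    if not t_vals:
        raise ValueError("no matched (compound_id, adduct_type) pairs between instruments")
    return mean_relative_error(t_vals, d_vals), len(t_vals)


def average_duplicate_ccs(df: pd.DataFrame) -> pd.DataFrame:
    """Average CCS over duplicate (compound_id, adduct_type) rows.

    Explicit pre-processing for multi-source tables (e.g. databases that
    report several drift-tube values for the same adduct); the reader itself
    rejects duplicates rather than averaging silently.
    """
    keys = ["compound_id", "adduct_type"]
    numeric = [c for c in df.columns if c not in keys and pd.api.types.is_numeric_dtype(df[c])]
    other = [c for c in df.columns if c not in keys + numeric]
    agg = {c: "mean" for c in numeric}
    agg.update({c: "first" for c in other})
    out = df.groupby(keys, as_index=False, sort=False).agg(agg)
    return out[df.columns]
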