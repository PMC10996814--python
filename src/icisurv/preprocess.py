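"""Leakage-safe feature encoding, scaling, time discretization and splits.

Encoding conventions: multi-level categoricals (race, histology, treatment
arm, maximum adverse-event grade) are one-hot encoded with *all* declared
levels kept (no reference-level drop), including levels with zero patients;
binary yes/no features keep their 0/1 coding as single columns; KPS is
treated as continuous.  The hybrid feature set is then 31 columns
(3 mathematical biomarkers + 4 continuous clinical + 4 binary + 20 one-hot),
clinical-only 28, biomarker-only 3.  The neutrophil-to-lymphocyte ratio is
deliberately never constructed (collinearity with its components).

Scaling standardizes continuous columns only, using training-set statistics
(refit per fold).  Time is discretized on an equidistant grid (default 20
bins) with a left-open/right-closed interval convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CATEGORICAL_LEVELS

__all__ = [
    "FeatureMatrix",
    "TimeGrid",
    "DiscreteLabel",
    "SplitAssignment",
    "ScalerState",
    "FEATURE_SETS",
    "encode_features",
    "fit_scaler",
    "apply_scaler",
    "make_time_grid",
    "discretize",
    "discretize_all",
    "split_cohort",
    "enumerate_folds",
]

_MB_CONTINUOUS = ["mu", "Lambda", "alpha1"]
_CLIN_CONTINUOUS = ["age", "neutrophil_bsl", "lymphocyte_bsl", "kps"]
_CLIN_BINARY = ["sex", "ever_smoker", "prior_systemic", "prior_radiation"]
_CLIN_ONEHOT = ["race", "histology", "treatment_arm", "max_ae_grade"]

FEATURE_SETS = ("hybrid", "clinical_only", "mb_only")


@dataclass
class FeatureMatrix:
    """Encoded design matrix with column metadata.

    ``kinds`` tags each column continuous / one-hot; ``groups`` maps each
    column back to its original (pre-encoding) feature, so one-hot blocks
    can be permuted or ablated together.
    """

    X: np.ndarray
    columns: list[str]
    kinds: list[str]
    groups: list[str]

    def group_indices(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for g in dict.fromkeys(self.groups):
            out[g] = np.array([i for i, gg in enumerate(self.groups) if gg == g])
        return out

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.X.copy(), list(self.columns), list(self.kinds), list(self.groups))


def encode_features(cohort: pd.DataFrame, feature_set: str = "hybrid") -> FeatureMatrix:
    """Encode a cohort table into a fixed-schema design matrix."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    if len(cohort) == 0:
        raise ValueError("empty cohort")

    continuous: list[str] = []
    binary: list[str] = []
    onehot: list[str] = []
    if feature_set in ("hybrid", "mb_only"):
        continuous += _MB_CONTINUOUS
    if feature_set in ("hybrid", "clinical_only"):
        continuous += _CLIN_CONTINUOUS
        binary += _CLIN_BINARY
        onehot += _CLIN_ONEHOT

    cols: list[np.ndarray] = []
    names: list[str] = []
    kinds: list[str] = []
    groups: list[str] = []
    for name in continuous:
        cols.append(cohort[name].to_numpy(float))
        names.append(name)
        kinds.append("continuous")
        groups.append(name)
    for name in binary:
        raw = cohort[name].to_numpy(object)
        if name == "sex":
            levels = {"female": 0.0, "male": 1.0, 0: 0.0, 1: 1.0, "0": 0.0, "1": 1.0}
            try:
                vals = np.array([levels[v] for v in raw], dtype=float)
            except KeyError as exc:
                raise ValueError(f"unknown level {exc.args[0]!r} in feature {name}") from None
        else:
            vals = np.asarray(raw, dtype=float)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                bad = vals[~np.isin(vals, (0.0, 1.0))][0]
                raise ValueError(f"unknown level {bad!r} in feature {name}")
        cols.append(vals)
        names.append(name)
        kinds.append("one-hot")
        groups.append(name)
    for name in onehot:
        declared = CATEGORICAL_LEVELS[name]
        raw = cohort[name].tolist()
        for v in raw:
            if v not in declared:
                raise ValueError(f"unknown level {v!r} in feature {name}")
        for level in declared:
            cols.append(np.array([1.0 if v == level else 0.0 for v in raw]))
            names.append(f"{name}={level}")
            kinds.append("one-hot")
            groups.append(name)

    X = np.column_stack(cols) if cols else np.empty((len(cohort), 0))
    if not np.all(np.isfinite(X)):
        raise ValueError("encoded matrix contains missing/non-finite values")
    return FeatureMatrix(X=X, columns=names, kinds=kinds, groups=groups)


@dataclass
class ScalerState:
    """Training-set standardization statistics for continuous columns."""

    mean: np.ndarray
    scale: np.ndarray
    continuous_idx: np.ndarray
    columns: list[str] = field(default_factory=list)


def fit_scaler(train: FeatureMatrix) -> ScalerState:
    idx = np.array([i for i, k in enumerate(train.kinds) if k == "continuous"], dtype=int)
    sub = train.X[:, idx]
    mean = sub.mean(axis=0)
    scale = sub.std(axis=0)
    zero = scale == 0
    if np.any(zero):
        warnings.warn(
            "zero-variance continuous column(s) "
            + ", ".join(np.array(train.columns)[idx[zero]])
            + "; scaling by 1"
        )
        scale = np.where(zero, 1.0, scale)
    return ScalerState(mean=mean, scale=scale, continuous_idx=idx, columns=list(train.columns))


def apply_scaler(state: ScalerState, fm: FeatureMatrix) -> FeatureMatrix:
    if fm.X.shape[1] != len(state.columns) or fm.columns != state.columns:
        raise ValueError("feature schema mismatch between scaler and matrix")
    out = fm.copy()
    out.X[:, state.continuous_idx] = (fm.X[:, state.continuous_idx] - state.mean) / state.scale
    return out


@dataclass(frozen=True)
class TimeGrid:
    """Equidistant time bins: edges[0] = 0, ``n_bins`` intervals."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", e)
        if e.size < 3 or e[0] != 0 or not np.all(np.diff(e) > 0):
            raise ValueError("edges must start at 0, be strictly increasing, length >= 3")
        widths = np.diff(e)
        if not np.allclose(widths, widths[0], atol=1e-9, rtol=0):
            raise ValueError("grid must be equidistant")

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1


@dataclass(frozen=True)
class DiscreteLabel:
    bin_index: int
    event: int


def make_time_grid(train_durations: np.ndarray, n_bins: int = 20) -> TimeGrid:
    """Equidistant grid from 0 to the maximum training duration."""
    d = np.asarray(train_durations, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    return TimeGrid(edges=np.linspace(0.0, float(d.max()), n_bins + 1))


def discretize(duration: float, event: int, grid: TimeGrid) -> DiscreteLabel:
    """Bin index of the (left-open, right-closed] interval containing ``duration``.

    Durations beyond the last edge clamp to the last bin with a warning
    (test patients may outlive the training horizon).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    e = grid.edges
    if duration > e[-1]:
        warnings.warn(f"duration {duration:.6g} beyond grid end {e[-1]:.6g}; clamping to last bin")
        return DiscreteLabel(bin_index=grid.n_bins - 1, event=int(event))
    k = int(np.searchsorted(e, duration, side="left")) - 1
    k = max(k, 0)
    return DiscreteLabel(bin_index=k, event=int(event))


def discretize_all(durations: np.ndarray, events: np.ndarray, grid: TimeGrid) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`discretize`; returns (bin_indices, events)."""
    labels = [discretize(float(d), int(ev), grid) for d, ev in zip(durations, events)]
    return (
        np.array([lab.bin_index for lab in labels], dtype=int),
        np.array([lab.event for lab in labels], dtype=int),
    )


@dataclass(frozen=True)
class SplitAssignment:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def split_cohort(
    ids,
    seed: int,
    fractions: tuple[float, float, float] | None = None,
) -> SplitAssignment:
    """Seeded random train/validation/test partition.

    By default the test set is ``ceil(0.2 n)`` and validation is 20% of the
    remaining patients (for the 93-patient cohort geometry: 19 test, 15
    validation, 59 training).  Explicit ``fractions`` override this.
    """
    ids = np.asarray(ids)
    n = ids.size
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    if fractions is None:
        n_test = math.ceil(0.2 * n)
        n_val = math.ceil(0.2 * (n - n_test))
    else:
        if not np.isclose(sum(fractions), 1.0):
            raise ValueError("fractions must sum to 1")
        n_test = math.ceil(fractions[2] * n)
        n_val = math.ceil(fractions[1] * (n - n_test))
    n_train = n - n_test - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("every split part must be nonempty")
    test = ids[perm[:n_test]]
    val = ids[perm[n_test : n_test + n_val]]
    train = ids[perm[n_test + n_val :]]
    return SplitAssignment(train=train, val=val, test=test)


def enumerate_folds(ids, n_groups: int = 5, seed: int = 0) -> list[SplitAssignment]:
    """All ordered (test-group, validation-group) folds over a seeded partition.

    The ids are split into ``n_groups`` near-equal groups; each fold takes
    one group as test, a different one as validation and the rest as
    training, giving ``n_groups * (n_groups - 1)`` folds.
    """
    if n_groups < 3:
        raise ValueError("n_groups must be >= 3")
    ids = np.asarray(ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids.size)
    groups = [ids[perm[g::n_groups]] for g in range(n_groups)]
    if min(g.size for g in groups) < 2:
        warnings.warn("some fold groups have fewer than 2 patients")
    folds = []
    for ti in range(n_groups):
        for vi in range(n_groups):
            if vi == ti:
                continue
            train = np.concatenate([groups[g] for g in range(n_groups) if g not in (ti, vi)])
            folds.append(SplitAssignment(train=train, val=groups[vi], test=groups[ti]))
    return folds
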