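"""The gated multi-branch ensemble.

Each *branch* is a classifier over an early-fused subset of sensors (for
the wrist: WB1 = {EDA, BVP, TEMP}, WB2 = {sweat, EDA, BVP}, WB3 =
{EDA, BVP}; for the chest a registry of 28 combinations, CB1–CB28).  A
*gate* classifier over context features (motion for wrist devices, muscle
activity for chest devices) assigns an activation probability to every
branch.  At inference the branch-selection threshold b in [0, 1] controls
how many non-maximum branches participate:

    selected = { i : p_i >= (1 - b) * max(p) }

so b = 0 activates only the argmax branch and b = 1 activates all of them.
The selected branches' class-probability vectors are combined by late
fusion — arithmetic averaging by default, majority voting as an option —
with argmax ties broken toward the lowest class code.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations  # noqa: F401  (re-exported convenience)

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .errors import ConfigurationError, ValidationError
from .features import feature_columns

logger = logging.getLogger(__name__)

BACKENDS = ("decision_tree", "random_forest", "support_vector_machine", "gradient_boosting")

#: frozen backend hyperparameters (every unstated training knob lives here)
BACKEND_DEFAULTS = {
    "decision_tree": {},  # depth unlimited
    "random_forest": {"n_estimators": 100},
    "support_vector_machine": {"kernel": "rbf", "C": 1.0},
    "gradient_boosting": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 6},
}


def load_branch_registry() -> dict[str, dict[str, list[str]]]:
    """The shipped branch registry: wrist WB1–WB3 and chest CB1–CB28.

    The chest registry intentionally reproduces its published source rows
    verbatim, duplicates included (CB3/CB4 and CB10/CB11 list identical
    modality sets); duplicates are flagged in the log.
    """
    with resources.files("stresscare.data").joinpath("branches.json").open() as fh:
        registry = json.load(fh)
    for device, branches in registry.items():
        seen: dict[tuple, str] = {}
        for bid, mods in branches.items():
            key = tuple(sorted(mods))
            if key in seen:
                logger.warning(
                    "branch registry: %s duplicates %s (%s, %s)", bid, seen[key], device, mods
                )
            else:
                seen[key] = bid
    return registry


@dataclass(frozen=True)
class BranchSpec:
    """A sensor-subset classifier definition."""

    branch_id: str
    device: str  # wrist | chest
    modalities: tuple[str, ...]
    task: str = "two_class"  # two_class | three_class

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValidationError(f"branch {self.branch_id}: empty modality set")
        if self.device not in ("wrist", "chest"):
            raise ValidationError(f"branch {self.branch_id}: unknown device {self.device!r}")
        if self.task not in ("two_class", "three_class"):
            raise ValidationError(f"branch {self.branch_id}: unknown task {self.task!r}")


def make_backend(name: str, seed: int):
    """Instantiate a classifier backend with the frozen hyperparameters."""
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **BACKEND_DEFAULTS[name])
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **BACKEND_DEFAULTS[name])
    if name == "support_vector_machine":
        # features standardised inside the fold; probabilities via Platt scaling
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(probability=True, random_state=seed, **BACKEND_DEFAULTS[name])),
            ]
        )
    if name == "gradient_boosting":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            **BACKEND_DEFAULTS[name],
        )
    raise ConfigurationError(f"unknown backend {name!r}; choose one of {BACKENDS}")


@dataclass
class BranchModel:
    """A trained branch: spec + backend + class list + feature columns."""

    spec: BranchSpec
    backend: str
    estimator: object
    classes: np.ndarray  # ascending class codes seen at fit time
    columns: list[str]
    seed: int

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Class-probability rows over ``self.classes`` (sums to 1)."""
        X = table[self.columns].to_numpy(dtype=float)
        return np.asarray(self.estimator.predict_proba(X), dtype=float)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        proba = self.predict_proba(table)
        return self.classes[np.argmax(proba, axis=1)]


def train_branch(
    spec: BranchSpec, backend: str, table: pd.DataFrame, seed: int
) -> BranchModel:
    """Fit one branch classifier on its early-fused feature table.

    Early fusion is plain column concatenation: the table's feature columns
    are exactly the spec's modality features (plus their within-branch
    correlations), and the backend sees them as one design matrix.
    """
    if backend not in BACKENDS:
        raise ConfigurationError(f"unknown backend {backend!r}; choose one of {BACKENDS}")
    cols = feature_columns(table)
    if not cols:
        raise ValidationError(f"branch {spec.branch_id}: no feature columns in table")
    y = table["label"].to_numpy(dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError(
            f"branch {spec.branch_id}: training data contains a single class"
        )
    est = make_backend(backend, seed)
    X = table[cols].to_numpy(dtype=float)
    # backends expect consecutive 0..k-1 targets
    y_enc = np.searchsorted(classes, y)
    est.fit(X, y_enc)
    return BranchModel(spec, backend, est, classes, cols, seed)


@dataclass
class GateModel:
    """The context gate: maps context features to branch probabilities."""

    context_modality: str  # ACC | EMG
    backend: str
    estimator: object | None
    branch_ids: list[str]
    columns: list[str]
    seed: int
    constant_branch: int | None = None  # set when supervision was degenerate
    _present: np.ndarray | None = None  # branch indices seen in supervision

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """One probability per registered branch, rows summing to 1."""
        n = len(table)
        B = len(self.branch_ids)
        if self.constant_branch is not None:
            out = np.zeros((n, B))
            out[:, self.constant_branch] = 1.0
            return out
        X = table[self.columns].to_numpy(dtype=float)
        proba = np.asarray(self.estimator.predict_proba(X), dtype=float)
        out = np.zeros((n, B))
        out[:, self._present] = proba
        return out


def train_gate(
    context_table: pd.DataFrame,
    branch_supervision: np.ndarray,
    branch_ids: list[str],
    backend: str,
    seed: int,
    context_modality: str = "ACC",
) -> GateModel:
    """Fit the gating classifier.

    ``branch_supervision`` gives, per segment, the index of the branch that
    classified it best on internal validation.  When the supervision is
    degenerate (one branch always best) a constant gate is fitted with a
    warning — the ensemble then reduces to that branch at b = 0.
    """
    if backend not in BACKENDS:
        raise ConfigurationError(f"unknown backend {backend!r}; choose one of {BACKENDS}")
    sup = np.asarray(branch_supervision, dtype=int)
    if sup.shape[0] != len(context_table):
        raise ValidationError("supervision length != context table length")
    if sup.size and (sup.min() < 0 or sup.max() >= len(branch_ids)):
        raise ValidationError("supervision indexes a branch outside the branch list")
    cols = feature_columns(context_table)
    present = np.unique(sup)
    if present.size < 2:
        warnings.warn(
            "gate supervision is degenerate (one branch always best); "
            "fitting a constant gate",
            stacklevel=2,
        )
        return GateModel(
            context_modality, backend, None, list(branch_ids), cols, seed,
            constant_branch=int(present[0]) if present.size else 0,
        )
    est = make_backend(backend, seed)
    X = context_table[cols].to_numpy(dtype=float)
    est.fit(X, np.searchsorted(present, sup))
    gate = GateModel(context_modality, backend, est, list(branch_ids), cols, seed)
    gate._present = present  # column positions in the full branch list
    return gate


def select_branches(probs: np.ndarray, b: float) -> list[int]:
    """Indices of the branches activated at threshold ``b``.

    Selection rule: branch i is active iff p_i >= (1 - b) * max(p).  This
    is the unique linear-in-b rule matching both stated endpoints: b = 0
    keeps only the highest-probability branch (ties at the maximum are all
    kept) and b = 1 keeps every branch.  Selected sets are nested in b.
    """
    if not 0.0 <= b <= 1.0:
        raise ValidationError(f"branch threshold b={b} outside [0, 1]")
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("probs must be a nonempty 1-D probability vector")
    if np.any(p < -1e-12):
        raise ValidationError("negative branch probability")
    cutoff = (1.0 - b) * p.max()
    return [int(i) for i in np.flatnonzero(p >= cutoff - 1e-12)]


@dataclass
class FusionResult:
    """The fused prediction for one segment."""

    probabilities: np.ndarray
    predicted_class: int
    contributing_branch_ids: list[str] = field(default_factory=list)


def late_fuse(
    branch_probs: list[np.ndarray],
    class_codes: np.ndarray,
    branch_ids: list[str] | None = None,
    method: str = "average",
) -> FusionResult:
    """Fuse the selected branches' class-probability vectors.

    ``average`` (default) takes the arithmetic mean of the vectors;
    ``majority`` votes with each branch's argmax and renormalises the vote
    counts.  The predicted class is the argmax of the fused vector, ties
    broken toward the lowest class code.
    """
    if not branch_probs:
        raise ValidationError("late_fuse requires at least one branch prediction")
    class_codes = np.asarray(class_codes)
    if len({np.asarray(v).shape for v in branch_probs}) != 1:
        raise ValidationError("branch predictions disagree on the class list")
    mat = np.asarray(branch_probs, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != class_codes.size:
        raise ValidationError("branch predictions disagree on the class list")
    if method == "average":
        if np.all(mat == mat[0]):
            fused = mat[0].copy()  # unanimous branches: keep the vector bit-exact
        else:
            fused = mat.mean(axis=0)
    elif method == "majority":
        votes = np.zeros(class_codes.size)
        for row in mat:
            votes[int(np.argmax(row))] += 1.0
        fused = votes / votes.sum()
    else:
        raise ConfigurationError(f"unknown fusion method {method!r}")
    # class_codes ascending => argmax's first-hit rule == lowest-code tie-break
    pred = int(class_codes[int(np.argmax(fused))])
    return FusionResult(fused, pred, list(branch_ids or []))


@dataclass
class GatedEnsemble:
    """Trained gate + branches, ready for thresholded fused prediction."""

    gate: GateModel
    branches: dict[str, BranchModel]
    class_codes: np.ndarray
    fusion_method: str = "average"

    def __post_init__(self) -> None:
        for bid, model in self.branches.items():
            if not np.array_equal(model.classes, self.class_codes):
                raise ValidationError(
                    f"branch {bid} class list {model.classes} != ensemble {self.class_codes}"
                )

    def predict(
        self,
        context_table: pd.DataFrame,
        branch_tables: dict[str, pd.DataFrame],
        b: float,
    ) -> list[FusionResult]:
        """Gate → threshold-b selection → branch inference → late fusion."""
        ids = self.gate.branch_ids
        for bid in ids:
            if bid not in branch_tables:
                raise ValidationError(f"no feature table supplied for branch {bid}")
            missing = [
                c for c in self.branches[bid].columns if c not in branch_tables[bid].columns
            ]
            if missing:
                raise ValidationError(f"branch {bid}: missing feature columns {missing}")
        gate_probs = self.gate.predict_proba(context_table)
        branch_probas = {bid: self.branches[bid].predict_proba(branch_tables[bid]) for bid in ids}
        results = []
        for row in range(len(context_table)):
            sel = select_branches(gate_probs[row], b)
            vecs = [branch_probas[ids[i]][row] for i in sel]
            results.append(
                late_fuse(vecs, self.class_codes, [ids[i] for i in sel], self.fusion_method)
            )
        return results

    def predict_labels(
        self, context_table: pd.DataFrame, branch_tables: dict[str, pd.DataFrame], b: float
    ) -> np.ndarray:
        return np.array(
            [r.predicted_class for r in self.predict(context_table, branch_tables, b)],
            dtype=int,
        )
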