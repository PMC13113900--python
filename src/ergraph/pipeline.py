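"""Classification pipeline: scenarios, subject-wise nested CV, classifier zoo.

Scenario construction merges or drops diagnostic groups into the four
study designs (two binary contrasts, three-group, four-group), stratifies
by sex and flash strength, and optionally concatenates right- and
left-eye feature vectors per (subject, flash, recording-index) pair.

Training is three-staged, all inside an outer 10-fold *subject-wise*
cross-validation (folds partition subjects, never rows, so repeat
recordings of one person cannot straddle train and test):

1. random-forest impurity importance with top-k selection (500 trees),
   refit on each outer-train split;
2. 3-fold subject-wise inner CV over the candidate classifiers, with
   SMOTE oversampling applied to the inner-training portion only;
3. refit the winning classifier on the full outer-train split (with
   SMOTE) and score the held-out outer fold.

Metrics are balanced accuracy (mean per-class recall) and macro-F1,
reported per fold and as mean +/- SD.  SMOTE is implemented here as
minority-class k-nearest-neighbour interpolation to class parity
(k_neighbors = 5, reduced to minority-1 when the class is tiny, skipped
with a warning when the minority has a single row); synthetic rows never
enter any validation or test partition.
"""

from __future__ import annotations

import enum
import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (AdaBoostClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.metrics import balanced_accuracy_score, f1_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import GRAPH_FEATURE_NAMES, feature_table
from .graphs import Construction, spectral_summary, build_graph
from .signal_io import Group, normalize, quantize

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "ScenarioSpec",
    "ScenarioData",
    "CVResult",
    "build_scenario",
    "subject_wise_folds",
    "stage1_select_features",
    "smote_oversample",
    "stage2_inner_cv",
    "run_nested_cv",
    "classifier_registry",
    "CLASSIFIER_DEFAULTS",
    "q_sweep",
    "compare_constructions",
    "column_family",
    "feature_importance_report",
]

META_COLUMNS = {"subject_id", "group", "sex", "eye", "flash_td",
                "recording_index", "construction", "Q", "label"}


class Scenario(str, enum.Enum):
    ASD_VS_CTRL = "asd_vs_ctrl"
    ADHD_VS_CTRL = "adhd_vs_ctrl"
    THREE_GROUP = "three_group"
    FOUR_GROUP = "four_group"


@dataclass
class ScenarioSpec:
    scenario: Scenario = Scenario.THREE_GROUP
    sex: str = "ALL"                 # M, F or ALL
    flash: float | None = None       # 113, 446 or None for all
    eye_mode: str = "RIGHT"          # RIGHT, LEFT or R_PLUS_L
    feature_families: Sequence[str] = ("GRAPH",)   # subset of GRAPH, TD, EXTERNAL

    def __post_init__(self) -> None:
        self.scenario = Scenario(self.scenario)
        self.sex = self.sex.upper()
        self.eye_mode = self.eye_mode.upper()


@dataclass
class ScenarioData:
    """Labeled analysis table plus the feature columns to model."""

    table: pd.DataFrame
    feature_cols: list[str]
    spec: ScenarioSpec
    n_dropped_unpaired: int = 0


def column_family(col: str) -> str:
    base = col[:-2] if col.endswith(("_R", "_L")) else col
    if base in GRAPH_FEATURE_NAMES:
        return "GRAPH"
    if base.startswith("td_"):
        return "TD"
    return "EXTERNAL"


_LABEL_MAPS = {
    Scenario.ASD_VS_CTRL: {Group.ASD.value: "ASD", Group.ASD_ADHD.value: "ASD",
                           Group.CONTROL.value: "CONTROL"},
    Scenario.ADHD_VS_CTRL: {Group.ADHD.value: "ADHD", Group.ASD_ADHD.value: "ADHD",
                            Group.CONTROL.value: "CONTROL"},
    Scenario.THREE_GROUP: {Group.ASD.value: "ASD", Group.ADHD.value: "ADHD",
                           Group.CONTROL.value: "CONTROL"},
    Scenario.FOUR_GROUP: {g.value: g.value for g in
                          (Group.ASD, Group.ADHD, Group.ASD_ADHD, Group.CONTROL)},
}


def build_scenario(table: pd.DataFrame, spec: ScenarioSpec) -> ScenarioData:
    """Filter/relabel a feature table into one classification scenario.

    Binary scenarios merge the co-occurring group into the positive class;
    the three-group scenario excludes it.  ``R_PLUS_L`` pairs right- and
    left-eye rows of the same (subject, flash, recording index) and
    concatenates their feature columns with _R/_L suffixes; unpaired
    recordings are dropped with a logged count.
    """
    df = table.copy()
    label_map = _LABEL_MAPS[spec.scenario]
    df = df[df["group"].isin(label_map)].copy()
    df["label"] = df["group"].map(label_map)
    if spec.sex != "ALL":
        df = df[df["sex"] == spec.sex]
    if spec.flash is not None:
        df = df[df["flash_td"] == float(spec.flash)]

    bad = df.groupby("subject_id")["label"].nunique()
    if (bad > 1).any():
        raise ValueError("a subject appears in more than one class: "
                         + ", ".join(bad[bad > 1].index.astype(str)))

    feature_cols = [c for c in df.columns
                    if c not in META_COLUMNS and pd.api.types.is_numeric_dtype(df[c])
                    and column_family(c) in spec.feature_families]
    n_dropped = 0
    if spec.eye_mode in ("RIGHT", "LEFT"):
        df = df[df["eye"] == spec.eye_mode]
    elif spec.eye_mode == "R_PLUS_L":
        keys = ["subject_id", "label", "group", "sex", "flash_td", "recording_index"]
        right = df[df["eye"] == "RIGHT"][keys + feature_cols]
        left = df[df["eye"] == "LEFT"][keys + feature_cols]
        merged = right.merge(left, on=keys, suffixes=("_R", "_L"))
        n_dropped = (len(right) + len(left)) - 2 * len(merged)
        if n_dropped:
            logger.warning("R_PLUS_L pairing dropped %d unpaired recordings", n_dropped)
        df = merged
        feature_cols = [f"{c}_R" for c in feature_cols] + [f"{c}_L" for c in feature_cols]
    else:
        raise ValueError(f"unknown eye_mode {spec.eye_mode!r}")

    counts = df["label"].value_counts()
    expected = sorted(set(label_map.values()))
    empty = [c for c in expected if counts.get(c, 0) == 0]
    if empty:
        raise ValueError(f"scenario class(es) empty after filtering: {', '.join(empty)}")
    return ScenarioData(table=df.reset_index(drop=True), feature_cols=feature_cols,
                        spec=spec, n_dropped_unpaired=n_dropped)


# ---------------------------------------------------------------------------
# Folds

def subject_wise_folds(subjects: Sequence, labels: Sequence, n_folds: int,
                       seed: int) -> dict:
    """Partition *subjects* (not rows) into n_folds, stratified by class.

    ``subjects``/``labels`` are row-aligned; every row of a subject shares
    its fold.  Returns {subject_id: fold}.  Deterministic in the seed.
    """
    df = pd.DataFrame({"subject": subjects, "label": labels})
    per_subject = df.drop_duplicates("subject")
    if per_subject["subject"].size < n_folds:
        raise ValueError(f"need at least {n_folds} subjects, "
                         f"got {per_subject['subject'].size}")
    if df.groupby("subject")["label"].nunique().max() > 1:
        raise ValueError("a subject carries more than one class label")
    rng = np.random.default_rng(seed)
    fold_fill = np.zeros(n_folds, dtype=int)
    assignment: dict = {}
    for lab in sorted(per_subject["label"].astype(str).unique()):
        subs = sorted(per_subject.loc[per_subject["label"].astype(str) == lab,
                                      "subject"].astype(str))
        rng.shuffle(subs)
        for s in subs:
            f = int(np.argmin(fold_fill))   # least-filled fold, ties to lowest index
            assignment[s] = f
            fold_fill[f] += 1
    return assignment


# ---------------------------------------------------------------------------
# Stage 1: feature selection

AUTO_TOPK_GRID = (3, 5, 7, 9, "all")


def _rf_ranking(X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    rf = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    # stable sort keeps column order on importance ties (e.g. all-zero)
    return np.argsort(-rf.feature_importances_, kind="stable")


def stage1_select_features(table: pd.DataFrame, feature_cols: Sequence[str],
                           label_col: str = "label", subject_col: str = "subject_id",
                           k="auto", seed: int = 0, smote: bool = True) -> list[str]:
    """Rank features by random-forest impurity importance; keep top-k.

    ``k='all'`` returns the columns unchanged; ``k='auto'`` picks k from
    AUTO_TOPK_GRID by 3-fold subject-wise CV balanced accuracy of a
    random forest on the candidate subset.
    """
    feature_cols = list(feature_cols)
    if k == "all" or k is None:
        return feature_cols
    X = table[feature_cols].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    order = _rf_ranking(X, y, seed)
    if k == "auto":
        best_k, best_ba = None, -np.inf
        for kk in AUTO_TOPK_GRID:
            cols = feature_cols if kk == "all" else [feature_cols[i] for i in order[:kk]]
            ba = _inner_cv_score(table, cols, label_col, subject_col,
                                 RandomForestClassifier(n_estimators=500,
                                                        random_state=seed, n_jobs=1),
                                 seed=seed, smote=smote)
            if ba > best_ba:
                best_k, best_ba = kk, ba
        k = best_k
        if k == "all":
            return feature_cols
    k = int(k)
    if k > len(feature_cols):
        logger.warning("top-k %d exceeds %d available features; clamped", k, len(feature_cols))
        k = len(feature_cols)
    return [feature_cols[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# SMOTE

def smote_oversample(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
                     rng: np.random.Generator | None = None):
    """Oversample every minority class to majority parity by synthetic
    minority interpolation.

    Each synthetic row is x_i + u (x_j - x_i) with u ~ U(0,1), x_j one of
    the k nearest same-class neighbours of a randomly chosen x_i.  When a
    class has fewer than k_neighbors + 1 rows, k is reduced to (size - 1)
    with a warning; a singleton class is left untouched with a warning.
    Original rows are returned first, synthetic rows appended.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n_major = counts.max()
    xs, ys = [X], [y]
    for cls, cnt in zip(classes, counts):
        need = n_major - cnt
        if need == 0:
            continue
        if cnt == 1:
            logger.warning("class %r has a single row; SMOTE skipped", cls)
            continue
        k = min(k_neighbors, cnt - 1)
        if k < k_neighbors:
            logger.warning("class %r: k_neighbors reduced to %d", cls, k)
        Xc = X[y == cls]
        d = np.linalg.norm(Xc[:, None, :] - Xc[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nn = np.argsort(d, axis=1, kind="stable")[:, :k]
        new = np.empty((need, X.shape[1]))
        for m in range(need):
            i = int(rng.integers(len(Xc)))
            j = int(nn[i, rng.integers(k)])
            new[m] = Xc[i] + rng.random() * (Xc[j] - Xc[i])
        xs.append(new)
        ys.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(xs), np.concatenate(ys)


# ---------------------------------------------------------------------------
# Classifier registry

#: Pinned hyperparameters for the seven candidate classifiers.  The named
#: settings (tree counts, max_depth, kernel, k, hidden sizes) are the study
#: defaults; everything else is pinned here so runs are reproducible across
#: library versions.  Distance/scale-sensitive models (svm, knn, mlp) are
#: wrapped with standardization.
CLASSIFIER_DEFAULTS: dict[str, dict] = {
    "rf": {"n_estimators": 500, "n_jobs": 1},
    "adab": {"n_estimators": 200},
    "gradb": {"n_estimators": 200},
    "xgb": {"max_depth": 6, "n_estimators": 300, "learning_rate": 0.1,
            "subsample": 1.0, "eval_metric": "logloss", "n_jobs": 1,
            "verbosity": 0, "tree_method": "hist"},
    "svm": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "knn": {"n_neighbors": 5, "weights": "uniform"},
    "mlp": {"hidden_layer_sizes": (128, 64), "max_iter": 1000, "early_stopping": False},
}


class _LabelEncoded(BaseEstimator, ClassifierMixin):
    """Adapter giving string-labelled y to estimators that need integer
    classes (xgboost)."""

    def __init__(self, estimator=None):
        self.estimator = estimator

    def fit(self, X, y):
        from sklearn.preprocessing import LabelEncoder

        self.encoder_ = LabelEncoder().fit(y)
        self.classes_ = self.encoder_.classes_
        self.model_ = clone(self.estimator).fit(X, self.encoder_.transform(y))
        return self

    def predict(self, X):
        return self.encoder_.inverse_transform(self.model_.predict(X))


def classifier_registry(seed: int = 0) -> dict:
    """The seven candidate classifiers, in fixed registry (tie-break) order."""
    from xgboost import XGBClassifier

    d = CLASSIFIER_DEFAULTS
    return {
        "rf": RandomForestClassifier(random_state=seed, **d["rf"]),
        "adab": AdaBoostClassifier(random_state=seed, **d["adab"]),
        "gradb": GradientBoostingClassifier(random_state=seed, **d["gradb"]),
        "xgb": _LabelEncoded(XGBClassifier(random_state=seed, **d["xgb"])),
        "svm": Pipeline([("scale", StandardScaler()),
                         ("clf", SVC(random_state=seed, **d["svm"]))]),
        "knn": Pipeline([("scale", StandardScaler()),
                         ("clf", KNeighborsClassifier(**d["knn"]))]),
        "mlp": Pipeline([("scale", StandardScaler()),
                         ("clf", MLPClassifier(random_state=seed, **d["mlp"]))]),
    }


def _resolve_classifiers(classifiers, seed: int) -> dict:
    registry = classifier_registry(seed)
    if classifiers is None:
        return registry
    out = {}
    for name in classifiers:
        if name not in registry:
            raise KeyError(f"unknown classifier {name!r}; registry has "
                           f"{', '.join(registry)}")
        out[name] = registry[name]
    return out


def _fit_predict(model, Xtr, ytr, Xte):
    model = clone(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xtr, ytr)
        return model, model.predict(Xte)


def _score(y_true, y_pred) -> tuple[float, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ba = balanced_accuracy_score(y_true, y_pred)
        f1 = f1_score(y_true, y_pred, average="macro")
    return float(ba), float(f1)


def _inner_cv_score(table, feature_cols, label_col, subject_col, model,
                    seed, n_inner: int = 3, smote: bool = True) -> float:
    subjects = table[subject_col].to_numpy()
    y = table[label_col].to_numpy()
    folds = subject_wise_folds(subjects, y, n_inner, seed)
    fold_of_row = np.array([folds[str(s)] for s in subjects])
    rng = np.random.default_rng(seed)
    bas = []
    X = table[list(feature_cols)].to_numpy(dtype=float)
    for f in range(n_inner):
        tr, te = fold_of_row != f, fold_of_row == f
        if len(np.unique(y[tr])) < 2 or te.sum() == 0:
            continue
        Xtr, ytr = X[tr], y[tr]
        if smote:
            Xtr, ytr = smote_oversample(Xtr, ytr, rng=rng)
        _, pred = _fit_predict(model, Xtr, ytr, X[te])
        bas.append(_score(y[te], pred)[0])
    return float(np.mean(bas)) if bas else -np.inf


def stage2_inner_cv(table: pd.DataFrame, feature_cols: Sequence[str],
                    label_col: str = "label", subject_col: str = "subject_id",
                    classifiers=None, seed: int = 0, n_inner: int = 3,
                    smote: bool = True) -> tuple[str, float]:
    """Pick the classifier maximizing mean inner-CV balanced accuracy.

    SMOTE is fitted on each inner-training portion only; validation rows
    stay untouched.  Ties go to the earlier registry entry.
    """
    candidates = _resolve_classifiers(classifiers, seed)
    best_name, best_ba = None, -np.inf
    for name, model in candidates.items():
        ba = _inner_cv_score(table, feature_cols, label_col, subject_col,
                             model, seed=seed, n_inner=n_inner, smote=smote)
        if ba > best_ba:
            best_name, best_ba = name, ba
    return best_name, best_ba


@dataclass
class CVResult:
    """Outer-CV outcome: per-fold metrics and the per-fold choices."""

    fold_ba: list[float]
    fold_f1: list[float]
    selected_features: list[list[str]]
    chosen_classifier: list[str]
    n_folds: int
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def mean_ba(self) -> float:
        return float(np.mean(self.fold_ba))

    @property
    def sd_ba(self) -> float:
        return float(np.std(self.fold_ba, ddof=1)) if len(self.fold_ba) > 1 else 0.0

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))

    @property
    def sd_f1(self) -> float:
        return float(np.std(self.fold_f1, ddof=1)) if len(self.fold_f1) > 1 else 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(mean_ba=self.mean_ba, sd_ba=self.sd_ba,
                 mean_f1=self.mean_f1, sd_f1=self.sd_f1)
        d["config_hash"] = hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()).hexdigest()[:16]
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, default=str, **kw)


def run_nested_cv(data: ScenarioData | pd.DataFrame, feature_cols=None,
                  label_col: str = "label", subject_col: str = "subject_id",
                  classifiers=None, n_folds: int = 10, top_k="auto",
                  seed: int = 0, smote: bool = True) -> CVResult:
    """Three-stage training under 10-fold subject-wise outer CV."""
    if isinstance(data, ScenarioData):
        table, feature_cols = data.table, data.feature_cols
        config = {"spec": asdict(data.spec)}
    else:
        table = data
        if feature_cols is None:
            raise ValueError("feature_cols required when passing a bare table")
        config = {}
    feature_cols = list(feature_cols)
    config.update(n_folds=n_folds, top_k=top_k, seed=seed, smote=smote,
                  classifiers=sorted(_resolve_classifiers(classifiers, seed)))
    subjects = table[subject_col].astype(str).to_numpy()
    y = table[label_col].to_numpy()
    folds = subject_wise_folds(subjects, y, n_folds, seed)
    fold_of_row = np.array([folds[s] for s in subjects])
    fold_ba, fold_f1, sel_feats, chosen = [], [], [], []
    registry_models = _resolve_classifiers(classifiers, seed)
    for f in range(n_folds):
        tr_mask = fold_of_row != f
        te_mask = fold_of_row == f
        train = table[tr_mask]
        cols = stage1_select_features(train, feature_cols, label_col, subject_col,
                                      k=top_k, seed=seed + f, smote=smote)
        name, _ = stage2_inner_cv(train, cols, label_col, subject_col,
                                  classifiers=classifiers, seed=seed + f, smote=smote)
        Xtr = train[cols].to_numpy(dtype=float)
        ytr = train[label_col].to_numpy()
        if smote:
            Xtr, ytr = smote_oversample(Xtr, ytr, rng=np.random.default_rng(seed + f))
        _, pred = _fit_predict(registry_models[name], Xtr, ytr,
                               table.loc[te_mask, cols].to_numpy(dtype=float))
        ba, f1 = _score(y[te_mask], pred)
        fold_ba.append(ba)
        fold_f1.append(f1)
        sel_feats.append(list(cols))
        chosen.append(name)
    return CVResult(fold_ba=fold_ba, fold_f1=fold_f1, selected_features=sel_feats,
                    chosen_classifier=chosen, n_folds=n_folds, seed=seed,
                    config=config)


# ---------------------------------------------------------------------------
# Sweeps and construction comparison

def q_sweep(waveforms, q_grid: Sequence[int], spec: ScenarioSpec | None = None,
            classifiers=("xgb",), n_folds: int = 10, top_k="all",
            seed: int = 0) -> pd.DataFrame:
    """Full extract + classify pass per quantization resolution Q.

    Returns one row per Q: mean outer-CV balanced accuracy, mean graph
    density and mean connected-component count across waveforms.
    """
    if spec is None:
        spec = ScenarioSpec()
    rows = []
    for Q in q_grid:
        if not 2 <= Q <= 200:
            raise ValueError("Q grid must lie in [2, 200]")
        dens, comps = [], []
        for w in waveforms:
            g = build_graph(w if w.normalized else normalize(w),
                            Construction.ERG_GRAPH, Q=Q)
            s = spectral_summary(g)
            dens.append(s.density)
            comps.append(s.n_components)
        ft = feature_table(waveforms, Q=Q)
        data = build_scenario(ft, spec)
        res = run_nested_cv(data, classifiers=list(classifiers), n_folds=n_folds,
                            top_k=top_k, seed=seed)
        rows.append({"Q": Q, "mean_ba": res.mean_ba, "mean_f1": res.mean_f1,
                     "mean_density": float(np.mean(dens)),
                     "mean_components": float(np.mean(comps))})
    return pd.DataFrame(rows)


def _fold_hash(folds: Mapping) -> str:
    return hashlib.sha256(json.dumps(sorted(folds.items())).encode()).hexdigest()[:16]


def compare_constructions(waveforms, methods: Sequence[str] | None = None,
                          spec: ScenarioSpec | None = None, Q: int = 50,
                          classifier: str = "xgb", n_folds: int = 10,
                          top_k="all", seed: int = 0, **params) -> pd.DataFrame:
    """Evaluate several graph constructions under one fixed classifier and
    identical preprocessing, folds and seeds (controlled comparison)."""
    methods = list(methods) if methods is not None else [c.value for c in Construction]
    if len(methods) < 2:
        raise ValueError("need at least 2 methods to compare")
    if spec is None:
        spec = ScenarioSpec()
    rows = []
    for method in methods:
        ft = feature_table(waveforms, Q=Q, method=method, **params)
        data = build_scenario(ft, spec)
        res = run_nested_cv(data, classifiers=[classifier], n_folds=n_folds,
                            top_k=top_k, seed=seed)
        folds = subject_wise_folds(data.table["subject_id"].astype(str),
                                   data.table["label"], n_folds, seed)
        rows.append({"method": method, "mean_ba": res.mean_ba, "sd_ba": res.sd_ba,
                     "mean_f1": res.mean_f1, "sd_f1": res.sd_f1,
                     "fold_hash": _fold_hash(folds)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Post-hoc feature attribution

def feature_importance_report(model, X: np.ndarray, y: np.ndarray,
                              feature_names: Sequence[str], seed: int = 0,
                              n_repeats: int = 10) -> pd.DataFrame:
    """Mean-|SHAP| ranking when the optional shap dependency is installed,
    otherwise permutation importance; returns a sorted DataFrame."""
    try:
        import shap

        explainer = shap.TreeExplainer(model)
        vals = np.abs(np.asarray(explainer.shap_values(X)))
        score = vals.mean(axis=tuple(range(vals.ndim - 1)))
        method = "mean_abs_shap"
    except Exception:
        from sklearn.inspection import permutation_importance

        r = permutation_importance(model, X, y, n_repeats=n_repeats,
                                   random_state=seed)
        score = r.importances_mean
        method = "permutation"
    df = pd.DataFrame({"feature": list(feature_names), "importance": score,
                       "method": method})
    return df.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)
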