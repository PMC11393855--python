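"""End-to-end orchestration: extract -> select -> train -> evaluate.

Evaluation is stratified k-fold (default 10) scored by Unweighted
Average Recall. Feature selection and feature scaling are fitted on each
fold's training split only, so test clips can never leak into selection
or training for their own fold.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .boost import AdaBoostWELMClassifier
from .elm import ELMClassifier, WELMClassifier, KernelWELMClassifier, resolve_view_split
from .features import FeatureTable, extract_features
from .metrics import uar, stratified_folds
from .optim import optimize_welm
from .selection import GEOSelector, SalpSelector
from .synth import SynthSpec, make_dataset

__all__ = ["RunConfig", "EvalReport", "SwarmBoostedWELMClassifier",
           "make_classifier", "make_selector", "run_pipeline",
           "uar", "stratified_folds"]

SELECTORS = ("none", "geo", "ssa", "rssa")
CLASSIFIERS = ("elm", "welm", "wkelm", "ckelm", "adaboost_welm",
               "fa_welm_adaboost", "csa_welm_adaboost",
               "dt", "nbc", "rf", "lr", "lda", "svm")


class SwarmBoostedWELMClassifier(BaseEstimator, ClassifierMixin):
    """FA/CSA-tuned WELM boosted with Adaboost (the FA/CSA-WELM-Adaboost model).

    The swarm optimizer tunes the WELM hidden layer once, on an inner
    stratified train/validation split of the training data; the tuned
    hidden parameters are then frozen and Adaboost re-solves the output
    weights each round under its reweighted sample distribution.
    """

    def __init__(self, optimizer: str = "fa", n_hidden: int = 50,
                 ridge: float = 0.01, n_rounds: int = 10, pop: int = 12,
                 iters: int = 12, val_fraction: float = 0.25, random_state: int = 0):
        self.optimizer = optimizer
        self.n_hidden = n_hidden
        self.ridge = ridge
        self.n_rounds = n_rounds
        self.pop = pop
        self.iters = iters
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        X_tr, X_val, y_tr, y_val = train_test_split(
            X, y, test_size=self.val_fraction, stratify=y,
            random_state=self.random_state)
        tuned = optimize_welm(X_tr, y_tr, X_val, y_val, optimizer=self.optimizer,
                              n_hidden=self.n_hidden, ridge=self.ridge,
                              pop=self.pop, iters=self.iters, seed=self.random_state)
        base = WELMClassifier(n_hidden=self.n_hidden, ridge=self.ridge,
                              random_state=self.random_state,
                              hidden=(tuned.input_weights_, tuned.biases_))
        self.booster_ = AdaBoostWELMClassifier(base=base, n_rounds=self.n_rounds,
                                               random_state=self.random_state)
        self.booster_.fit(X, y)
        self.classes_ = self.booster_.classes_
        return self

    def predict(self, X):
        return self.booster_.predict(X)

    def decision_function(self, X):
        return self.booster_.decision_function(X)


def make_classifier(name: str, *, random_state: int = 0, feature_names=None,
                    **kw) -> BaseEstimator:
    """Instantiate a classifier by registry name."""
    if name == "elm":
        return ELMClassifier(n_hidden=100, ridge=0.01, random_state=random_state, **kw)
    if name == "welm":
        return WELMClassifier(n_hidden=100, ridge=0.01, random_state=random_state, **kw)
    if name == "wkelm":
        return KernelWELMClassifier(kernel="rbf", gamma=kw.pop("gamma", 0.01),
                                    ridge=kw.pop("ridge", 0.01), **kw)
    if name == "ckelm":
        if feature_names is None:
            raise ValueError("ckelm needs feature_names to build its view split")
        split = resolve_view_split(list(feature_names))
        return KernelWELMClassifier(kernel="composited", view_split=split,
                                    gamma=kw.pop("gamma", 0.01), mu=kw.pop("mu", 0.5),
                                    ridge=kw.pop("ridge", 0.01), **kw)
    if name == "adaboost_welm":
        return AdaBoostWELMClassifier(base=WELMClassifier(n_hidden=50, ridge=0.01),
                                      n_rounds=kw.pop("n_rounds", 10),
                                      random_state=random_state)
    if name in ("fa_welm_adaboost", "csa_welm_adaboost"):
        return SwarmBoostedWELMClassifier(optimizer=name.split("_")[0],
                                          random_state=random_state, **kw)
    baselines = {
        "dt": lambda: DecisionTreeClassifier(random_state=random_state),
        "nbc": GaussianNB,
        "rf": lambda: RandomForestClassifier(n_estimators=100, random_state=random_state),
        "lr": lambda: LogisticRegression(max_iter=2000, random_state=random_state),
        "lda": LinearDiscriminantAnalysis,
        "svm": lambda: LinearSVC(random_state=random_state),
    }
    if name in baselines:
        return baselines[name]()
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIERS}")


def make_selector(name: str, *, random_state: int = 0, **kw):
    """Instantiate a feature selector by registry name (None for 'none')."""
    if name in (None, "none"):
        return None
    if name == "geo":
        return GEOSelector(random_state=random_state, **kw)
    if name == "ssa":
        return SalpSelector(refined=False, random_state=random_state, **kw)
    if name == "rssa":
        return SalpSelector(refined=True, random_state=random_state, **kw)
    raise ValueError(f"unknown selector {name!r}; expected one of {SELECTORS}")


@dataclass
class RunConfig:
    """Everything needed for one reproducible evaluation run."""

    domains: tuple[str, ...] = ("time", "cepstral")
    selector: str = "none"
    selector_params: dict = field(default_factory=dict)
    classifier: str = "welm"
    classifier_params: dict = field(default_factory=dict)
    cv_folds: int = 10
    seed: int = 0
    # data source: either a feature CSV or synthetic generation settings
    features_csv: str | None = None
    synth: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = cls.__dataclass_fields__
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "domains" in raw:
            raw["domains"] = tuple(raw["domains"])
        return cls(**raw)


@dataclass
class EvalReport:
    fold_uars: list[float]
    mean_uar: float
    confusion: list[list[int]]
    classes: list[str]
    masks: list[dict]
    config: dict
    runtime_s: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def summary(self) -> str:
        lines = [f"mean UAR over {len(self.fold_uars)} folds: {self.mean_uar:.4f}"]
        lines += [f"  fold {i}: UAR {u:.4f}" for i, u in enumerate(self.fold_uars)]
        if self.masks:
            sizes = [m["n_selected"] for m in self.masks]
            lines.append(f"selected features per fold: {sizes}")
        return "\n".join(lines)


def _load_table(config: RunConfig) -> FeatureTable:
    if config.features_csv:
        return FeatureTable.from_csv(config.features_csv)
    spec = SynthSpec(seed=config.seed, **config.synth)
    clips = make_dataset(spec)
    return extract_features(clips, config.domains)


def evaluate_folds(table: FeatureTable, config: RunConfig) -> EvalReport:
    """Stratified k-fold evaluation with per-fold selection and scaling."""
    t0 = time.perf_counter()
    y = table.labels
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed)
    fold_uars, masks = [], []
    y_true_all, y_pred_all = [], []
    classes = np.unique(y)
    for fold, (tr, te) in enumerate(skf.split(table.X, y)):
        X_tr, X_te = table.X[tr], table.X[te]
        names = table.names
        selector = make_selector(config.selector, random_state=config.seed + fold,
                                 **config.selector_params)
        if selector is not None:
            selector.fit(X_tr, y[tr])
            support = selector.support_
            X_tr, X_te = X_tr[:, support], X_te[:, support]
            names = [n for n, b in zip(table.names, support) if b]
            masks.append({"fold": fold, "n_selected": int(support.sum()),
                          "fitness": float(selector.fitness_),
                          "selected": names})
        scaler = StandardScaler().fit(X_tr)
        X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        clf = make_classifier(config.classifier, random_state=config.seed,
                              feature_names=names, **config.classifier_params)
        clf.fit(X_tr, y[tr])
        pred = clf.predict(X_te)
        fold_uars.append(uar(y[te], pred))
        y_true_all.append(y[te])
        y_pred_all.append(pred)
    cm = confusion_matrix(np.concatenate(y_true_all), np.concatenate(y_pred_all),
                          labels=classes)
    cfg = asdict(config)
    cfg["domains"] = list(config.domains)
    return EvalReport(fold_uars=[float(u) for u in fold_uars],
                      mean_uar=float(np.mean(fold_uars)),
                      confusion=cm.tolist(),
                      classes=[str(c) for c in classes],
                      masks=masks, config=cfg,
                      runtime_s=time.perf_counter() - t0)


def run_pipeline(config: RunConfig) -> EvalReport:
    """Load or synthesize data, then run the k-fold evaluation."""
    try:
        table = _load_table(config)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'data/extract' failed: {exc}") from exc
    return evaluate_folds(table, config)
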