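"""Neural-network classification with repeated random sub-sampling.

Each repeat draws a fresh random 60/5/35 train/validation/test split,
trains a two-layer feed-forward network (one hidden layer of 20
sigmoidal units, softmax-style output over the classes) with
validation-based early stopping, and scores plain accuracy on the test
portion; the report carries the per-repeat accuracies and their mean and
standard deviation over (by default) 20 repeats.  Features are z-scored
with statistics fitted on the training portion only.  A split that
leaves a class absent from the training or test portion is redrawn with
an incremented sub-seed (at most 10 attempts).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix, log_loss
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .mrmr import FeatureDataset


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture and trainer settings for the feed-forward network."""

    hidden_units: int = 20
    activation: str = "logistic"
    learning_rate: float = 0.01
    batch_size: int = 200
    max_epochs: int = 200
    patience: int = 20

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")


@dataclass(frozen=True)
class EvalProtocol:
    """Repeated random sub-sampling protocol."""

    train_frac: float = 0.60
    val_frac: float = 0.05
    test_frac: float = 0.35
    n_repeats: int = 20
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class EvalReport:
    """Per-repeat accuracies (percent) and their summary statistics."""

    case: str
    per_repeat: tuple[float, ...]
    mean: float
    sd: float
    confusions: tuple[np.ndarray, ...]
    selected: tuple[tuple[str, ...], ...]
    class_names: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "case": self.case,
            "k": len(self.selected[0]) if self.selected else 0,
            "per_repeat": list(self.per_repeat),
            "mean": self.mean,
            "sd": self.sd,
            "selected": [list(s) for s in self.selected],
            "class_names": list(self.class_names),
        }


def _draw_split(rng: np.random.Generator, n: int,
                proto: EvalProtocol) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    n_tr = int(round(proto.train_frac * n))
    n_val = int(round(proto.val_frac * n))
    return perm[:n_tr], perm[n_tr:n_tr + n_val], perm[n_tr + n_val:]


def _fit_mlp(X_tr: np.ndarray, y_tr: np.ndarray, X_val: np.ndarray,
             y_val: np.ndarray, classes: np.ndarray, spec: ClassifierSpec,
             seed: int) -> MLPClassifier:
    """Train with explicit validation-set early stopping via partial_fit.

    The monitored quantity is the validation log-loss (cross-entropy):
    unlike accuracy it keeps improving after the small validation split
    is classified correctly, so training is not cut off prematurely.
    The parameters of the best-validation epoch are restored at the end.
    """
    mlp = MLPClassifier(
        hidden_layer_sizes=(spec.hidden_units,),
        activation=spec.activation,
        solver="adam",
        learning_rate_init=spec.learning_rate,
        batch_size=min(spec.batch_size, len(y_tr)),
        random_state=seed,
    )
    best_loss = np.inf
    best_params = None
    stall = 0
    X_mon, y_mon = (X_val, y_val) if len(y_val) else (X_tr, y_tr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter from sklearn
        for _ in range(spec.max_epochs):
            mlp.partial_fit(X_tr, y_tr, classes=classes)
            loss = log_loss(y_mon, mlp.predict_proba(X_mon), labels=classes)
            if loss < best_loss - 1e-6:
                best_loss = loss
                best_params = (copy.deepcopy(mlp.coefs_),
                               copy.deepcopy(mlp.intercepts_))
                stall = 0
            else:
                stall += 1
                if stall >= spec.patience:
                    break
    if best_params is not None:
        mlp.coefs_, mlp.intercepts_ = best_params
    return mlp


def train_eval(ds: FeatureDataset,
               selected: Sequence[str] | None = None,
               clf: ClassifierSpec | None = None,
               proto: EvalProtocol | None = None,
               selector: Callable[[FeatureDataset], Sequence[str]] | None = None,
               case: str = "") -> EvalReport:
    """Run the repeated random sub-sampling evaluation.

    ``selected`` fixes the feature subset for every repeat; alternatively
    ``selector`` is called on the training portion of each repeat (the
    leakage-safe protocol) and may differ from repeat to repeat.  With
    neither, all features are used.
    """
    clf = clf or ClassifierSpec()
    proto = proto or EvalProtocol()
    if selected is not None:
        missing = set(selected) - set(ds.feature_names)
        if missing:
            raise ValueError(f"unknown features requested: {sorted(missing)}")
    classes = np.unique(ds.y)
    if classes.size < 2:
        raise ValueError("evaluation needs at least 2 classes")
    n = ds.n_samples
    seeds = np.random.SeedSequence(proto.seed).generate_state(
        proto.n_repeats * 2, dtype=np.uint32)

    accs: list[float] = []
    confusions: list[np.ndarray] = []
    selections: list[tuple[str, ...]] = []
    for rep in range(proto.n_repeats):
        split_seed = int(seeds[2 * rep])
        for attempt in range(10):
            rng = np.random.default_rng(split_seed + attempt)
            tr, val, te = _draw_split(rng, n, proto)
            ok = (set(classes) <= set(ds.y[tr])
                  and set(classes) <= set(ds.y[te]))
            if ok:
                break
        else:
            raise RuntimeError(
                f"repeat {rep}: could not draw a split containing every "
                "class in train and test after 10 attempts")

        if selector is not None:
            train_ds = FeatureDataset(ds.X[tr], ds.y[tr], ds.feature_names,
                                      ds.class_names)
            names = tuple(selector(train_ds))
        elif selected is not None:
            names = tuple(selected)
        else:
            names = ds.feature_names
        selections.append(names)
        cols = [ds.feature_names.index(f) for f in names]

        X_tr, X_val, X_te = ds.X[tr][:, cols], ds.X[val][:, cols], \
            ds.X[te][:, cols]
        if proto.standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr = scaler.transform(X_tr)
            X_val = scaler.transform(X_val) if len(val) else X_val
            X_te = scaler.transform(X_te)
        mlp = _fit_mlp(X_tr, ds.y[tr], X_val, ds.y[val], classes, clf,
                       seed=int(seeds[2 * rep + 1]) % (2 ** 31))
        pred = mlp.predict(X_te)
        accs.append(100.0 * accuracy_score(ds.y[te], pred))
        confusions.append(confusion_matrix(ds.y[te], pred, labels=classes))

    accs_arr = np.array(accs)
    sd = float(accs_arr.std(ddof=1)) if len(accs) > 1 else 0.0
    return EvalReport(case=case, per_repeat=tuple(accs),
                      mean=float(accs_arr.mean()), sd=sd,
                      confusions=tuple(confusions),
                      selected=tuple(selections),
                      class_names=ds.class_names)
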