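"""Bagged class-weighted logistic-regression experts.

One expert is trained per functional characterization dataset: an ensemble
of L2-penalized binary logistic regressions, each member fit on a bootstrap
resample of the training loci with per-sample weights given by the class
weight rule w(activating) = n_neutral, w(neutral) = 3 * n_activating. That
rule yields an effective activating fraction of exactly 1/4 regardless of
the raw class counts, so expert scores concentrate probability mass on the
activating tail rather than being balanced. The ensemble prediction is the
mean of the member probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

DEFAULT_N_MEMBERS = 100
DEFAULT_C = 1.0


class ExpertError(ValueError):
    pass


@dataclass(frozen=True)
class ClassWeights:
    w_activating: float
    w_neutral: float

    @property
    def effective_positive_fraction(self) -> float:
        """Weighted activating fraction implied by the counts that produced us."""
        # w_a = n_n, w_n = 3 n_a  =>  n_a w_a / (n_a w_a + n_n w_n) = 1/4
        return 0.25


def class_weights(n_activating: int, n_neutral: int) -> ClassWeights:
    """Class weight rule: activating regions get weight n_neutral, neutral 3*n_activating."""
    if n_activating <= 0 or n_neutral <= 0:
        raise ExpertError("both classes must be non-empty")
    return ClassWeights(float(n_neutral), float(3 * n_activating))


def effective_positive_fraction(n_activating: int, n_neutral: int) -> float:
    """Weighted positive fraction n_a*w_a / (n_a*w_a + n_n*w_n) under the rule."""
    w = class_weights(n_activating, n_neutral)
    num = n_activating * w.w_activating
    return num / (num + n_neutral * w.w_neutral)


@dataclass(frozen=True)
class ExpertConfig:
    n_members: int = DEFAULT_N_MEMBERS
    C: float = DEFAULT_C
    seed: int = 0
    bootstrap: bool = True
    tol: float = 1e-6
    max_iter: int = 1000
    max_redraws: int = 20   # retries when a bootstrap misses a class


@dataclass
class ExpertEnsemble:
    """Fitted bagging ensemble for one dataset."""

    name: str
    cell_type: str
    assay_class: str
    feature_names: tuple[str, ...]
    coefs: np.ndarray        # (n_members, n_features)
    intercepts: np.ndarray   # (n_members,)
    config: ExpertConfig

    @property
    def n_members(self) -> int:
        return self.coefs.shape[0]

    def predict(self, X: np.ndarray, feature_names=None) -> np.ndarray:
        return predict_expert(self, X, feature_names)

    def to_json(self, path) -> None:
        obj = {
            "name": self.name,
            "cell_type": self.cell_type,
            "assay_class": self.assay_class,
            "feature_names": list(self.feature_names),
            "coefs": self.coefs.tolist(),
            "intercepts": self.intercepts.tolist(),
            "config": vars(self.config) if not hasattr(self.config, "__dict__") else {
                k: getattr(self.config, k) for k in (
                    "n_members", "C", "seed", "bootstrap", "tol", "max_iter", "max_redraws")
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "ExpertEnsemble":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            name=obj["name"],
            cell_type=obj["cell_type"],
            assay_class=obj["assay_class"],
            feature_names=tuple(obj["feature_names"]),
            coefs=np.asarray(obj["coefs"]),
            intercepts=np.asarray(obj["intercepts"]),
            config=ExpertConfig(**obj["config"]),
        )


def _member_rng(base_seed: int, member: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(member,)))


def train_expert(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ExpertConfig = ExpertConfig(),
    name: str = "expert",
    cell_type: str = "",
    assay_class: str = "",
    feature_names: tuple[str, ...] | None = None,
) -> ExpertEnsemble:
    """Fit the bagging ensemble on standardized features and binary labels.

    Each member draws N loci with replacement (a bootstrap of the full
    training set); a drawn locus carries its class weight as sample weight in
    the member's log-loss. The L2 penalty applies to coefficients only.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(bool)
    n = X.shape[0]
    n_act, n_neut = int(y.sum()), int((~y).sum())
    if n_act == 0 or n_neut == 0:
        raise ExpertError("training data must contain both classes")
    w = class_weights(n_act, n_neut)
    sample_w = np.where(y, w.w_activating, w.w_neutral)

    coefs = np.empty((cfg.n_members, X.shape[1]))
    intercepts = np.empty(cfg.n_members)
    for m in range(cfg.n_members):
        rng = _member_rng(cfg.seed, m)
        if cfg.bootstrap:
            for attempt in range(cfg.max_redraws + 1):
                idx = rng.integers(0, n, size=n)
                if y[idx].any() and (~y[idx]).any():
                    break
            else:
                raise ExpertError(f"member {m}: bootstrap never contained both classes")
        else:
            idx = np.arange(n)
        # default penalty is the L2 norm; lbfgs leaves the intercept unpenalized
        clf = LogisticRegression(
            C=cfg.C, solver="lbfgs", tol=cfg.tol, max_iter=cfg.max_iter
        )
        clf.fit(X[idx], y[idx], sample_weight=sample_w[idx])
        coefs[m] = clf.coef_[0]
        intercepts[m] = clf.intercept_[0]
    return ExpertEnsemble(
        name, cell_type, assay_class,
        tuple(feature_names) if feature_names is not None else tuple(f"f{i}" for i in range(X.shape[1])),
        coefs, intercepts, cfg,
    )


def predict_expert(ens: ExpertEnsemble, X: np.ndarray, feature_names=None) -> np.ndarray:
    """Mean of member sigmoid probabilities; values in [0, 1]."""
    X = np.asarray(X, dtype=np.float64)
    if feature_names is not None and tuple(feature_names) != tuple(ens.feature_names):
        raise ExpertError("feature names do not match the ensemble's training features")
    if X.shape[1] != ens.coefs.shape[1]:
        raise ExpertError(
            f"feature count mismatch: got {X.shape[1]}, expected {ens.coefs.shape[1]}"
        )
    z = X @ ens.coefs.T + ens.intercepts  # (n, members)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-z))
    return p.mean(axis=1)
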