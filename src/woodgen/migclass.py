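"""Immigrant-vs-local classification with a Random-Forest ensemble.

Immigrants and locally born birds show no clear separation on single
principal components, but nonlinear combinations of PCs may still carry
signal.  The pipeline: balance the two classes by undersampling the
majority, split 70/30 stratified by class, feed the first 15 PC scores to a
Random Forest, and repeat over many resampled splits to get an accuracy
distribution.  A label-permutation null establishes the chance baseline
(balanced accuracy ~50%).  An ensemble of 50 forests on one split averages
the tree-proximity matrices; classical MDS of (1 - averaged proximity)
visualises the model's similarity space, and per-individual vote fractions
quantify classification confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import logging

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

__all__ = ["ClassifierConfig", "ClassifierReport", "balanced_split",
           "rf_ensemble", "null_baseline", "classical_mds"]


@dataclass
class ClassifierConfig:
    train_frac: float = 0.70
    n_pcs: int = 15
    n_forests: int = 50
    trees_per_forest: int = 500
    n_repeats: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.n_pcs < 2:
            raise ValueError("need at least 2 principal components")


@dataclass
class ClassifierReport:
    accuracy_mean: float
    accuracy_sd: float
    rate_local: float
    rate_immigrant: float
    balanced_accuracy: float
    oob_error: float
    null_balanced_accuracy_mean: float | None
    null_sd: float | None
    vote_fraction: pd.DataFrame | None      # id, class, mean immigrant vote
    proximity: np.ndarray | None            # averaged, over balanced samples
    mds: np.ndarray | None                  # (n, 2), centred
    sample_ids: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("accuracy_mean", "accuracy_sd", "rate_local",
                 "rate_immigrant", "balanced_accuracy", "oob_error",
                 "null_balanced_accuracy_mean", "null_sd")}


def balanced_split(labels: np.ndarray, cfg: ClassifierConfig,
                   rng: np.random.Generator):
    """Undersample the majority class, then a stratified train/test split.

    Returns (balanced_idx, train_idx, test_idx) as indices into ``labels``.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    if counts.min() < 10:
        raise ValueError("each class needs at least 10 samples")
    n_keep = counts.min()
    train, test, balanced = [], [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = rng.choice(idx, size=n_keep, replace=False)
        rng.shuffle(idx)
        n_train = int(round(cfg.train_frac * n_keep))
        train.append(idx[:n_train])
        test.append(idx[n_train:])
        balanced.append(idx)
    return (np.sort(np.concatenate(balanced)),
            np.concatenate(train), np.concatenate(test))


def _forest(cfg: ClassifierConfig, seed: int, oob: bool = False):
    return RandomForestClassifier(n_estimators=cfg.trees_per_forest,
                                  oob_score=oob, n_jobs=1,
                                  random_state=int(seed % (2**31)))


def _proximity(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees in which two samples fall in the same leaf."""
    leaves = forest.apply(X)  # (n, n_trees)
    n = len(X)
    prox = np.zeros((n, n))
    for t in range(leaves.shape[1]):
        col = leaves[:, t]
        same = col[:, None] == col[None, :]
        prox += same
    return prox / leaves.shape[1]


def _train_only_pca(X_raw, tr, te, n_pcs):
    """Leakage-safe features: PCA fitted on the training rows only, test
    rows projected onto the training axes."""
    mu = X_raw[tr].mean(axis=0)
    sd = X_raw[tr].std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X_raw - mu) / sd
    _, _, vt = np.linalg.svd(Z[tr], full_matrices=False)
    comps = vt[:n_pcs].T
    return Z @ comps


def _accuracy_pass(X, y, cfg, rng, permute: bool, X_raw=None):
    yy = y.copy()
    if permute:
        yy = rng.permutation(yy)
    _, tr, te = balanced_split(yy, cfg, rng)
    if X_raw is not None:
        X = _train_only_pca(X_raw, tr, te, cfg.n_pcs)
    clf = _forest(cfg, rng.integers(2**31))
    clf.fit(X[tr], yy[tr])
    pred = clf.predict(X[te])
    acc = float((pred == yy[te]).mean())
    rates = {}
    for c in np.unique(yy):
        mask = yy[te] == c
        rates[c] = float((pred[mask] == c).mean()) if mask.any() else np.nan
    bal = float(np.nanmean(list(rates.values())))
    return acc, rates, bal


def rf_ensemble(features: np.ndarray, labels: np.ndarray,
                cfg: ClassifierConfig | None = None,
                sample_ids: np.ndarray | None = None,
                with_null: bool = False,
                raw_genotypes: np.ndarray | None = None,
                leakage_safe: bool = False) -> ClassifierReport:
    """Repeated-split accuracy distribution plus a proximity ensemble.

    ``features`` are PC scores (n_samples x >= n_pcs); only the first
    ``n_pcs`` columns are used.  By default the features come from a PCA
    fitted on the full sample before splitting, mirroring the replicated
    analysis order even though test samples influence the axes; pass
    ``leakage_safe=True`` together with ``raw_genotypes`` (a dosage
    matrix) to refit the PCA on each training split instead.  Ties in the
    ensemble vote break toward 'local' by fixed rule.
    """
    if cfg is None:
        cfg = ClassifierConfig()
    X = np.asarray(features, dtype=float)[:, :cfg.n_pcs]
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    X_raw = None
    if leakage_safe:
        if raw_genotypes is None:
            raise ValueError("leakage_safe=True requires raw_genotypes")
        X_raw = np.asarray(raw_genotypes, dtype=float)
    else:
        logger.info("PCA features were fitted on the full sample before "
                    "splitting; pass leakage_safe=True for split-wise PCA")
    y = np.asarray(labels)
    rng = np.random.default_rng(cfg.seed)

    accs, bals, rl, ri = [], [], [], []
    for _ in range(cfg.n_repeats):
        acc, rates, bal = _accuracy_pass(X, y, cfg, rng, permute=False,
                                         X_raw=X_raw)
        accs.append(acc); bals.append(bal)
        rl.append(rates.get("local", np.nan))
        ri.append(rates.get("immigrant", np.nan))

    # ensemble of forests on one balanced split
    bal_idx, tr, te = balanced_split(y, cfg, rng)
    Xb, yb = X[bal_idx], y[bal_idx]
    prox = np.zeros((len(bal_idx), len(bal_idx)))
    votes = np.zeros(len(bal_idx))
    oob = []
    pos = {v: i for i, v in enumerate(bal_idx)}
    tr_local = np.array([pos[i] for i in tr])
    classes = np.unique(y)
    imm_label = "immigrant" if "immigrant" in classes else classes[-1]
    for f in range(cfg.n_forests):
        clf = _forest(cfg, rng.integers(2**31), oob=True)
        clf.fit(Xb[tr_local], yb[tr_local])
        oob.append(1.0 - clf.oob_score_)
        prox += _proximity(clf, Xb)
        col = list(clf.classes_).index(imm_label)
        votes += clf.predict_proba(Xb)[:, col]
    prox /= cfg.n_forests
    votes /= cfg.n_forests
    mds = classical_mds(1.0 - prox, k=2)

    ids = (np.asarray(sample_ids)[bal_idx] if sample_ids is not None
           else bal_idx)
    vote_df = pd.DataFrame({"id": ids, "label": yb,
                            "immigrant_vote": votes,
                            "predicted": np.where(votes > 0.5, imm_label,
                                                  "local")})

    null_mean = null_sd = None
    if with_null:
        nb = null_baseline(features, labels, cfg)
        null_mean, null_sd = float(np.mean(nb)), float(np.std(nb))

    return ClassifierReport(
        accuracy_mean=float(np.mean(accs)), accuracy_sd=float(np.std(accs)),
        rate_local=float(np.nanmean(rl)), rate_immigrant=float(np.nanmean(ri)),
        balanced_accuracy=float(np.mean(bals)), oob_error=float(np.mean(oob)),
        null_balanced_accuracy_mean=null_mean, null_sd=null_sd,
        vote_fraction=vote_df, proximity=prox, mds=mds, sample_ids=ids)


def null_baseline(features: np.ndarray, labels: np.ndarray,
                  cfg: ClassifierConfig | None = None) -> np.ndarray:
    """Balanced-accuracy distribution under per-repeat label permutation."""
    if cfg is None:
        cfg = ClassifierConfig()
    X = np.asarray(features, dtype=float)[:, :cfg.n_pcs]
    y = np.asarray(labels)
    rng = np.random.default_rng(cfg.seed + 1)
    bals = []
    for _ in range(cfg.n_repeats):
        _, _, bal = _accuracy_pass(X, y, cfg, rng, permute=True)
        bals.append(bal)
    return np.array(bals)


def classical_mds(dist: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) scaling of a distance matrix to k dimensions."""
    d2 = np.asarray(dist, dtype=float) ** 2
    n = len(d2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals)
    return coords - coords.mean(axis=0)
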