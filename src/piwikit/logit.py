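"""Logistic decision function for in vivo cleavage probability.

P(cleaved) = 1 / (1 + exp(-(b0 + b1 x1 + ... + b35 x35))) over 35 features:
per-position pairing indicators for g2-g25 (x1-x24), total paired
nucleotides (x25), piRNA abundance (x26), negative predicted duplex
delta-G0 (x27) -- each rescaled to [0, 1] -- plus one-vs-rest t1-identity
indicators (x28-x31) and target-region indicators (x32-x35).

The ensemble scheme fits 5x-repeated stratified 5-fold cross-validation
within each of 16 cohort permutations: 16 x 5 x 5 = 400 models, with
L2 regularization (lambda = 1, i.e. scikit-learn C = 1), balanced class
weights, L-BFGS, and at most 1,000 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold

PAIRING_FEATURES = [f"pair_g{i}" for i in range(2, 26)]           # x1-x24
CONTINUOUS_FEATURES = ["paired_count", "abundance", "neg_delta_g0"]  # x25-x27
T1_FEATURES = ["t1A", "t1U", "t1C", "t1G"]                         # x28-x31
REGION_FEATURES = ["utr5", "orf", "utr3", "lncRNA"]                # x32-x35
FEATURE_NAMES = PAIRING_FEATURES + CONTINUOUS_FEATURES + T1_FEATURES + REGION_FEATURES

MIN_PAIRED = 19          # inclusion: >= 19 paired nucleotides in g2-g25
MIN_ABUNDANCE_PPM = 0.1  # inclusion: piRNA abundance >= 0.1 ppm

N_PERMUTATIONS = 16
N_REPEATS = 5
N_SPLITS = 5


def minmax_rescale(x: np.ndarray, lo: Optional[float] = None,
                   hi: Optional[float] = None) -> np.ndarray:
    """Min-max rescale to [0, 1]; out-of-range values (when applying a
    training-set scale to held-out data) are clipped."""
    x = np.asarray(x, float)
    lo = float(np.min(x)) if lo is None else lo
    hi = float(np.max(x)) if hi is None else hi
    if hi <= lo:
        return np.zeros_like(x)
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def build_features(candidates: pd.DataFrame) -> pd.DataFrame:
    """Assemble the 35-feature matrix from annotated candidate sites.

    ``candidates`` needs: ``pairing`` (24-character string of 0/1 for
    g2..g25, or an iterable of bools), ``abundance_ppm``, ``delta_g0``,
    ``t1`` (A/U/C/G), ``region`` (5UTR/ORF/3UTR/lncRNA), ``has_indel``
    and ``cleaved``.  Rows failing the inclusion filter (>= 19 paired
    positions in g2-g25, abundance >= 0.1 ppm, no indels) are dropped, with
    reasons tallied in ``attrs['excluded']``.  The continuous features are
    returned min-max rescaled on the included set; unscaled copies are kept
    in ``attrs['raw_continuous']`` for fold-level rescaling.
    """
    pair = np.array([
        [bool(int(c)) if isinstance(p, str) else bool(c) for c in p]
        for p in candidates["pairing"]
    ])
    if pair.shape[1] != 24:
        raise ValueError("pairing must describe positions g2..g25 (24 values)")
    paired_count = pair.sum(axis=1)
    excluded = {
        "too_few_paired": int((paired_count < MIN_PAIRED).sum()),
        "low_abundance": int(
            (candidates["abundance_ppm"].to_numpy(float) < MIN_ABUNDANCE_PPM).sum()
        ),
        "has_indel": int(candidates["has_indel"].astype(bool).sum()),
    }
    keep = (
        (paired_count >= MIN_PAIRED)
        & (candidates["abundance_ppm"].to_numpy(float) >= MIN_ABUNDANCE_PPM)
        & ~candidates["has_indel"].astype(bool).to_numpy()
    )
    sub = candidates[keep].reset_index(drop=True)
    pair = pair[keep]
    raw = np.column_stack([
        pair.sum(axis=1).astype(float),
        sub["abundance_ppm"].to_numpy(float),
        -sub["delta_g0"].to_numpy(float),
    ])
    X = pd.DataFrame(pair.astype(float), columns=PAIRING_FEATURES)
    for j, name in enumerate(CONTINUOUS_FEATURES):
        X[name] = minmax_rescale(raw[:, j])
    t1 = sub["t1"].astype(str).str.upper()
    for base, name in zip("AUCG", T1_FEATURES):
        X[name] = (t1 == base).astype(float)
    region = sub["region"].astype(str)
    X["utr5"] = (region == "5UTR").astype(float)
    X["orf"] = (region == "ORF").astype(float)
    X["utr3"] = (region == "3UTR").astype(float)
    X["lncRNA"] = (region == "lncRNA").astype(float)
    X = X[FEATURE_NAMES]
    X["cleaved"] = sub["cleaved"].astype(int).to_numpy()
    X.attrs["excluded"] = excluded
    X.attrs["raw_continuous"] = raw
    return X


@dataclass
class ModelEnsemble:
    """400 fitted coefficient vectors with provenance and held-out PR-AUC."""

    intercepts: np.ndarray          # (n_models,)
    coefficients: np.ndarray        # (n_models, 35)
    provenance: pd.DataFrame        # permutation, repeat, fold per model
    pr_auc_heldout: np.ndarray      # (n_models,)
    feature_names: List[str]

    @property
    def n_models(self) -> int:
        return len(self.intercepts)

    def coefficient_summary(self) -> pd.DataFrame:
        """Median and IQR of each coefficient over the ensemble."""
        q1, med, q3 = np.percentile(self.coefficients, [25, 50, 75], axis=0)
        return pd.DataFrame(
            {"median": med, "q1": q1, "q3": q3}, index=self.feature_names
        )


def pr_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve by trapezoidal integration.

    Predictions are ranked descending with stable tie-breaking; tied scores
    contribute a single PR point so the curve is threshold-wise.  Undefined
    (no positive labels) raises.
    """
    labels = np.asarray(labels, int)
    scores = np.asarray(scores, float)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("PR-AUC undefined: no positive labels in test set")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    l = labels[order]
    tp = np.cumsum(l)
    fp = np.cumsum(1 - l)
    # keep only the last index of each tied-score run (one point per threshold)
    last = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    precision = tp[last] / (tp[last] + fp[last])
    recall = tp[last] / n_pos
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    return float(np.trapezoid(precision, recall))


def _fold_scaled(X: np.ndarray, raw: np.ndarray, train_idx, test_idx,
                 cont_slice: slice):
    """Apply training-fold min-max scaling of the continuous features."""
    Xtr = X[train_idx].copy()
    Xte = X[test_idx].copy()
    for j in range(raw.shape[1]):
        col = raw[:, j]
        lo, hi = float(col[train_idx].min()), float(col[train_idx].max())
        Xtr[:, cont_slice.start + j] = minmax_rescale(col[train_idx], lo, hi)
        Xte[:, cont_slice.start + j] = minmax_rescale(col[test_idx], lo, hi)
    return Xtr, Xte


def fit_ensemble(
    features: pd.DataFrame,
    n_permutations: int = N_PERMUTATIONS,
    n_repeats: int = N_REPEATS,
    n_splits: int = N_SPLITS,
    lam: float = 1.0,
    seed: int = 0,
    labels_per_permutation: Optional[np.ndarray] = None,
) -> ModelEnsemble:
    """Fit the 16 x 5 x 5 = 400-model logistic ensemble.

    ``features`` is the output of :func:`build_features` (35 columns plus
    ``cleaved``).  Each cohort permutation re-labels the same sites from a
    different control/mutant animal pairing; pass ``labels_per_permutation``
    (n_permutations x n_sites) to supply them, else the single ``cleaved``
    column is used for every permutation.  Continuous features are min-max
    rescaled on each training fold and the scale applied (clipped) to the
    held-out fold.  The fold structure is stratified and seeded per
    permutation so runs are reproducible.
    """
    feat_cols = [c for c in features.columns if c != "cleaved"]
    X = features[feat_cols].to_numpy(float)
    raw = features.attrs.get("raw_continuous")
    if raw is None:
        raw = X[:, [feat_cols.index(c) for c in CONTINUOUS_FEATURES]]
    cont_slice = slice(feat_cols.index(CONTINUOUS_FEATURES[0]),
                       feat_cols.index(CONTINUOUS_FEATURES[-1]) + 1)
    if labels_per_permutation is None:
        y_all = np.tile(features["cleaved"].to_numpy(int), (n_permutations, 1))
    else:
        y_all = np.asarray(labels_per_permutation, int)
        if y_all.shape != (n_permutations, len(features)):
            raise ValueError("labels_per_permutation has wrong shape")

    intercepts, coefs, aucs, prov = [], [], [], []
    for perm in range(n_permutations):
        y = y_all[perm]
        if len(np.unique(y)) < 2:
            raise ValueError(f"permutation {perm + 1}: only one class present")
        cv = RepeatedStratifiedKFold(
            n_splits=n_splits, n_repeats=n_repeats,
            random_state=(seed * n_permutations + perm) % (2**31),
        )
        for split_i, (tr, te) in enumerate(cv.split(X, y)):
            Xtr, Xte = _fold_scaled(X, raw, tr, te, cont_slice)
            clf = LogisticRegression(
                C=1.0 / lam, class_weight="balanced",
                solver="lbfgs", max_iter=1000,
            )
            clf.fit(Xtr, y[tr])
            scores = clf.predict_proba(Xte)[:, 1]
            try:
                auc = pr_auc(y[te], scores)
            except ValueError:
                auc = float("nan")
            intercepts.append(float(clf.intercept_[0]))
            coefs.append(clf.coef_[0].copy())
            aucs.append(auc)
            prov.append({
                "permutation": perm + 1,
                "repeat": split_i // n_splits + 1,
                "fold": split_i % n_splits + 1,
            })
    return ModelEnsemble(
        intercepts=np.array(intercepts),
        coefficients=np.array(coefs),
        provenance=pd.DataFrame(prov),
        pr_auc_heldout=np.array(aucs),
        feature_names=feat_cols,
    )


def evaluate_pr_auc(
    ensemble: ModelEnsemble,
    features: pd.DataFrame,
    labels_per_permutation: Optional[np.ndarray] = None,
) -> np.ndarray:
    """PR-AUC of every ensemble model on an independent cohort.

    With a single label vector the result is (n_models,); with one label
    vector per cohort permutation it is (n_models, n_permutations), i.e.
    400 x 16 = 6,400 values for the full design.
    """
    feat_cols = ensemble.feature_names
    X = features[feat_cols].to_numpy(float)
    logits = ensemble.intercepts[:, None] + ensemble.coefficients @ X.T
    scores = 1.0 / (1.0 + np.exp(-logits))      # (n_models, n_sites)
    if labels_per_permutation is None:
        y = features["cleaved"].to_numpy(int)
        return np.array([pr_auc(y, s) for s in scores])
    ys = np.asarray(labels_per_permutation, int)
    return np.array([[pr_auc(y, s) for y in ys] for s in scores])
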