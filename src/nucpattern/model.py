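"""Linear SVM dyad scoring: training sets, the classifier, scanning, CV.

The dyad score of a window is ``w . f(S) + b`` where ``f`` is the
correlation + count feature map and ``(w, b)`` are the weights of a linear
soft-margin SVM (hinge loss, L2 penalty) trained to separate dyad windows
(label +1) from linker windows at a distance ``L`` on either side of each
dyad (label -1, hence twice as many negatives as positives).  Features are
standardized per column with training-set statistics before the SVM;
the sign of the score gives the predicted class and its magnitude the
confidence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from . import patterns as pt
from .features import PatternFeaturizer, feature_names
from .seqio import extract_window

logger = logging.getLogger(__name__)


@dataclass
class WeightVector:
    """SVM discriminant in raw feature space: score = w . x + bias."""

    w: np.ndarray
    bias: float
    feature_names: list[str]
    meta: dict


@dataclass
class ScoreTrace:
    """Per-position dyad scores over a region (NaN where no window fits)."""

    chrom: str
    start: int
    scores: np.ndarray
    smoothing_width: int = 1

    @property
    def positions(self) -> np.ndarray:
        return self.start + np.arange(len(self.scores))


def assemble_training_set(genome: dict[str, str], dyads: pd.DataFrame,
                          L: int = 110, width: int = 301,
                          ) -> tuple[list[str], np.ndarray, pd.DataFrame]:
    """One positive window per dyad plus negatives at ``pos +/- L``.

    Windows that overrun the chromosome or contain N are dropped
    individually (their mates are kept).  Returns (windows, labels,
    provenance table with chrom/pos/label per kept window).
    """
    windows: list[str] = []
    rows: list[tuple[str, int, int]] = []
    n_dropped = 0
    for chrom, pos in zip(dyads["chrom"], dyads["pos"]):
        seq = genome.get(chrom)
        if seq is None:
            n_dropped += 3
            continue
        for p, label in ((pos, 1), (pos - L, -1), (pos + L, -1)):
            win = extract_window(seq, int(p), width)
            if win is None:
                n_dropped += 1
                continue
            windows.append(win)
            rows.append((chrom, int(p), label))
    prov = pd.DataFrame(rows, columns=["chrom", "pos", "label"])
    labels = prov["label"].to_numpy()
    if (labels == 1).sum() == 0:
        raise ValueError("no positive examples could be extracted")
    logger.info("training set: %d positives, %d negatives, %d windows dropped",
                (labels == 1).sum(), (labels == -1).sum(), n_dropped)
    return windows, labels, prov


def train_linear(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                 tol: float = 1e-4, random_state: int = 0,
                 max_iter: int = 100000) -> Pipeline:
    """Fit scaler + linear soft-margin SVM (hinge loss, L2 penalty)."""
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    # C is defined against the *average* hinge loss, so the fitted
    # discriminant is invariant to duplicating the training set
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", LinearSVC(C=C / len(y), loss="hinge", penalty="l2", tol=tol,
                          random_state=random_state, max_iter=max_iter)),
    ])
    return pipe.fit(X, y)


def _raw_space_weights(pipe: Pipeline, names: list[str], meta: dict) -> WeightVector:
    scaler: StandardScaler = pipe.named_steps["scale"]
    svm: LinearSVC = pipe.named_steps["svm"]
    coef = svm.coef_[0]
    w = coef / scaler.scale_
    bias = float(svm.intercept_[0] - np.sum(coef * scaler.mean_ / scaler.scale_))
    return WeightVector(w=w, bias=bias, feature_names=names, meta=meta)


class DyadClassifier(ClassifierMixin, BaseEstimator):
    """Nucleosome dyad vs linker classifier over sequence windows.

    ``fit(X, y)`` takes windows (strings of length ``width``) with labels
    +1 (dyad) / -1 (non-dyad).  The k-mer patterns are learned from the
    positive windows only; the SVM is trained on the features of all
    windows.  ``decision_function`` returns the dyad score.
    """

    def __init__(self, width: int = 301, k_max: int = 3, C: float = 1.0,
                 tol: float = 1e-4, random_state: int = 0,
                 interpolate_artifact: bool = False, max_iter: int = 100000):
        self.width = width
        self.k_max = k_max
        self.C = C
        self.tol = tol
        self.random_state = random_state
        self.interpolate_artifact = interpolate_artifact
        self.max_iter = max_iter

    def fit(self, X: Sequence[str], y) -> "DyadClassifier":
        windows = list(X)
        y = np.asarray(y)
        if set(np.unique(y)) - {-1, 1}:
            raise ValueError("labels must be +1 (dyad) or -1 (non-dyad)")
        positives = [w for w, lab in zip(windows, y) if lab == 1]
        self.featurizer_ = PatternFeaturizer(
            width=self.width, k_max=self.k_max,
            interpolate_artifact=self.interpolate_artifact).fit(positives)
        Xf = self.featurizer_.transform(windows)
        self.pipeline_ = train_linear(Xf, y, C=self.C, tol=self.tol,
                                      random_state=self.random_state,
                                      max_iter=self.max_iter)
        self.classes_ = self.pipeline_.named_steps["svm"].classes_
        return self

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.decision_function(self.featurizer_.transform(list(X)))

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)

    @property
    def weight_vector_(self) -> WeightVector:
        check_is_fitted(self, "pipeline_")
        names = list(self.featurizer_.get_feature_names_out())
        meta = {"width": self.width, "k_max": self.k_max, "C": self.C,
                "tol": self.tol, "random_state": self.random_state}
        return _raw_space_weights(self.pipeline_, names, meta)


def fit_dyad_model(genome: dict[str, str], dyads: pd.DataFrame,
                   width: int = 301, k_max: int = 3, L: int = 110,
                   C: float = 1.0, random_state: int = 0,
                   interpolate_artifact: bool = False) -> DyadClassifier:
    """Assemble the +/-L training set from a genome and fit the classifier."""
    windows, labels, _ = assemble_training_set(genome, dyads, L=L, width=width)
    clf = DyadClassifier(width=width, k_max=k_max, C=C,
                         random_state=random_state,
                         interpolate_artifact=interpolate_artifact)
    return clf.fit(windows, labels)


def score_position(genome: dict[str, str], chrom: str, pos: int,
                   model: DyadClassifier) -> float:
    """Dyad score at one position; NaN when no window can be extracted."""
    win = extract_window(genome[chrom], pos, model.width)
    if win is None:
        return float("nan")
    return float(model.decision_function([win])[0])


def scan_region(genome: dict[str, str], chrom: str, start: int, end: int,
                model: DyadClassifier, smooth: int = 1) -> ScoreTrace:
    """Per-position dyad scores over [start, end), optionally smoothed.

    Smoothing is a centred moving average of odd width ``smooth`` (the
    evaluation default is 11); positions whose window overruns the contig
    or contains N are NaN and are excluded from the averaging denominator.
    """
    seq = genome.get(chrom)
    if seq is None:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if not (0 <= start < end <= len(seq)):
        raise ValueError(f"interval [{start}, {end}) outside chromosome of length {len(seq)}")
    if smooth % 2 == 0:
        raise ValueError("smoothing width must be odd")
    scores = np.full(end - start, np.nan)
    windows, idx = [], []
    for i, pos in enumerate(range(start, end)):
        win = extract_window(seq, pos, model.width)
        if win is not None:
            windows.append(win)
            idx.append(i)
    if windows:
        scores[np.asarray(idx)] = model.decision_function(windows)
    if smooth > 1:
        scores = moving_average(scores, smooth)
    return ScoreTrace(chrom=chrom, start=start, scores=scores,
                      smoothing_width=smooth)


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average; NaNs excluded from the denominator."""
    kernel = np.ones(width)
    finite = np.isfinite(x)
    total = np.convolve(np.where(finite, x, 0.0), kernel, mode="same")
    count = np.convolve(finite.astype(float), kernel, mode="same")
    out = np.full_like(total, np.nan)
    np.divide(total, count, out=out, where=count > 0)
    return out


def loco_crossval(genome: dict[str, str], dyads: pd.DataFrame,
                  width: int = 301, k_max: int = 3, L: int = 110,
                  C: float = 1.0, random_state: int = 0,
                  ) -> tuple[pd.DataFrame, "RocResult"]:
    """Leave-one-chromosome-out cross-validation.

    For each chromosome the patterns and SVM are trained on the dyads of
    all other chromosomes and evaluated on the held-out chromosome's
    positives and +/-L negatives.  Returns the per-chromosome AUC table and
    the composite ROC over the pooled held-out scores.
    """
    from .evaluate import roc_auc  # local import to avoid a cycle

    chroms = [c for c in dyads["chrom"].unique() if (dyads["chrom"] == c).any()]
    if len(chroms) < 2:
        raise ValueError("need dyads on at least two chromosomes")
    rows = []
    pooled_pos, pooled_neg = [], []
    for held in sorted(chroms):
        train_d = dyads[dyads["chrom"] != held]
        test_d = dyads[dyads["chrom"] == held]
        if len(test_d) == 0:
            logger.warning("chromosome %s has no dyads; skipped", held)
            continue
        model = fit_dyad_model(genome, train_d, width=width, k_max=k_max,
                               L=L, C=C, random_state=random_state)
        windows, labels, _ = assemble_training_set(genome, test_d, L=L, width=width)
        scores = model.decision_function(windows)
        pos, neg = scores[labels == 1], scores[labels == -1]
        pooled_pos.append(pos)
        pooled_neg.append(neg)
        rows.append({"chrom": held, "n_pos": len(pos), "n_neg": len(neg),
                     "auc": roc_auc(pos, neg).auc})
    composite = roc_auc(np.concatenate(pooled_pos), np.concatenate(pooled_neg))
    return pd.DataFrame(rows), composite


# ---------------------------------------------------------------------------
# model bundle persistence (patterns TSV + weights TSV + JSON metadata)

def save_model(model: DyadClassifier, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pt.save_patterns(model.featurizer_.patterns_, outdir / "patterns")
    wv = model.weight_vector_
    pd.DataFrame({"feature": wv.feature_names, "weight": wv.w}).to_csv(
        outdir / "weights.tsv", sep="\t", index=False)
    scaler = model.pipeline_.named_steps["scale"]
    meta = dict(wv.meta)
    meta.update({
        "bias": wv.bias,
        "intercept": float(model.pipeline_.named_steps["svm"].intercept_[0]),
        "coef_scaled": model.pipeline_.named_steps["svm"].coef_[0].tolist(),
        "scaler_mean": scaler.mean_.tolist(),
        "scaler_scale": scaler.scale_.tolist(),
        "interpolate_artifact": model.interpolate_artifact,
    })
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(indir: str | Path) -> DyadClassifier:
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    model = DyadClassifier(width=meta["width"], k_max=meta["k_max"],
                           C=meta["C"], tol=meta["tol"],
                           random_state=meta["random_state"],
                           interpolate_artifact=meta["interpolate_artifact"])
    feat = PatternFeaturizer(width=meta["width"], k_max=meta["k_max"],
                             interpolate_artifact=meta["interpolate_artifact"])
    feat.classes_kmer_ = pt.kmer_classes(meta["k_max"])
    feat.patterns_ = pt.load_patterns(indir / "patterns")
    feat.n_features_out_ = 3 * len(feat.classes_kmer_)
    model.featurizer_ = feat

    scaler = StandardScaler()
    scaler.mean_ = np.asarray(meta["scaler_mean"])
    scaler.scale_ = np.asarray(meta["scaler_scale"])
    scaler.var_ = scaler.scale_ ** 2
    scaler.n_features_in_ = len(scaler.mean_)
    svm = LinearSVC(C=meta["C"], loss="hinge", tol=meta["tol"],
                    random_state=meta["random_state"])
    svm.coef_ = np.asarray([meta["coef_scaled"]])
    svm.intercept_ = np.asarray([meta["intercept"]])
    svm.classes_ = np.asarray([-1, 1])
    model.pipeline_ = Pipeline([("scale", scaler), ("svm", svm)])
    model.classes_ = svm.classes_
    return model
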