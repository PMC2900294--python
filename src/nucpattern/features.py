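"""Correlation + count feature vectors for dyad scoring.

For each reverse-complement k-mer class (44 classes at k <= 3) a window
yields three features:

* ``corr_fwd`` — how well the window's two-strand k-mer match layout fits
  the learned pattern shape;
* ``corr_refl`` — the same against the pattern reflected across the dyad
  (components of the profile are occasionally reversed in real data);
* ``count`` — occurrences of the k-mer in the window plus its reverse
  complement, which disambiguates "no occurrences" from "no correlation".

The correlation sums two Pearson-type terms: the forward-strand match
vector, and the bottom-strand match vector mapped back onto the forward
coordinate axis (i.e. reversed).  Each term is the standardized match
vector dotted with the standardized pattern, divided by the window width,
so each lies in [-1, 1]; a zero-variance match vector contributes 0.
Mapping the bottom strand onto the forward axis makes the strand-flip
identity exact:  correlate(revcomp(S), P) == correlate(S, reflect(P)).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import patterns as pt
from .patterns import KmerClass, Pattern, kmer_classes

FEATURE_KINDS = ("corr_fwd", "corr_refl", "count")


def _corr_terms(M: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Row-wise Pearson term dot(z(M_i), p)/W with zero-variance rows -> 0."""
    W = M.shape[1]
    sd = M.std(axis=1)
    dots = M @ p  # p has mean 0, so the centring term vanishes
    out = np.zeros(M.shape[0])
    nz = sd > 0
    out[nz] = dots[nz] / (sd[nz] * W)
    return out


def feature_matrix(windows: Sequence[str],
                   patterns: dict[str, Pattern],
                   classes: Sequence[KmerClass]) -> np.ndarray:
    """(n_windows, 3 * n_classes) feature matrix, class-major ordering."""
    enc = pt.encode_windows(list(windows))
    enc_rc = pt.revcomp_codes(enc)
    n = enc.shape[0]
    X = np.empty((n, 3 * len(classes)))
    for j, c in enumerate(classes):
        p = patterns[c.rep]
        if p.width != enc.shape[1]:
            raise ValueError(
                f"pattern width {p.width} != window width {enc.shape[1]}")
        F = pt.match_matrix(enc, c.rep)          # forward strand, start offsets
        B = pt.match_matrix(enc_rc, c.rep)       # bottom strand, own coordinates
        comp = B[:, ::-1]                        # mapped onto the forward axis
        pv, pr = p.values, p.values[::-1]
        X[:, 3 * j] = _corr_terms(F, pv) + _corr_terms(comp, pv)
        X[:, 3 * j + 1] = _corr_terms(F, pr) + _corr_terms(comp, pr)
        X[:, 3 * j + 2] = F.sum(axis=1) + B.sum(axis=1)
    return X


def feature_names(classes: Sequence[KmerClass]) -> list[str]:
    return [f"{c.rep}/{c.partner}:{kind}" for c in classes for kind in FEATURE_KINDS]


def correlate(window: str, pattern: Pattern) -> float:
    """Two-strand pattern correlation of one window against one pattern."""
    if not pattern.standardized:
        raise ValueError("pattern must be standardized")
    enc = pt.encode(window)[None, :]
    if pattern.width != enc.shape[1]:
        raise ValueError(f"pattern width {pattern.width} != window length {enc.shape[1]}")
    F = pt.match_matrix(enc, pattern.kmer)
    comp = pt.match_matrix(pt.revcomp_codes(enc), pattern.kmer)[:, ::-1]
    p = pattern.values
    return float(_corr_terms(F, p)[0] + _corr_terms(comp, p)[0])


def correlate_forward(window: str, pattern: Pattern) -> float:
    """Forward-strand-only pattern correlation.

    The two-strand correlation is invariant under complementary swaps of
    the pattern assignment (the companion term pairs each nucleotide's
    complement against the same pattern), so it cannot distinguish the
    nucleotide-permuted pattern variants; variant assignment therefore
    correlates the forward strand alone.
    """
    if not pattern.standardized:
        raise ValueError("pattern must be standardized")
    enc = pt.encode(window)[None, :]
    if pattern.width != enc.shape[1]:
        raise ValueError(f"pattern width {pattern.width} != window length {enc.shape[1]}")
    F = pt.match_matrix(enc, pattern.kmer)
    return float(_corr_terms(F, pattern.values)[0])


def count_kmer(window: str, c: KmerClass | str) -> int:
    """Overlapping occurrences of the class k-mer in the window and its
    reverse complement (both strands summed, palindromic classes included
    once per strand)."""
    if isinstance(c, str):
        c = KmerClass.from_kmer(c)
    enc = pt.encode(window)[None, :]
    F = pt.match_matrix(enc, c.rep)
    B = pt.match_matrix(pt.revcomp_codes(enc), c.rep)
    return int(F.sum() + B.sum())


def build_features(window: str, patterns: dict[str, Pattern],
                   classes: Sequence[KmerClass]) -> np.ndarray:
    """Ordered (corr_fwd, corr_refl, count) concatenation for one window."""
    missing = [c.rep for c in classes if c.rep not in patterns]
    if missing:
        raise ValueError(f"missing patterns for classes: {missing}")
    return feature_matrix([window], patterns, classes)[0]


class PatternFeaturizer(TransformerMixin, BaseEstimator):
    """Learn per-class k-mer patterns from dyad windows; featurize windows.

    Parameters
    ----------
    width : odd int, default 301
        Pattern / window width in bp (core plus flanking linker).
    k_max : int in 1..3, default 3
        Longest k-mer; classes are reverse-complement equivalence classes.
    interpolate_artifact : bool, default False
        Linearly interpolate the learned patterns across the nuclease
        cut-site bumps (for read-derived training data with long reads).
    artifact_centers, artifact_half_width :
        Location/extent of the interpolated regions (default 30 bp at +/-80).

    ``fit`` expects dyad-centred windows of length ``width``; ``transform``
    maps windows to the (n, 3 * n_classes) feature matrix.
    """

    def __init__(self, width: int = 301, k_max: int = 3,
                 interpolate_artifact: bool = False,
                 artifact_centers: tuple[int, ...] = (-80, 80),
                 artifact_half_width: int = 15):
        self.width = width
        self.k_max = k_max
        self.interpolate_artifact = interpolate_artifact
        self.artifact_centers = artifact_centers
        self.artifact_half_width = artifact_half_width

    def fit(self, X: Sequence[str], y=None) -> "PatternFeaturizer":
        if self.width % 2 == 0:
            raise ValueError("width must be odd")
        windows = list(X)
        if any(len(w) != self.width for w in windows):
            raise ValueError(f"all training windows must have length {self.width}")
        self.classes_kmer_ = kmer_classes(self.k_max)
        self.patterns_ = {}
        for c in self.classes_kmer_:
            p = pt.learn_pattern(windows, c.rep)
            if self.interpolate_artifact:
                p = pt.interpolate_artifact(p, self.artifact_centers,
                                            self.artifact_half_width)
            self.patterns_[c.rep] = p
        self.n_features_out_ = 3 * len(self.classes_kmer_)
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        check_is_fitted(self, "patterns_")
        return feature_matrix(list(X), self.patterns_, self.classes_kmer_)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "patterns_")
        return np.asarray(feature_names(self.classes_kmer_), dtype=object)
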