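"""ROC machinery, the empirical pattern-significance null, spacing
analysis, anchored score profiles, and pattern-variant partitioning.

The discrimination task throughout is dyad vs adjacent linker: positives
are dyad positions, negatives the positions a fixed distance on either
side, and performance is summarized by the trapezoidal AUC and by the true
positive rate at a 10% false positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from . import patterns as pt
from .features import correlate_forward
from .patterns import Pattern, mono_psfm
from .seqio import extract_window

NUCLEOTIDES = "ACGT"


# ---------------------------------------------------------------------------
# ROC

@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def tpr_at_fpr(self, fpr: float = 0.10) -> float:
        """TPR of the ROC step curve at the given FPR (the usual operating
        point reported is FPR = 10%)."""
        return float(np.interp(fpr, self.fpr, self.tpr))


def roc_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> RocResult:
    """ROC curve and trapezoidal AUC for positive vs negative score sets.

    Tied scores contribute diagonal segments, so the AUC equals the
    Mann-Whitney statistic P(pos > neg) + 0.5 P(pos = neg).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(neg))):
        raise ValueError("non-finite scores")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    fpr, tpr, thr = _roc_curve(y, s, drop_intermediate=False)
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# pattern significance against a jittered-position null

@dataclass
class NullDistribution:
    """Null samples of the max-min PSFM amplitude per nucleotide."""

    observed: dict[str, float]
    samples: np.ndarray          # (n_sets, 4), columns A,C,G,T
    p_values: dict[str, float]
    n_sets: int
    span: int


def psfm_amplitude(psfm: np.ndarray) -> np.ndarray:
    """Max minus min of each nucleotide trace across the matrix span."""
    return psfm.max(axis=1) - psfm.min(axis=1)


def _dyad_psfm(genome: dict[str, str], chroms: np.ndarray, positions: np.ndarray,
               span: int) -> np.ndarray:
    """PSFM over span-wide windows at the given positions (N windows kept;
    N bases excluded from the frequency denominators)."""
    half = span // 2
    counts = np.zeros((5, span))
    for chrom in np.unique(chroms):
        seq = genome[chrom]
        enc = pt.encode(seq)
        pos = positions[chroms == chrom]
        pos = pos[(pos >= half) & (pos + half < len(seq))]
        if pos.size == 0:
            continue
        idx = pos[:, None] + np.arange(-half, half + 1)[None, :]
        win = enc[idx]
        for i in range(5):
            counts[i] += (win == i).sum(axis=0)
    denom = counts[:4].sum(axis=0)
    denom[denom == 0] = 1
    return counts[:4] / denom


def pattern_significance(dyads: pd.DataFrame, genome: dict[str, str],
                         n_sets: int = 1000, jitter: int = 1000,
                         span: int = 151, seed: int | None = 0,
                         ) -> NullDistribution:
    """Empirical p-value of the per-nucleotide PSFM amplitude.

    The observed statistic is the max-min amplitude of each nucleotide's
    trace in the PSFM of ``span``-wide (default 151 bp) windows centred at
    the dyads.  The null draws ``n_sets`` random sets, each the same size
    as the dyad set, displacing every dyad uniformly within +/- ``jitter``
    bp (default 1000), and recomputes the amplitude.  The add-one estimator
    p = (1 + #{null >= observed}) / (1 + n_sets) is reported per
    nucleotide; a constant trace gives amplitude 0 and p = 1.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if span % 2 == 0:
        raise ValueError("span must be odd")
    rng = np.random.default_rng(seed)
    chroms = dyads["chrom"].to_numpy()
    positions = dyads["pos"].to_numpy(int)
    observed = psfm_amplitude(_dyad_psfm(genome, chroms, positions, span))
    samples = np.empty((n_sets, 4))
    lengths = {c: len(genome[c]) for c in np.unique(chroms)}
    maxpos = np.array([lengths[c] - 1 for c in chroms])
    for s in range(n_sets):
        offs = rng.integers(-jitter, jitter + 1, size=positions.size)
        jpos = np.clip(positions + offs, 0, maxpos)
        samples[s] = psfm_amplitude(_dyad_psfm(genome, chroms, jpos, span))
    p = (1 + (samples >= observed[None, :]).sum(axis=0)) / (1 + n_sets)
    p[observed == 0] = 1.0
    return NullDistribution(
        observed=dict(zip(NUCLEOTIDES, observed.tolist())),
        samples=samples,
        p_values=dict(zip(NUCLEOTIDES, p.tolist())),
        n_sets=n_sets, span=span)


def extrapolate_tail_p(null_samples: np.ndarray, observed: float,
                       tail_fraction: float = 0.10) -> float:
    """EXTRAPOLATION: exponential fit to the null upper tail.

    Fits log survival ~ linear in the amplitude over the top
    ``tail_fraction`` of the null samples and evaluates the fitted survival
    at the observed amplitude.  Reported separately from the empirical
    add-one p-value; the functional form of the tail is an assumption, not
    a measurement.
    """
    x = np.sort(np.asarray(null_samples, dtype=float))
    n = x.size
    k = max(int(np.ceil(n * tail_fraction)), 3)
    tail = x[-k:]
    surv = (n - np.arange(n - k, n)) / n
    slope, intercept = np.polyfit(tail, np.log(surv), 1)
    return float(np.exp(slope * observed + intercept))


# ---------------------------------------------------------------------------
# inter-dyad spacing

def interdyad_histogram(dyads: pd.DataFrame, max_dist: int = 500,
                        mean_spacing: float = 165.0) -> pd.DataFrame:
    """Successive same-chromosome dyad distances with a geometric reference.

    Randomly placed positions produce geometrically distributed successive
    distances; the reference column is the geometric pmf with the stated
    mean spacing (default 165 bp) scaled to the number of observed gaps.
    """
    gaps = []
    for _, grp in dyads.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy(int))
        if pos.size >= 2:
            gaps.append(np.diff(pos))
    if not gaps:
        raise ValueError("need at least two dyads on some chromosome")
    gaps = np.concatenate(gaps)
    d = np.arange(1, max_dist + 1)
    counts = np.bincount(gaps[gaps <= max_dist], minlength=max_dist + 1)[1:]
    pmf = stats.geom.pmf(d, 1.0 / mean_spacing)
    return pd.DataFrame({"distance": d, "count": counts,
                         "geometric_expected": pmf * gaps.size})


# ---------------------------------------------------------------------------
# anchored score profiles

def anchored_profile(score_fn: Callable[[str, int, int], np.ndarray],
                     anchors: pd.DataFrame, half_width: int,
                     ) -> pd.DataFrame:
    """Strand-aware mean score profile around a set of anchor positions.

    ``score_fn(chrom, start, end)`` must return per-position scores (NaN
    allowed).  Minus-strand anchors are flipped so offsets are 5'->3' with
    the anchor at 0.  Returns offset, mean score, and the count of
    contributing anchors per offset.
    """
    width = 2 * half_width + 1
    total = np.zeros(width)
    count = np.zeros(width)
    n_used = 0
    for _, row in anchors.iterrows():
        pos = int(row["pos"])
        scores = score_fn(row["chrom"], pos - half_width, pos + half_width + 1)
        if scores is None or len(scores) != width:
            continue
        scores = np.asarray(scores, dtype=float)
        if str(row.get("strand", "+")) == "-":
            scores = scores[::-1]
        finite = np.isfinite(scores)
        total[finite] += scores[finite]
        count += finite
        n_used += 1
    if n_used == 0:
        raise ValueError("no valid anchors")
    mean = np.full(width, np.nan)
    np.divide(total, count, out=mean, where=count > 0)
    return pd.DataFrame({"offset": np.arange(-half_width, half_width + 1),
                         "mean_score": mean, "n": count.astype(int)})


# ---------------------------------------------------------------------------
# pattern-variant partitioning

NO_MATCH = "no-match"


def assign_variant(window: str, variants: dict[str, dict[str, Pattern]],
                   threshold: float = 0.2) -> str:
    """Best-matching nucleotide-permuted pattern variant for one window.

    The score of a variant is the summed forward-strand mono-nucleotide
    correlation of the window against the variant's four patterns (the
    two-strand correlation is blind to complement swaps and cannot
    separate the variants).  The argmax label is returned when it exceeds
    the threshold; otherwise (or on ties) ``"no-match"``.
    """
    scores = {label: sum(correlate_forward(window, p) for p in pats.values())
              for label, pats in variants.items()}
    best = max(scores, key=lambda k: scores[k])
    best_score = scores[best]
    if best_score <= threshold:
        return NO_MATCH
    if sum(np.isclose(v, best_score) for v in scores.values()) > 1:
        return NO_MATCH
    return best


def partition_windows_by_variant(windows: Sequence[str],
                                 variants: dict[str, dict[str, Pattern]],
                                 threshold: float = 0.2) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {label: [] for label in list(variants) + [NO_MATCH]}
    for w in windows:
        out[assign_variant(w, variants, threshold)].append(w)
    return out


# ---------------------------------------------------------------------------
# partitioning by a per-dyad scalar (repeat fraction, AT fraction, ...)

def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge possibly-overlapping (chrom, start, end) intervals."""
    if (intervals["end"] <= intervals["start"]).any():
        raise ValueError("malformed interval with end <= start")
    merged = []
    for chrom, grp in intervals.groupby("chrom"):
        grp = grp.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def repeat_fraction(dyads: pd.DataFrame, repeats: pd.DataFrame,
                    window: int = 200) -> np.ndarray:
    """Fraction of the ``window`` bp centred at each dyad covered by the
    (merged) repeat intervals."""
    merged = merge_intervals(repeats)
    half = window // 2
    fracs = np.zeros(len(dyads))
    for i, (chrom, pos) in enumerate(zip(dyads["chrom"], dyads["pos"])):
        lo, hi = pos - half, pos - half + window
        cov = 0
        sub = merged[merged["chrom"] == chrom]
        for s, e in zip(sub["start"], sub["end"]):
            cov += max(0, min(e, hi) - max(s, lo))
        fracs[i] = cov / window
    return fracs


def partition_by_scalar(dyads: pd.DataFrame, values: np.ndarray,
                        lo: float = 0.25, hi: float = 0.75,
                        ) -> dict[str, pd.DataFrame]:
    """Split dyads into low (< lo), high (> hi) and mid subsets of a
    per-dyad scalar — one implementation shared by repeat-content and
    AT-content partitioning."""
    values = np.asarray(values, dtype=float)
    return {
        "low": dyads[values < lo].reset_index(drop=True),
        "mid": dyads[(values >= lo) & (values <= hi)].reset_index(drop=True),
        "high": dyads[values > hi].reset_index(drop=True),
    }


def partition_by_repeat(dyads: pd.DataFrame, repeats: pd.DataFrame,
                        window: int = 200, lo: float = 0.25, hi: float = 0.75,
                        ) -> dict[str, pd.DataFrame]:
    """Partition dyads by the repeat-annotated fraction of the 200 bp
    around each dyad (< 25% / 25-75% / > 75% by default)."""
    return partition_by_scalar(dyads, repeat_fraction(dyads, repeats, window),
                               lo=lo, hi=hi)


def at_fraction(dyads: pd.DataFrame, genome: dict[str, str],
                window: int = 200) -> np.ndarray:
    """A+T fraction of the ``window`` bp centred at each dyad (for the
    AT-content partitions)."""
    fracs = np.full(len(dyads), np.nan)
    for i, (chrom, pos) in enumerate(zip(dyads["chrom"], dyads["pos"])):
        win = extract_window(genome[chrom], int(pos), window + 1 - window % 2)
        if win is not None:
            fracs[i] = (win.count("A") + win.count("T")) / len(win)
    return fracs
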