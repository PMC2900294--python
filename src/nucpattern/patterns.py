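"""Position-specific k-mer patterns learned from dyad-aligned windows.

A *pattern* is the per-offset average, over a set of dyad-centred windows,
of the numerical match representation of one k-mer, standardized to mean 0
and variance 1.  Each window contributes the representations of both its
forward sequence and its reverse complement (each read in its own 5'->3'
frame), which makes the patterns of reverse-complementary k-mers exact
mirror images of one another:

    P_revcomp(m)[x] = P_m[-x - (k-1)]

with matches recorded at the start offset (leftmost base) of each
occurrence and ``x`` the offset relative to the dyad.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import reverse_complement

NUCLEOTIDES = "ACGT"
_CODE = {c: i for i, c in enumerate("ACGTN")}
_CODE["N"] = 4


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes A=0, C=1, G=2, T=3, N=4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in zip("ACGT", range(4)):
        out[arr == ord(base)] = code
    return out


def encode_windows(windows: Sequence[str]) -> np.ndarray:
    """Stack equal-length windows into an (n, W) uint8 code matrix."""
    widths = {len(w) for w in windows}
    if len(widths) != 1:
        raise ValueError(f"windows have unequal widths: {sorted(widths)}")
    return encode("".join(windows)).reshape(len(windows), widths.pop())


def revcomp_codes(enc: np.ndarray) -> np.ndarray:
    """Reverse-complement an encoded window matrix (N maps to N)."""
    out = (3 - enc[..., ::-1].astype(np.int16)).astype(np.uint8)
    out[out > 3] = 4  # 3 - 4 wraps; restore N
    out[enc[..., ::-1] == 4] = 4
    return out


def kmer_code(m: str) -> int:
    code = 0
    for c in m:
        code = code * 4 + _CODE[c]
    return code


def match_matrix(enc: np.ndarray, m: str) -> np.ndarray:
    """Per-window indicator of exact matches of ``m`` at each start offset.

    Input is an (n, W) code matrix; output is float64 (n, W) with a 1 at the
    leftmost base of every (possibly overlapping) occurrence, zero in the
    last k-1 columns.  Occurrences overlapping an N never match.
    """
    if enc.ndim == 1:
        enc = enc[None, :]
    n, W = enc.shape
    k = len(m)
    if k > W:
        raise ValueError(f"k-mer {m!r} longer than window width {W}")
    code = np.zeros((n, W - k + 1), dtype=np.int32)
    valid = np.ones((n, W - k + 1), dtype=bool)
    for j in range(k):
        col = enc[:, j:W - k + 1 + j]
        code = code * 4 + col
        valid &= col < 4
    out = np.zeros((n, W), dtype=np.float64)
    out[:, :W - k + 1] = (code == kmer_code(m)) & valid
    return out


# ---------------------------------------------------------------------------
# k-mer reverse-complement classes

@dataclass(frozen=True)
class KmerClass:
    """A k-mer and its reverse complement treated as one unit."""

    rep: str       # lexicographically smaller of m and revcomp(m)
    partner: str   # revcomp(rep)
    k: int = field(init=False)
    palindromic: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "k", len(self.rep))
        object.__setattr__(self, "palindromic", self.rep == self.partner)

    @classmethod
    def from_kmer(cls, m: str) -> "KmerClass":
        rc = reverse_complement(m)
        rep = min(m, rc)
        return cls(rep=rep, partner=reverse_complement(rep))


def kmer_classes(k_max: int) -> list[KmerClass]:
    """All reverse-complement equivalence classes of k-mers with k <= k_max.

    Deterministic order: by k, then lexicographically by representative.
    k_max=3 yields 2 + 10 + 32 = 44 classes.
    """
    if not 1 <= k_max <= 3:
        raise ValueError(f"k_max must be in 1..3, got {k_max}")
    classes: dict[str, KmerClass] = {}
    for k in range(1, k_max + 1):
        for tup in itertools.product(NUCLEOTIDES, repeat=k):
            c = KmerClass.from_kmer("".join(tup))
            classes.setdefault(c.rep, c)
    return sorted(classes.values(), key=lambda c: (c.k, c.rep))


# ---------------------------------------------------------------------------
# patterns

@dataclass
class Pattern:
    """Standardized positional profile of one k-mer over dyad offsets."""

    kmer: str
    values: np.ndarray
    n_sequences: int = 0
    standardized: bool = True

    @property
    def width(self) -> int:
        return len(self.values)

    @property
    def offsets(self) -> np.ndarray:
        h = (self.width - 1) // 2
        return np.arange(-h, h + 1)

    def at(self, x: int) -> float:
        """Value at offset ``x`` relative to the dyad."""
        return float(self.values[x + (self.width - 1) // 2])


def standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        raise ValueError("degenerate pattern: zero variance")
    return (values - values.mean()) / sd


def numeric_representation(window: str, m: str) -> np.ndarray:
    """Forward-strand match representation of ``m`` in ``window``.

    A 1 is added at the start offset of every (possibly overlapping) exact
    match; the companion bottom-strand vector is obtained by calling this on
    ``reverse_complement(window)``.  The two vectors sum to the number of
    occurrences of ``m`` in the window and its reverse complement.
    """
    if len(m) > len(window):
        raise ValueError(f"k-mer {m!r} longer than window")
    return match_matrix(encode(window), m)[0]


def learn_pattern(windows: Sequence[str], m: str, standardized: bool = True) -> Pattern:
    """Average the two-strand match representations over windows.

    Each window contributes the representation of ``m`` in its forward
    sequence plus the representation of ``m`` in its reverse complement
    (each in its own 5'->3' coordinates); the mean over windows is then
    standardized to mean 0, variance 1.
    """
    if len(windows) == 0:
        raise ValueError("need at least one window")
    enc = encode_windows(list(windows))
    raw = (match_matrix(enc, m) + match_matrix(revcomp_codes(enc), m)).mean(axis=0)
    values = standardize(raw) if standardized else raw
    return Pattern(kmer=m, values=values, n_sequences=len(windows),
                   standardized=standardized)


def reflect(p: Pattern) -> Pattern:
    """Reflection of a pattern across the axis of symmetry at the dyad."""
    return replace(p, values=p.values[::-1].copy())


def interpolate_artifact(p: Pattern, centers: Iterable[int] = (-80, 80),
                         half_width: int = 15) -> Pattern:
    """Linearly interpolate across nuclease cut-site bumps.

    Values inside ``[c - half_width, c + half_width]`` (default a 30-bp
    region centred at offsets +/-80, where the cleavage-bias artifact sits
    for ~156-bp reads) are replaced by the straight line joining the
    boundary values, and the pattern is re-standardized.
    """
    h = (p.width - 1) // 2
    values = p.values.astype(float).copy()
    for c in centers:
        lo, hi = c - half_width + h, c + half_width + h
        if lo < 0 or hi > p.width - 1:
            raise ValueError(f"interpolation interval at offset {c} exceeds pattern extent")
        values[lo:hi + 1] = np.linspace(values[lo], values[hi], hi - lo + 1)
    if p.standardized:
        values = standardize(values)
    return replace(p, values=values)


_SHAPE_ORDER = "AGCT"  # 5'->3' order of the local maxima in the learned profile
VARIANT_LABELS = ("AGCT", "ACGT", "TGCA", "TCGA")


def permuted_variants(mono_patterns: dict[str, Pattern]) -> dict[str, dict[str, Pattern]]:
    """The four nucleotide-permuted variants of the mono-nucleotide pattern set.

    The learned profile is of type AGCT (named for the 5'->3' ordering of
    the per-nucleotide local maxima).  Variant label ``XYZW`` assigns the
    first-peaking (A-shaped) curve to nucleotide X, the G-shaped curve to Y,
    the C-shaped to Z and the T-shaped to W; e.g. TCGA swaps the A/T and C/G
    curves.
    """
    missing = set(NUCLEOTIDES) - set(mono_patterns)
    if missing:
        raise ValueError(f"missing mono-nucleotide patterns: {sorted(missing)}")
    widths = {p.width for p in mono_patterns.values()}
    if len(widths) != 1:
        raise ValueError("mono-nucleotide patterns must share one width")
    variants = {}
    for label in VARIANT_LABELS:
        variants[label] = {
            nuc: replace(mono_patterns[shape_of], kmer=nuc)
            for nuc, shape_of in zip(label, _SHAPE_ORDER)
        }
    return variants


def mono_psfm(windows: Sequence[str]) -> np.ndarray:
    """Position-specific frequency matrix (4, W), rows A,C,G,T.

    Forward-strand per-offset nucleotide frequencies of aligned windows;
    columns sum to 1 when no N is present.
    """
    enc = encode_windows(list(windows))
    return np.stack([(enc == i).mean(axis=0) for i in range(4)])


# ---------------------------------------------------------------------------
# persistence: TSV per pattern + one JSON sidecar

def save_patterns(patterns: dict[str, Pattern], outdir: str | Path,
                  meta: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    order = list(patterns)
    for m, p in patterns.items():
        np.savetxt(outdir / f"{m}.tsv",
                   np.column_stack([p.offsets, p.values]),
                   fmt=["%d", "%.12g"], delimiter="\t",
                   header="offset\tvalue")
    sidecar = {
        "kmers": order,
        "width": patterns[order[0]].width,
        "n_sequences": {m: patterns[m].n_sequences for m in order},
        "standardized": {m: patterns[m].standardized for m in order},
    }
    if meta:
        sidecar["meta"] = meta
    (outdir / "patterns.json").write_text(json.dumps(sidecar, indent=2))


def load_patterns(indir: str | Path) -> dict[str, Pattern]:
    indir = Path(indir)
    sidecar = json.loads((indir / "patterns.json").read_text())
    patterns = {}
    for m in sidecar["kmers"]:
        table = np.loadtxt(indir / f"{m}.tsv", delimiter="\t")
        patterns[m] = Pattern(kmer=m, values=table[:, 1],
                              n_sequences=sidecar["n_sequences"][m],
                              standardized=sidecar["standardized"][m])
    return patterns
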