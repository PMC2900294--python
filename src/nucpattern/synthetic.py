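"""Synthetic genomes, dyads and reads with planted nucleosome structure.

The generator emulates the statistical structure the dyad model assumes:
an i.i.d. background at a stated GC fraction, and around each planted dyad
a per-offset nucleotide distribution drawn from a reverse-complement-
symmetric core profile (asymmetric A/T ramps with troughs at +/-40 bp, G
and C bumps 40 bp 5' and 3' of the dyad respectively, optional 10-bp
sinusoid) mixed with the background at a stated effect size.  Reads are
full-length fragments whose midpoints jitter around the planted dyads.

All randomness flows from the single ``seed`` in :class:`GeneratorSpec`
through one ``numpy`` generator, so fixtures are byte-identical across
runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import seqio

NUCLEOTIDES = "ACGT"


def default_profile(width: int = 147, gc: float = 0.46, ramp: float = 0.08,
                    bump: float = 0.12, bump_sd: float = 28.0,
                    bump_offset: int = 40, periodic_amp: float = 0.0,
                    ) -> np.ndarray:
    """Planted per-offset nucleotide probabilities (4, width), rows A,C,G,T.

    The shapes mimic the canonical core profile: the G density peaks
    ``bump_offset`` bp 5' of the dyad and C the same distance 3', A ramps
    down 5'->3' with a trough at +40 and T mirrors it, and an optional
    even 10-bp sinusoid can be added to the G/C components.  The profile is
    reverse-complement symmetric (p_A(x) = p_T(-x), p_C(x) = p_G(-x)) and
    every column sums to 1.
    """
    h = (width - 1) // 2
    x = np.arange(-h, h + 1)
    a0, g0 = (1 - gc) / 2, gc / 2
    gauss_m = np.exp(-0.5 * ((x + bump_offset) / bump_sd) ** 2)  # centred 5'
    gauss_p = np.exp(-0.5 * ((x - bump_offset) / bump_sd) ** 2)  # centred 3'
    wave = periodic_amp * np.cos(2 * np.pi * x / 10.0)
    A = a0 - ramp * (x / h) - bump * gauss_p - wave
    T = a0 + ramp * (x / h) - bump * gauss_m - wave
    G = g0 + bump * gauss_m + wave
    C = g0 + bump * gauss_p + wave
    profile = np.stack([A, C, G, T])
    if (profile <= 0).any() or (profile >= 1).any():
        raise ValueError("profile parameters push probabilities outside (0, 1)")
    sums = profile.sum(axis=0)
    if not np.allclose(sums, 1.0):
        raise ValueError("profile columns do not sum to 1")
    return profile


@dataclass
class GeneratorSpec:
    """Study conditions for the synthetic generator.

    Defaults encode the emulated experiment: 147-bp core profile, fixed
    165-bp dyad spacing (the canonical yeast repeat length), background GC
    0.46, full effect size, ~156-bp reads (sd 10, truncated at 100) with
    5-bp dyad jitter at depth 20.
    """

    seed: int
    genome_length: int = 200_000
    n_chromosomes: int = 1
    gc: float = 0.46
    spacing: str = "fixed"          # "fixed" | "geometric"
    mean_spacing: float = 165.0
    effect_size: float = 1.0
    profile: np.ndarray = field(default_factory=default_profile)
    read_length_mean: float = 156.0
    read_length_sd: float = 10.0
    read_jitter_sd: float = 5.0
    depth: int = 20
    margin: int = 350               # dyad-free flank at contig ends

    def __post_init__(self):
        self.profile = np.asarray(self.profile, dtype=float)
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must be in [0, 1]")
        if self.profile.shape[0] != 4 or self.profile.shape[1] % 2 == 0:
            raise ValueError("profile must be (4, odd_width)")
        if not np.allclose(self.profile.sum(axis=0), 1.0):
            raise ValueError("profile columns must sum to 1")
        if ((self.profile <= 0) | (self.profile >= 1)).any():
            raise ValueError("profile probabilities must lie in (0, 1)")
        if self.spacing not in ("fixed", "geometric"):
            raise ValueError("spacing must be 'fixed' or 'geometric'")
        if self.profile.shape[1] > self.mean_spacing:
            raise ValueError("planted profile wider than the dyad spacing")

    @property
    def background(self) -> np.ndarray:
        at = (1 - self.gc) / 2
        return np.array([at, self.gc / 2, self.gc / 2, at])

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["profile"] = self.profile.tolist()
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorSpec":
        d = json.loads(Path(path).read_text())
        d["profile"] = np.asarray(d["profile"])
        return cls(**d)


def _dyad_positions(spec: GeneratorSpec, length: int,
                    rng: np.random.Generator) -> np.ndarray:
    width = spec.profile.shape[1]
    pos, cur = [], spec.margin
    while cur < length - spec.margin:
        pos.append(cur)
        if spec.spacing == "fixed":
            gap = int(round(spec.mean_spacing))
        else:
            # geometric gaps with a floor of the profile width so planted
            # cores never overlap; overall mean stays at mean_spacing
            excess = max(spec.mean_spacing - width, 1.0)
            gap = width + int(rng.geometric(1.0 / excess))
        cur += gap
    return np.asarray(pos, dtype=int)


def simulate_genome(spec: GeneratorSpec,
                    ) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate chromosomes with planted dyads; return (genome, truth).

    Background bases are i.i.d. at the stated GC fraction; around each
    planted dyad, bases are drawn per offset from
    ``effect_size * profile + (1 - effect_size) * background``.  The truth
    table carries every planted dyad with confidence 1.
    """
    rng = np.random.default_rng(spec.seed)
    width = spec.profile.shape[1]
    half = width // 2
    mixed = (spec.effect_size * spec.profile
             + (1 - spec.effect_size) * spec.background[:, None])
    cdf = np.cumsum(mixed, axis=0)
    genome: dict[str, str] = {}
    rows = []
    per_chrom = spec.genome_length // spec.n_chromosomes
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        bases = rng.choice(4, size=per_chrom, p=spec.background).astype(np.uint8)
        dyads = _dyad_positions(spec, per_chrom, rng)
        if dyads.size:
            u = rng.random((dyads.size, width))
            draws = (u[:, None, :] > cdf[None, :, :]).sum(axis=1).astype(np.uint8)
            idx = dyads[:, None] + np.arange(-half, half + 1)[None, :]
            bases[idx.ravel()] = draws.ravel()
        genome[chrom] = "".join(NUCLEOTIDES[b] for b in bases)
        rows.extend((chrom, int(p), 1.0) for p in dyads)
    truth = pd.DataFrame(rows, columns=seqio.DYAD_COLUMNS)
    return genome, truth


def sample_dyad_windows(spec: GeneratorSpec, n: int, width: int | None = None,
                        rng: np.random.Generator | None = None) -> list[str]:
    """Draw ``n`` dyad-centred windows directly from the planted model
    (profile core, background flanks) without building a genome."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    width = width or spec.profile.shape[1]
    core_w = spec.profile.shape[1]
    if width < core_w:
        h, ch = width // 2, core_w // 2
        profile = spec.profile[:, ch - h: ch + h + 1]
    else:
        pad = (width - core_w) // 2
        profile = np.concatenate([
            np.tile(spec.background[:, None], (1, pad)),
            spec.profile,
            np.tile(spec.background[:, None], (1, pad)),
        ], axis=1)
    mixed = (spec.effect_size * profile
             + (1 - spec.effect_size) * spec.background[:, None])
    cdf = np.cumsum(mixed, axis=0)
    u = rng.random((n, width))
    draws = (u[:, None, :] > cdf[None, :, :]).sum(axis=1)
    lut = np.array(list(NUCLEOTIDES))
    return ["".join(row) for row in lut[draws]]


def jitter_positions(dyads: pd.DataFrame, sd: float,
                     seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Displace dyad positions by rounded Gaussian noise (emulates the
    position error of experimental dyad estimation, e.g. read-binning)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = dyads.copy()
    out["pos"] = out["pos"] + np.rint(rng.normal(0, sd, len(out))).astype(int)
    return out


def simulate_reads(truth: pd.DataFrame, spec: GeneratorSpec,
                   chrom_lengths: dict[str, int] | None = None,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """``depth`` reads per planted dyad, midpoint-jittered, length-varying.

    Read midpoints are the dyad plus rounded Gaussian jitter; lengths are
    Gaussian (mean 156, sd 10 by default) truncated at 100 bp; reads are
    clipped to the contig.
    """
    if spec.depth < 1:
        raise ValueError("depth must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    rows = []
    for chrom, pos in zip(truth["chrom"], truth["pos"]):
        mids = pos + np.rint(rng.normal(0, spec.read_jitter_sd, spec.depth)).astype(int)
        lens = np.rint(rng.normal(spec.read_length_mean, spec.read_length_sd,
                                  spec.depth)).astype(int)
        lens = np.maximum(lens, 100)
        starts = mids - (lens - 1) // 2
        ends = starts + lens
        if chrom_lengths and chrom in chrom_lengths:
            starts = np.clip(starts, 0, chrom_lengths[chrom])
            ends = np.clip(ends, 0, chrom_lengths[chrom])
        keep = ends > starts
        rows.extend((chrom, int(s), int(e))
                    for s, e in zip(starts[keep], ends[keep]))
    return (pd.DataFrame(rows, columns=seqio.READ_COLUMNS)
            .sort_values(["chrom", "start"]).reset_index(drop=True))


def write_fixtures(spec: GeneratorSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit genome FASTA, truth dyad table, reads BED and the spec JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = simulate_genome(spec)
    lengths = {c: len(s) for c, s in genome.items()}
    reads = simulate_reads(truth, spec, chrom_lengths=lengths)
    paths = {
        "fasta": outdir / "genome.fa",
        "dyads": outdir / "dyads.tsv",
        "reads": outdir / "reads.bed",
        "spec": outdir / "spec.json",
    }
    seqio.write_fasta(genome, paths["fasta"])
    seqio.write_dyads(truth, paths["dyads"])
    seqio.write_reads(reads, paths["reads"])
    spec.to_json(paths["spec"])
    return paths
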