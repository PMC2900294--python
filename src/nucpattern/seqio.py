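"""Reading and writing genomic inputs, plus dyad-centred window extraction.

Coordinate conventions used throughout the package:

* all positions are 0-based; a dyad position is the index of the central
  nucleotide of the nucleosome;
* windows have odd length ``W`` and are inclusive on both ends, covering
  offsets ``x`` in ``[-(W-1)/2, +(W-1)/2]`` with the dyad at ``x = 0``;
* windows that would overrun a chromosome end, or that contain ``N``, are
  skipped rather than padded (padding would distort positional frequencies).

Genomes are plain ``dict[str, str]`` (chromosome name -> uppercase sequence
over ``{A, C, G, T, N}``); dyad tables are pandas DataFrames with columns
``chrom``, ``pos``, ``confidence``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_TO_N = {c: "N" for c in map(chr, range(256)) if c.upper() not in ALPHABET}

DYAD_COLUMNS = ["chrom", "pos", "confidence"]
READ_COLUMNS = ["chrom", "start", "end"]


def reverse_complement(s: str) -> str:
    """Reverse complement of a sequence over {A,C,G,T,N} (involution)."""
    bad = set(s) - ALPHABET
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str, name: str) -> str:
    seq = seq.upper()
    if set(seq) - ALPHABET:
        seq = seq.translate(str.maketrans(_TO_N))
    if not seq:
        raise ValueError(f"empty sequence for FASTA record {name!r}")
    return seq


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly line-wrapped, multi-record) FASTA file.

    Lowercase is folded to uppercase and any character outside the
    {A,C,G,T,N} alphabet is mapped to ``N``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = _normalize(str(rec.seq), rec.id)
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_dyads(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited dyad table (chrom, pos, confidence).

    A single header line is tolerated.  The result is sorted by
    (chrom, pos) and deduplicated; duplicate (chrom, pos) rows keep the
    maximum confidence (a warning is logged).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=DYAD_COLUMNS, dtype=str)
    # drop an optional header row (both numeric columns must be non-numeric)
    if len(df):
        first = df.iloc[0]
        try:
            float(first["confidence"])
            header = False
        except (TypeError, ValueError):
            header = not first["pos"].lstrip("-").isdigit()
        if header:
            df = df.iloc[1:]
    try:
        pos = df["pos"].astype(int)
    except ValueError as exc:
        raise ValueError(f"non-integer dyad position in {path}") from exc
    if (pos < 0).any():
        raise ValueError(f"negative dyad position in {path}")
    out = pd.DataFrame({
        "chrom": df["chrom"].to_numpy(),
        "pos": pos.to_numpy(),
        "confidence": df["confidence"].astype(float).to_numpy(),
    })
    n_dup = out.duplicated(subset=["chrom", "pos"]).sum()
    if n_dup:
        logger.warning("%d duplicate dyad positions; keeping max confidence", n_dup)
        out = (out.sort_values("confidence", ascending=False)
                  .drop_duplicates(subset=["chrom", "pos"]))
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_dyads(dyads: pd.DataFrame, path: str | Path) -> None:
    dyads[DYAD_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_reads(path: str | Path) -> pd.DataFrame:
    """Read mapped-read intervals as BED3 (chrom, start, end; half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=READ_COLUMNS,
                     dtype={"chrom": str, "start": int, "end": int})
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"zero- or negative-length read interval in {path}")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_reads(reads: pd.DataFrame, path: str | Path) -> None:
    reads[READ_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def extract_window(seq: str, pos: int, width: int) -> str | None:
    """The ``width``-length window of ``seq`` centred at ``pos``.

    Returns ``None`` when the window overruns the sequence or contains
    ``N`` (callers skip such dyads).  ``width`` must be odd.
    """
    if width % 2 == 0:
        raise ValueError(f"window width must be odd, got {width}")
    half = width // 2
    if pos - half < 0 or pos + half >= len(seq):
        return None
    win = seq[pos - half: pos + half + 1]
    if "N" in win:
        return None
    return win
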