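"""Genome-window derivation calls for recombinant inbred lines.

Rit-1/Rit-2 are F5 sibling RILs from a Tak-1 x Tak-2 cross. Mapping Tak-2,
Rit-1 and Rit-2 reads against the Tak-1 reference and counting polymorphisms
(SNPs + INDELs) in fixed windows lets each autosomal window be assigned a
parental origin from the intersection pattern of "significant polymorphism"
flags:

* Tak-2 flag false                      -> SHARED (Tak-1 and Tak-2 identical here)
* Tak-2 true and (Rit-1 or Rit-2) true  -> TAK2   (RILs inherited the Tak-2 haplotype)
* Tak-2 true and both Rit flags false   -> TAK1

A window is flagged significant when it contains strictly more than 100
polymorphisms per 100 kb (equivalently 1,000 per 1,000 kb); truncated
terminal windows scale the threshold proportionally to their width. Windows
index positions by ``pos // window_size`` (a variant at exactly the window
size falls in the second window). Sex chromosomes (U/V) are excluded from
derivation calls.

Inputs are simplified per-line variant tables (chrom, pos, line TSV, or a
minimal VCF from which only CHROM/POS are used); the upstream read-mapping
and variant-calling chain is out of scope. A synthetic genome generator with
planted derivation tracks supports desk-scale validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.random import default_rng

LINES = ("tak2", "rit1", "rit2")
#: strict threshold: > 100 polymorphisms per 100 kb
THRESHOLD_PER_100KB = 100
_100KB = 100_000
SEX_CHROMOSOMES = frozenset({"chrU", "chrV", "U", "V"})


class Derivation(str, Enum):
    TAK1 = "TAK1"
    TAK2 = "TAK2"
    SHARED = "SHARED"


@dataclass(frozen=True)
class WindowCounts:
    """Per-window polymorphism counts against the Tak-1 reference."""

    chrom: str
    start: int  # inclusive window start coordinate (first window starts at 0)
    end: int    # inclusive end position
    window_size: int
    counts: Mapping[str, int]       # per line
    intersection: int               # variants shared by all three lines

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class WindowDerivationCall:
    chrom: str
    start: int
    end: int
    call: Derivation
    flags: Mapping[str, bool]


# ---------------------------------------------------------------------------
# input parsing
# ---------------------------------------------------------------------------


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a variant table: TSV with columns chrom, pos, line, or a minimal
    per-line VCF whose filename stem names the line (CHROM/POS only used)."""
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        rows = []
        for line in path.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), path.stem.lower()))
        return pd.DataFrame(rows, columns=["chrom", "pos", "line"])
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if not {"chrom", "pos", "line"}.issubset(df.columns):
        raise ValueError("variant TSV needs columns chrom, pos, line")
    return df[["chrom", "pos", "line"]]


# ---------------------------------------------------------------------------
# counting and flagging
# ---------------------------------------------------------------------------


def count_window_polymorphisms(
    variants: pd.DataFrame,
    window_size: int,
    chrom_lengths: Mapping[str, int],
) -> List[WindowCounts]:
    """Count per-line variants and the three-line intersection per window.

    ``variants`` has columns chrom, pos (1-based), line. A variant position
    present in all three lines at the same (chrom, pos) counts toward the
    intersection. Positions outside [1, chrom length] raise.
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    v = variants.copy()
    bad_line = set(v["line"]) - set(LINES)
    if bad_line:
        raise ValueError(f"unknown lines in variant table: {sorted(bad_line)}")
    for row in v.itertuples():
        length = chrom_lengths.get(row.chrom)
        if length is None:
            raise ValueError(f"variant on unknown chromosome: {row.chrom}:{row.pos}")
        if not (1 <= row.pos <= length):
            raise ValueError(
                f"position out of range: {row.chrom}:{row.pos} ({row.line}), "
                f"chromosome length {length}"
            )
    v["win"] = v["pos"] // window_size
    per_line = v.groupby(["chrom", "win", "line"]).size()
    inter = (
        v.drop_duplicates(["chrom", "pos", "line"])
        .groupby(["chrom", "pos"])["line"].nunique()
    )
    inter_by_win = (
        (inter[inter == len(LINES)]).reset_index()
        .assign(win=lambda d: d["pos"] // window_size)
        .groupby(["chrom", "win"]).size()
    )
    out = []
    for chrom, length in chrom_lengths.items():
        n_win = length // window_size + 1
        for k in range(n_win):
            # nominal tiling [k*W, (k+1)*W); the first window's position 0 is
            # never observable (positions are 1-based) but its nominal width
            # is still W, so thresholds scale uniformly
            start = k * window_size
            end = min((k + 1) * window_size - 1, length)
            if end < start:
                continue
            counts = {
                line: int(per_line.get((chrom, k, line), 0)) for line in LINES
            }
            out.append(WindowCounts(
                chrom=chrom, start=start, end=end, window_size=window_size,
                counts=counts, intersection=int(inter_by_win.get((chrom, k), 0)),
            ))
    return out


def flag_significant(
    window: WindowCounts, threshold_per_100kb: int = THRESHOLD_PER_100KB
) -> Dict[str, bool]:
    """Per-line significance flags: count strictly exceeds the width-scaled
    threshold (100 per 100 kb; truncated windows scale proportionally)."""
    threshold = threshold_per_100kb * window.width / _100KB
    return {line: window.counts[line] > threshold for line in LINES}


def classify_derivation(flags: Mapping[str, bool], chrom: str = "chr1") -> Derivation:
    """Parental-origin call from the three significance flags (autosomes only)."""
    if chrom in SEX_CHROMOSOMES:
        raise ValueError(f"sex-chromosome window excluded from derivation: {chrom}")
    if not flags["tak2"]:
        return Derivation.SHARED
    if flags["rit1"] or flags["rit2"]:
        return Derivation.TAK2
    return Derivation.TAK1


def call_windows(
    windows: Sequence[WindowCounts],
    threshold_per_100kb: int = THRESHOLD_PER_100KB,
) -> List[WindowDerivationCall]:
    """Flag and classify every autosomal window; sex chromosomes are skipped."""
    calls = []
    for w in windows:
        if w.chrom in SEX_CHROMOSOMES:
            continue
        flags = flag_significant(w, threshold_per_100kb)
        calls.append(WindowDerivationCall(
            chrom=w.chrom, start=w.start, end=w.end,
            call=classify_derivation(flags, w.chrom), flags=flags,
        ))
    return calls


def summarize_derivation(calls: Sequence[WindowDerivationCall]) -> Dict[str, float]:
    """Length-weighted fraction of autosomal sequence per derivation class."""
    if not calls:
        raise ValueError("no derivation calls to summarize")
    by_chrom: Dict[str, List[WindowDerivationCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, cs in by_chrom.items():
        cs.sort(key=lambda c: c.start)
        cursor = cs[0].start
        for c in cs:
            if c.start > cursor:
                raise ValueError(f"coverage gap on {chrom} before position {c.start}")
            cursor = c.end + 1
    total = sum(c.end - c.start + 1 for c in calls)
    fractions = {d.value: 0.0 for d in Derivation}
    for c in calls:
        fractions[c.call.value] += (c.end - c.start + 1) / total
    return fractions


def calls_to_bed(calls: Sequence[WindowDerivationCall]) -> pd.DataFrame:
    """BED-like track (chrom, start, end, call), 0-based half-open windows."""
    return pd.DataFrame(
        [dict(chrom=c.chrom, start=c.start, end=c.end + 1, call=c.call.value)
         for c in calls]
    )


# ---------------------------------------------------------------------------
# synthetic genomes with planted derivation
# ---------------------------------------------------------------------------


def simulate_variant_table(
    planted: Sequence[Tuple[str, Derivation]],
    window_size: int,
    seed: int = 0,
    low_high: Tuple[float, float] = (0.3, 2.0),
) -> Tuple[pd.DataFrame, Mapping[str, int], List[Derivation]]:
    """Plant a derivation class per window and sample counts away from the
    significance threshold.

    ``planted`` lists (chrom, derivation) per full window in order; windows of
    one chromosome are laid out contiguously. "Low" counts are uniform in
    [0, low*threshold], "high" counts in [high*threshold, (high+1)*threshold],
    so flags are unambiguous. Returns (variant table, chromosome lengths,
    planted classes in window order).
    """
    rng = default_rng(seed)
    thr = THRESHOLD_PER_100KB * window_size / _100KB
    lo_max = int(low_high[0] * thr)
    hi_min, hi_max = int(low_high[1] * thr), int((low_high[1] + 1) * thr)
    rows = []
    lengths: Dict[str, int] = {}
    next_window: Dict[str, int] = {}
    for chrom, deriv in planted:
        k = next_window.get(chrom, 0)
        next_window[chrom] = k + 1
        lengths[chrom] = (k + 1) * window_size - 1
        if deriv is Derivation.SHARED:
            per_line = {ln: rng.integers(0, lo_max + 1) for ln in LINES}
        elif deriv is Derivation.TAK2:
            per_line = {ln: rng.integers(hi_min, hi_max + 1) for ln in LINES}
        else:
            per_line = {"tak2": rng.integers(hi_min, hi_max + 1),
                        "rit1": rng.integers(0, lo_max + 1),
                        "rit2": rng.integers(0, lo_max + 1)}
        start, end = max(1, k * window_size), (k + 1) * window_size - 1
        for line, cnt in per_line.items():
            pos = rng.choice(np.arange(start, end + 1), size=int(cnt), replace=False)
            rows += [(chrom, int(p), line) for p in pos]
    table = pd.DataFrame(rows, columns=["chrom", "pos", "line"])
    return table, lengths, [d for _, d in planted]
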