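"""Nucleotide composition and strand-skew statistics.

Strand skews measure compositional asymmetry between the two strands of a
genome, computed on one (the stored major) strand:

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

Velvet-worm mitogenomes differ qualitatively in the sign structure of their
GC-skew landscape, so besides whole-genome values this module computes
sliding-window profiles on a COX1-anchored orientation and classifies each
genome into a qualitative regime: globally positive, globally negative, or
bimodal (the landscape partitioned into positive and negative segments).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import AnnotatedMitogenome, anchor_genome

GLOBALLY_POSITIVE = "globally_positive"
GLOBALLY_NEGATIVE = "globally_negative"
BIMODAL = "bimodal"

DEFAULT_WINDOW = 300
DEFAULT_STEP = 50
DEFAULT_HI = 0.75
DEFAULT_LO = 0.25


class UndefinedSkewError(ValueError):
    """Skew denominator is zero (the base pair is absent from the span)."""


@dataclass(frozen=True)
class BaseCounts:
    nA: int
    nC: int
    nG: int
    nT: int
    nOther: int = 0

    @property
    def total(self) -> int:
        return self.nA + self.nC + self.nG + self.nT + self.nOther

    @property
    def unambiguous(self) -> int:
        return self.nA + self.nC + self.nG + self.nT


def base_counts(sequence: str) -> BaseCounts:
    """Case-insensitive exact base tally; non-ACGT counted as ``nOther``."""
    if not sequence:
        raise ValueError("empty sequence")
    c = Counter(sequence.upper())
    acgt = c["A"] + c["C"] + c["G"] + c["T"]
    return BaseCounts(c["A"], c["C"], c["G"], c["T"], len(sequence) - acgt)


def at_skew(counts: BaseCounts) -> float:
    """(A - T) / (A + T); raises :class:`UndefinedSkewError` when A+T = 0."""
    denom = counts.nA + counts.nT
    if denom == 0:
        raise UndefinedSkewError("A + T = 0")
    return (counts.nA - counts.nT) / denom


def gc_skew(counts: BaseCounts) -> float:
    """(G - C) / (G + C); raises :class:`UndefinedSkewError` when G+C = 0."""
    denom = counts.nG + counts.nC
    if denom == 0:
        raise UndefinedSkewError("G + C = 0")
    return (counts.nG - counts.nC) / denom


def gc_content(counts: BaseCounts) -> float:
    """GC percentage of unambiguous bases."""
    if counts.unambiguous == 0:
        raise ValueError("no unambiguous bases")
    return 100.0 * (counts.nG + counts.nC) / counts.unambiguous


@dataclass
class SkewProfile:
    """Per-window skews along a genome, on its COX1-anchored orientation.

    Windows with a zero denominator are missing (NaN), not zero — treating
    them as zero would fabricate a sign. ``fraction_positive`` is the share
    of sign-carrying (defined and nonzero) windows with positive GC skew.
    """

    genome_id: str
    window: int
    step: int
    centers: np.ndarray
    gc_skew: np.ndarray
    at_skew: np.ndarray
    regime: str | None = field(default=None)

    @property
    def fraction_positive(self) -> float:
        vals = self.gc_skew[~np.isnan(self.gc_skew)]
        vals = vals[vals != 0.0]
        if vals.size == 0:
            raise UndefinedSkewError(
                f"{self.genome_id}: no sign-carrying windows")
        return float(np.mean(vals > 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "genome_id": self.genome_id,
            "window_center": self.centers,
            "gc_skew": self.gc_skew,
            "at_skew": self.at_skew,
        })


def _window_sums(indicator: np.ndarray, starts: np.ndarray, window: int,
                 circular: bool, length: int) -> np.ndarray:
    cum = np.concatenate(([0], np.cumsum(indicator)))
    if circular:
        ends = starts + window
        wrap = ends > length
        out = np.where(
            wrap,
            (cum[length] - cum[starts]) + cum[np.minimum(ends - length,
                                                         length)],
            cum[np.minimum(ends, length)] - cum[starts],
        )
        return out
    ends = np.minimum(starts + window, length)
    return cum[ends] - cum[starts]


def sliding_window_profile(genome: AnnotatedMitogenome,
                           window: int = DEFAULT_WINDOW,
                           step: int = DEFAULT_STEP,
                           anchor: str | None = "COX1") -> SkewProfile:
    """Windowed AT/GC skews advancing by ``step`` along the major strand.

    Circular genomes wrap past the origin (ceil(length/step) windows);
    linear genomes truncate the final windows. When ``anchor`` is given and
    present, the genome is re-oriented to start at that gene first.
    """
    if window > genome.length:
        raise ValueError(
            f"window {window} exceeds genome length {genome.length}")
    if step < 1:
        raise ValueError("step must be >= 1")
    g = genome
    if anchor is not None and any(f.label == anchor for f in genome.features):
        g = anchor_genome(genome, anchor)
    seq = np.frombuffer(g.sequence.upper().encode(), dtype="S1")
    length = g.length
    circular = g.topology == "circular"
    n_windows = math.ceil(length / step)
    starts = (np.arange(n_windows) * step).astype(np.int64)
    if not circular:
        starts = starts[starts < length]
    sums = {}
    for base in "ACGT":
        ind = (seq == base.encode()).astype(np.int64)
        sums[base] = _window_sums(ind, starts, window, circular, length)
    with np.errstate(divide="ignore", invalid="ignore"):
        gc_den = (sums["G"] + sums["C"]).astype(float)
        at_den = (sums["A"] + sums["T"]).astype(float)
        gc = np.where(gc_den > 0, (sums["G"] - sums["C"]) / gc_den, np.nan)
        at = np.where(at_den > 0, (sums["A"] - sums["T"]) / at_den, np.nan)
    centers = (starts + window / 2.0) % length if circular else \
        starts + np.minimum(window, length - starts) / 2.0
    return SkewProfile(g.id, window, step, centers, gc, at)


def classify_regime(profile: SkewProfile, hi: float = DEFAULT_HI,
                    lo: float = DEFAULT_LO) -> str:
    """Qualitative GC-skew regime from the fraction of positive windows.

    ``fraction_positive >= hi`` -> globally positive, ``<= lo`` -> globally
    negative, otherwise bimodal. The thresholds separate "predominantly
    positive", "globally negative" and "partitioned almost equally"
    landscapes.
    """
    if np.all(np.isnan(profile.gc_skew)):
        raise UndefinedSkewError(f"{profile.genome_id}: all windows undefined")
    f = profile.fraction_positive
    if f >= hi:
        regime = GLOBALLY_POSITIVE
    elif f <= lo:
        regime = GLOBALLY_NEGATIVE
    else:
        regime = BIMODAL
    profile.regime = regime
    return regime


def per_gene_skews(genome: AnnotatedMitogenome) -> pd.DataFrame:
    """Skews per annotated gene on the major strand (alternative to the
    windowed profile for gene-resolution landscapes)."""
    rows = []
    for f in genome.features:
        counts = base_counts(genome.feature_seq(f))
        try:
            gcs: float | None = gc_skew(counts)
        except UndefinedSkewError:
            gcs = None
        try:
            ats: float | None = at_skew(counts)
        except UndefinedSkewError:
            ats = None
        rows.append({"genome_id": genome.id, "label": f.label, "cls": f.cls,
                     "start": f.start, "strand": f.strand,
                     "gc_skew": gcs, "at_skew": ats})
    return pd.DataFrame(rows)


def genome_composition(genome: AnnotatedMitogenome) -> dict:
    """Whole-genome composition summary (one row of the report table)."""
    counts = base_counts(genome.sequence)
    return {
        "id": genome.id,
        "length_bp": genome.length,
        "gc_percent": gc_content(counts),
        "at_skew": at_skew(counts),
        "gc_skew": gc_skew(counts),
    }
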