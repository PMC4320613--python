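"""Purine-rich acceptor (REPA) scan and G-tract detection.

The scan flags acceptor splice sites whose region between the
polypyrimidine tract and the 3'AG (intron-relative positions -10..-3)
is purine-rich (>60% A/G, strict), locates maximal guanine runs
("G tracts", the minimal functional unit being G3) upstream of the AG,
assigns each site to a literal hexamer/pentamer group, and aggregates
positional base-composition profiles and G-tract histograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AcceptorWindow
from .coords import index_to_pos, pos_to_index, positions

__all__ = [
    "GTract",
    "RepaCall",
    "PositionProfile",
    "DEFAULT_GROUP_PRECEDENCE",
    "purine_fraction",
    "is_repa_candidate",
    "find_g_tracts",
    "classify_group",
    "call_site",
    "scan_windows",
    "position_profile",
    "first_g_histogram",
    "run_length_distribution",
    "write_calls_tsv",
    "read_calls_tsv",
]

PURINES = frozenset("AG")

#: Literal group motifs in precedence order (first match wins when a window
#: matches several).  A window matching none but carrying a purine at -3
#: falls into the "nnnrag" consensus-deviant bucket; everything else is
#: "other".
DEFAULT_GROUP_PRECEDENCE: tuple[str, ...] = (
    "gtggaa",
    "ggggg",
    "ggaaa",
    "gaaaa",
    "aaataa",
)


@dataclass(frozen=True)
class GTract:
    """A maximal run of Gs, in intron-relative coordinates.

    ``first_g_position`` is the 5'-most G; the run occupies
    ``first_g_position .. first_g_position + length - 1`` (all intronic,
    so the skip-zero convention never bites).  ``over_cap`` marks runs
    longer than the reporting cap (8 by default) — they are reported with
    their true length.
    """

    first_g_position: int
    length: int
    over_cap: bool = False

    @property
    def last_g_position(self) -> int:
        return self.first_g_position + self.length - 1


@dataclass(frozen=True)
class RepaCall:
    site_id: str
    purine_fraction_10_3: float
    is_repa: bool
    group_label: str
    g_tracts: tuple[GTract, ...] = ()
    gene_id: str = ""

    @property
    def has_g_tract(self) -> bool:
        return len(self.g_tracts) > 0

    @property
    def representative_tract(self) -> GTract | None:
        """The 5'-most tract (tie-break: longest, then most 3')."""
        if not self.g_tracts:
            return None
        return min(self.g_tracts, key=lambda t: (t.first_g_position, -t.length))


def _range_indices(window: AcceptorWindow, from_pos: int, to_pos: int) -> list[int]:
    idx = [pos_to_index(p, window.intron_span) for p in positions(from_pos, to_pos)]
    if any(i >= len(window.window) for i in idx):
        raise IndexError(f"range {from_pos}..{to_pos} outside window {window.site_id}")
    return idx


def purine_fraction(window: AcceptorWindow, from_pos: int, to_pos: int) -> float:
    """Fraction of A/G among non-N bases in the inclusive position range.

    Returns NaN when every base in the range is N.
    """
    bases = [window.window[i] for i in _range_indices(window, from_pos, to_pos)]
    informative = [b for b in bases if b != "N"]
    if not informative:
        return math.nan
    return sum(b in PURINES for b in informative) / len(informative)


def is_repa_candidate(window: AcceptorWindow, threshold: float = 0.60) -> bool:
    """True iff the acceptor is AG-terminated and strictly more than
    ``threshold`` of the non-N bases at -10..-3 are purines.

    With 8 informative positions the strict >0.60 rule means 5/8 passes
    and 4/8 fails.  Truncated windows (intron shorter than 10 nt) are
    never candidates.
    """
    if window.truncated or window.intron_span < 10:
        return False
    if window.acceptor_dinucleotide != "AG":
        return False
    frac = purine_fraction(window, -10, -3)
    return (not math.isnan(frac)) and frac > threshold


def find_g_tracts(
    window: AcceptorWindow,
    min_len: int = 3,
    max_len: int = 8,
    search_from: int = -15,
    search_to: int = -3,
) -> list[GTract]:
    """Maximal G runs intersecting ``search_from..search_to``, 5'->3'.

    Only maximal runs are reported (never sub-runs); a run must end at or
    before ``search_to`` (it may not invade the acceptor AG).  Runs longer
    than ``max_len`` keep their true length but carry the over-cap flag.
    """
    seq = window.window[: window.intron_span]
    tracts: list[GTract] = []
    i = 0
    while i < len(seq):
        if seq[i] != "G":
            i += 1
            continue
        j = i
        while j + 1 < len(seq) and seq[j + 1] == "G":
            j += 1
        first = index_to_pos(i, window.intron_span)
        last = index_to_pos(j, window.intron_span)
        length = j - i + 1
        if (
            length >= min_len
            and last <= search_to
            and last >= search_from
            and first <= search_to
        ):
            tracts.append(GTract(first, length, over_cap=length > max_len))
        i = j + 1
    return tracts


def classify_group(
    window: AcceptorWindow,
    precedence: Sequence[str] = DEFAULT_GROUP_PRECEDENCE,
    search_from: int = -12,
    search_to: int = -3,
) -> str:
    """Assign the literal motif group of the acceptor.

    Motifs from ``precedence`` are matched (case-insensitive) anywhere
    within ``search_from..search_to``; the first motif in precedence
    order that matches wins.  With no literal match, a purine at -3
    (deviating from the constitutive ``y``) yields "nnnrag", otherwise
    "other".
    """
    region = window.subseq(search_from, search_to).upper()
    for motif in precedence:
        if motif.upper() in region:
            return motif
    if window.intron_span >= 3 and window.at(-3) in PURINES:
        return "nnnrag"
    return "other"


def call_site(
    window: AcceptorWindow,
    threshold: float = 0.60,
    min_len: int = 3,
    max_len: int = 8,
    precedence: Sequence[str] = DEFAULT_GROUP_PRECEDENCE,
) -> RepaCall:
    frac = (
        purine_fraction(window, -10, -3) if window.intron_span >= 10 else math.nan
    )
    return RepaCall(
        site_id=window.site_id,
        purine_fraction_10_3=frac,
        is_repa=is_repa_candidate(window, threshold),
        group_label=classify_group(window, precedence),
        g_tracts=tuple(find_g_tracts(window, min_len, max_len)),
        gene_id=window.gene_id,
    )


def scan_windows(
    windows: Iterable[AcceptorWindow],
    threshold: float = 0.60,
    min_len: int = 3,
    max_len: int = 8,
    precedence: Sequence[str] = DEFAULT_GROUP_PRECEDENCE,
) -> list[RepaCall]:
    return [call_site(w, threshold, min_len, max_len, precedence) for w in windows]


@dataclass
class PositionProfile:
    """Per-position base counts over a set of equal-span windows."""

    positions: list[int]
    counts: pd.DataFrame  # index = positions, columns = A, C, G, T, N
    n_sites: int

    @property
    def freq(self) -> pd.DataFrame:
        """A/C/G/T frequencies normalized over non-N bases per position."""
        acgt = self.counts[["A", "C", "G", "T"]]
        return acgt.div(acgt.sum(axis=1), axis=0)

    @property
    def purine_fraction(self) -> pd.Series:
        """The A/G marginal per position (the quantity plotted against
        position in acceptor composition profiles)."""
        f = self.freq
        return f["A"] + f["G"]

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "position", self.positions)
        out["purine_fraction"] = self.purine_fraction.values
        return out


def position_profile(windows: Sequence[AcceptorWindow]) -> PositionProfile:
    """Base-composition profile of a set of windows of identical span."""
    windows = list(windows)
    if not windows:
        raise ValueError("position_profile needs at least one window")
    spans = {(w.intron_span, w.exon_span) for w in windows}
    if len(spans) > 1:
        raise ValueError(f"windows have mixed spans: {sorted(spans)}")
    intron_span, exon_span = spans.pop()
    pos = [index_to_pos(i, intron_span) for i in range(intron_span + exon_span)]
    mat = np.zeros((len(pos), 5), dtype=np.int64)
    order = "ACGTN"
    lut = {b: k for k, b in enumerate(order)}
    for w in windows:
        for i, b in enumerate(w.window):
            mat[i, lut.get(b, 4)] += 1
    counts = pd.DataFrame(mat, index=pos, columns=list(order))
    return PositionProfile(positions=pos, counts=counts, n_sites=len(windows))


def _representative_tracts(calls: Iterable[RepaCall]) -> list[GTract]:
    reps = [c.representative_tract for c in calls]
    return [t for t in reps if t is not None]


def first_g_histogram(calls: Iterable[RepaCall]) -> pd.Series:
    """Counts of the first-G position of each site's 5'-most tract."""
    reps = _representative_tracts(calls)
    ser = pd.Series([t.first_g_position for t in reps], dtype=int)
    return ser.value_counts().sort_index()


def run_length_distribution(calls: Iterable[RepaCall]) -> pd.Series:
    """Counts of the run length of each site's 5'-most tract."""
    reps = _representative_tracts(calls)
    ser = pd.Series([t.length for t in reps], dtype=int)
    return ser.value_counts().sort_index()


def _tracts_to_str(tracts: Sequence[GTract]) -> str:
    return ";".join(
        f"{t.first_g_position}:{t.length}{':over' if t.over_cap else ''}" for t in tracts
    )


def _tracts_from_str(s: str) -> tuple[GTract, ...]:
    if not s or (isinstance(s, float) and math.isnan(s)):
        return ()
    out = []
    for part in str(s).split(";"):
        bits = part.split(":")
        out.append(GTract(int(bits[0]), int(bits[1]), over_cap=len(bits) > 2))
    return tuple(out)


def write_calls_tsv(calls: Sequence[RepaCall], path: str | Path) -> None:
    rows = [
        {
            "site_id": c.site_id,
            "gene_id": c.gene_id,
            "purine_fraction_10_3": c.purine_fraction_10_3,
            "is_repa": c.is_repa,
            "group_label": c.group_label,
            "g_tracts": _tracts_to_str(c.g_tracts),
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=["site_id", "gene_id", "purine_fraction_10_3", "is_repa",
                 "group_label", "g_tracts"],
    ).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> list[RepaCall]:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str}, keep_default_na=False)
    return [
        RepaCall(
            site_id=row.site_id,
            gene_id=str(row.gene_id),
            purine_fraction_10_3=float(row.purine_fraction_10_3),
            is_repa=str(row.is_repa) in ("True", "true", "1"),
            group_label=row.group_label,
            g_tracts=_tracts_from_str(row.g_tracts),
        )
        for row in df.itertuples()
    ]
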