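"""Coordinate conventions used throughout the package.

Two conventions meet here and are converted in one place only:

* **Genomic** intervals follow GTF: 1-based, closed on both ends.
  BED output is 0-based, half-open.
* **Intron-relative** positions are anchored at the intron end on the
  transcribed strand and skip zero: position ``-1`` is the last intronic
  base (the G of the acceptor AG), ``-2`` the A, and ``+1`` is the first
  exonic base.  There is no position 0.  A window with ``intron_span``
  intronic and ``exon_span`` exonic bases therefore covers positions
  ``-intron_span .. -1, +1 .. +exon_span``.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement of a DNA string (case preserved, N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_position(pos: int) -> int:
    """Validate an intron-relative position (zero is not a position)."""
    if pos == 0:
        raise ValueError("intron-relative coordinates skip 0; use -1 or +1")
    return pos


def pos_to_index(pos: int, intron_span: int) -> int:
    """Map an intron-relative position to a 0-based string index.

    The window string is laid out 5'->3' on the transcribed strand:
    intronic part first (positions ``-intron_span..-1``), then the exonic
    part (``+1..``).
    """
    check_position(pos)
    if pos < 0:
        idx = intron_span + pos
        if idx < 0:
            raise IndexError(f"position {pos} outside intron span {intron_span}")
        return idx
    return intron_span + pos - 1


def index_to_pos(idx: int, intron_span: int) -> int:
    """Inverse of :func:`pos_to_index`."""
    if idx < 0:
        raise IndexError(idx)
    if idx < intron_span:
        return idx - intron_span
    return idx - intron_span + 1


def positions(from_pos: int, to_pos: int) -> list[int]:
    """Ordered intron-relative positions from ``from_pos`` to ``to_pos``
    inclusive, skipping zero."""
    check_position(from_pos)
    check_position(to_pos)
    if from_pos > to_pos:
        raise ValueError(f"range {from_pos}..{to_pos} not in 5'->3' order")
    return [p for p in range(from_pos, to_pos + 1) if p != 0]


def gtf_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based closed (GTF) -> 0-based half-open (BED)."""
    if end < start:
        raise ValueError(f"interval end {end} < start {start}")
    return start - 1, end


def bed_to_gtf(start: int, end: int) -> tuple[int, int]:
    """0-based half-open (BED) -> 1-based closed (GTF)."""
    if end <= start:
        raise ValueError(f"empty BED interval {start}..{end}")
    return start + 1, end
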