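"""Evolutionary emergence of acceptor G tracts across vertebrates.

A gene's orthologous acceptor windows are scored for G-tract presence in
each of five vertebrate clades, treated as an ordered ladder from fish
(outermost) to placental/other mammals (innermost), with birds and
reptiles as siblings at one level.  Presence at the clade level is an OR
over the clade's species, so a loss in one nested lineage (the wallaby
pattern: a tract interrupted by a single base while opossum keeps it)
does not erase clade presence.  Emergence is called under Dollo
parsimony — a tract arises once, at the outermost clade showing it, and
may be lost repeatedly inside that clade.

The packaged survey table carries 21 human acceptor windows
(intron-relative -15..-1) with clade-level presence/absence/ND calls for
the non-human clades; presence for clades with a sequence is recomputed
from the sequence itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotation import AcceptorWindow
from .scan import find_g_tracts

__all__ = [
    "CLADES",
    "MAMMALIAN_CLADES",
    "SpeciesRecord",
    "OrthologWindowSet",
    "PresenceRow",
    "load_ortholog_table",
    "load_packaged_survey",
    "presence_row",
    "call_emergence",
    "summarize_emergence",
    "write_presence_tsv",
]

#: Ordered ladder, outermost (earliest-diverging) first.
CLADES: tuple[str, ...] = ("fish", "reptiles", "birds", "marsupials", "other_mammals")
MAMMALIAN_CLADES = frozenset({"marsupials", "other_mammals"})

ND = "ND"


@dataclass(frozen=True)
class SpeciesRecord:
    species: str
    clade: str
    window: str | None = None       # -15..-1 acceptor window, when sequenced
    presence_code: int | None = None  # direct 1/0 call when no sequence

    @property
    def determined(self) -> bool:
        return self.window is not None or self.presence_code is not None

    @property
    def has_acceptor(self) -> bool:
        return self.window is not None and self.window.upper().endswith("AG")


@dataclass(frozen=True)
class OrthologWindowSet:
    gene_symbol: str
    records: tuple[SpeciesRecord, ...]


@dataclass(frozen=True)
class PresenceRow:
    gene_symbol: str
    presence: dict  # clade -> 1 | 0 | "ND"
    complete: bool
    emergence_call: str = "undetermined"
    emergence_clade: str | None = None

    def value(self, clade: str):
        return self.presence[clade]


def _parse_cell(cell: str) -> tuple[str | None, int | None]:
    cell = cell.strip()
    if cell.upper() == ND or cell == "":
        return None, None
    if cell in ("0", "1"):
        return None, int(cell)
    if not set(cell.upper()) <= set("ACGTN"):
        raise ValueError(f"bad window/presence cell {cell!r}")
    return cell.upper(), None


def load_ortholog_table(path: str | Path) -> list[OrthologWindowSet]:
    """Read the long-format ortholog table: columns ``gene``, ``species``,
    ``clade``, ``window`` (a sequence, a direct 1/0 presence call, or ND)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "species", "clade", "window"}
    if not required <= set(df.columns):
        raise ValueError(f"ortholog table needs columns {sorted(required)}")
    sets: dict[str, list[SpeciesRecord]] = {}
    order: list[str] = []
    for row in df.itertuples():
        if row.clade not in CLADES:
            raise ValueError(f"unknown clade label {row.clade!r}")
        window, code = _parse_cell(row.window)
        rec = SpeciesRecord(row.species, row.clade, window, code)
        if row.gene not in sets:
            order.append(row.gene)
        sets.setdefault(row.gene, []).append(rec)
    return [OrthologWindowSet(g, tuple(sets[g])) for g in order]


def load_packaged_survey() -> list[OrthologWindowSet]:
    """The packaged 21-gene vertebrate acceptor G-tract survey."""
    ref = resources.files("repa").joinpath("data/vertebrate_gtract_survey.tsv")
    with resources.as_file(ref) as path:
        return load_ortholog_table(path)


def _window_has_tract(seq: str, gmin: int) -> bool:
    w = AcceptorWindow(site_id="", window=seq.upper(), intron_span=len(seq),
                      exon_span=0)
    return bool(find_g_tracts(w, min_len=gmin, max_len=8,
                              search_from=-len(seq), search_to=-3))


def presence_row(window_set: OrthologWindowSet, gmin: int = 3) -> PresenceRow:
    """Clade-level presence of a G tract of >= ``gmin`` Gs ending at or
    before position -3: 1 if any species in the clade has one, 0 if all
    determined species lack one, ND if no species is determined."""
    presence: dict[str, object] = {}
    for clade in CLADES:
        vals = []
        for rec in window_set.records:
            if rec.clade != clade or not rec.determined:
                continue
            if rec.presence_code is not None:
                vals.append(rec.presence_code)
            else:
                vals.append(1 if _window_has_tract(rec.window, gmin) else 0)
        presence[clade] = ND if not vals else (1 if any(vals) else 0)
    complete = all(presence[c] in (0, 1) for c in CLADES)
    return PresenceRow(window_set.gene_symbol, presence, complete)


def _call_one(row: PresenceRow) -> PresenceRow:
    if not row.complete:
        return replace(row, emergence_call="undetermined", emergence_clade=None)
    outermost = next((c for c in CLADES if row.presence[c] == 1), None)
    if outermost is None:
        return replace(row, emergence_call="absent", emergence_clade=None)
    pre_mammalian = any(
        row.presence[c] == 1 for c in ("birds", "reptiles", "fish")
    )
    call = "pre_mammalian" if pre_mammalian else "mammalian_ancestor"
    return replace(row, emergence_call=call, emergence_clade=outermost)


def call_emergence(rows: Iterable[PresenceRow]) -> list[PresenceRow]:
    """Dollo emergence calls: the tract arose at the outermost clade with
    presence; absence in a clade nested inside the origin counts as a
    secondary loss, never as a second origin."""
    return [_call_one(r) for r in rows]


def summarize_emergence(rows: Sequence[PresenceRow]) -> dict:
    """Summary counts over called rows.  Percentages use complete rows
    only; with zero complete rows they are NaN."""
    rows = list(rows)
    complete = [r for r in rows if r.complete]
    n_complete = len(complete)
    n_mam = sum(r.emergence_call == "mammalian_ancestor" for r in complete)
    n_pre = sum(r.emergence_call == "pre_mammalian" for r in complete)
    n_absent = sum(r.emergence_call == "absent" for r in complete)
    per_clade = {
        c: sum(r.presence[c] == 1 for r in complete) for c in CLADES
    }
    mam_not_marsupial = [
        r for r in complete
        if r.presence["other_mammals"] == 1 and r.presence["marsupials"] == 0
    ]
    marsupial_present = [
        r for r in complete
        if r.emergence_call == "mammalian_ancestor" and r.presence["marsupials"] == 1
    ]

    def pct(k: int) -> float:
        return 100.0 * k / n_complete if n_complete else math.nan

    return {
        "n_rows": len(rows),
        "n_complete": n_complete,
        "n_mammalian": n_mam,
        "n_pre_mammalian": n_pre,
        "n_absent": n_absent,
        "pct_mammalian": pct(n_mam),
        "pct_pre_mammalian": pct(n_pre),
        "n_mammal_not_marsupial": len(mam_not_marsupial),
        "pct_mammal_not_marsupial": pct(len(mam_not_marsupial)),
        "n_marsupial_present": len(marsupial_present),
        "pct_marsupial_present": pct(len(marsupial_present)),
        "per_clade_presence": per_clade,
    }


def write_presence_tsv(rows: Sequence[PresenceRow], path: str | Path) -> None:
    recs = []
    for r in rows:
        rec = {"gene": r.gene_symbol}
        rec.update({c: r.presence[c] for c in CLADES})
        rec["complete"] = r.complete
        rec["emergence_call"] = r.emergence_call
        rec["emergence_clade"] = r.emergence_clade or ""
        recs.append(rec)
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)
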