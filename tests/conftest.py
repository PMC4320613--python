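"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own scanning code paths:
they work on raw strings with regexes and exhaustive enumeration, so
agreement with the pipeline is a genuine cross-check.
"""

from __future__ import annotations

import re
from fractions import Fraction
from itertools import combinations

import pytest

from repa.annotation import AcceptorWindow
from repa.synth import GeneratorConfig, generate_genome


def make_window(seq: str, exon_span: int = 0, **kw) -> AcceptorWindow:
    """Build an acceptor window straight from a string (intron part
    first; last ``exon_span`` characters are exonic)."""
    kw.setdefault("site_id", "w")
    return AcceptorWindow(
        window=seq.upper(),
        intron_span=len(seq) - exon_span,
        exon_span=exon_span,
        **kw,
    )


@pytest.fixture
def window_factory():
    return make_window


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def naive_revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_g_tracts(seq: str, min_len=3, search_from=-15, search_to=-3):
    """Regex scan for maximal G runs in an intron-only window string;
    returns (first_g_position, length) pairs, 5'->3'."""
    n = len(seq)
    out = []
    for m in re.finditer(r"G+", seq.upper()):
        first = m.start() - n
        last = m.end() - 1 - n
        length = m.end() - m.start()
        if length >= min_len and last <= search_to and last >= search_from \
                and first <= search_to:
            out.append((first, length))
    return out


def naive_purine_fraction(seq: str, lo=-10, hi=-3):
    """Hand count over intron-relative lo..hi of an intron-only string."""
    region = seq.upper()[len(seq) + lo : len(seq) + hi + 1]
    informative = [b for b in region if b != "N"]
    if not informative:
        return None
    return sum(b in "AG" for b in informative) / len(informative)


def hypergeom_upper_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """Exhaustive enumeration of all C(N, n) draws (tiny N only)."""
    population = [1] * K + [0] * (N - K)
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return Fraction(hits, total)


@pytest.fixture(scope="session")
def oracle():
    class Oracle:
        revcomp = staticmethod(naive_revcomp)
        g_tracts = staticmethod(naive_g_tracts)
        purine_fraction = staticmethod(naive_purine_fraction)
        hypergeom_upper = staticmethod(hypergeom_upper_exact)

    return Oracle


# ---------------------------------------------------------------------------
# shared synthetic data (one generation per session keeps the suite fast)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_genome():
    """~120 genes, the default planted distributions."""
    return generate_genome(GeneratorConfig(seed=13, n_genes=120))


@pytest.fixture(scope="session")
def big_genome():
    """~400 genes: enough sites per class to train the full-window
    strength model."""
    return generate_genome(GeneratorConfig(seed=21, n_genes=400))


@pytest.fixture(scope="session")
def small_genome_files(small_genome, tmp_path_factory):
    out = tmp_path_factory.mktemp("synth")
    return small_genome, small_genome.write(out)


@pytest.fixture(scope="session")
def trained(big_genome):
    """Strength model fitted on planted data: signal = constitutive
    windows, decoys = purine-rich windows, both 23 nt."""
    from repa.annotation import derive_introns, extract_windows
    from repa.strength import train_strength_model

    windows, _ = extract_windows(big_genome.genome,
                                 derive_introns(big_genome.models))
    truth = big_genome.truth.set_index("site_id")
    known = [w for w in windows if w.site_id in truth.index
             and len(w.window) == 23]
    const = [w.window for w in known if not truth.loc[w.site_id].is_repa]
    repa = [w.window for w in known if truth.loc[w.site_id].is_repa]
    return train_strength_model(const, repa), const, repa
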