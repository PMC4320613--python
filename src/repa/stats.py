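"""Enrichment statistics: hypergeometric upper tails, positional purine
enrichment, alternative-splicing abundance, and Fisher right-tailed
gene-set enrichment with random-set backgrounds.

Tail probabilities are summed in log space (gammaln + logsumexp), so a
p-value of 1e-300 is still exact rather than underflowing to a printed
0; values below 1e-300 are additionally flagged by ``is_underflow``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "hypergeom_upper",
    "log_hypergeom_upper",
    "fisher_right_tail",
    "is_underflow",
    "positional_purine_test",
    "as_abundance_test",
    "GeneSetResult",
    "gene_set_enrichment",
    "read_gmt",
]

UNDERFLOW_P = 1e-300


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _validate(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid population: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"observed k={k} outside 0..min(K={K}, n={n})")


def log_hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """log P(X >= k) for X ~ Hypergeometric(N population, K successes,
    n draws), by exact log-space summation."""
    _validate(k, K, n, N)
    floor = max(0, n - (N - K))  # smallest possible draw count
    if k <= floor:
        return 0.0  # P(X >= k) = 1 exactly
    lo, hi = k, min(K, n)
    j = np.arange(lo, hi + 1)
    terms = _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
    return float(min(logsumexp(terms), 0.0))


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k); exact to well below 1e-300 (use
    :func:`log_hypergeom_upper` for the log value)."""
    return float(np.exp(log_hypergeom_upper(k, K, n, N)))


def is_underflow(p: float) -> bool:
    """Whether a tail probability is below the reporting floor at which
    older tools printed "p = 0"."""
    return p < UNDERFLOW_P


def fisher_right_tail(table: Sequence[Sequence[int]]) -> float:
    """Right-tailed Fisher's exact test on a 2x2 table
    ``[[a, b], [c, d]]`` (a = overlap); identical to the hypergeometric
    upper tail with k=a, K=a+b, n=a+c, N=a+b+c+d."""
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    return hypergeom_upper(a, a + b, a + c, a + b + c + d)


def positional_purine_test(profile_query, profile_background) -> pd.Series:
    """Per-position purine enrichment of a query window set against a
    background set (one hypergeometric upper tail per position, query
    purines drawn from the pooled population)."""
    if list(profile_query.positions) != list(profile_background.positions):
        raise ValueError("profiles cover different positions")
    out = {}
    for pos in profile_query.positions:
        qc = profile_query.counts.loc[pos]
        bc = profile_background.counts.loc[pos]
        q_pur, q_tot = int(qc["A"] + qc["G"]), int(qc[["A", "C", "G", "T"]].sum())
        b_pur, b_tot = int(bc["A"] + bc["G"]), int(bc[["A", "C", "G", "T"]].sum())
        N, K, n = q_tot + b_tot, q_pur + b_pur, q_tot
        k = min(q_pur, min(K, n))
        out[pos] = hypergeom_upper(k, K, n, N) if N else np.nan
    return pd.Series(out, name="p_purine_enrichment")


def as_abundance_test(
    group_alt_count: int,
    group_size: int,
    population_alt_count: int,
    population_size: int,
) -> tuple[float, float]:
    """Alternative-splicing abundance of a motif group, normalized to the
    population (random-exon) rate, with a hypergeometric upper-tail p.

    Returns ``(p_value, normalized_abundance)``.
    """
    if group_size <= 0 or population_size <= 0:
        raise ValueError("empty group or population")
    baseline = population_alt_count / population_size
    if baseline == 0:
        raise ValueError("zero baseline alternative-splicing rate")
    abundance = (group_alt_count / group_size) / baseline
    p = hypergeom_upper(
        group_alt_count, population_alt_count, group_size, population_size
    )
    return p, abundance


@dataclass(frozen=True)
class GeneSetResult:
    set_name: str
    overlap: int
    set_size: int
    p_value: float
    minus_log10_p: float


def gene_set_enrichment(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    n_random: int = 6,
    random_size: int | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Right-tailed Fisher enrichment of a query gene list in each gene
    set, plus the same statistic for ``n_random`` random query sets of
    matched (or given) size drawn from the universe — the background
    bars against which real enrichment is judged.

    Returns ``(results, random_results)``; both are sorted/indexed by
    gene set, results ascending by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    if not set(query_genes) <= universe:
        missing = len(set(query_genes)) - len(query)
        raise ValueError(f"{missing} query gene(s) outside the universe")

    def _test(q: set[str]) -> list[GeneSetResult]:
        res = []
        for name, members in gene_sets.items():
            members = set(members) & universe
            k = len(q & members)
            p = hypergeom_upper(k, len(members), len(q), len(universe))
            res.append(GeneSetResult(name, k, len(members), p, -np.log10(max(p, 5e-324))))
        return res

    results = pd.DataFrame([r.__dict__ for r in _test(query)]).sort_values("p_value")
    rng = np.random.default_rng(seed)
    size = random_size or len(query)
    pool = sorted(universe)
    random_rows = []
    for r in range(n_random):
        rand_q = set(rng.choice(pool, size=size, replace=False))
        for res in _test(rand_q):
            random_rows.append({"random_set": r, **res.__dict__})
    return results.reset_index(drop=True), pd.DataFrame(random_rows)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets (name <tab> description <tab> genes...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets
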