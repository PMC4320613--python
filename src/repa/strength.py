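"""Acceptor splice-site strength: a trainable maximum-entropy sequence
model with log-odds scoring.

The model follows the maximum-entropy framework for splice-site
discrimination: two distributions over fixed-length acceptor windows
(signal = true sites, background = decoys) are fitted subject to
empirical marginal constraints, and a site's strength is the log2
likelihood ratio in bits,

    score(w) = log2 P_signal(w) - log2 P_background(w).

Two constraint sets are supported:

* ``"singletons"`` — per-position marginals only; the maximum-entropy
  solution is the closed-form product of marginals (a position weight
  matrix).
* ``"adjacent_pairs"`` — marginals of every adjacent position pair (and
  hence all singletons); the solution is chain-structured and is fitted
  by iterative proportional scaling with exact chain marginals computed
  by a transfer-matrix recursion.

Empirical marginals carry a +0.5 Laplace pseudocount so every A/C/G/T
window has a finite score.  The default window is 23 nt (20 intronic +
3 exonic bases).

The module is organised like a statsmodels model: build
:class:`MaxEntAcceptorStrength` from training data, call :meth:`fit`,
and use the returned :class:`StrengthResults` to score sites, compare
groups and serialize parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

__all__ = [
    "MaxEntAcceptorStrength",
    "StrengthResults",
    "ConvergenceError",
    "compare_groups",
    "train_strength_model",
]


class ConvergenceError(RuntimeError):
    """Fitting stopped at the iteration cap; carries the residual."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"marginal residual {residual:.3g} after {max_iter} iterations"
        )
        self.residual = residual


def _encode(seqs: Sequence[str]) -> np.ndarray:
    n, L = len(seqs), len(seqs[0])
    arr = np.empty((n, L), dtype=np.int8)
    for i, s in enumerate(seqs):
        s = s.upper()
        if len(s) != L:
            raise ValueError("training sequences have non-uniform lengths")
        try:
            arr[i] = [_BASE_INDEX[b] for b in s]
        except KeyError as exc:
            raise ValueError(f"non-ACGT base in training sequence: {exc}") from exc
    return arr


def _singleton_marginals(arr: np.ndarray, smoothing: float) -> np.ndarray:
    n, L = arr.shape
    counts = np.zeros((L, 4))
    for i in range(L):
        counts[i] = np.bincount(arr[:, i], minlength=4)
    probs = (counts + smoothing) / (n + 4 * smoothing)
    return probs


def _pair_marginals(arr: np.ndarray, smoothing: float) -> np.ndarray:
    n, L = arr.shape
    out = np.zeros((L - 1, 4, 4))
    for i in range(L - 1):
        np.add.at(out[i], (arr[:, i], arr[:, i + 1]), 1.0)
    return (out + smoothing) / (n + 16 * smoothing)


def _chain_marginals(psis: list[np.ndarray]) -> tuple[list[np.ndarray], float]:
    """Exact edge marginals and log partition function of a chain model
    P(x) prop prod_e psi_e(x_i, x_{i+1})  (transfer-matrix recursion)."""
    n_edges = len(psis)
    alphas = [np.full(4, 0.25)]
    logz = math.log(4.0)
    for psi in psis:
        v = alphas[-1] @ psi
        s = float(v.sum())
        logz += math.log(s)
        alphas.append(v / s)
    betas = [np.ones(4)] * (n_edges + 1)
    betas[n_edges] = np.full(4, 1.0)
    for i in range(n_edges - 1, -1, -1):
        w = psis[i] @ betas[i + 1]
        betas[i] = w / w.sum()
    marginals = []
    for i in range(n_edges):
        mu = alphas[i][:, None] * psis[i] * betas[i + 1][None, :]
        marginals.append(mu / mu.sum())
    return marginals, logz


@dataclass
class _Distribution:
    """One fitted normalized distribution over L-mers."""

    kind: str  # "singletons" | "adjacent_pairs"
    log_singleton: np.ndarray | None = None  # (L, 4)
    log_psi: list[np.ndarray] | None = None  # edges, each (4, 4)
    logz: float = 0.0
    length: int = 0

    def log_prob(self, arr: np.ndarray) -> np.ndarray:
        """Natural-log probability of encoded sequences (n, L)."""
        if self.kind == "singletons":
            idx = np.arange(self.length)
            return self.log_singleton[idx, arr].sum(axis=1)
        lp = np.zeros(arr.shape[0])
        for i, psi in enumerate(self.log_psi):
            lp += psi[arr[:, i], arr[:, i + 1]]
        return lp - self.logz


def _fit_distribution(
    arr: np.ndarray, kind: str, smoothing: float, tol: float, max_iter: int
) -> tuple[_Distribution, int, float]:
    n, L = arr.shape
    if kind == "singletons" or L == 1:
        probs = _singleton_marginals(arr, smoothing)
        return (
            _Distribution("singletons", log_singleton=np.log(probs), length=L),
            0,
            0.0,
        )
    targets = _pair_marginals(arr, smoothing)
    psis = [np.ones((4, 4)) for _ in range(L - 1)]
    residual = np.inf
    for it in range(1, max_iter + 1):
        current, _ = _chain_marginals(psis)
        residual = max(
            float(np.abs(cur - tgt).max()) for cur, tgt in zip(current, targets)
        )
        if residual < tol:
            break
        # iterative proportional fitting: one edge at a time, marginals
        # recomputed after each update (simultaneous updates diverge)
        for i in range(L - 1):
            current, _ = _chain_marginals(psis)
            psis[i] = psis[i] * targets[i] / np.maximum(current[i], 1e-300)
            psis[i] /= psis[i].mean()
    else:
        raise ConvergenceError(residual, max_iter)
    _, logz = _chain_marginals(psis)
    dist = _Distribution(
        "adjacent_pairs", log_psi=[np.log(p) for p in psis], logz=logz, length=L
    )
    return dist, it, residual


class MaxEntAcceptorStrength:
    """Maximum-entropy acceptor-strength model.

    Parameters
    ----------
    signal_seqs, decoy_seqs
        Equal-length A/C/G/T training windows for true acceptors and
        decoys.  At the full 23-nt window at least 200 sequences per
        class are required; shorter (reduced) windows accept any n >= 2,
        which keeps exhaustive-enumeration checks tractable.
    constraints
        ``"adjacent_pairs"`` (default) or ``"singletons"``.
    smoothing
        Laplace pseudocount added to empirical marginal counts.
    window_spec
        (intron_span, exon_span) metadata; must sum to the sequence
        length.
    """

    FULL_WINDOW = 23
    MIN_TRAIN_FULL = 200

    def __init__(
        self,
        signal_seqs: Sequence[str],
        decoy_seqs: Sequence[str],
        constraints: str = "adjacent_pairs",
        smoothing: float = 0.5,
        window_spec: tuple[int, int] | None = None,
    ):
        if constraints not in ("adjacent_pairs", "singletons"):
            raise ValueError(f"unsupported constraint set {constraints!r}")
        self.signal = _encode(list(signal_seqs))
        self.decoy = _encode(list(decoy_seqs))
        if self.signal.shape[1] != self.decoy.shape[1]:
            raise ValueError("signal and decoy windows differ in length")
        self.length = self.signal.shape[1]
        if self.length >= self.FULL_WINDOW:
            for name, arr in (("signal", self.signal), ("decoy", self.decoy)):
                if arr.shape[0] < self.MIN_TRAIN_FULL:
                    raise ValueError(
                        f"need >= {self.MIN_TRAIN_FULL} {name} sequences at the "
                        f"full window, got {arr.shape[0]}"
                    )
        if window_spec is None:
            window_spec = (
                (self.length - 3, 3) if self.length == self.FULL_WINDOW
                else (self.length, 0)
            )
        if sum(window_spec) != self.length:
            raise ValueError(
                f"window_spec {window_spec} does not sum to length {self.length}"
            )
        self.window_spec = window_spec
        self.constraints = constraints
        self.smoothing = smoothing

    def fit(self, tol: float = 1e-4, max_iter: int = 200) -> "StrengthResults":
        sig, it_s, res_s = _fit_distribution(
            self.signal, self.constraints, self.smoothing, tol, max_iter
        )
        bg, it_b, res_b = _fit_distribution(
            self.decoy, self.constraints, self.smoothing, tol, max_iter
        )
        meta = {
            "n_signal": int(self.signal.shape[0]),
            "n_decoy": int(self.decoy.shape[0]),
            "constraints": self.constraints,
            "smoothing": self.smoothing,
            "window_spec": list(self.window_spec),
            "iterations": max(it_s, it_b),
            "residual": max(res_s, res_b),
            "tol": tol,
        }
        return StrengthResults(self, sig, bg, meta)


@dataclass
class StrengthResults:
    """Fitted acceptor-strength model: scoring, diagnostics, I/O."""

    model: MaxEntAcceptorStrength | None
    signal_dist: _Distribution
    background_dist: _Distribution
    training_meta: dict

    LN2 = math.log(2.0)

    @property
    def length(self) -> int:
        return self.signal_dist.length

    def _check(self, windows: Sequence[str]) -> np.ndarray:
        for w in windows:
            if len(w) != self.length:
                raise ValueError(
                    f"window length {len(w)} != model length {self.length}"
                )
            if "N" in w.upper():
                raise ValueError("cannot score windows containing N")
        return _encode(list(windows))

    def score(self, window: str) -> float:
        """Log2 likelihood-ratio score of one window, in bits."""
        return float(self.score_many([window])[0])

    def score_many(self, windows: Sequence[str]) -> np.ndarray:
        arr = self._check(windows)
        lr = self.signal_dist.log_prob(arr) - self.background_dist.log_prob(arr)
        return lr / self.LN2

    def log_prob(self, windows: Sequence[str], which: str = "signal") -> np.ndarray:
        """Natural-log probability under the signal or background model
        (used by exhaustive normalization checks)."""
        arr = self._check(windows)
        dist = self.signal_dist if which == "signal" else self.background_dist
        return dist.log_prob(arr)

    def summary(self) -> str:
        m = self.training_meta
        lines = [
            "Maximum-entropy acceptor strength model",
            "=" * 44,
            f"window length        {self.length} nt "
            f"({m['window_spec'][0]} intron + {m['window_spec'][1]} exon)",
            f"constraint set       {m['constraints']}",
            f"smoothing            +{m['smoothing']} pseudocount",
            f"training sequences   {m['n_signal']} signal / {m['n_decoy']} decoy",
            f"scaling iterations   {m['iterations']}",
            f"marginal residual    {m['residual']:.2e} (tol {m['tol']:.0e})",
        ]
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        def dist_dict(d: _Distribution) -> dict:
            return {
                "kind": d.kind,
                "length": d.length,
                "log_singleton": None if d.log_singleton is None
                else d.log_singleton.tolist(),
                "log_psi": None if d.log_psi is None
                else [p.tolist() for p in d.log_psi],
                "logz": d.logz,
            }

        payload = {
            "training_meta": self.training_meta,
            "signal": dist_dict(self.signal_dist),
            "background": dist_dict(self.background_dist),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "StrengthResults":
        payload = json.loads(Path(path).read_text())

        def load(d: dict) -> _Distribution:
            return _Distribution(
                kind=d["kind"],
                log_singleton=None if d["log_singleton"] is None
                else np.asarray(d["log_singleton"]),
                log_psi=None if d["log_psi"] is None
                else [np.asarray(p) for p in d["log_psi"]],
                logz=d["logz"],
                length=d["length"],
            )

        return cls(None, load(payload["signal"]), load(payload["background"]),
                   payload["training_meta"])


def train_strength_model(
    true_sites: Sequence[str],
    decoy_sites: Sequence[str],
    constraint_set: str = "adjacent_pairs",
    smoothing: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 200,
    window_spec: tuple[int, int] | None = None,
) -> StrengthResults:
    """Functional wrapper: build the model and fit in one call."""
    return MaxEntAcceptorStrength(
        true_sites, decoy_sites, constraint_set, smoothing, window_spec
    ).fit(tol=tol, max_iter=max_iter)


def compare_groups(
    scores_by_group: Mapping[str, Sequence[float]],
    reference: str | None = None,
) -> pd.DataFrame:
    """Group means/SDs and classic equal-variance two-sample t-tests of
    the reference (first) group against each other group, two-tailed.

    Degenerate groups (n < 2 or zero pooled variance) are flagged and
    get NaN statistics rather than an error.
    """
    names = list(scores_by_group)
    if reference is None:
        reference = names[0]
    ref = np.asarray(scores_by_group[reference], dtype=float)
    rows = []
    for name in names:
        vals = np.asarray(scores_by_group[name], dtype=float)
        row = {
            "group": name,
            "n": len(vals),
            "mean": float(vals.mean()) if len(vals) else np.nan,
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            "t_vs_reference": np.nan,
            "p_vs_reference": np.nan,
            "degenerate": len(vals) < 2,
        }
        if name != reference and len(vals) >= 2 and len(ref) >= 2:
            if np.ptp(vals) == 0 and np.ptp(ref) == 0:
                row["degenerate"] = True
                if vals.mean() == ref.mean():
                    row["t_vs_reference"], row["p_vs_reference"] = 0.0, 1.0
            else:
                t, p = sps.ttest_ind(ref, vals, equal_var=True)
                row["t_vs_reference"], row["p_vs_reference"] = float(t), float(p)
        rows.append(row)
    return pd.DataFrame(rows)
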