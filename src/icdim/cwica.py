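"""Split-half determination of the number of independent components.

The estimator divides the ``p`` observed channels at random into two
near-equal blocks, fits ICA with ``q`` components to each block for
``q = 2 .. A_max``, and measures how reproducible the two component sets
are through the cross-block matrix of absolute rank correlations.  For each
block-2 component the best-matching block-1 component is found
(column-wise maximum of absolute Spearman correlation); the statistic

    R_q = min over components of that column-wise maximum

is close to 1 while every extracted component has a counterpart in the
other block (q at or below the true dimension) and collapses toward 0 once
extra components are pure noise.  The optimum is read off the largest
single drop: with D_q = R_q - R_{q-1}, the estimate is argmin(D_q) - 1.
The whole procedure is repeated over independent random splits and the
modal estimate returned.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .ica import BackendSpec, ICAFitError, fit_ica
from .simulate import SignalMatrix

__all__ = [
    "BlockSplit",
    "CrossCorrelationBlock",
    "CorrelationProfile",
    "DeterminationResult",
    "split_two_blocks",
    "rank_correlation_block",
    "rq_statistic",
    "first_differences",
    "select_q_single",
    "cw_ica",
]

_CORRELATIONS = ("spearman", "pearson")


@dataclass(frozen=True)
class BlockSplit:
    """A random partition of channel indices into two near-equal blocks."""

    block1_rows: np.ndarray
    block2_rows: np.ndarray
    rep_index: int
    seed: int


@dataclass(frozen=True)
class CrossCorrelationBlock:
    """Cross-block correlation matrix: rows = block-1, columns = block-2."""

    values: np.ndarray

    @property
    def q(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CorrelationProfile:
    """R_{i,q} for repetitions i and q = 2..a_max (NaN marks failed fits)."""

    r_values: np.ndarray
    a_max: int
    rep: int

    def row(self, i: int) -> np.ndarray:
        return self.r_values[i]


@dataclass(frozen=True)
class DeterminationResult:
    """Outcome of a component-number determination."""

    per_rep_q: list[int | None]
    q_opt: int
    vote_counts: dict[int, int]
    tie_broken: bool
    profile: CorrelationProfile
    method: str = "cw_ica"
    diagnostics: dict = field(default_factory=dict)


def split_two_blocks(p: int, seed: int, rep_index: int = 0) -> BlockSplit:
    """Uniformly random partition of ``{0..p-1}`` into blocks of
    ceil(p/2) and floor(p/2) channels."""
    if p < 4:
        raise ValueError(f"need p >= 4 channels to split, got {p}")
    perm = np.random.default_rng(seed).permutation(p)
    k = (p + 1) // 2
    return BlockSplit(
        block1_rows=np.sort(perm[:k]),
        block2_rows=np.sort(perm[k:]),
        rep_index=rep_index,
        seed=seed,
    )


def _rank_rows(S: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 1, S)


def _standardize_rows(S: np.ndarray, label: str) -> np.ndarray:
    """Center/scale rows; constant rows become zero (correlate as 0)."""
    S = S - S.mean(axis=1, keepdims=True)
    sd = S.std(axis=1, keepdims=True)
    degenerate = sd[:, 0] == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant component(s) in {label}; "
            "their correlations are set to 0",
            stacklevel=3,
        )
        sd[degenerate] = 1.0
    return S / sd


def rank_correlation_block(
    S1: np.ndarray, S2: np.ndarray, correlation: str = "spearman"
) -> CrossCorrelationBlock:
    """Cross-block correlation matrix between two component sets.

    Entry ``(j, k)`` is the Spearman (rank-then-product-moment, average
    ranks on ties) or Pearson correlation of block-1 component ``j`` with
    block-2 component ``k``.  Degenerate constant components yield zero
    correlations with a warning.
    """
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    if S1.shape != S2.shape:
        raise ValueError(f"component sets differ in shape: {S1.shape} vs {S2.shape}")
    if S1.shape[1] < 3:
        raise ValueError("need at least 3 samples per component")
    if correlation not in _CORRELATIONS:
        raise ValueError(f"correlation must be one of {_CORRELATIONS}")
    if correlation == "spearman":
        S1, S2 = _rank_rows(S1), _rank_rows(S2)
    n = S1.shape[1]
    A = _standardize_rows(S1, "block 1")
    B = _standardize_rows(S2, "block 2")
    C = (A @ B.T) / n
    return CrossCorrelationBlock(values=np.clip(C, -1.0, 1.0))


def rq_statistic(block: CrossCorrelationBlock) -> float:
    """min over columns of the column-wise maximum absolute correlation."""
    return float(np.abs(block.values).max(axis=0).min())


def first_differences(r_row: np.ndarray, q_start: int = 2) -> np.ndarray:
    """D_q = R_q - R_{q-1} for q = q_start+1 .. a_max.

    ``r_row[j]`` holds R at q = q_start + j; NaN marks a failed fit and
    propagates to both adjacent differences.
    """
    r = np.asarray(r_row, dtype=float)
    if np.sum(np.isfinite(r)) < 2:
        raise ValueError("need at least 2 present R values to difference")
    return r[1:] - r[:-1]


def select_q_single(r_row: np.ndarray, q_start: int = 2) -> tuple[int, bool]:
    """Pick q for one repetition by the largest-drop rule.

    Returns ``(q, fallback)``: q is ``argmin(D) - 1`` (the value before the
    drop; ties toward the smallest q).  If no difference is negative there
    is no drop to detect; the fallback returns the q with maximal R and
    flags it.
    """
    r = np.asarray(r_row, dtype=float)
    d = first_differences(r, q_start)
    finite = np.isfinite(d)
    if finite.any() and np.nanmin(d[finite]) < 0:
        j = int(np.flatnonzero(finite)[np.argmin(d[finite])])
        # D at index j corresponds to q* = q_start + 1 + j; optimum is q* - 1
        return q_start + j, False
    finite_r = np.isfinite(r)
    j = int(np.flatnonzero(finite_r)[np.argmax(r[finite_r])])
    return q_start + j, True


def _block_seed(base_seed: int, q: int, block_index: int) -> int:
    return (base_seed + 10007 * q + 7919 * (block_index + 1)) % 2**31


def score_blocks(
    X: SignalMatrix,
    blocks: list[np.ndarray],
    q: int,
    backend: BackendSpec,
    correlation: str,
    base_seed: int,
) -> float:
    """Reproducibility score for one q: fit ICA per block, return the
    minimum over unordered block pairs of the R_q statistic.

    NaN when any block's fit fails outright (raises / non-finite output);
    iterates that merely hit the iteration cap are used as-is.
    """
    comps = []
    for b, rows in enumerate(blocks):
        sub = SignalMatrix(data=X.data[rows], channel_labels=None)
        try:
            res = fit_ica(sub, q, backend, seed=_block_seed(base_seed, q, b))
        except ICAFitError:
            return float("nan")
        comps.append(res.components)
    scores = []
    for a in range(len(comps) - 1):
        for b in range(a + 1, len(comps)):
            block = rank_correlation_block(comps[a], comps[b], correlation)
            scores.append(rq_statistic(block))
    return float(min(scores))


def _rep_seed(seed: int, rep_index: int) -> int:
    return (seed + 1000003 * rep_index) % 2**31


def cw_ica(
    X: SignalMatrix,
    a_max: int | None = None,
    rep: int = 10,
    backend: BackendSpec | None = None,
    correlation: str = "spearman",
    seed: int = 0,
) -> DeterminationResult:
    """Estimate the optimal number of independent components.

    For each of ``rep`` repetitions the channels are re-split at random into
    two blocks, ICA is fitted per block for ``q = 2 .. a_max``, and the
    cross-block statistic R_q recorded; the repetition's estimate is the q
    preceding the largest drop in R_q.  The final estimate is the mode of
    the per-repetition estimates (ties toward the smallest q).

    Parameters
    ----------
    X
        Observed channels, ``p x n``.
    a_max
        Largest candidate q; defaults to ``floor(p / 2)`` and must satisfy
        ``3 <= a_max <= floor(p / 2)`` so each block can host a_max
        components.
    rep
        Number of independent random splits (>= 1).
    backend, correlation, seed
        ICA backend configuration, correlation flavour, master seed.
    """
    spec = backend or BackendSpec()
    p = X.p
    if a_max is None:
        a_max = p // 2
    if not 3 <= a_max <= p // 2:
        raise ValueError(
            f"a_max={a_max} violates 3 <= a_max <= floor(p/2) = {p // 2} "
            "(each block must be able to host a_max components)"
        )
    if rep < 1:
        raise ValueError("rep must be >= 1")
    if correlation not in _CORRELATIONS:
        raise ValueError(f"correlation must be one of {_CORRELATIONS}")

    qs = np.arange(2, a_max + 1)
    r_values = np.full((rep, len(qs)), np.nan)
    per_rep_q: list[int | None] = []
    fallbacks = 0
    for i in range(rep):
        rs = _rep_seed(seed, i)
        split = split_two_blocks(p, rs, rep_index=i)
        blocks = [split.block1_rows, split.block2_rows]
        for j, q in enumerate(qs):
            r_values[i, j] = score_blocks(X, blocks, int(q), spec, correlation, rs)
        try:
            q_i, fb = select_q_single(r_values[i], q_start=2)
        except ValueError:
            per_rep_q.append(None)
            continue
        fallbacks += fb
        per_rep_q.append(q_i)
    votes = Counter(q for q in per_rep_q if q is not None)
    if not votes:
        raise RuntimeError("every repetition failed; no estimate available")
    top = max(votes.values())
    winners = sorted(q for q, c in votes.items() if c == top)
    profile = CorrelationProfile(r_values=r_values, a_max=a_max, rep=rep)
    return DeterminationResult(
        per_rep_q=per_rep_q,
        q_opt=winners[0],
        vote_counts=dict(votes),
        tie_broken=len(winners) > 1,
        profile=profile,
        method="cw_ica",
        diagnostics={"fallback_reps": fallbacks, "backend": spec.name,
                     "correlation": correlation},
    )
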