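"""Comparator methods for determining the number of independent components.

Three classical approaches:

* Durbin-Watson criterion — the DW statistic of each residual channel after
  rank-q reconstruction measures how white the residual is (near 0: smooth
  structure remains, decompose further; near 2: pure noise,
  over-decomposed).  The original procedure reads q off a heatmap by eye;
  here the selection is automated as the largest jump ("sudden increase")
  in the per-q mean DW, and the full per-channel table is retained.
* ICA_corr_y — requires one known source signal y; the per-q score is the
  best absolute correlation between any estimated component and y, and the
  smallest q attaining the global best wins.
* ICA-by-Blocks — channels are split into B blocks, ICA fitted per block,
  and component reproducibility across blocks scored per q; originally a
  visual signal-correlation plot, automated here with the same largest-drop
  rule as the split-half estimator (a single split, no repetitions).

The automated selection rules for DW and ICA-by-Blocks are this package's
formalization of procedures that were originally visual; results carry a
``method_flag`` saying so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .cwica import (
    BackendSpec,
    CorrelationProfile,
    DeterminationResult,
    score_blocks,
    select_q_single,
)
from .ica import ICAFitError, fit_ica, reconstruct
from .simulate import SignalMatrix

__all__ = [
    "DWProfile",
    "CorrYProfile",
    "dw_statistic",
    "dw_determination",
    "ica_corr_y",
    "ica_by_blocks",
]


@dataclass(frozen=True)
class DWProfile:
    """Durbin-Watson values per channel and candidate q, plus the automated
    selection (rows of ``dw_values`` = channels, columns = q = 2..a_max)."""

    dw_values: np.ndarray
    mean_dw: np.ndarray
    q_opt: int
    method_flag: str = "auto: argmax first difference of mean DW"


@dataclass(frozen=True)
class CorrYProfile:
    """Best |corr(component, y)| per candidate q and the selected q."""

    best_corr: np.ndarray
    q_opt: int


def dw_statistic(residual_row: np.ndarray) -> float:
    """Durbin-Watson statistic of one residual signal.

    Ratio of the sum of squared successive differences to the sum of
    squares; 0 for a constant (perfectly smooth) residual, about 2 for
    white noise, at most 4 (perfectly alternating).
    """
    r = np.asarray(residual_row, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("residual must be a 1-D vector with n >= 2")
    denom = float(np.sum(r * r))
    if denom == 0.0:
        warnings.warn(
            "all-zero residual (perfect reconstruction); DW defined as 0",
            stacklevel=2,
        )
        return 0.0
    num = float(np.sum(np.diff(r) ** 2))
    return num / denom


def _fit_seed(seed: int, q: int) -> int:
    return (seed + 10007 * q) % 2**31


def dw_determination(
    X: SignalMatrix,
    a_max: int | None = None,
    backend: BackendSpec | None = None,
    seed: int = 0,
) -> DWProfile:
    """Select q by the Durbin-Watson criterion on reconstruction residuals.

    For each ``q = 2..a_max``: fit ICA, reconstruct, compute the DW
    statistic of every residual channel and its mean.  The selected q is
    one before the largest increase of the mean DW across q (the automated
    reading of the "sudden increase" rule).
    """
    spec = backend or BackendSpec()
    p = X.p
    if a_max is None:
        a_max = p // 2
    if not 2 <= a_max <= p:
        raise ValueError(f"a_max={a_max} violates 2 <= a_max <= p = {p}")
    qs = np.arange(2, a_max + 1)
    table = np.full((p, len(qs)), np.nan)
    for j, q in enumerate(qs):
        try:
            res = fit_ica(X, int(q), spec, seed=_fit_seed(seed, int(q)))
        except ICAFitError:
            continue
        residual = X.data - reconstruct(res, X).data
        if q == min(p, X.n):
            # full basis retained: reconstruction is the identity by
            # construction, the residual is round-off; DW is 0 by definition
            warnings.warn(
                f"q={q} retains the full basis (perfect reconstruction); "
                "all DW reported as 0",
                stacklevel=2,
            )
            table[:, j] = 0.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table[:, j] = [dw_statistic(row) for row in residual]
    mean_dw = np.nanmean(table, axis=0) if np.isfinite(table).any() else table.mean(0)
    diffs = mean_dw[1:] - mean_dw[:-1]
    finite = np.isfinite(diffs)
    if not finite.any():
        raise RuntimeError("no usable DW differences; all ICA fits failed")
    j = int(np.flatnonzero(finite)[np.argmax(diffs[finite])])
    # increase happens AT q = 3 + j; the optimum is the q before it
    q_opt = 2 + j
    return DWProfile(dw_values=table, mean_dw=mean_dw, q_opt=q_opt)


def _abs_corr(S: np.ndarray, y: np.ndarray, correlation: str) -> np.ndarray:
    if correlation == "spearman":
        S = np.apply_along_axis(rankdata, 1, S)
        y = rankdata(y)
    Sc = S - S.mean(axis=1, keepdims=True)
    sd = Sc.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf  # constant component -> correlation 0
    yc = y - y.mean()
    return np.abs((Sc / sd) @ yc) / (np.linalg.norm(yc) * np.sqrt(S.shape[1]))


def ica_corr_y(
    X: SignalMatrix,
    y: np.ndarray,
    a_max: int | None = None,
    backend: BackendSpec | None = None,
    correlation: str = "pearson",
    seed: int = 0,
) -> CorrYProfile:
    """Select q by correlation with a known source signal ``y``.

    For each q the score is the maximum absolute correlation between any
    estimated component and y; the selected q is the smallest one attaining
    the global maximum (parsimony on ties).
    """
    spec = backend or BackendSpec()
    y = np.asarray(y, dtype=float).ravel()
    if y.size != X.n:
        raise ValueError(f"y has length {y.size}, expected n={X.n}")
    if np.std(y) == 0:
        raise ValueError("y is constant; correlation is undefined")
    p = X.p
    if a_max is None:
        a_max = p // 2
    if not 2 <= a_max <= p:
        raise ValueError(f"a_max={a_max} violates 2 <= a_max <= p = {p}")
    qs = np.arange(2, a_max + 1)
    best = np.full(len(qs), np.nan)
    for j, q in enumerate(qs):
        try:
            res = fit_ica(X, int(q), spec, seed=_fit_seed(seed, int(q)))
        except ICAFitError:
            continue
        best[j] = float(_abs_corr(res.components, y, correlation).max())
    if not np.isfinite(best).any():
        raise RuntimeError("all ICA fits failed; no correlation profile")
    top = np.nanmax(best)
    q_opt = int(qs[np.flatnonzero(best >= top - 1e-9)[0]])
    return CorrYProfile(best_corr=best, q_opt=q_opt)


def _split_blocks(p: int, n_blocks: int, seed: int) -> list[np.ndarray]:
    """Random partition into n_blocks blocks with sizes differing by <= 1.

    For two blocks this reproduces the split-half partition exactly (block
    sizes ceil(p/2), floor(p/2) from the same seeded permutation).
    """
    perm = np.random.default_rng(seed).permutation(p)
    parts = np.array_split(perm, n_blocks)
    return [np.sort(part) for part in parts]


def ica_by_blocks(
    X: SignalMatrix,
    n_blocks: int = 2,
    a_max: int | None = None,
    backend: BackendSpec | None = None,
    correlation: str = "pearson",
    seed: int = 0,
) -> DeterminationResult:
    """Component-number selection by cross-block component reproducibility.

    One random partition of the channels into ``n_blocks`` near-equal
    blocks; for each ``q = 2..a_max`` ICA is fitted per block and the score
    is the minimum over block pairs of the min-of-column-max absolute
    correlation; q is then selected with the largest-drop rule.  With two
    blocks, Spearman correlation and a single repetition this coincides
    exactly with the split-half estimator's profile.
    """
    spec = backend or BackendSpec()
    p = X.p
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    limit = p // n_blocks
    if a_max is None:
        a_max = limit
    if not 3 <= a_max <= limit:
        raise ValueError(
            f"a_max={a_max} violates a_max <= floor(p / B) = {limit} "
            f"(p={p}, B={n_blocks})"
        )
    blocks = _split_blocks(p, n_blocks, seed)
    qs = np.arange(2, a_max + 1)
    r_values = np.full((1, len(qs)), np.nan)
    for j, q in enumerate(qs):
        r_values[0, j] = score_blocks(X, blocks, int(q), spec, correlation, seed)
    q_opt, fallback = select_q_single(r_values[0], q_start=2)
    profile = CorrelationProfile(r_values=r_values, a_max=a_max, rep=1)
    return DeterminationResult(
        per_rep_q=[q_opt],
        q_opt=q_opt,
        vote_counts={q_opt: 1},
        tie_broken=False,
        profile=profile,
        method="ica_by_blocks",
        diagnostics={
            "n_blocks": n_blocks,
            "fallback": fallback,
            "backend": spec.name,
            "correlation": correlation,
            "selection": "auto: largest-drop rule (formalized from the "
            "original visual signal-correlation plot)",
        },
    )
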