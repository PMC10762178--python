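"""Benchmark harness: accuracy and robustness experiments.

The accuracy experiment keeps one fixed source set and redraws the mixing
matrix per run; each determination method estimates the number of
components and Accuracy = 100 * m / N is the percentage of runs that hit
the true value.  The robustness sweep varies one generation axis (number
of mixed channels, signal length, SNR, frequency scale) and records every
(method, backend) estimate per level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .baselines import dw_determination, ica_by_blocks, ica_corr_y
from .cwica import BackendSpec, cw_ica
from .simulate import SourceSet, mix_signals, simulate_sources

__all__ = [
    "METHODS",
    "AccuracyReport",
    "SweepResult",
    "estimate_q",
    "accuracy_experiment",
    "robustness_sweep",
]

logger = logging.getLogger("icdim")

METHODS = ("cwica", "dw", "blocks", "icacorry")

_SWEEP_AXES = ("n_mixed_signals", "signal_length", "snr_db", "freq_scale")

# Documented default sweep levels per axis.
DEFAULT_LEVELS: dict[str, list] = {
    "signal_length": [256, 512, 1024, 2048],
    "n_mixed_signals": [12, 20, 30, 40],
    "snr_db": [None, 20, 10, 5],
    "freq_scale": [0.5, 1.0, 2.0],
}


@dataclass(frozen=True)
class AccuracyReport:
    """Accuracy of one method over N repeated mixings of a fixed source set."""

    method: str
    correct_runs: int
    total_runs: int
    accuracy: float
    per_run_estimates: list[Any]
    config: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SweepResult:
    """Per-level, per-(method, backend) estimates along one generation axis."""

    axis: str
    levels: list
    estimates: dict[tuple, Any]
    config: dict = field(default_factory=dict)

    def to_records(self) -> list[dict]:
        """Long-format rows (axis, level, method, backend, estimate)."""
        return [
            {
                "axis": self.axis,
                "level": level,
                "method": method,
                "backend": backend,
                "estimate": est,
            }
            for (level, method, backend), est in self.estimates.items()
        ]


def estimate_q(
    method: str,
    X,
    a_max: int,
    backend: BackendSpec,
    seed: int,
    y: np.ndarray | None = None,
    rep: int = 10,
    n_blocks: int = 2,
    correlation: str = "spearman",
) -> int:
    """Run one determination method and return its estimate."""
    if method == "cwica":
        return cw_ica(X, a_max=a_max, rep=rep, backend=backend,
                      correlation=correlation, seed=seed).q_opt
    if method == "dw":
        return dw_determination(X, a_max=a_max, backend=backend, seed=seed).q_opt
    if method == "blocks":
        return ica_by_blocks(X, n_blocks=n_blocks, a_max=a_max, backend=backend,
                             correlation=correlation, seed=seed).q_opt
    if method == "icacorry":
        if y is None:
            raise ValueError("icacorry requires a known source signal y")
        return ica_corr_y(X, y, a_max=a_max, backend=backend, seed=seed).q_opt
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def _a_max_for(p: int, method: str, n_blocks: int) -> int:
    if method == "blocks":
        return p // n_blocks
    return p // 2


def accuracy_experiment(
    q_true: int = 8,
    p: int = 30,
    n: int = 512,
    methods: tuple[str, ...] = ("cwica",),
    backend: BackendSpec | None = None,
    n_runs: int = 25,
    seed: int = 0,
    snr_db: float | None = None,
    rep: int = 10,
    sources: SourceSet | None = None,
) -> dict[str, AccuracyReport]:
    """Accuracy (percentage of correct runs) per method, Eq-style 100*m/N.

    One fixed source set; each run draws a fresh mixing matrix.  The known
    source for the corr-y method is the last catalog source.  A run where a
    method raises counts as incorrect, with the failure reason recorded in
    its per-run slot.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    spec = backend or BackendSpec()
    src = sources if sources is not None else simulate_sources(q_true, n, seed=seed)
    estimates: dict[str, list[Any]] = {m: [] for m in methods}
    for run in range(n_runs):
        run_seed = (seed + 7907 * (run + 1)) % 2**31
        X, _ = mix_signals(src, p, snr_db=snr_db, seed=run_seed)
        for m in methods:
            try:
                est = estimate_q(
                    m, X, _a_max_for(p, m, 2), spec, run_seed,
                    y=src.signals[-1], rep=rep,
                )
            except Exception as exc:  # failure is data, never silently dropped
                est = f"failed: {exc}"
            estimates[m].append(est)
            logger.info("run %d/%d %s -> %s", run + 1, n_runs, m, est)
    reports = {}
    for m in methods:
        correct = sum(1 for e in estimates[m] if e == src.source_count)
        reports[m] = AccuracyReport(
            method=m,
            correct_runs=correct,
            total_runs=n_runs,
            accuracy=100.0 * correct / n_runs,
            per_run_estimates=estimates[m],
            config={
                "q_true": src.source_count, "p": p, "n": n, "snr_db": snr_db,
                "backend": spec.name, "rep": rep, "seed": seed,
                "n_runs": n_runs,
            },
        )
    return reports


def robustness_sweep(
    q_true: int = 5,
    axis: str = "signal_length",
    levels: list | None = None,
    methods: tuple[str, ...] = ("cwica",),
    backends: tuple[str, ...] = ("fastica",),
    seed: int = 0,
    p: int = 30,
    n: int = 512,
    rep: int = 10,
) -> SweepResult:
    """Estimate q per (level, method, backend) along one generation axis.

    Parameters not on the swept axis stay at their defaults (p=30, n=512,
    no noise, freq_scale=1).
    """
    if axis not in _SWEEP_AXES:
        raise ValueError(f"axis must be one of {_SWEEP_AXES}, got {axis!r}")
    if levels is None:
        levels = DEFAULT_LEVELS[axis]
    if not levels:
        raise ValueError("levels must be nonempty")
    estimates: dict[tuple, Any] = {}
    for k, level in enumerate(levels):
        level_seed = (seed + 104729 * (k + 1)) % 2**31
        kw = {"p": p, "n": n, "snr_db": None, "freq_scale": 1.0}
        if axis == "n_mixed_signals":
            kw["p"] = int(level)
        elif axis == "signal_length":
            kw["n"] = int(level)
        elif axis == "snr_db":
            kw["snr_db"] = level
        elif axis == "freq_scale":
            kw["freq_scale"] = float(level)
        src = simulate_sources(q_true, kw["n"], freq_scale=kw["freq_scale"],
                               seed=level_seed)
        X, _ = mix_signals(src, kw["p"], snr_db=kw["snr_db"], seed=level_seed)
        for method in methods:
            for backend_name in backends:
                spec = BackendSpec(name=backend_name)
                try:
                    est = estimate_q(
                        method, X, _a_max_for(kw["p"], method, 2), spec,
                        level_seed, y=src.signals[-1], rep=rep,
                    )
                except Exception as exc:
                    est = f"failed: {exc}"
                estimates[(level, method, backend_name)] = est
                logger.info("%s=%s %s+%s -> %s", axis, level, method,
                            backend_name, est)
    return SweepResult(
        axis=axis,
        levels=list(levels),
        estimates=estimates,
        config={"q_true": q_true, "seed": seed, "p": p, "n": n, "rep": rep},
    )
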