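"""Uniform (over)determined ICA fitting across interchangeable backends.

All backends share the same preprocessing: the input is centered and
whitened onto its leading ``q`` principal directions, so a backend only has
to find a ``q x q`` rotation of the whitened rows.  This makes the
reconstruction from ``q`` components the rank-``q`` principal-subspace
reconstruction, hence the residual norm is non-increasing in ``q``.

Backends: FastICA (scikit-learn), extended Infomax (mne), and JADE
(implemented here — joint approximate diagonalization of fourth-order
cumulant matrices by Jacobi rotations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .simulate import SignalMatrix

__all__ = ["BackendSpec", "ICAResult", "ICAFitError", "fit_ica", "reconstruct"]

_BACKENDS = ("fastica", "infomax", "jade")

# Relative floor for singular values during whitening: directions below it
# carry only numerical noise but are retained so that requesting q above the
# true rank yields pure-noise components rather than an error.
_SV_FLOOR = 1e-12


class ICAFitError(RuntimeError):
    """A backend raised or produced non-finite output on every retry."""


@dataclass(frozen=True)
class BackendSpec:
    """Configuration of an ICA backend."""

    name: str = "fastica"
    max_iter: int = 500
    tol: float = 1e-4
    retries: int = 3

    def __post_init__(self) -> None:
        if self.name not in _BACKENDS:
            raise ValueError(f"backend must be one of {_BACKENDS}, got {self.name!r}")
        if self.retries < 1:
            raise ValueError("retries must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class ICAResult:
    """A fitted ICA model.

    ``components`` holds the estimated sources (unit-variance rows; sign and
    order are arbitrary), ``mixing_estimate`` the least-squares mixing matrix
    mapping components back to the centered data, ``unmixing`` the linear map
    from centered channels to components.
    """

    components: np.ndarray
    mixing_estimate: np.ndarray
    unmixing: np.ndarray
    mean: np.ndarray
    method: str
    requested_q: int
    converged: bool
    seed: int


def _whiten(X: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and project onto q principal directions with unit variance.

    Returns (Z, W_white, mean): Z is q x n with uncorrelated unit-variance
    rows, W_white the q x p map such that Z = W_white (X - mean).
    """
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    n = X.shape[1]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # Rows of Vt have unit norm even in directions where s underflows, so
    # rank-deficient inputs yield unit-variance numerical-noise rows instead
    # of wildly mis-scaled ones.
    Z = np.sqrt(n) * Vt[:q]
    s = np.maximum(s, _SV_FLOOR * max(s[0], 1.0))
    W_white = np.sqrt(n) * (U[:, :q] / s[:q]).T
    return Z, W_white, mean


def _rotation_fastica(Z, q, spec, seed):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ica = FastICA(
            whiten=False,
            max_iter=spec.max_iter,
            tol=spec.tol,
            random_state=np.random.RandomState(seed % 2**31),
        )
        ica.fit(Z.T)
    return ica.components_, ica.n_iter_ < spec.max_iter


def _rotation_infomax(Z, q, spec, seed):
    from mne.preprocessing import infomax

    W, n_iter = infomax(
        Z.T,
        max_iter=spec.max_iter,
        extended=True,
        rng=np.random.default_rng(seed % 2**31),
        return_n_iter=True,
        verbose="error",
    )
    return W, n_iter < spec.max_iter


def _rotation_jade(Z, q, spec, seed):
    return _jade_rotation(Z, max_sweeps=spec.max_iter, tol=spec.tol)


def _jade_rotation(Z: np.ndarray, max_sweeps: int = 500, tol: float = 1e-4):
    """JADE on whitened data: jointly diagonalize cumulant matrices.

    Builds the parallel set of fourth-order cumulant matrices of the
    whitened rows and diagonalizes them simultaneously with Givens
    rotations, returning the orthogonal unmixing rotation.
    """
    q, n = Z.shape
    # Cumulant matrices Q_kl = E[zk zl z z^T] - delta_kl I - e_k e_l^T - e_l e_k^T
    eye = np.eye(q)
    mats = []
    for k in range(q):
        for l in range(k + 1):
            Qkl = (Z * Z[k] * Z[l]) @ Z.T / n
            Qkl -= eye * (1.0 if k == l else 0.0)
            Qkl -= np.outer(eye[k], eye[l]) + np.outer(eye[l], eye[k])
            if k != l:
                # only k >= l pairs are kept; weight for the omitted twin
                Qkl *= np.sqrt(2.0)
            mats.append(Qkl)
    M = np.concatenate(mats, axis=1)  # q x (q * nmat)
    V = np.eye(q)
    nmat = len(mats)
    threshold = tol / np.sqrt(n)
    converged = False
    for _ in range(max_sweeps):
        rotated = False
        for i in range(q - 1):
            for j in range(i + 1, q):
                ii = np.arange(i, nmat * q, q)
                jj = np.arange(j, nmat * q, q)
                g1 = M[i, ii] - M[j, jj]
                g2 = M[i, jj] + M[j, ii]
                gg11 = g1 @ g1
                gg22 = g2 @ g2
                gg12 = g1 @ g2
                ton = gg11 - gg22
                toff = 2.0 * gg12
                theta = 0.5 * np.arctan2(toff, ton + np.sqrt(ton * ton + toff * toff))
                if abs(np.sin(theta)) > threshold:
                    rotated = True
                    c, s = np.cos(theta), np.sin(theta)
                    G = np.array([[c, -s], [s, c]])
                    pair = np.array([i, j])
                    M[pair, :] = G.T @ M[pair, :]
                    # rotate the (i,j) columns of every cumulant matrix
                    M[:, np.concatenate([ii, jj])] = np.column_stack(
                        [
                            c * M[:, ii] + s * M[:, jj],
                            -s * M[:, ii] + c * M[:, jj],
                        ]
                    )
                    V[pair, :] = G.T @ V[pair, :]
        if not rotated:
            converged = True
            break
    return V, converged


_ROTATIONS = {
    "fastica": _rotation_fastica,
    "infomax": _rotation_infomax,
    "jade": _rotation_jade,
}


def fit_ica(
    X: SignalMatrix,
    q: int,
    backend: BackendSpec | None = None,
    seed: int = 0,
) -> ICAResult:
    """Fit an ICA decomposition with ``q`` components.

    The data are centered, whitened to ``q`` dimensions, and the backend
    estimates the unmixing rotation.  On non-convergence the fit is retried
    up to ``backend.retries`` times with derived sub-seeds (``seed + 1000 *
    attempt``); if no attempt converges the last finite iterate is returned
    with ``converged=False``.  Component order and sign are
    backend-arbitrary; callers must not rely on either.

    Raises
    ------
    ValueError
        If ``q < 2``, ``q > p``, or ``n <= q``.
    ICAFitError
        If every retry raised or produced non-finite output.
    """
    spec = backend or BackendSpec()
    data = X.data
    p, n = data.shape
    if q < 2:
        raise ValueError(f"q must be >= 2, got {q}")
    if q > p:
        raise ValueError(
            f"q={q} > p={p}: the underdetermined regime is not supported"
        )
    if n <= q:
        raise ValueError(f"need n > q, got n={n}, q={q}")

    Z, W_white, mean = _whiten(data, q)
    rotate = _ROTATIONS[spec.name]
    last: tuple[np.ndarray, bool] | None = None
    last_seed = seed
    for attempt in range(spec.retries):
        sub_seed = seed + 1000 * attempt
        try:
            R, converged = rotate(Z, q, spec, sub_seed)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if not np.all(np.isfinite(R)):
            continue
        last, last_seed = (R, converged), sub_seed
        if converged:
            break
        if spec.name == "jade":
            # JADE is deterministic: retrying cannot help.
            break
    if last is None:
        raise ICAFitError(
            f"{spec.name} failed on all {spec.retries} attempts (q={q})"
        )
    R, converged = last
    S_hat = R @ Z
    sd = S_hat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    S_hat = S_hat / sd
    unmixing = (R / sd) @ W_white
    Xc = data - mean
    # Least-squares mixing estimate: Xc ≈ A_hat @ S_hat
    A_hat = np.linalg.lstsq(S_hat.T, Xc.T, rcond=None)[0].T
    return ICAResult(
        components=S_hat,
        mixing_estimate=A_hat,
        unmixing=unmixing,
        mean=mean,
        method=spec.name,
        requested_q=q,
        converged=converged,
        seed=last_seed,
    )


def reconstruct(result: ICAResult, original: SignalMatrix) -> SignalMatrix:
    """Rebuild the rank-``q`` approximation ``X_hat = mean + A_hat S_hat``."""
    p, n = original.data.shape
    if result.mixing_estimate.shape[0] != p or result.components.shape[1] != n:
        raise ValueError(
            f"fitted model ({result.mixing_estimate.shape[0]} channels, "
            f"{result.components.shape[1]} samples) does not match input "
            f"({p} x {n})"
        )
    X_hat = result.mean + result.mixing_estimate @ result.components
    return SignalMatrix(data=X_hat, channel_labels=original.channel_labels)
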