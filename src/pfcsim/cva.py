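"""Canonical variates analysis of synthetic neural data.

Demonstrates predictive validity: the three simulated population
time-courses (rule, target, choice beliefs across a trial) form a design
matrix; synthetic "recordings" are random linear mixtures of those columns
plus Gaussian noise at a fixed signal-to-noise ratio.  CVA recovers the
mapping: paired linear combinations of design and data with maximal
correlation, with successive canonical correlations tested by Bartlett's
chi-square approximation to Wilks' lambda (a permutation test is available
as an assumption-free alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .engine import frame_posterior
from .environment import TrialRecord
from .model import GenerativeModel

__all__ = [
    "DesignMatrix",
    "SyntheticNeuralData",
    "CVAResult",
    "build_design",
    "synthesize_data",
    "cva",
]


@dataclass
class DesignMatrix:
    """Population regressors: rows are within-trial bins, columns factors."""

    X: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValueError("DesignMatrix: X must be 2-D")
        if np.any(np.all(X == 0, axis=0)):
            raise ValueError("DesignMatrix: constant-zero column")
        if X.shape[0] <= X.shape[1]:
            raise ValueError("DesignMatrix: needs more rows than columns")
        self.X = X

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns)


@dataclass
class SyntheticNeuralData:
    """Random linear mixture of the design columns plus Gaussian noise."""

    Y: np.ndarray
    mixing: np.ndarray
    noise_scale: float
    snr: float
    seed: int | None = None


@dataclass
class CVAResult:
    """Canonical correlations (descending), vectors, and per-variate tests."""

    correlations: np.ndarray
    x_vectors: np.ndarray  # (p, s) canonical vectors for the design side
    y_vectors: np.ndarray  # (q, s) canonical vectors for the data side
    p_values: np.ndarray
    n_significant: int
    alpha: float


def build_design(
    model: GenerativeModel, record: TrialRecord, aggregation: str = "iteration"
) -> DesignMatrix:
    """Design matrix of rule/target/choice population firing for one trial.

    Each factor contributes one column: the policy-averaged belief in the
    level the agent eventually infers (argmax of the final-bin belief),
    averaged across the represented time steps.  ``aggregation`` is
    ``"iteration"`` (one row per update sweep, T * n_iter rows) or
    ``"epoch"`` (epoch means, T rows).
    """
    if record.beliefs is None or not record.beliefs.trace:
        raise ValueError("build_design: trial record carries no iteration trace")
    if aggregation not in ("iteration", "epoch"):
        raise ValueError(f"build_design: unknown aggregation {aggregation!r}")
    frames = record.beliefs.trace
    weights = [frame_posterior(fr) for fr in frames]
    cols = []
    labels = []
    for n, f in enumerate(model.factors):
        # policy- and tau-averaged beliefs, all bins: (bins, levels)
        bma = np.stack(
            [w @ fr.s[n].mean(axis=1) for w, fr in zip(weights, frames)]
        )
        # the eventually-inferred level: final-bin belief about the last
        # represented step (for the choice factor this is the picked option)
        final = weights[-1] @ frames[-1].s[n][:, -1, :]
        inferred = int(np.argmax(final))
        cols.append(bma[:, inferred])
        labels.append(f"{f.name}:{f.levels[inferred]}")
    X = np.stack(cols, axis=1)
    if aggregation == "epoch":
        epochs = np.array([fr.epoch for fr in frames])
        X = np.stack([X[epochs == e].mean(axis=0) for e in np.unique(epochs)])
    return DesignMatrix(X=X, columns=labels)


def synthesize_data(
    design: DesignMatrix,
    k_neurons: int = 10,
    snr: float = 8.0,
    rng: np.random.Generator | None = None,
) -> SyntheticNeuralData:
    """Mix the design columns into ``k_neurons`` noisy synthetic recordings.

    ``Y = X M + E`` with ``M`` standard normal and the noise standard
    deviation set to ``rms(X M - mean) / snr``: the signal-to-noise ratio is
    the rms of the signal *fluctuation* over the rms of the noise.  The
    column means are excluded from the signal because the analysis centers
    both matrices, so only fluctuations carry information.
    """
    if not snr > 0:
        raise ValueError("synthesize_data: snr must be positive")
    p = design.X.shape[1]
    if k_neurons < p:
        raise ValueError("synthesize_data: k_neurons must be >= design columns")
    rng = rng or np.random.default_rng(0)
    M = rng.standard_normal((p, k_neurons))
    S = design.X @ M
    noise_scale = float(np.sqrt(np.mean((S - S.mean(axis=0)) ** 2))) / snr
    Y = S + noise_scale * rng.standard_normal(S.shape)
    return SyntheticNeuralData(Y=Y, mixing=M, noise_scale=noise_scale, snr=snr)


def canonical_correlations(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical correlations/vectors of two centered matrices via SVD.

    Whitens each side with its singular decomposition and takes the SVD of
    the whitened cross-covariance.  Raises on rank deficiency, naming the
    deficient side.
    """
    n, p = X.shape
    q = Y.shape[1]
    Ux, Sx, Vxt = np.linalg.svd(X, full_matrices=False)
    Uy, Sy, Vyt = np.linalg.svd(Y, full_matrices=False)
    for name, S, d in (("design", Sx, p), ("data", Sy, q)):
        if np.sum(S > S[0] * 1e-10) < d:
            raise np.linalg.LinAlgError(f"cva: rank-deficient {name} matrix")
    U, r, Vt = np.linalg.svd(Ux.T @ Uy)
    s = min(p, q)
    r = np.clip(r[:s], 0.0, 1.0)
    a = Vxt.T @ (U[:, :s] / Sx[:, None])     # design-side canonical vectors
    b = Vyt.T @ (Vt[:s].T / Sy[:, None])     # data-side canonical vectors
    return r, a, b


def cva(
    design: DesignMatrix | np.ndarray,
    data: SyntheticNeuralData | np.ndarray,
    alpha: float = 0.05,
    method: str = "bartlett",
    n_permutations: int = 500,
    rng: np.random.Generator | None = None,
) -> CVAResult:
    """Canonical variates analysis with successive significance tests.

    Tests the null that at most ``k`` canonical correlations are non-zero
    for k = 0, 1, ...: Bartlett's chi-square approximation to Wilks' lambda
    by default, or a row-permutation test (``method="permutation"``).  The
    significant-variate count is the longest run of successive rejections
    starting from the first variate.
    """
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, float)
    Y = data.Y if isinstance(data, SyntheticNeuralData) else np.asarray(data, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("cva: row mismatch between design and data")
    n, p = X.shape
    q = Y.shape[1]
    if n <= max(p, q):
        raise ValueError("cva: needs more rows than columns on both sides")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    r, a, b = canonical_correlations(Xc, Yc)
    s = len(r)

    if method == "bartlett":
        p_values = _bartlett_pvalues(r, n, p, q)
    elif method == "permutation":
        rng = rng or np.random.default_rng(0)
        p_values = _permutation_pvalues(Xc, Yc, r, n_permutations, rng)
    else:
        raise ValueError(f"cva: unknown method {method!r}")

    n_sig = 0
    for k in range(s):
        if p_values[k] < alpha:
            n_sig += 1
        else:
            break
    return CVAResult(
        correlations=r,
        x_vectors=a,
        y_vectors=b,
        p_values=p_values,
        n_significant=n_sig,
        alpha=alpha,
    )


def _bartlett_pvalues(r: np.ndarray, n: int, p: int, q: int) -> np.ndarray:
    """Bartlett's chi-square tests of successive canonical correlations."""
    s = len(r)
    lam = np.clip(1.0 - r**2, 1e-300, None)
    scale = n - 1 - (p + q + 1) / 2.0
    pvals = np.empty(s)
    for k in range(s):
        chi2 = -scale * np.sum(np.log(lam[k:]))
        df = (p - k) * (q - k)
        pvals[k] = stats.chi2.sf(chi2, df)
    return pvals


def _permutation_pvalues(
    Xc: np.ndarray, Yc: np.ndarray, r_obs: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Row-shuffle null for the successive Wilks statistics."""
    s = len(r_obs)
    obs = np.array([-np.sum(np.log(np.clip(1 - r_obs[k:] ** 2, 1e-300, None))) for k in range(s)])
    exceed = np.zeros(s)
    n = Xc.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        try:
            r_p, _, _ = canonical_correlations(Xc, Yc[perm])
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate shuffle
            continue
        stat = np.array(
            [-np.sum(np.log(np.clip(1 - r_p[k:] ** 2, 1e-300, None))) for k in range(s)]
        )
        exceed += stat >= obs
    return (exceed + 1.0) / (n_perm + 1.0)
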