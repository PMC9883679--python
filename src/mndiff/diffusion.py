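"""Network diffusion of a gene-by-layer score matrix.

Scores are smoothed by random walk with restart over the symmetrically
normalized adjacency W:

    X_{q+1} = alpha * W @ X_q + (1 - alpha) * X_0,     X^ss = lim X_q

with restart weight ``1 - alpha``. Because the spectral radius of W is at
most 1 and alpha < 1, the map is a contraction and the iteration converges
to the unique fixed point

    X^ss = (1 - alpha) * (I - alpha * W)^{-1} @ X_0 .

The steady state is column-normalized by each column's maximum to give X*,
which makes heterogeneous layers (mutation frequencies, -log10 FDR values,
per-patient profiles) directly comparable: the diffusion is linear in each
column, so X* is invariant to rescaling any input layer by a positive
constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreMatrix",
    "DiffusionResult",
    "diffuse",
    "diffuse_closed_form",
    "diffusion_kernel",
    "column_normalize",
    "load_scores",
    "write_scores",
]

#: guard for the dense closed-form solve
_CLOSED_FORM_MAX_N = 5000


@dataclass
class ScoreMatrix:
    """A nonnegative gene-by-layer evidence matrix.

    Each column ("layer") is one score vector over the genes: an omics type
    such as per-gene mutation frequency or -log10 FDR of differential
    expression, or one sample's profile.
    """

    genes: list[str]
    layers: list[str]
    X: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape != (len(self.genes), len(self.layers)):
            raise ValueError("X must be (n_genes, n_layers)")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        if len(set(self.layers)) != len(self.layers):
            raise ValueError("layer names must be unique")
        if np.any(self.X < 0) or not np.all(np.isfinite(self.X)):
            raise ValueError("scores must be finite and nonnegative")
        for l, name in enumerate(self.layers):
            if not np.any(self.X[:, l] > 0):
                logger.warning("layer %r has no positive score (degenerate layer)", name)
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=pd.Index(self.genes, name="gene"),
                            columns=self.layers)


@dataclass
class DiffusionResult:
    """Steady-state matrix and its column-max-normalized form.

    ``Xss`` is the converged steady state; ``Xstar`` divides each column by
    its maximum so every layer lives on [0, 1] (all-zero columns stay zero).
    """

    genes: list[str]
    layers: list[str]
    Xss: np.ndarray
    Xstar: np.ndarray
    iterations: int
    residual: float


def column_normalize(Xss: np.ndarray) -> np.ndarray:
    """Divide each column by its maximum; all-zero columns pass unchanged."""
    Xss = np.asarray(Xss, dtype=float)
    if np.any(Xss < 0):
        raise ValueError("column_normalize expects a nonnegative matrix")
    maxima = Xss.max(axis=0)
    zero = maxima == 0
    if np.any(zero):
        logger.warning("%d all-zero column(s) left unnormalized", int(zero.sum()))
    safe = np.where(zero, 1.0, maxima)
    return Xss / safe


def _check_inputs(scores: ScoreMatrix, W: sp.spmatrix, alpha: float) -> None:
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if W.shape[0] != W.shape[1] or W.shape[0] != scores.n_genes:
        raise ValueError("score matrix is not aligned to W")


def diffuse(
    scores: ScoreMatrix,
    W: sp.spmatrix,
    alpha: float = 0.7,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> DiffusionResult:
    """Iterative diffusion; stops when max |X_{q+1} - X_q| < ``tol``.

    The termination criterion is checked on the un-normalized iterate;
    normalization to X* happens once, after convergence.
    """
    _check_inputs(scores, W, alpha)
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    X0 = scores.X
    restart = (1.0 - alpha) * X0
    X = X0.copy()
    residual = np.inf
    for it in range(1, max_iter + 1):
        X_next = alpha * (W @ X) + restart
        residual = float(np.max(np.abs(X_next - X))) if X.size else 0.0
        X = X_next
        if residual < tol:
            return DiffusionResult(list(scores.genes), list(scores.layers),
                                   X, column_normalize(X), it, residual)
    raise RuntimeError(
        f"diffusion did not converge in {max_iter} iterations (residual {residual:.3e})"
    )


def diffusion_kernel(W: sp.spmatrix, alpha: float) -> np.ndarray:
    """Dense closed-form kernel K = (1-alpha) (I - alpha W)^{-1}.

    X^ss = K @ X0. Entrywise nonnegative; guarded to N <= 5000 for memory.
    """
    n = W.shape[0]
    if n > _CLOSED_FORM_MAX_N:
        raise ValueError(f"closed-form solve guarded to N <= {_CLOSED_FORM_MAX_N}, got {n}")
    A = np.eye(n) - alpha * np.asarray(W.todense())
    # alpha < 1 and rho(W) <= 1 make A strictly diagonally dominant in the
    # spectral sense; a singular A indicates a broken W.
    if n and abs(np.linalg.det(A)) == 0.0:
        raise np.linalg.LinAlgError("I - alpha W is singular")
    return (1.0 - alpha) * np.linalg.inv(A)


def diffuse_closed_form(
    scores: ScoreMatrix,
    W: sp.spmatrix,
    alpha: float = 0.7,
) -> DiffusionResult:
    """Analytic steady state X^ss = (1-alpha)(I - alpha W)^{-1} X0."""
    _check_inputs(scores, W, alpha)
    n = scores.n_genes
    A = np.eye(n) - alpha * np.asarray(W.todense())
    Xss = (1.0 - alpha) * np.linalg.solve(A, scores.X)
    return DiffusionResult(list(scores.genes), list(scores.layers),
                           Xss, column_normalize(Xss), 0, 0.0)


def load_scores(path: str | Path) -> ScoreMatrix:
    """Read a score matrix TSV: first column ``gene``, one column per layer."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a gene column plus at least one layer column")
    genes = df.iloc[:, 0].astype(str).tolist()
    layers = [str(c) for c in df.columns[1:]]
    return ScoreMatrix(genes, layers, df.iloc[:, 1:].to_numpy(dtype=float))


def write_scores(scores: ScoreMatrix, path: str | Path,
                 header_comments: list[str] | None = None) -> None:
    """Write the TSV dialect read by :func:`load_scores`, full precision."""
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        fh.write("gene\t" + "\t".join(scores.layers) + "\n")
        for i, g in enumerate(scores.genes):
            vals = "\t".join(f"{v:.17g}" for v in scores.X[i])
            fh.write(f"{g}\t{vals}\n")
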