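"""Factor-analytic extension of temporal PCA: scaling and rotation.

Scaling eigenvectors by the square root of their eigenvalues turns them into
*loadings* that (on correlation-based input) are the correlations of each
timepoint with the component.  Rotations then transform the loadings toward
simple structure: varimax keeps components orthogonal, promax (Hendrickson &
White's procedure — varimax, then an oblique least-squares fit to the
loadings raised to a power ``kappa``) lets them correlate, with the
inter-component correlations collected in ``Phi``.  Oblique solutions
distinguish the *pattern* matrix (regression-style weights) from the
*structure* matrix (timepoint-component correlations, ``pattern @ Phi``).

The rotated pipeline standardises columns (correlation-matrix PCA) before
scaling and rotation, the factor-analytic convention; the plain
:class:`~pupilpca.reduction.TemporalPCA` stays covariance-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import DegenerateDataError, SchemaError, TrialMatrix
from .reduction import TemporalPCAResults, fix_signs, select_ncomp

logger = logging.getLogger("pupilpca")

__all__ = [
    "scale_loadings", "varimax", "promax", "congruence", "match_components",
    "rotated_scores", "RotatedPCA", "RotatedPCAResults",
]


def rotated_scores(tm: TrialMatrix, results: "RotatedPCAResults",
                   add: list[str] | None = None) -> pd.DataFrame:
    """Tidy rotated score table for a (possibly new) TrialMatrix on the
    fitted grid: subject, trial, requested conditions, score_1..score_k."""
    add = list(add or [])
    unknown = [c for c in add if c not in tm.row_meta.columns]
    if unknown:
        raise SchemaError(f"unknown condition column(s): {unknown}")
    scores = results.transform(tm.values)
    out = tm.row_meta[["subject", "trial", *add]].copy()
    for j in range(results.k):
        out[f"score_{j + 1}"] = scores[:, j]
    return out


def scale_loadings(results: TemporalPCAResults) -> np.ndarray:
    """Scale the retained eigenvectors by the square roots of their eigenvalues.

    Column j of the output is ``eigenvector_j * sqrt(eigenvalue_j)``; on
    correlation-based input its entries are the correlations between each
    timepoint and component j, bounded by [-1, 1].
    """
    eig = np.clip(results.eigenvalues[:results.k], 0.0, None)
    return results.loadings * np.sqrt(eig)


class VarimaxResult(NamedTuple):
    loadings: np.ndarray
    rotmat: np.ndarray
    n_iter: int


def varimax(loadings: np.ndarray, kaiser_normalize: bool = True,
            tol: float = 1e-10, max_iter: int = 1000) -> VarimaxResult:
    """Orthogonal varimax rotation (Kaiser criterion, SVD iterations).

    Maximises the sum over components of the variance of squared loadings,
    with Kaiser row-normalisation by default (rows scaled to unit
    communality during the optimisation and restored afterwards).  Stops
    when the relative criterion gain drops below `tol` or after `max_iter`
    iterations.  A single-component input is returned unchanged with the
    identity rotation.
    """
    L = np.array(loadings, dtype=float, copy=True)
    p, k = L.shape
    if k < 2:
        return VarimaxResult(L, np.eye(k), 0)
    if p < k:
        raise ValueError(f"need at least as many rows as components ({p} < {k})")
    comm = np.sqrt((L**2).sum(axis=1))
    if kaiser_normalize:
        safe = np.where(comm > 0, comm, 1.0)
        L = L / safe[:, None]
    R = np.eye(k)
    d = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        Z = L @ R
        B = L.T @ (Z**3 - Z @ np.diag((Z**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(B)
        R = u @ vt
        d_old, d = d, s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
    Z = L @ R
    if kaiser_normalize:
        Z = Z * np.where(comm > 0, comm, 1.0)[:, None]
    return VarimaxResult(Z, R, it)


class PromaxResult(NamedTuple):
    pattern: np.ndarray
    phi: np.ndarray
    rotmat: np.ndarray          # total transformation: loadings @ rotmat = pattern
    varimax_loadings: np.ndarray


def promax(loadings: np.ndarray, kappa: float = 4,
           kaiser_normalize: bool = True) -> PromaxResult:
    """Oblique promax rotation.

    Varimax-rotates first, builds the sign-preserving power target
    ``sign(l) * |l|**kappa`` and obliquely transforms the varimax solution
    toward it by column-normalised least squares; the inter-component
    correlation matrix ``Phi`` derives from the transformation.  `kappa`
    (the promax power) defaults to 4, the method's conventional value.
    Raises on a singular intermediate system (callers may fall back to
    varimax).
    """
    if kappa < 1:
        raise ValueError(f"kappa must be >= 1, got {kappa}")
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return PromaxResult(L.copy(), np.eye(k), np.eye(k), L.copy())
    vm = varimax(L, kaiser_normalize=kaiser_normalize)
    X = vm.loadings
    Q = X * np.abs(X) ** (kappa - 1)          # sign-preserving |l|^kappa
    U, *_ = np.linalg.lstsq(X, Q, rcond=None)
    M = U.T @ U
    Minv = np.linalg.inv(M)                    # may raise LinAlgError
    U = U @ np.diag(np.sqrt(np.diag(Minv)))    # unit-diagonal normalisation
    pattern = X @ U
    Ui = np.linalg.inv(U)
    phi = Ui @ Ui.T                            # = (U'U)^-1, unit diagonal
    phi = (phi + phi.T) / 2
    return PromaxResult(pattern, phi, vm.rotmat @ U, X)


def congruence(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Tucker congruence coefficients between every column pair of A and B.

    ``phi(a, b) = sum(a*b) / sqrt(sum(a^2) * sum(b^2))`` — the cosine of the
    angle between two loading curves; values >= ~0.95 are conventionally
    read as factor equivalence.  A zero column yields NaN entries.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("loading matrices must share the row (time) grid")
    na = np.sqrt((A**2).sum(axis=0))
    nb = np.sqrt((B**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (A.T @ B) / np.outer(na, nb)
    C[~np.isfinite(C)] = np.nan
    return C


def match_components(A: np.ndarray, B: np.ndarray):
    """Greedily pair columns of A with columns of B by maximal |congruence|.

    Returns ``(pairs, phis)``: for each column of A (in order) the matched
    column index of B and the *signed* Tucker coefficient.  Ties break by
    column order.
    """
    C = congruence(A, B)
    absC = np.where(np.isnan(C), -np.inf, np.abs(C))
    pairs = np.full(C.shape[0], -1, dtype=int)
    phis = np.full(C.shape[0], np.nan)
    free = list(range(C.shape[1]))
    # greedy: repeatedly take the globally largest remaining |phi|
    work = absC.copy()
    for _ in range(min(C.shape)):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        if not np.isfinite(work[i, j]):
            break
        pairs[i] = j
        phis[i] = C[i, j]
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return pairs, phis


# ---------------------------------------------------------------------------
# model / results pair
# ---------------------------------------------------------------------------

class RotatedPCA:
    """Rotated (factor-analytic) temporal PCA of a :class:`TrialMatrix`.

    Standardises columns, eigen-decomposes the timepoint correlation matrix,
    scales the leading ``ncomp`` eigenvectors into loadings and rotates them
    (``rotation`` in ``{"promax", "varimax", "none"}``).  Per-trial component
    scores are estimated by the regression method
    (``weights = R^-1 @ structure`` applied to the standardised columns);
    Bartlett scores are available via ``score_method="bartlett"``.
    """

    def __init__(self, data: TrialMatrix, ncomp: float = 3, rotation: str = "promax",
                 kappa: float = 4, kaiser_normalize: bool = True,
                 score_method: str = "regression"):
        if rotation not in ("promax", "varimax", "none"):
            raise ValueError(f"unknown rotation {rotation!r}")
        if score_method not in ("regression", "bartlett"):
            raise ValueError(f"unknown score_method {score_method!r}")
        self.data = data
        self.ncomp = ncomp
        self.rotation = rotation
        self.kappa = kappa
        self.kaiser_normalize = kaiser_normalize
        self.score_method = score_method

    def fit(self) -> "RotatedPCAResults":
        X = self.data.values
        n, p = X.shape
        center = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DegenerateDataError("zero-variance column; epoch after target onset")
        Z = (X - center) / sd
        Rmat = (Z.T @ Z) / (n - 1)
        eigval, eigvec = np.linalg.eigh(Rmat)
        order = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[order], 0.0, None)
        eigvec = eigvec[:, order]
        var_prop = eigval / p
        k = select_ncomp(var_prop, self.ncomp)
        A = eigvec[:, :k] * np.sqrt(eigval[:k])   # scaled loadings (correlations)

        label = self.rotation
        if k < 2 or self.rotation == "none":
            pattern, phi = A.copy(), np.eye(k)
            if self.rotation != "none":
                label = "none"
        elif self.rotation == "varimax":
            pattern = varimax(A, kaiser_normalize=self.kaiser_normalize).loadings
            phi = np.eye(k)
        else:
            try:
                pr = promax(A, kappa=self.kappa, kaiser_normalize=self.kaiser_normalize)
                pattern, phi = pr.pattern, pr.phi
            except np.linalg.LinAlgError:
                warnings.warn("promax transformation singular; falling back to varimax",
                              stacklevel=2)
                pattern = varimax(A, kaiser_normalize=self.kaiser_normalize).loadings
                phi = np.eye(k)
                label = "varimax"

        # order by descending rotated variance share, then fix signs
        ss = np.diag(phi @ pattern.T @ pattern)
        order_k = np.argsort(ss)[::-1]
        pattern = pattern[:, order_k]
        phi = phi[np.ix_(order_k, order_k)]
        pattern, flip = fix_signs(pattern)
        phi = phi * np.outer(flip, flip)
        structure = pattern @ phi
        rot_var_prop = np.diag(phi @ pattern.T @ pattern) / p

        W = self._score_weights(Rmat, eigval, eigvec, pattern, structure)
        scores = Z @ W
        return RotatedPCAResults(
            model=self, center=center, scale=sd, eigenvalues=eigval,
            var_prop=var_prop, k=k, pattern=pattern, structure=structure,
            phi=phi, rot_var_prop=rot_var_prop, scores=scores, rotation=label,
            kappa=self.kappa, score_weights=W,
        )

    def _score_weights(self, Rmat, eigval, eigvec, pattern, structure,
                       floor: float = 1e-8) -> np.ndarray:
        # invert R through its eigen-decomposition; floor tiny eigenvalues
        # (ridge-like stabilisation) when the correlation matrix is
        # near-singular, e.g. fewer trials than timepoints
        small = eigval < floor
        if small.any():
            logger.warning("correlation matrix near-singular: %d eigenvalue(s) "
                           "floored at %g for score estimation", small.sum(), floor)
        inv_eig = 1.0 / np.maximum(eigval, floor)
        Rinv_mul = lambda M: eigvec @ (inv_eig[:, None] * (eigvec.T @ M))
        if self.score_method == "regression":
            return Rinv_mul(structure)
        # bartlett
        RiP = Rinv_mul(pattern)
        return RiP @ np.linalg.inv(pattern.T @ RiP)


@dataclass
class RotatedPCAResults:
    """Rotated-PCA fit: pattern/structure matrices, Phi, and rotated scores.

    ``pattern`` holds the rotated loading curves (timepoints x k), ``phi``
    the inter-component correlations (identity for orthogonal rotations),
    ``structure = pattern @ phi`` the timepoint-component correlations, and
    ``scores`` the per-trial component scores — the coordinates of each
    trial on the pupillary manifold.
    """

    model: RotatedPCA
    center: np.ndarray
    scale: np.ndarray
    eigenvalues: np.ndarray
    var_prop: np.ndarray
    k: int
    pattern: np.ndarray
    structure: np.ndarray
    phi: np.ndarray
    rot_var_prop: np.ndarray
    scores: np.ndarray
    rotation: str
    kappa: float
    score_weights: np.ndarray | None = None

    @property
    def col_times(self) -> np.ndarray:
        return self.model.data.col_times

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Score new trials (same time grid) with the fitted weight matrix."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] != len(self.center):
            raise ValueError("new data do not match the fitted time grid")
        return ((values - self.center) / self.scale) @ self.score_weights

    @property
    def row_meta(self) -> pd.DataFrame:
        return self.model.data.row_meta

    def scores_table(self, add: list[str] | None = None) -> pd.DataFrame:
        add = list(add or [])
        unknown = [c for c in add if c not in self.row_meta.columns]
        if unknown:
            raise SchemaError(f"unknown condition column(s): {unknown}")
        out = self.row_meta[["subject", "trial", *add]].copy()
        for j in range(self.k):
            out[f"score_{j + 1}"] = self.scores[:, j]
        return out

    def fingerprints(self) -> pd.DataFrame:
        """Tidy (time, component, loading) table of the rotated loading curves."""
        k = self.k
        return pd.DataFrame({
            "time": np.tile(self.col_times, k),
            "component": np.repeat(np.arange(1, k + 1), len(self.col_times)),
            "loading": self.pattern.T.ravel(),
        })

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(1, self.k + 1),
            "ss_loadings": self.rot_var_prop * len(self.center),
            "var_prop": self.rot_var_prop,
            "cumulative": np.cumsum(self.rot_var_prop),
        })

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<RotatedPCAResults rotation={self.rotation!r} k={self.k}, "
                f"n={self.scores.shape[0]} trials, "
                f"cumvar={np.cumsum(self.rot_var_prop)[-1]:.3f}>")

    def plot_fingerprints(self, ax=None):
        """Plot the rotated loading curves — the component "fingerprints"
        (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for j in range(self.k):
            ax.plot(self.col_times, self.pattern[:, j],
                    label=f"RC{j + 1} ({100 * self.rot_var_prop[j]:.1f}%)")
        ax.axhline(0.0, color="0.6", lw=0.5)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("pattern loading")
        ax.legend()
        return ax

    def save(self, outdir, sep: str = ",") -> None:
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cols = [f"component_{j + 1}" for j in range(self.k)]
        for name, mat in (("pattern", self.pattern), ("structure", self.structure)):
            df = pd.DataFrame(mat, columns=cols)
            df.insert(0, "time", self.col_times)
            df.to_csv(outdir / f"{name}.csv", sep=sep, index=False)
        pd.DataFrame(self.phi, columns=cols).to_csv(outdir / "phi.csv", sep=sep, index=False)
        self.fingerprints().to_csv(outdir / "fingerprints.csv", sep=sep, index=False)
        self.scores_table(add=[c for c in self.row_meta.columns
                               if c not in ("subject", "trial")]
                          ).to_csv(outdir / "scores.csv", sep=sep, index=False)
        self.summary().to_csv(outdir / "variance.csv", sep=sep, index=False)
        meta = {
            "kind": "rotated_pca",
            "k": int(self.k),
            "rotation": self.rotation,
            "kappa": self.kappa,
            "kaiser_normalize": self.model.kaiser_normalize,
            "score_method": self.model.score_method,
            "col_times": self.col_times.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
        }
        (outdir / "reduction_meta.json").write_text(json.dumps(meta, indent=1))
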