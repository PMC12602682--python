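"""Temporal PCA on the trial x timepoint matrix.

Each timepoint is a variable and each trial an observation, so the principal
components are *temporal shapes*: the loading curve of a component gives the
per-timepoint weights, and a trial's score is the weighted average of its
samples by that curve — the strength of that temporal shape in the trial.

The model object is :class:`TemporalPCA`; :meth:`TemporalPCA.fit` returns a
:class:`TemporalPCAResults` carrying eigenvalues, unit-norm loadings,
variance proportions (with the *total* variance in the denominator, so
truncation does not inflate them), per-trial scores and the row metadata.
Columns are centred but, by default, not rescaled: the data reaching this
stage are already z-scored per subject, and the raw covariance preserves the
amplitude information the scores summarise.  ``standardize=True`` switches to
correlation-based PCA (the convention the rotated pipeline uses).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DegenerateDataError, SchemaError, TrialMatrix

logger = logging.getLogger("pupilpca")

__all__ = ["TemporalPCA", "TemporalPCAResults", "select_ncomp", "fix_signs"]


def select_ncomp(var_prop: np.ndarray, ncomp: float) -> int:
    """Resolve the number of components to retain.

    An integer ``ncomp >= 1`` is returned as-is (clamped to the number of
    components with a warning if it exceeds it).  A fraction in (0, 1)
    selects the smallest k whose cumulative variance proportion reaches at
    least that share.
    """
    var_prop = np.asarray(var_prop, dtype=float)
    if ncomp <= 0:
        raise ValueError(f"ncomp must be positive, got {ncomp}")
    if ncomp >= 1:
        if ncomp != int(ncomp):
            raise ValueError(f"ncomp >= 1 must be an integer, got {ncomp}")
        k = int(ncomp)
        if k > len(var_prop):
            warnings.warn(
                f"ncomp={k} exceeds the {len(var_prop)} available components; clamped",
                stacklevel=2)
            k = len(var_prop)
        return k
    cum = np.cumsum(var_prop)
    return min(int(np.searchsorted(cum, ncomp - 1e-12) + 1), len(var_prop))


def fix_signs(loadings: np.ndarray, scores: np.ndarray | None = None):
    """Flip each loading column so its element of maximum |value| is positive.

    The sign of an eigenvector is arbitrary (flipping a column and its score
    column is an equivalent solution); this deterministic convention makes
    results reproducible.  Scores, when given, are flipped jointly so the
    reconstruction is unchanged.
    """
    loadings = np.array(loadings, dtype=float, copy=True)
    flip = np.ones(loadings.shape[1])
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            flip[j] = -1.0
    if scores is None:
        return loadings, flip
    return loadings, np.asarray(scores, dtype=float) * flip, flip


class TemporalPCA:
    """Temporal principal components analysis of a :class:`TrialMatrix`.

    Parameters
    ----------
    data : TrialMatrix
        Complete trials x timepoints matrix (preprocessed, epoched post
        onset so no column has zero variance).
    ncomp : int or float
        Components to retain: an integer count, or a fraction in (0, 1)
        meaning "enough components to explain at least this share of the
        total variance" (e.g. 0.95).
    standardize : bool
        If True, divide each centred column by its sample sd before the
        decomposition (correlation-based PCA).  Default False.
    """

    def __init__(self, data: TrialMatrix, ncomp: float = 0.95, standardize: bool = False):
        if not isinstance(data, TrialMatrix):
            raise TypeError("data must be a TrialMatrix (see core.to_trial_matrix)")
        self.data = data
        self.ncomp = ncomp
        self.standardize = bool(standardize)

    def fit(self) -> "TemporalPCAResults":
        X = self.data.values
        n, p = X.shape
        center = X.mean(axis=0)
        Xc = X - center
        scale = np.ones(p)
        if self.standardize:
            scale = Xc.std(axis=0, ddof=1)
            if np.any(scale == 0):
                raise DegenerateDataError("zero-variance column; cannot standardize")
            Xc = Xc / scale
        # SVD of the centred matrix: eigenvalues of the sample covariance are
        # singular values squared over (n - 1); right singular vectors are the
        # loading (eigenvector) columns.
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        eigenvalues = np.clip(s**2 / (n - 1), 0.0, None)
        total_var = Xc.var(axis=0, ddof=1).sum()
        var_prop = eigenvalues / total_var
        k = select_ncomp(var_prop, self.ncomp)
        loadings = Vt[:k].T  # p x k, unit-norm columns
        loadings, flip = fix_signs(loadings)
        scores = Xc @ loadings
        return TemporalPCAResults(
            model=self, center=center, scale=scale, eigenvalues=eigenvalues,
            var_prop=var_prop, loadings=loadings, scores=scores, k=k,
        )


@dataclass
class TemporalPCAResults:
    """Fitted temporal PCA: eigen-structure, scores and reconstruction.

    Attributes
    ----------
    center, scale : per-timepoint centring vector and (if standardized)
        scaling vector applied before the decomposition.
    eigenvalues : full descending spectrum (all ``min(n-1, p)`` values).
    var_prop : variance proportion of *every* component; the denominator is
        the total column variance, so ``var_prop[:k].sum()`` reproduces
        statements like "three components reconstruct 94.4% of the data".
    loadings : timepoints x k eigenvector matrix, unit-norm columns, signs
        fixed so each column's max-|element| is positive.
    scores : trials x k projection of the centred data onto the loadings.
    """

    model: TemporalPCA
    center: np.ndarray
    scale: np.ndarray
    eigenvalues: np.ndarray
    var_prop: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    k: int

    @property
    def col_times(self) -> np.ndarray:
        return self.model.data.col_times

    @property
    def row_meta(self) -> pd.DataFrame:
        return self.model.data.row_meta

    @property
    def cumulative_var(self) -> np.ndarray:
        return np.cumsum(self.var_prop)

    # -- projection -----------------------------------------------------
    def transform(self, values: np.ndarray) -> np.ndarray:
        """Project new rows (same time grid) onto the retained components."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] != len(self.center):
            raise ValueError("new data do not match the fitted time grid")
        return ((values - self.center) / self.scale) @ self.loadings

    def back_project(self, component: int, score_values) -> np.ndarray:
        """Trace(s) implied by given score values on one component.

        Returns ``center + score * loading_column`` for each score value
        (one trace per row); a score of 0 gives the grand-mean trace.
        Components are numbered from 1.
        """
        if not 1 <= component <= self.k:
            raise IndexError(f"component must be in 1..{self.k}, got {component}")
        s = np.atleast_1d(np.asarray(score_values, dtype=float))
        u = self.loadings[:, component - 1]
        return self.center + (s[:, None] * u[None, :]) * self.scale

    def reconstruct(self, scores: np.ndarray | None = None) -> np.ndarray:
        """Back-project score rows through all retained components."""
        if scores is None:
            scores = self.scores
        return self.center + (np.asarray(scores) @ self.loadings.T) * self.scale

    def scores_table(self, add: list[str] | None = None) -> pd.DataFrame:
        """Tidy per-trial score table: subject, trial, conditions, score_1..k.

        `add` selects condition columns from the row metadata to append;
        unknown names raise a schema error.
        """
        add = list(add or [])
        unknown = [c for c in add if c not in self.row_meta.columns]
        if unknown:
            raise SchemaError(f"unknown condition column(s): {unknown}")
        out = self.row_meta[["subject", "trial", *add]].copy()
        for j in range(self.k):
            out[f"score_{j + 1}"] = self.scores[:, j]
        return out

    # -- reporting ------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Per-component table: sd (sqrt eigenvalue), variance share, cumulative."""
        return pd.DataFrame({
            "component": np.arange(1, len(self.eigenvalues) + 1),
            "sd": np.sqrt(self.eigenvalues),
            "var_prop": self.var_prop,
            "cumulative": self.cumulative_var,
            "retained": np.arange(len(self.eigenvalues)) < self.k,
        })

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<TemporalPCAResults k={self.k}, n={self.scores.shape[0]} trials, "
                f"{len(self.center)} timepoints, "
                f"cumvar={self.cumulative_var[self.k - 1]:.3f}>")

    def plot_loadings(self, ax=None):
        """Plot the retained loading curves over time (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for j in range(self.k):
            ax.plot(self.col_times, self.loadings[:, j],
                    label=f"PC{j + 1} ({100 * self.var_prop[j]:.1f}%)")
        ax.axhline(0.0, color="0.6", lw=0.5)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("loading")
        ax.legend()
        return ax

    def save(self, outdir, sep: str = ",") -> None:
        """Export loadings, scores and the variance table as delimited text,
        with a sidecar metadata file (grid, centring, options)."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        load_df = pd.DataFrame(self.loadings,
                               columns=[f"loading_{j + 1}" for j in range(self.k)])
        load_df.insert(0, "time", self.col_times)
        load_df.to_csv(outdir / "loadings.csv", sep=sep, index=False)
        self.scores_table(add=[c for c in self.row_meta.columns
                               if c not in ("subject", "trial")]
                          ).to_csv(outdir / "scores.csv", sep=sep, index=False)
        self.summary().to_csv(outdir / "variance.csv", sep=sep, index=False)
        meta = {
            "kind": "temporal_pca",
            "k": int(self.k),
            "standardize": self.model.standardize,
            "ncomp": self.model.ncomp,
            "col_times": self.col_times.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
        }
        (outdir / "reduction_meta.json").write_text(json.dumps(meta, indent=1))
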