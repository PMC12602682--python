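"""Time-course and score-level statistics for pupil traces.

Two complementary inference paths are offered.  The *mass-univariate* path
tests the condition effect at every timepoint — with linear mixed-effects
models (:class:`TimecourseLMM`), with JZS Bayes factors under a standardized
Cauchy prior (:class:`BayesFactorTimecourse`), or with a cluster-based
permutation test (:class:`ClusterPermutation`) — and controls multiplicity
across the hundreds of correlated tests by BH-FDR or by the permutation null
of the maximal cluster mass.  The *score* path (:class:`ScoreModel`) fits a
mixed model directly to the handful of per-trial component scores produced
by the reduction stage, which is the recommended low-dimensional route.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

logger = logging.getLogger("pupilpca")

__all__ = [
    "fdr_adjust", "find_clusters", "Cluster", "TimecourseResult",
    "TimecourseLMM", "ClusterPermutation", "BayesFactorTimecourse",
    "ScoreModel", "ScoreModelResults", "jzs_logbf10", "jzs_bf10",
]

DEFAULT_PRIOR_SCALE = np.sqrt(2) / 2


# ---------------------------------------------------------------------------
# multiplicity and clusters
# ---------------------------------------------------------------------------

def fdr_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone-enforced).

    Input order is preserved; NaN entries (e.g. non-converged timepoints)
    pass through as NaN and do not count toward the number of tests.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = np.isfinite(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[valid] = res
    return out


@dataclass
class Cluster:
    """A maximal run of consecutive significant timepoints."""

    start: float          # ms, first flagged timepoint
    end: float            # ms, last flagged timepoint (inclusive)
    n_timepoints: int
    mass: float | None = None   # sum of |statistic| over the run
    p: float | None = None      # permutation p-value, when available


def find_clusters(flags, times, statistics=None) -> list[Cluster]:
    """Maximal consecutive runs of flagged timepoints as (start, end) ms.

    `end` is the time of the last flagged sample (inclusive).  When
    `statistics` is given, each cluster carries the mass
    ``sum(|statistic|)`` over its run.  Returns an empty list when nothing
    is flagged; NaN flags count as not significant.
    """
    flags = np.asarray(flags)
    if flags.dtype != bool:
        flags = np.nan_to_num(flags.astype(float), nan=0.0) != 0
    times = np.asarray(times, dtype=float)
    if flags.shape != times.shape:
        raise ValueError("flags and times must align")
    clusters: list[Cluster] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], flags.view(np.int8), [0]))))
    for a, b in zip(edges[::2], edges[1::2]):
        mass = None
        if statistics is not None:
            mass = float(np.nansum(np.abs(np.asarray(statistics, dtype=float)[a:b])))
        clusters.append(Cluster(start=float(times[a]), end=float(times[b - 1]),
                                n_timepoints=int(b - a), mass=mass))
    return clusters


@dataclass
class TimecourseResult:
    """Per-timepoint statistics with significance flags and clusters."""

    table: pd.DataFrame            # columns: time, statistic, p, p_adj?, bf10?, flag
    clusters: list[Cluster]
    alpha: float
    method: str
    adjust: str = "none"
    notes: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return self.table

    def cluster_table(self) -> pd.DataFrame:
        return pd.DataFrame([{"start": c.start, "end": c.end,
                              "n_timepoints": c.n_timepoints,
                              "mass": c.mass, "p": c.p} for c in self.clusters])

    def save(self, outdir, sep: str = ",") -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "timecourse.csv", sep=sep, index=False)
        self.cluster_table().to_csv(outdir / "clusters.csv", sep=sep, index=False)


# ---------------------------------------------------------------------------
# shared data plumbing
# ---------------------------------------------------------------------------

def _timecourse_arrays(rec, fixed: str, numeric: bool | None = None):
    """Pivot an epoched Recording into (Y, x, subjects, times).

    Y is trials x timepoints (incomplete trials dropped), x the per-trial
    condition, subjects the per-trial subject codes.  `numeric=None`
    auto-detects: numeric condition values are treated as an ordered
    covariate, otherwise as categorical.
    """
    df = rec.data
    if fixed not in df.columns:
        raise KeyError(f"condition column {fixed!r} not in recording")
    times = np.unique(df["time"].to_numpy(dtype=float))
    wide = df.pivot_table(index=["subject", "trial"], columns="time",
                          values="pupil", observed=True, dropna=False, sort=True)
    wide = wide.reindex(columns=times)
    complete = ~wide.isna().any(axis=1)
    wide = wide[complete]
    if len(wide) < 4:
        raise ValueError("fewer than 4 complete trials; cannot run time-course tests")
    meta = rec.trial_meta().set_index(["subject", "trial"]).loc[wide.index]
    xraw = meta[fixed]
    if numeric is None:
        numeric = pd.api.types.is_numeric_dtype(xraw) or \
            pd.to_numeric(xraw, errors="coerce").notna().all()
    if numeric:
        x = pd.to_numeric(xraw).to_numpy(dtype=float)[:, None]
        levels = None
    else:
        dummies = pd.get_dummies(xraw.astype(str), drop_first=True, dtype=float)
        x = dummies.to_numpy()
        levels = list(dummies.columns)
    subjects = pd.factorize(wide.index.get_level_values("subject"))[0]
    if len(np.unique(subjects)) < 2:
        raise ValueError("need at least 2 subjects")
    return wide.to_numpy(dtype=float), x, subjects, times, levels


# ---------------------------------------------------------------------------
# per-timepoint linear mixed models
# ---------------------------------------------------------------------------

class TimecourseLMM:
    """Per-timepoint linear mixed-effects test of a condition effect.

    At every timepoint, ``pupil ~ condition`` is fitted with a by-subject
    random intercept (random slopes via ``random_slope=True``); the fixed
    effect is tested by a likelihood-ratio test between the full and the
    intercept-only model, both refitted by full maximum likelihood.
    Multiplicity across timepoints is handled by BH-FDR by default
    (``adjust="none"`` flags at the raw level).  Timepoints where the
    optimiser fails are recorded as missing and the run continues.
    """

    def __init__(self, rec, fixed: str, alpha: float = 0.05, adjust: str = "fdr",
                 numeric: bool | None = None, random_slope: bool = False):
        if adjust not in ("fdr", "none"):
            raise ValueError(f"adjust must be 'fdr' or 'none', got {adjust!r}")
        self.rec = rec
        self.fixed = fixed
        self.alpha = alpha
        self.adjust = adjust
        self.numeric = numeric
        self.random_slope = random_slope

    def fit(self) -> TimecourseResult:
        from statsmodels.regression.mixed_linear_model import MixedLM

        Y, x, subjects, times, _ = _timecourse_arrays(self.rec, self.fixed, self.numeric)
        if np.all(np.ptp(x, axis=0) == 0):
            raise ValueError(f"condition {self.fixed!r} does not vary")
        n, T = Y.shape
        ones = np.ones((n, 1))
        exog_full = np.column_stack([ones, x])
        exog_re = np.column_stack([ones, x]) if self.random_slope else None
        df_test = x.shape[1]
        stat = np.full(T, np.nan)
        pval = np.full(T, np.nan)
        n_fail = 0
        for j in range(T):
            y = Y[:, j]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m0 = MixedLM(y, ones, groups=subjects).fit(reml=False)
                    m1 = MixedLM(y, exog_full, groups=subjects,
                                 exog_re=exog_re).fit(reml=False)
                lrt = 2.0 * (m1.llf - m0.llf)
                stat[j] = max(lrt, 0.0)
                pval[j] = stats.chi2.sf(stat[j], df_test)
            except Exception:  # non-convergence at this timepoint
                n_fail += 1
        if n_fail == T:
            raise RuntimeError("mixed model failed to converge at every timepoint")
        if n_fail:
            logger.warning("TimecourseLMM: %d/%d timepoints failed to converge", n_fail, T)
        p_adj = fdr_adjust(pval) if self.adjust == "fdr" else pval.copy()
        flag = p_adj < self.alpha
        clusters = find_clusters(flag, times, statistics=stat)
        table = pd.DataFrame({"time": times, "statistic": stat, "p": pval,
                              "p_adj": p_adj, "flag": flag})
        return TimecourseResult(table=table, clusters=clusters, alpha=self.alpha,
                                method="lmem_lrt", adjust=self.adjust,
                                notes={"n_trials": n, "n_failed": n_fail,
                                       "df_test": df_test})


# ---------------------------------------------------------------------------
# cluster-based permutation
# ---------------------------------------------------------------------------

def _max_cluster_mass(flags2d: np.ndarray, stats2d: np.ndarray) -> np.ndarray:
    """Row-wise maximal cluster mass: largest sum of |stat| over a
    consecutive flagged run.  Vectorised over rows with a scan over time."""
    P, T = flags2d.shape
    cur = np.zeros(P)
    best = np.zeros(P)
    a = np.abs(stats2d)
    for t in range(T):
        cur = np.where(flags2d[:, t], cur + a[:, t], 0.0)
        best = np.maximum(best, cur)
    return best


class ClusterPermutation:
    """Cluster-based permutation test of a condition effect over time.

    The per-timepoint statistic is two-stage: within each subject the OLS
    slope of pupil on the (numeric) condition across trials, then a
    one-sample t statistic of those slopes across subjects.  Clusters form
    where the two-sided p of that t drops below `cluster_alpha`; the cluster
    mass is the sum of |t| over the run.  The null distribution is the
    maximal cluster mass over `n_perm` permutations that shuffle condition
    labels across trials *within* each subject (preserving subject-level
    exchangeability); each observed cluster gets
    ``p = (1 + #{null >= mass}) / (1 + n_perm)``.
    """

    def __init__(self, rec, fixed: str, n_perm: int = 1000,
                 cluster_alpha: float = 0.05, seed: int = 0):
        if n_perm < 100:
            warnings.warn(f"n_perm={n_perm} is small; permutation p-values will be "
                          "coarse (minimum attainable p is 1/(n_perm+1))", stacklevel=2)
        self.rec = rec
        self.fixed = fixed
        self.n_perm = int(n_perm)
        self.cluster_alpha = cluster_alpha
        self.seed = seed

    def fit(self) -> TimecourseResult:
        Y, x, subjects, times, _ = _timecourse_arrays(self.rec, self.fixed, numeric=True)
        x = x[:, 0]
        T = Y.shape[1]
        subj_ids = np.unique(subjects)
        S = len(subj_ids)
        rng = np.random.default_rng(self.seed)

        # per-subject centred condition and trial blocks
        blocks = []
        for s in subj_ids:
            idx = subjects == s
            xc = x[idx] - x[idx].mean()
            if np.allclose(xc, 0):
                raise ValueError(
                    f"condition {self.fixed!r} does not vary within subject {s}; "
                    "nothing to permute")
            blocks.append((xc, Y[idx]))

        nrow = self.n_perm + 1  # row 0 = observed labelling
        sum_b = np.zeros((nrow, T))
        sumsq = np.zeros((nrow, T))
        for xc, Ys in blocks:
            Xp = np.empty((nrow, len(xc)))
            Xp[0] = xc
            Xp[1:] = rng.permuted(np.broadcast_to(xc, (self.n_perm, len(xc))).copy(),
                                  axis=1)
            denom = (xc**2).sum()
            slopes = (Xp @ Ys) / denom          # (nrow, T)
            sum_b += slopes
            sumsq += slopes**2
        mean = sum_b / S
        var = (sumsq - S * mean**2) / (S - 1)
        var = np.clip(var, 1e-300, None)
        tmat = mean / np.sqrt(var / S)           # (nrow, T)
        tcrit = stats.t.ppf(1 - self.cluster_alpha / 2, S - 1)
        flags2d = np.abs(tmat) > tcrit
        null_max = _max_cluster_mass(flags2d[1:], tmat[1:])

        tobs = tmat[0]
        pobs = 2 * stats.t.sf(np.abs(tobs), S - 1)
        flag = flags2d[0]
        clusters = find_clusters(flag, times, statistics=tobs)
        for c in clusters:
            c.p = float((1 + np.sum(null_max >= c.mass)) / (1 + self.n_perm))
        table = pd.DataFrame({"time": times, "statistic": tobs, "p": pobs,
                              "flag": flag})
        return TimecourseResult(table=table, clusters=clusters,
                                alpha=self.cluster_alpha, method="cluster_permutation",
                                notes={"n_perm": self.n_perm, "seed": self.seed,
                                       "n_subjects": S, "tcrit": float(tcrit),
                                       "null_max": null_max})


# ---------------------------------------------------------------------------
# JZS Bayes factors
# ---------------------------------------------------------------------------

def jzs_logbf10(t: float, n_eff: float, df: float,
                r: float = DEFAULT_PRIOR_SCALE) -> float:
    """log Bayes factor (alternative over null) for a t statistic under a
    zero-centred Cauchy(0, r) prior on the standardized effect.

    The Cauchy prior is expressed as a scale mixture of normals over the
    mixing parameter g (g ~ InverseGamma(1/2, r^2/2)) and the marginal
    likelihood integrated numerically in one dimension (log-substitution
    u = log g, adaptive quadrature around the integrand's mode).
    """
    t = float(t)
    if not np.isfinite(t):
        return np.nan

    def log_f(u):
        g = np.exp(u)
        c = 1.0 + n_eff * g
        lp = (0.5 * np.log(r**2 / (2 * np.pi)) - 1.5 * u - r**2 / (2 * g))
        ll = -0.5 * np.log(c) - (df + 1) / 2 * np.log1p(t**2 / (c * df))
        return lp + ll + u  # + u: jacobian of g = exp(u)

    # locate the mode on a coarse grid, then integrate around it
    grid = np.linspace(-35.0, 35.0, 301)
    lf = log_f(grid)
    m = float(np.max(lf))
    u0 = float(grid[np.argmax(lf)])
    val, _ = integrate.quad(lambda u: np.exp(log_f(u) - m), -35.0, 35.0,
                            points=[u0], limit=200)
    log_num = m + np.log(val)
    log_den = -(df + 1) / 2 * np.log1p(t**2 / df)
    return log_num - log_den


def jzs_bf10(t: float, n_eff: float, df: float,
             r: float = DEFAULT_PRIOR_SCALE) -> float:
    """``exp(jzs_logbf10(...))`` — the Bayes factor itself."""
    return float(np.exp(jzs_logbf10(t, n_eff, df, r)))


class BayesFactorTimecourse:
    """Per-timepoint JZS Bayes factor for a (numeric) condition effect.

    The subject enters as an additive nuisance: pupil and condition are
    residualized on subject means, the slope t statistic computed on the
    residuals (df = n - n_subjects - 1), and BF10 obtained under a
    Cauchy(0, `prior_scale`) prior on the standardized slope
    (default scale sqrt(2)/2).  Timepoints flag as "evidence for an effect"
    at BF10 > `threshold` (default 3).
    """

    def __init__(self, rec, fixed: str, prior_scale: float = DEFAULT_PRIOR_SCALE,
                 threshold: float = 3.0):
        self.rec = rec
        self.fixed = fixed
        self.prior_scale = prior_scale
        self.threshold = threshold

    def fit(self) -> TimecourseResult:
        Y, x, subjects, times, _ = _timecourse_arrays(self.rec, self.fixed, numeric=True)
        x = x[:, 0]
        n, T = Y.shape
        S = len(np.unique(subjects))
        # residualize out subject means (additive nuisance)
        xr = x - pd.Series(x).groupby(subjects).transform("mean").to_numpy()
        Yr = Y - pd.DataFrame(Y).groupby(subjects).transform("mean").to_numpy()
        sxx = (xr**2).sum()
        if sxx == 0:
            raise ValueError(f"condition {self.fixed!r} does not vary within subjects")
        df_resid = n - S - 1
        beta = (xr @ Yr) / sxx
        rss = (Yr**2).sum(axis=0) - beta**2 * sxx
        se = np.sqrt(np.clip(rss, 0, None) / df_resid / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = beta / se
        bf = np.full(T, np.nan)
        n_fail = 0
        for j in range(T):
            try:
                bf[j] = jzs_bf10(tvals[j], n_eff=n, df=df_resid, r=self.prior_scale)
            except Exception:
                n_fail += 1
        if n_fail:
            logger.warning("BayesFactorTimecourse: %d/%d timepoints failed", n_fail, T)
        pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
        flag = bf > self.threshold
        clusters = find_clusters(flag, times, statistics=tvals)
        table = pd.DataFrame({"time": times, "statistic": tvals, "p": pvals,
                              "bf10": bf, "flag": flag})
        return TimecourseResult(table=table, clusters=clusters, alpha=np.nan,
                                method="jzs_bf",
                                notes={"prior_scale": self.prior_scale,
                                       "threshold": self.threshold,
                                       "df_resid": df_resid})


# ---------------------------------------------------------------------------
# score-level mixed models
# ---------------------------------------------------------------------------

class ScoreModel:
    """Linear mixed model on per-trial component scores.

    For each ``score_*`` column of a tidy score table (from
    ``scores_table``), fits ``score ~ condition`` with a by-subject random
    intercept (REML).  This is the recommended low-dimensional inference
    path: a handful of models on a handful of interpretable values instead
    of hundreds of correlated per-timepoint tests.
    """

    def __init__(self, scores: pd.DataFrame, fixed: str,
                 score_cols: list[str] | None = None, numeric: bool | None = None,
                 random_slope: bool = False, reml: bool = True):
        if fixed not in scores.columns:
            raise KeyError(f"condition column {fixed!r} not in score table")
        if "subject" not in scores.columns:
            raise KeyError("score table must carry a 'subject' column")
        self.scores = scores
        self.fixed = fixed
        self.score_cols = score_cols or [c for c in scores.columns
                                         if c.startswith("score_")]
        if not self.score_cols:
            raise ValueError("no score_* columns found")
        self.numeric = numeric
        self.random_slope = random_slope
        self.reml = reml

    def fit(self) -> "ScoreModelResults":
        from statsmodels.regression.mixed_linear_model import MixedLM

        df = self.scores
        xraw = df[self.fixed]
        numeric = self.numeric
        if numeric is None:
            numeric = pd.api.types.is_numeric_dtype(xraw) or \
                pd.to_numeric(xraw, errors="coerce").notna().all()
        if numeric:
            X = pd.to_numeric(xraw).to_numpy(dtype=float)[:, None]
            terms = [self.fixed]
        else:
            dummies = pd.get_dummies(xraw.astype(str), drop_first=True, dtype=float)
            X = dummies.to_numpy()
            terms = [f"{self.fixed}[{c}]" for c in dummies.columns]
        groups = pd.factorize(df["subject"])[0]
        ones = np.ones((len(df), 1))
        exog = np.column_stack([ones, X])
        rows = []
        fits = {}
        for col in self.score_cols:
            y = df[col].to_numpy(dtype=float)
            exog_re = np.column_stack([ones, X]) if self.random_slope else None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = MixedLM(y, exog, groups=groups, exog_re=exog_re
                                  ).fit(reml=self.reml)
                except Exception:
                    if exog_re is None:
                        raise
                    logger.warning("ScoreModel: random slope fit failed for %s; "
                                   "refitting with intercept-only random effects", col)
                    res = MixedLM(y, exog, groups=groups).fit(reml=self.reml)
            fits[col] = res
            ci = res.conf_int()
            for i, term in enumerate(["(Intercept)", *terms]):
                rows.append({
                    "component": col, "term": term,
                    "estimate": res.params[i], "se": res.bse[i],
                    "z": res.tvalues[i], "p": res.pvalues[i],
                    "ci_low": ci[i][0], "ci_high": ci[i][1],
                })
        return ScoreModelResults(table=pd.DataFrame(rows), fits=fits,
                                 fixed=self.fixed)


@dataclass
class ScoreModelResults:
    """Tidy per-component fixed-effect estimates with Wald intervals."""

    table: pd.DataFrame
    fits: dict
    fixed: str

    def summary(self) -> pd.DataFrame:
        return self.table

    def effects(self) -> pd.DataFrame:
        """Only the condition-effect rows (intercepts dropped)."""
        return self.table[self.table["term"] != "(Intercept)"].reset_index(drop=True)

    def save(self, outdir, sep: str = ",") -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "score_model.csv", sep=sep, index=False)
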