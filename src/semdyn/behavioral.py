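"""Behavioral speed-sensitivity analyses for lexical-decision RT data.

The chain of procedures:

1. inverse-transform RTs to the speed scale (1/RT), on which the harmonic
   mean of RTs equals the mean;
2. check predictor collinearity with the condition index of the
   mean-centered, column-equilibrated design;
3. fit an ordinary multiple regression *per subject* (random regression)
   of inverse RT on the item predictors and session covariates, yielding
   per-subject standardized coefficients;
4. correlate each predictor's per-subject coefficients with the subjects'
   mean inverse RTs — a negative correlation for a facilitatory predictor
   means slower participants carry a larger effect;
5. quantify uncertainty with a bias-corrected bootstrap CI over subjects
   and compare two predictors' speed correlations with a permutation test
   that shuffles the subject speed vector jointly against both coefficient
   vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "inverse_transform",
    "harmonic_mean",
    "phoneme_rate",
    "condition_index",
    "subject_regressions",
    "speed_sensitivity",
    "bootstrap_ci",
    "permutation_diff",
    "SpeedSensitivityModel",
    "SpeedSensitivityResults",
]

SESSION_COVARIATES = ["trial_order", "prev_same", "prev_error", "prev_rt_inv"]


def inverse_transform(rt):
    """Inverse-RT (speed) transform: 1/RT, in 1/ms for RT in ms."""
    rt = np.asarray(rt, float)
    if (rt <= 0).any():
        raise ValueError("reaction times must be positive")
    return 1.0 / rt


def harmonic_mean(rts) -> float:
    """Harmonic mean of RTs: the RT whose speed is the mean speed."""
    rts = np.asarray(rts, float)
    if (rts <= 0).any():
        raise ValueError("reaction times must be positive")
    return float(len(rts) / inverse_transform(rts).sum())


def phoneme_rate(n_phonemes, duration_ms):
    """Phonemes per millisecond: number of phonemes / stimulus duration."""
    duration_ms = np.asarray(duration_ms, float)
    if (duration_ms <= 0).any():
        raise ValueError("durations must be positive")
    n = np.asarray(n_phonemes, float)
    if (n == 0).any():
        warnings.warn("zero phoneme counts yield a zero phoneme rate")
    out = n / duration_ms
    return float(out) if out.ndim == 0 else out


def condition_index(predictors: pd.DataFrame) -> float:
    """Collinearity condition index of a predictor table.

    Columns are mean-centered and scaled to unit Euclidean length
    (Belsley's column equilibration on the centered design); the index is
    the ratio of the largest to the smallest singular value.  A rank
    deficient design yields ``inf``.
    """
    X = np.asarray(predictors, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a table with at least 2 predictor columns")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than predictors")
    X = X - X.mean(axis=0)
    norms = np.linalg.norm(X, axis=0)
    if (norms == 0).any():
        return float("inf")
    X = X / norms
    sv = np.linalg.svd(X, compute_uv=False)
    tol = sv.max() * max(X.shape) * np.finfo(float).eps
    if sv.min() <= tol:
        return float("inf")
    return float(sv.max() / sv.min())


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.full_like(x, np.nan)
    return (x - x.mean()) / sd


def subject_regressions(
    data: pd.DataFrame,
    predictors: list[str],
    include_session: bool = True,
    min_extra_rows: int = 10,
) -> pd.DataFrame:
    """Per-subject OLS of inverse RT on standardized predictors.

    Only correct responses enter the analysis.  Predictors (and session
    covariates, when present and included) are standardized over the full
    analyzed dataset so coefficients are comparable across subjects; the
    dependent variable is the inverse RT in 1/ms.  Subjects with fewer
    than ``len(predictors) + min_extra_rows`` usable rows are excluded
    with a warning.

    Returns a DataFrame with one row per (subject, predictor): ``beta``,
    ``se``, ``t``, ``p``, plus the subject's ``mean_inv_rt`` and ``n_rows``.
    """
    d = data[data["correct"]].copy()
    if d.empty:
        raise ValueError("no correct-response rows to analyze")
    d["inv_rt"] = inverse_transform(d["rt_ms"])
    session = [c for c in SESSION_COVARIATES if include_session and c in d.columns]
    columns = list(predictors) + session
    missing = [c for c in columns if c not in d.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    for c in columns:
        d[c] = _zscore(d[c].astype(float).to_numpy())

    min_rows = len(columns) + min_extra_rows
    rows = []
    for subject, sub in d.groupby("subject"):
        if len(sub) < min_rows:
            warnings.warn(
                f"subject {subject} excluded: {len(sub)} rows < {min_rows}"
            )
            continue
        y = sub["inv_rt"].to_numpy()
        X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy() for c in columns])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = len(sub) - X.shape[1]
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        for j, c in enumerate(columns, start=1):
            tstat = coef[j] / se[j] if se[j] > 0 else np.nan
            rows.append(
                {
                    "subject": subject,
                    "predictor": c,
                    "beta": coef[j],
                    "se": se[j],
                    "t": tstat,
                    "p": 2.0 * sps.t.sf(abs(tstat), df=dof),
                    "mean_inv_rt": float(sub["inv_rt"].mean()),
                    "n_rows": len(sub),
                }
            )
    if not rows:
        raise ValueError("no subject had enough data for the regression")
    return pd.DataFrame(rows)


def speed_sensitivity(betas, mean_inv_rt) -> tuple[float, float]:
    """Pearson correlation between per-subject coefficients and speed.

    Returns (r, two-sided parametric p).  Raises on fewer than 4 subjects
    or a zero-variance input (a zero-variance vector carries no
    speed-sensitivity information; it is an error, not r = 0).
    """
    b = np.asarray(betas, float)
    v = np.asarray(mean_inv_rt, float)
    if len(b) != len(v):
        raise ValueError("misaligned subject vectors")
    if len(b) < 4:
        raise ValueError("need at least 4 subjects")
    if b.std() == 0 or v.std() == 0:
        raise ValueError("zero-variance input to speed-sensitivity correlation")
    r, p = sps.pearsonr(b, v)
    return float(r), float(p)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def bootstrap_ci(
    betas,
    mean_inv_rt,
    B: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    max_redraws: int = 1000,
) -> tuple[float, float]:
    """Bias-corrected bootstrap CI for the speed-sensitivity correlation.

    Subjects are resampled with replacement ``B`` times and the Pearson
    correlation recomputed each time; the interval is the bias-corrected
    (BC, median-bias without acceleration) percentile interval.  Resamples
    with a zero-variance vector are redrawn; more than ``max_redraws``
    such degenerate draws is an error.
    """
    b = np.asarray(betas, float)
    v = np.asarray(mean_inv_rt, float)
    n = len(b)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    r_hat = _corr(b, v)
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    redraws = 0
    i = 0
    while i < B:
        idx = rng.integers(0, n, size=n)
        r = _corr(b[idx], v[idx])
        if np.isnan(r):
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError(
                    f"exceeded {max_redraws} degenerate bootstrap resamples"
                )
            continue
        stats[i] = r
        i += 1
    prop_below = (stats < r_hat).mean()
    # median-bias correction; clip so z0 is finite on degenerate distributions
    z0 = sps.norm.ppf(np.clip(prop_below, 1.0 / (B + 1), B / (B + 1.0)))
    alpha = 1.0 - level
    zlo, zhi = sps.norm.ppf(alpha / 2), sps.norm.ppf(1 - alpha / 2)
    qlo = sps.norm.cdf(2 * z0 + zlo)
    qhi = sps.norm.cdf(2 * z0 + zhi)
    lower, upper = np.quantile(stats, [qlo, qhi])
    return float(lower), float(upper)


def permutation_diff(
    betas_a,
    betas_b,
    mean_inv_rt,
    P: int = 10_000,
    seed: int = 0,
    signed: bool = False,
) -> tuple[float, float]:
    """One-sided permutation test for the difference of two speed correlations.

    The observed statistic is ``|r(betas_a, speed)| - |r(betas_b, speed)|``
    (raw signed difference with ``signed=True``), testing whether predictor
    A's coefficients track subject speed more strongly than predictor B's.
    The null distribution permutes the speed vector jointly against both
    coefficient vectors, preserving their mutual dependence.  The p-value
    uses the add-one rule, ``p = (#{null >= observed} + 1) / (P + 1)``.

    Returns (observed difference, one-sided p).
    """
    a = np.asarray(betas_a, float)
    b = np.asarray(betas_b, float)
    v = np.asarray(mean_inv_rt, float)
    if not (len(a) == len(b) == len(v)):
        raise ValueError("misaligned subject vectors")
    if P < 100:
        warnings.warn(f"only {P} permutations; p-value resolution is coarse")

    def stat(speed):
        ra, rb = _corr(a, speed), _corr(b, speed)
        if signed:
            return ra - rb
        return abs(ra) - abs(rb)

    observed = stat(v)
    rng = np.random.default_rng(seed)
    null = np.empty(P)
    for i in range(P):
        null[i] = stat(rng.permutation(v))
    p = (float((null >= observed - 1e-12).sum()) + 1.0) / (P + 1.0)
    return float(observed), float(p)


@dataclass
class SpeedSensitivityResults:
    """Per-subject coefficients and their correlations with subject speed.

    ``subject_betas``: output of :func:`subject_regressions`.
    ``correlations``: per predictor — r with mean inverse RT, parametric p,
    and (when computed) the bias-corrected bootstrap CI.
    """

    subject_betas: pd.DataFrame = field(repr=False)
    correlations: pd.DataFrame
    predictors: list[str]
    condition_index: float
    n_subjects: int

    def beta_vector(self, predictor: str) -> pd.Series:
        sub = self.subject_betas[self.subject_betas["predictor"] == predictor]
        return sub.set_index("subject")["beta"]

    @property
    def mean_inv_rt(self) -> pd.Series:
        sub = self.subject_betas[
            self.subject_betas["predictor"] == self.predictors[0]
        ]
        return sub.set_index("subject")["mean_inv_rt"]

    def bootstrap_ci(self, predictor: str, B: int = 10_000, level: float = 0.95,
                     seed: int = 0) -> tuple[float, float]:
        return bootstrap_ci(
            self.beta_vector(predictor).to_numpy(),
            self.mean_inv_rt.to_numpy(),
            B=B, level=level, seed=seed,
        )

    def permutation_diff(self, predictor_a: str, predictor_b: str,
                         P: int = 10_000, seed: int = 0,
                         signed: bool = False) -> tuple[float, float]:
        return permutation_diff(
            self.beta_vector(predictor_a).to_numpy(),
            self.beta_vector(predictor_b).to_numpy(),
            self.mean_inv_rt.to_numpy(),
            P=P, seed=seed, signed=signed,
        )

    def summary(self) -> str:
        lines = [
            "Speed sensitivity of per-subject regression coefficients",
            "=" * 56,
            f"subjects         {self.n_subjects}",
            f"condition index  {self.condition_index:.2f}",
            "",
            f"{'predictor':<24}{'r':>8}{'p':>10}",
        ]
        for _, row in self.correlations.iterrows():
            lines.append(
                f"{row['predictor']:<24}{row['r']:>+8.3f}{row['p']:>10.4f}"
            )
        return "\n".join(lines)


class SpeedSensitivityModel:
    """Model object for the full behavioral speed-sensitivity analysis.

    Parameters
    ----------
    data : subject x item table (see :mod:`semdyn.synth` for the layout).
    predictors : item predictors entering the per-subject regressions.
    include_session : also enter the session covariates present in the data.
    """

    def __init__(self, data: pd.DataFrame, predictors: list[str],
                 include_session: bool = True) -> None:
        self.data = data
        self.predictors = list(predictors)
        self.include_session = include_session

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, predictors: list[str],
                       **kwargs) -> "SpeedSensitivityModel":
        return cls(data, predictors, **kwargs)

    def fit(self) -> SpeedSensitivityResults:
        items = self.data.drop_duplicates("item")
        ci = condition_index(items[self.predictors])
        betas = subject_regressions(
            self.data, self.predictors, include_session=self.include_session
        )
        speed = betas[betas["predictor"] == self.predictors[0]].set_index(
            "subject"
        )["mean_inv_rt"]
        rows = []
        for p in self.predictors:
            bv = betas[betas["predictor"] == p].set_index("subject")["beta"]
            r, pval = speed_sensitivity(
                bv.loc[speed.index].to_numpy(), speed.to_numpy()
            )
            rows.append({"predictor": p, "r": r, "p": pval})
        return SpeedSensitivityResults(
            subject_betas=betas,
            correlations=pd.DataFrame(rows),
            predictors=self.predictors,
            condition_index=ci,
            n_subjects=int(speed.size),
        )
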