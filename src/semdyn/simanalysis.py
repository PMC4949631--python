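"""Analyses of simulated activation trajectories.

Two analyses mirror the two levels at which the simulation output is read:

* **feature level** — mean activation per tick for the distinguishing (D),
  moderately shared (low S) and highly shared (high S) feature bands of
  target concepts, plus the non-target band (features outside each item's
  concept), with per-tick pairwise contrasts Bonferroni-corrected for the
  number of ticks and contrasts;
* **concept level** — an ordinary least-squares regression fitted at every
  tick, relating mean target-feature activation (the proxy for response
  speed) to mean distinctiveness and (log) mean correlational strength,
  with variables standardized so the coefficients are comparable across
  ticks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .network import ActivationTrajectory
from .norms import (
    BAND_D,
    BAND_HIGH_S,
    BAND_LOW_S,
    PropertyNorms,
)

__all__ = [
    "band_trajectories",
    "band_contrasts",
    "per_tick_regression",
    "TickRegression",
    "TickRegressionResults",
    "smooth",
    "sign_changes",
    "CONTRASTS",
]

CONTRASTS = [(BAND_HIGH_S, BAND_LOW_S), (BAND_D, BAND_LOW_S), (BAND_HIGH_S, BAND_D)]

DEFAULT_PREDICTORS = ["mean_distinctiveness", "mean_cs_log"]


def band_trajectories(
    traj: ActivationTrajectory,
    norms: PropertyNorms,
    stats: pd.DataFrame,
) -> pd.DataFrame:
    """Mean activation per feature band per tick.

    A *feature instance* is a (concept, feature-of-that-concept) pair; each
    instance contributes the feature's activation for that item at every
    tick to its band's pool.  Taxonomic features are excluded from the
    target bands.  The ``nontarget`` band pools, per item, the features
    absent from that item's concept.

    Returns a tidy DataFrame with columns ``band``, ``tick``,
    ``mean_activation``, ``n`` (instances, constant across ticks).
    """
    if "band" not in stats.columns:
        raise ValueError("feature statistics lack band assignments; "
                         "run sharedness_bands first")
    feat_index = pd.Index(traj.feature_ids)
    missing = set(norms.features) - set(feat_index)
    if missing:
        raise ValueError(f"trajectory lacks features: {sorted(missing)[:5]}")
    bands = stats.reindex(feat_index)
    member = np.zeros((len(traj.item_ids), len(feat_index)), dtype=bool)
    t = norms.table
    fpos = {f: i for i, f in enumerate(feat_index)}
    ipos = {c: i for i, c in enumerate(traj.item_ids)}
    for concept, feature in zip(t["concept"], t["feature"]):
        if concept in ipos:
            member[ipos[concept], fpos[feature]] = True

    rows = []
    n_ticks = traj.n_ticks
    for band in (BAND_D, BAND_LOW_S, BAND_HIGH_S):
        in_band = (bands["band"] == band) & (~bands["taxonomic"].fillna(False))
        mask = member & in_band.to_numpy()[None, :]
        n = int(mask.sum())
        if n == 0:
            rows += [
                {"band": band, "tick": t_ + 1, "mean_activation": np.nan, "n": 0}
                for t_ in range(n_ticks)
            ]
            continue
        vals = traj.values[mask]  # (n_instances, ticks)
        means = vals.mean(axis=0)
        rows += [
            {"band": band, "tick": t_ + 1, "mean_activation": float(means[t_]), "n": n}
            for t_ in range(n_ticks)
        ]
    nt_mask = ~member
    means = traj.values[nt_mask].mean(axis=0)
    rows += [
        {
            "band": "nontarget",
            "tick": t_ + 1,
            "mean_activation": float(means[t_]),
            "n": int(nt_mask.sum()),
        }
        for t_ in range(n_ticks)
    ]
    return pd.DataFrame(rows)


def band_contrasts(
    members: list[pd.DataFrame],
    alpha: float = 0.05,
    n_contrasts: int | None = None,
) -> pd.DataFrame:
    """Per-tick two-sample t-tests between feature bands across an ensemble.

    ``members`` is one :func:`band_trajectories` table per ensemble instance
    (trained model); the dispersion entering each test is the spread of
    band means across instances.  Each of the three pairwise contrasts is
    tested at every tick against the Bonferroni-corrected level
    ``alpha / (n_ticks * n_contrasts)``.

    Returns a DataFrame with columns ``tick``, ``contrast``, ``t``, ``p``,
    ``significant`` plus the corrected threshold in ``df.attrs["threshold"]``.
    """
    if len(members) < 2:
        raise ValueError(
            "band contrasts need >= 2 ensemble instances; run the model "
            "grid (pattern sets x c x seeds) to obtain replication"
        )
    stacked = pd.concat(
        [m.assign(member=i) for i, m in enumerate(members)], ignore_index=True
    )
    ticks = sorted(stacked["tick"].unique())
    n_contrasts = n_contrasts or len(CONTRASTS)
    threshold = alpha / (len(ticks) * n_contrasts)
    wide = stacked.pivot_table(
        index=["member", "tick"], columns="band", values="mean_activation"
    )
    rows = []
    for band_a, band_b in CONTRASTS:
        for tick in ticks:
            sub = wide.xs(tick, level="tick")
            a = sub[band_a].dropna().to_numpy()
            b = sub[band_b].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                raise ValueError(
                    f"band {band_a if len(a) < 2 else band_b} empty or "
                    "unreplicated; excluded bands cannot be contrasted"
                )
            tstat, p = sps.ttest_ind(a, b)
            rows.append(
                {
                    "tick": tick,
                    "contrast": f"{band_a}-{band_b}",
                    "t": float(tstat),
                    "p": float(p),
                    "significant": bool(p < threshold),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = threshold
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.full_like(x, np.nan)
    return (x - x.mean()) / sd


def _ols_standardized(y: np.ndarray, X: np.ndarray):
    """OLS of z-scored y on z-scored columns of X (with intercept).

    Returns betas, standard errors, t statistics and p-values for the
    predictor columns.  A zero-variance predictor yields NaN estimates.
    """
    n, k = X.shape
    Xz = np.column_stack([_standardize(X[:, j]) for j in range(k)])
    yz = _standardize(y)
    if np.isnan(yz).all():
        return (np.full(k, np.nan),) * 4
    bad = np.isnan(Xz).all(axis=0)
    design = np.column_stack([np.ones(n), np.where(bad[None, :], 0.0, Xz)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1] - bad.sum():
        raise np.linalg.LinAlgError(
            "rank-deficient design: predictors are collinear"
        )
    coef, *_ = np.linalg.lstsq(design, yz, rcond=None)
    resid = yz - design @ coef
    dof = n - (design.shape[1] - bad.sum())
    if dof <= 0:
        raise ValueError("not enough observations for the design")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.diag(cov))[1:]
    beta = coef[1:]
    beta[bad] = np.nan
    se[bad] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    p = 2.0 * sps.t.sf(np.abs(tstat), df=dof)
    return beta, se, tstat, p


@dataclass
class TickRegressionResults:
    """Standardized per-tick coefficients for the concept-level analysis.

    ``table`` has one row per (tick, predictor): ``beta`` (mean across
    ensemble members when several trajectories were supplied), ``se``
    (across-member standard error, or the OLS standard error for a single
    member), ``t``, ``p`` and ``n_members``.
    """

    table: pd.DataFrame
    predictors: list[str]
    member_betas: pd.DataFrame = field(repr=False, default=None)
    n_concepts: int = 0

    def betas(self, predictor: str) -> pd.Series:
        sub = self.table[self.table["predictor"] == predictor]
        return sub.set_index("tick")["beta"]

    def summary(self) -> str:
        lines = [
            "Per-tick regression of mean concept activation",
            "=" * 48,
            f"concepts             {self.n_concepts}",
            f"predictors           {', '.join(self.predictors)}",
            f"ticks                {self.table['tick'].max()}",
            f"ensemble members     {int(self.table['n_members'].iloc[0])}",
            "",
        ]
        for p in self.predictors:
            b = self.betas(p)
            first_pos = b[b > 0]
            lines.append(
                f"{p}: beta range [{b.min():+.3f}, {b.max():+.3f}]"
                + (
                    f", first positive at tick {first_pos.index[0]}"
                    if len(first_pos)
                    else ""
                )
            )
        return "\n".join(lines)


class TickRegression:
    """Model: per-tick OLS of mean concept activation on concept statistics.

    Parameters
    ----------
    trajectories : one trajectory or a list (ensemble members).
    norms : the property norms, defining each concept's target features.
    concepts : concept statistics carrying the predictors.
    predictors : default mean distinctiveness + log mean correlational
        strength.  Concepts with a missing predictor are excluded.
    include_taxonomic : include taxonomic features in the dependent
        variable (excluded by default, matching the predictors).
    """

    def __init__(
        self,
        trajectories,
        norms: PropertyNorms,
        concepts: pd.DataFrame,
        predictors: list[str] | None = None,
        include_taxonomic: bool = False,
    ) -> None:
        if isinstance(trajectories, ActivationTrajectory):
            trajectories = [trajectories]
        if not trajectories:
            raise ValueError("at least one trajectory required")
        self.trajectories = trajectories
        self.norms = norms
        self.concepts = concepts
        self.predictors = predictors or list(DEFAULT_PREDICTORS)
        self.include_taxonomic = include_taxonomic
        if len(self.predictors) < 1:
            raise ValueError("at least one predictor required")

    def _dv_matrix(self, traj: ActivationTrajectory, items) -> np.ndarray:
        """(n_items, n_ticks) mean activation over each concept's targets."""
        t = self.norms.table
        if not self.include_taxonomic:
            t = t[~t["taxonomic"]]
        fpos = {f: i for i, f in enumerate(traj.feature_ids)}
        ipos = {c: i for i, c in enumerate(traj.item_ids)}
        dv = np.empty((len(items), traj.n_ticks))
        grouped = t.groupby("concept")["feature"].agg(list)
        for row, concept in enumerate(items):
            idx = [fpos[f] for f in grouped[concept]]
            dv[row] = traj.values[ipos[concept], idx, :].mean(axis=0)
        return dv

    def fit(self) -> TickRegressionResults:
        stats = self.concepts.dropna(subset=self.predictors)
        items = [c for c in stats.index if c in set(self.trajectories[0].item_ids)]
        if len(items) < len(self.predictors) + 2:
            raise ValueError("too few concepts with complete statistics")
        X = stats.loc[items, self.predictors].to_numpy(float)
        n_ticks = self.trajectories[0].n_ticks

        member_rows = []
        for m, traj in enumerate(self.trajectories):
            dv = self._dv_matrix(traj, items)
            for tick in range(1, n_ticks + 1):
                beta, se, tstat, p = _ols_standardized(dv[:, tick - 1], X)
                for j, pred in enumerate(self.predictors):
                    member_rows.append(
                        {
                            "member": m,
                            "tick": tick,
                            "predictor": pred,
                            "beta": beta[j],
                            "se_ols": se[j],
                            "t_ols": tstat[j],
                            "p_ols": p[j],
                        }
                    )
        member_betas = pd.DataFrame(member_rows)
        n_members = len(self.trajectories)
        rows = []
        for (tick, pred), sub in member_betas.groupby(["tick", "predictor"]):
            b = sub["beta"].to_numpy()
            if n_members > 1:
                mean = float(np.nanmean(b))
                se = float(np.nanstd(b, ddof=1) / np.sqrt(n_members))
                tstat = mean / se if se > 0 else np.nan
                p = 2.0 * sps.t.sf(abs(tstat), df=n_members - 1) if se > 0 else np.nan
            else:
                mean = float(b[0])
                se = float(sub["se_ols"].iloc[0])
                tstat = float(sub["t_ols"].iloc[0])
                p = float(sub["p_ols"].iloc[0])
            rows.append(
                {
                    "tick": tick,
                    "predictor": pred,
                    "beta": mean,
                    "se": se,
                    "t": tstat,
                    "p": p,
                    "n_members": n_members,
                }
            )
        table = pd.DataFrame(rows).sort_values(["predictor", "tick"]).reset_index(
            drop=True
        )
        return TickRegressionResults(
            table=table,
            predictors=self.predictors,
            member_betas=member_betas,
            n_concepts=len(items),
        )


def per_tick_regression(
    trajectories,
    norms: PropertyNorms,
    concepts: pd.DataFrame,
    predictors: list[str] | None = None,
    include_taxonomic: bool = False,
) -> TickRegressionResults:
    """Functional wrapper over :class:`TickRegression`."""
    return TickRegression(
        trajectories, norms, concepts, predictors, include_taxonomic
    ).fit()


def smooth(series: pd.Series, window: int = 5) -> pd.Series:
    """Centered moving average, shrinking at the edges."""
    return series.rolling(window, center=True, min_periods=1).mean()


def sign_changes(values) -> int:
    """Number of sign changes in a sequence, ignoring exact zeros."""
    v = np.asarray(values, float)
    signs = np.sign(v[v != 0])
    return int((np.diff(signs) != 0).sum())
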