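"""Synthetic data generators.

Three generators make every downstream stage testable without any external
download:

* :func:`generate_norms` builds a property-norm set with category structure:
  concepts within a category draw shared features from a common category
  pool (producing correlated shared features), a small cross-category pool
  supplies highly shared features, and each concept additionally carries
  features unique to it (distinguishing features).  One taxonomic
  category-label feature is attached per category.
* :func:`generate_wordforms` samples the abstract word-form input patterns:
  distinct binary vectors with exactly ``n_active`` of ``n_input`` nodes on
  (3 of 30 by default).
* :func:`generate_behavioral` simulates a lexical-decision dataset whose
  inverse reaction times follow a planted linear model over the concept
  statistics, with a correlational-strength effect that grows linearly with
  each subject's overall slowness.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .norms import PropertyNorms

__all__ = [
    "NormsGenConfig",
    "BehavioralGenConfig",
    "generate_norms",
    "generate_wordforms",
    "wordform_capacity",
    "generate_behavioral",
]


@dataclass(frozen=True)
class NormsGenConfig:
    """Configuration for the synthetic property-norms generator.

    Defaults give the desk-scale substrate used throughout: 60 concepts in
    6 categories of 10, each concept listing 10-14 features of which about
    a quarter are unique to it.
    """

    n_concepts: int = 60
    n_categories: int = 6
    features_per_concept: tuple[int, int] = (10, 14)
    p_distinguishing: float = 0.25
    category_feature_pool: int = 14
    cross_category_pool: int = 10
    freq_law: tuple[str, float] = ("poisson", 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_concepts < 1 or self.n_categories < 1:
            raise ValueError("counts must be positive")
        if self.n_concepts % self.n_categories:
            raise ValueError("n_concepts must be divisible by n_categories")
        lo, hi = self.features_per_concept
        if lo < 2 or hi < lo:
            raise ValueError("features_per_concept range invalid")
        if not 0.0 <= self.p_distinguishing <= 1.0:
            raise ValueError("p_distinguishing must be in [0, 1]")
        if self.category_feature_pool < 0 or self.cross_category_pool < 0:
            raise ValueError("pool sizes must be nonnegative")
        if self.p_distinguishing < 1.0 and self.category_feature_pool == 0 \
                and self.cross_category_pool == 0:
            raise ValueError(
                "shared features requested (p_distinguishing < 1) but both "
                "feature pools are empty"
            )


def _sample_freqs(rng: np.random.Generator, law: tuple[str, float], size: int):
    name, param = law
    if name == "poisson":
        return rng.poisson(param, size=size) + 1
    if name == "uniform":
        return rng.integers(1, int(param) + 1, size=size)
    raise ValueError(f"unknown production-frequency law {name!r}")


def generate_norms(cfg: NormsGenConfig = NormsGenConfig()) -> PropertyNorms:
    """Generate a synthetic property-norm set with category structure."""
    rng = np.random.default_rng(cfg.seed)
    per_cat = cfg.n_concepts // cfg.n_categories
    lo, hi = cfg.features_per_concept

    rows: list[tuple[str, str, int, bool]] = []
    uid = 0
    for cat in range(cfg.n_categories):
        cat_pool = [f"cat{cat}_shared{j}" for j in range(cfg.category_feature_pool)]
        tax_feature = f"is_category_{cat}"
        for m in range(per_cat):
            concept = f"c{cat * per_cat + m:03d}"
            n_feat = int(rng.integers(lo, hi + 1))
            n_dist = int(rng.binomial(n_feat, cfg.p_distinguishing))
            n_shared = n_feat - n_dist
            if n_shared and not (cfg.category_feature_pool or cfg.cross_category_pool):
                n_dist, n_shared = n_feat, 0
            feats: list[str] = []
            for _ in range(n_dist):
                feats.append(f"unique{uid}")
                uid += 1
            # roughly 2/3 of shared slots from the category pool, the rest
            # from the small cross-category pool of very widely shared features
            n_cross = min(
                int(rng.binomial(n_shared, 0.3)), cfg.cross_category_pool
            )
            n_cat = min(n_shared - n_cross, cfg.category_feature_pool)
            n_cross = min(n_shared - n_cat, cfg.cross_category_pool)
            if n_cat:
                feats += list(rng.choice(cat_pool, size=n_cat, replace=False))
            if n_cross:
                feats += [
                    f"global_shared{j}"
                    for j in rng.choice(cfg.cross_category_pool, size=n_cross,
                                        replace=False)
                ]
            if len(feats) < n_feat:
                # pools exhausted; top up with unique features
                for _ in range(n_feat - len(feats)):
                    feats.append(f"unique{uid}")
                    uid += 1
            freqs = _sample_freqs(rng, cfg.freq_law, len(feats))
            rows += [(concept, f, int(q), False) for f, q in zip(feats, freqs)]
            rows.append((concept, tax_feature, int(_sample_freqs(rng, cfg.freq_law, 1)[0]), True))
    table = pd.DataFrame(rows, columns=["concept", "feature", "prod_freq", "taxonomic"])
    return PropertyNorms(table)


def wordform_capacity(n_input: int, n_active: int) -> int:
    """Number of distinct binary patterns with ``n_active`` of ``n_input`` on."""
    return math.comb(n_input, n_active)


def generate_wordforms(
    n_items: int,
    n_input: int = 30,
    n_active: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Sample ``n_items`` distinct random n_active-of-n_input binary patterns.

    Returns an (n_items, n_input) float array of 0/1 rows, each summing to
    ``n_active``.
    """
    cap = wordform_capacity(n_input, n_active)
    if n_items > cap:
        raise ValueError(
            f"cannot draw {n_items} distinct patterns: capacity is "
            f"C({n_input},{n_active}) = {cap}"
        )
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    out = np.zeros((n_items, n_input))
    i = 0
    while i < n_items:
        subset = tuple(sorted(rng.choice(n_input, size=n_active, replace=False)))
        if subset in seen:
            continue
        seen.add(subset)
        out[i, list(subset)] = 1.0
        i += 1
    return out


@dataclass(frozen=True)
class BehavioralGenConfig:
    """Configuration for the synthetic lexical-decision RT generator.

    The planted model operates on the speed scale (inverse RT, 1/s):

    ``speed(s, i) = base + eta_s + sum_p beta_p z(x_pi) + beta_cs(s) z(cs_i) + noise``

    with ``beta_cs(s) = true_betas['mean_cs_log'] + speed_cs_slope * z(eta_s)``
    so that the correlational-strength effect varies linearly with the
    subject's overall speed.  With the default negative slope, slower
    subjects (lower mean inverse RT) get a *larger* facilitatory
    correlational-strength effect, the structure the speed-sensitivity
    analyses are designed to detect.
    """

    n_subjects: int = 34
    true_betas: dict = field(
        default_factory=lambda: {
            "mean_distinctiveness": -0.05,
            "mean_cs_log": 0.02,
            "nof": 0.02,
        }
    )
    speed_cs_slope: float = -0.06
    subject_sd: float = 0.12
    rt_noise: float = 0.12
    rt_base: float = 800.0
    error_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_base <= 0 or self.rt_noise <= 0:
            raise ValueError("rt_base and rt_noise must be positive")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_behavioral(
    cfg: BehavioralGenConfig,
    concepts: pd.DataFrame,
) -> pd.DataFrame:
    """Simulate a subject x item lexical-decision dataset.

    Parameters
    ----------
    cfg : BehavioralGenConfig
    concepts : DataFrame
        Concept statistics (as from :func:`semdyn.norms.concept_statistics`);
        concepts with a missing ``mean_cs_log`` are dropped before
        generation, mirroring their exclusion from the analyses.

    Returns
    -------
    DataFrame with one row per subject x item: ``subject``, ``item``,
    ``trial_order``, ``rt_ms``, ``correct``, ``prev_same``, ``prev_error``,
    ``prev_rt_inv`` plus the item-predictor columns.  Session covariates
    carry no planted effect, so their estimated coefficients are pure noise.
    """
    rng = np.random.default_rng(cfg.seed)
    items = concepts.dropna(subset=["mean_cs_log"]).copy()
    if items.empty:
        raise ValueError("no items with complete statistics")
    predictors = [p for p in cfg.true_betas if p != "mean_cs_log"]
    missing = [p for p in predictors + ["mean_cs_log"] if p not in items.columns]
    if missing:
        raise ValueError(f"concept statistics lack predictors: {missing}")
    n_items = len(items)
    z = {p: _zscore(items[p].to_numpy(float)) for p in predictors}
    z_cs = _zscore(items["mean_cs_log"].to_numpy(float))

    base_speed = 1000.0 / cfg.rt_base  # 1/s
    eta = rng.normal(0.0, cfg.subject_sd, size=cfg.n_subjects)
    z_eta = _zscore(eta)
    beta_cs = cfg.true_betas.get("mean_cs_log", 0.0) + cfg.speed_cs_slope * z_eta

    frames = []
    for s in range(cfg.n_subjects):
        fixed = np.zeros(n_items)
        for p in predictors:
            fixed += cfg.true_betas[p] * z[p]
        fixed += beta_cs[s] * z_cs
        speed = base_speed + eta[s] + fixed
        for attempt in range(100):
            noisy = speed + rng.normal(0.0, cfg.rt_noise, size=n_items)
            if (noisy > 0).all():
                break
            warnings.warn("resampling non-positive simulated speeds")
        else:
            raise RuntimeError("persistent non-positive simulated RTs")
        rt_ms = 1000.0 / noisy
        order = rng.permutation(n_items) + 1
        correct = rng.random(n_items) >= cfg.error_rate
        df = pd.DataFrame(
            {
                "subject": f"s{s:02d}",
                "item": items.index,
                "trial_order": order,
                "rt_ms": rt_ms,
                "correct": correct,
                "prev_same": rng.random(n_items) < 0.5,
                "prev_error": rng.random(n_items) < cfg.error_rate,
                "prev_rt_inv": rng.normal(base_speed, cfg.subject_sd, size=n_items),
            }
        )
        for p in predictors + ["mean_cs_log"]:
            df[p] = items[p].to_numpy(float)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    assert (out["rt_ms"] > 0).all()
    return out
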