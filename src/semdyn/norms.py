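"""Property norms and conceptual-structure statistics.

A property-norm set lists, for each concept, the semantic features that
participants produced for it and how many participants produced each
(the *production frequency*).  From such a table this module derives the
feature- and concept-level statistics used throughout the package:

* feature **distinctiveness** ``d = 1/k`` where ``k`` is the number of
  concepts listing the feature; features with ``k <= 2`` are
  *distinguishing*, features with ``k > 2`` are *shared*;
* a median split of the shared features' distinctiveness values into
  *moderately shared* (low S) and *highly shared* (high S) bands;
* pairwise **correlational strength**: the Pearson correlation between two
  features' production-frequency vectors across all concepts;
* per-concept summaries: NOF (number of non-taxonomic features), mean
  distinctiveness, and (log) mean correlational strength over the
  significantly correlated shared-feature pairs inside the concept.

Taxonomic features (category labels such as "is an animal") are carried in
the table but excluded from every statistic.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PropertyNorms",
    "NormsFormatError",
    "read_norms",
    "write_norms",
    "feature_statistics",
    "sharedness_bands",
    "feature_correlations",
    "concept_statistics",
]

NORMS_COLUMNS = ["concept", "feature", "prod_freq", "taxonomic"]

BAND_D = "D"
BAND_LOW_S = "lowS"
BAND_HIGH_S = "highS"
BAND_UNASSIGNED = "unassigned"

CLASS_DISTINGUISHING = "distinguishing"
CLASS_SHARED = "shared"


class NormsFormatError(ValueError):
    """Raised when a norms table violates the format or its invariants."""


@dataclass(frozen=True)
class PropertyNorms:
    """A validated concept x feature production-frequency table.

    Parameters
    ----------
    table : pandas.DataFrame
        Long-format table with columns ``concept`` (str), ``feature`` (str),
        ``prod_freq`` (int >= 1) and ``taxonomic`` (bool).  One row per
        (concept, feature) pair.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in NORMS_COLUMNS if c not in t.columns]
        if missing:
            raise NormsFormatError(f"norms table missing columns: {missing}")
        t = t[NORMS_COLUMNS].copy()
        t["concept"] = t["concept"].astype(str)
        t["feature"] = t["feature"].astype(str)
        freq = pd.to_numeric(t["prod_freq"], errors="coerce")
        bad = t.index[freq.isna() | (freq != freq.round()) | (freq < 1)]
        if len(bad):
            raise NormsFormatError(
                "production frequencies must be integers >= 1; offending "
                f"rows (0-based): {list(bad[:5])}"
            )
        t["prod_freq"] = freq.astype(int)
        t["taxonomic"] = t["taxonomic"].astype(bool)
        dup = t.duplicated(subset=["concept", "feature"])
        if dup.any():
            pairs = t.loc[dup, ["concept", "feature"]].head().to_records(index=False)
            raise NormsFormatError(f"duplicate (concept, feature) pairs: {list(pairs)}")
        if t.empty:
            raise NormsFormatError("norms table is empty")
        # a feature must carry a single consistent taxonomic flag
        flags = t.groupby("feature")["taxonomic"].nunique()
        inconsistent = flags.index[flags > 1].tolist()
        if inconsistent:
            raise NormsFormatError(
                f"features with inconsistent taxonomic flags: {inconsistent[:5]}"
            )
        n_nontax = t.loc[~t["taxonomic"]].groupby("concept").size()
        all_concepts = t["concept"].unique()
        lacking = sorted(set(all_concepts) - set(n_nontax.index))
        if lacking:
            raise NormsFormatError(
                f"concepts without any non-taxonomic feature: {lacking[:5]}"
            )
        t = t.sort_values(["concept", "feature"], kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "table", t)

    @property
    def concepts(self) -> list[str]:
        return sorted(self.table["concept"].unique())

    @property
    def features(self) -> list[str]:
        return sorted(self.table["feature"].unique())

    @property
    def taxonomic_features(self) -> list[str]:
        t = self.table
        return sorted(t.loc[t["taxonomic"], "feature"].unique())

    def frequency_matrix(self, include_taxonomic: bool = True) -> pd.DataFrame:
        """Concept x feature matrix of production frequencies (0 = absent)."""
        t = self.table if include_taxonomic else self.table[~self.table["taxonomic"]]
        mat = t.pivot(index="concept", columns="feature", values="prod_freq")
        return mat.reindex(index=self.concepts).fillna(0).astype(int)

    def target_matrix(self, frequency_weighted: bool = False) -> pd.DataFrame:
        """Concept x feature training-target matrix (binary by default)."""
        mat = self.frequency_matrix(include_taxonomic=True)
        if frequency_weighted:
            return mat / mat.to_numpy().max()
        return (mat > 0).astype(float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PropertyNorms):
            return NotImplemented
        return self.table.equals(other.table)


def read_norms(path) -> PropertyNorms:
    """Read a norms TSV (columns ``concept feature prod_freq taxonomic``).

    ``taxonomic`` is coded 0/1.  Raises :class:`NormsFormatError` naming the
    offending line for malformed input.
    """
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise NormsFormatError(f"cannot parse norms file {path}: {exc}") from exc
    missing = [c for c in NORMS_COLUMNS if c not in raw.columns]
    if missing:
        raise NormsFormatError(f"{path}: missing columns {missing}")
    freq = pd.to_numeric(raw["prod_freq"], errors="coerce")
    bad = raw.index[freq.isna() | (freq != freq.round()) | (freq < 1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise NormsFormatError(
            f"{path}: line {bad[0] + 2}: production frequency "
            f"{raw.loc[bad[0], 'prod_freq']!r} is not a positive integer"
        )
    tax = pd.to_numeric(raw["taxonomic"], errors="coerce")
    bad = raw.index[~tax.isin([0, 1])]
    if len(bad):
        raise NormsFormatError(
            f"{path}: line {bad[0] + 2}: taxonomic flag "
            f"{raw.loc[bad[0], 'taxonomic']!r} is not 0/1"
        )
    dup = raw.duplicated(subset=["concept", "feature"])
    if dup.any():
        i = raw.index[dup][0]
        raise NormsFormatError(
            f"{path}: line {i + 2}: duplicate pair "
            f"({raw.loc[i, 'concept']}, {raw.loc[i, 'feature']})"
        )
    table = pd.DataFrame(
        {
            "concept": raw["concept"],
            "feature": raw["feature"],
            "prod_freq": freq.astype(int),
            "taxonomic": tax.astype(bool),
        }
    )
    return PropertyNorms(table)


def write_norms(norms: PropertyNorms, path) -> None:
    """Write norms to TSV with deterministic row and column order."""
    if norms.table.empty:
        raise NormsFormatError("refusing to write an empty norms table")
    out = norms.table.copy()
    out["taxonomic"] = out["taxonomic"].astype(int)
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)


def feature_statistics(norms: PropertyNorms) -> pd.DataFrame:
    """Per-feature concept count, distinctiveness and class.

    Returns a DataFrame indexed by feature with columns ``k`` (number of
    concepts listing the feature), ``distinctiveness`` (= 1/k),
    ``feature_class`` (distinguishing iff k <= 2, shared iff k > 2),
    ``taxonomic`` and ``band`` (initially D for distinguishing features,
    unassigned otherwise; see :func:`sharedness_bands`).
    """
    t = norms.table
    k = t.groupby("feature").size().rename("k")
    tax = t.groupby("feature")["taxonomic"].first()
    stats = pd.DataFrame({"k": k, "taxonomic": tax})
    stats["distinctiveness"] = 1.0 / stats["k"]
    stats["feature_class"] = np.where(
        stats["k"] <= 2, CLASS_DISTINGUISHING, CLASS_SHARED
    )
    stats["band"] = np.where(
        stats["feature_class"] == CLASS_DISTINGUISHING, BAND_D, BAND_UNASSIGNED
    )
    return stats.sort_index()


def sharedness_bands(stats: pd.DataFrame) -> pd.DataFrame:
    """Median-split shared features into low-S and high-S bands.

    The split is on the shared features' distinctiveness values: the half
    with distinctiveness at or below the median (i.e. the more widely
    shared features) become ``highS``; the rest become ``lowS``.  Features
    exactly at the median therefore go to ``highS``, which is the
    deterministic tie rule used throughout.  Taxonomic features are left
    unassigned since they are excluded from every analysis.
    """
    out = stats.copy()
    shared = out.index[
        (out["feature_class"] == CLASS_SHARED) & (~out["taxonomic"])
    ]
    if len(shared) < 2:
        raise ValueError(
            f"need at least 2 shared non-taxonomic features for a median "
            f"split, found {len(shared)}"
        )
    d = out.loc[shared, "distinctiveness"]
    med = d.median()
    out.loc[shared, "band"] = np.where(d <= med, BAND_HIGH_S, BAND_LOW_S)
    return out


def feature_correlations(
    norms: PropertyNorms,
    alpha: float = 0.05,
    positive_only: bool = True,
) -> pd.DataFrame:
    """Pairwise Pearson correlations between shared features.

    For every unordered pair of non-taxonomic shared features, correlates
    their production-frequency vectors across *all* concepts in the norms
    (0 where a feature is absent).  A pair is marked ``significant`` when
    its two-sided p-value is below ``alpha`` and, if ``positive_only``,
    when r > 0.  Pairs involving a constant vector get a missing r and are
    never significant.

    Returns a DataFrame with columns ``feature_i``, ``feature_j`` (with
    ``feature_i < feature_j`` lexicographically), ``r``, ``p``,
    ``significant``.
    """
    stats = feature_statistics(norms)
    shared = stats.index[
        (stats["feature_class"] == CLASS_SHARED) & (~stats["taxonomic"])
    ].tolist()
    if not shared:
        warnings.warn("no shared non-taxonomic features; correlation table is empty")
        return pd.DataFrame(
            columns=["feature_i", "feature_j", "r", "p", "significant"]
        )
    mat = norms.frequency_matrix(include_taxonomic=True)[shared].to_numpy(float)
    n = mat.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 concepts for correlations, found {n}")
    centered = mat - mat.mean(axis=0)
    ss = (centered**2).sum(axis=0)
    denom = np.sqrt(np.outer(ss, ss))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered.T @ centered) / denom
    r[denom == 0] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    iu, ju = np.triu_indices(len(shared), k=1)
    rv = r[iu, ju]
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rv * np.sqrt((n - 2) / (1.0 - rv**2))
    p = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isclose(np.abs(rv), 1.0), 0.0, p)
    sig = (p < alpha) & ~np.isnan(rv)
    if positive_only:
        sig &= rv > 0
    names = np.asarray(shared)
    return pd.DataFrame(
        {
            "feature_i": names[iu],
            "feature_j": names[ju],
            "r": rv,
            "p": np.where(np.isnan(rv), np.nan, p),
            "significant": sig,
        }
    )


def concept_statistics(
    norms: PropertyNorms,
    stats: pd.DataFrame | None = None,
    corr: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-concept NOF, mean distinctiveness and mean correlational strength.

    Taxonomic features are excluded from all three statistics.  The mean
    correlational strength of a concept averages r over the significantly
    correlated shared-feature pairs whose two members both belong to the
    concept; it is missing (NaN) when the concept has no such pair, and its
    natural log is reported alongside.

    Returns a DataFrame indexed by concept with columns ``nof``,
    ``mean_distinctiveness``, ``mean_cs_raw``, ``mean_cs_log``,
    ``n_sig_pairs``.
    """
    if stats is None:
        stats = feature_statistics(norms)
    if corr is None:
        corr = feature_correlations(norms)
    t = norms.table[~norms.table["taxonomic"]]
    unknown = set(t["feature"]) - set(stats.index)
    if unknown:
        raise ValueError(f"features absent from statistics table: {sorted(unknown)[:5]}")

    concept_feats = t.groupby("concept")["feature"].agg(set)
    if corr.empty:
        sig_pairs = []
    else:
        sig = corr[corr["significant"]]
        sig_pairs = list(zip(sig["feature_i"], sig["feature_j"], sig["r"]))

    rows = []
    for concept in norms.concepts:
        feats = concept_feats.get(concept, set())
        if not feats:
            raise ValueError(f"concept {concept!r} has no non-taxonomic features")
        d = stats.loc[sorted(feats), "distinctiveness"]
        rs = [r for fi, fj, r in sig_pairs if fi in feats and fj in feats]
        n_sig = len(rs)
        raw = float(np.mean(rs)) if n_sig else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            log = np.log(raw) if n_sig and raw > 0 else np.nan
        rows.append(
            {
                "concept": concept,
                "nof": len(feats),
                "mean_distinctiveness": float(d.mean()),
                "mean_cs_raw": raw,
                "mean_cs_log": log,
                "n_sig_pairs": n_sig,
            }
        )
    out = pd.DataFrame(rows).set_index("concept")
    n_missing = int(out["mean_cs_raw"].isna().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} concepts have no significantly correlated shared "
            "pair; their mean correlational strength is missing and they are "
            "excluded from regressions using it"
        )
    return out
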