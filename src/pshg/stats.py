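"""Group comparison of polarimetric/texture features.

Mirrors the comparison stage of the tissue pipeline: robust percentile
trimming per group, a Kruskal-Wallis omnibus rank test per feature, and
Dunn's post hoc pairwise z-tests with Bonferroni adjustment over the
pairwise comparisons within that feature.  Pairwise differences are
categorized as highly significant (p < 0.001), significant
(0.001 <= p < 0.05) or not significant.  Features in which *no*
normal-vs-tumor-subtype pair reaches significance are collected into an
exclusion list consumed by the classification stage.

Dunn's z statistic between groups i and j uses the mean ranks of the
pooled sample with tie correction,

    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)),

with ``t`` the tie-group sizes.  There is no post hoc routine in the
scientific-Python stack proper, so the statistic is implemented here and
cross-checked in the tests against the two-group identity with the
rank-sum test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedFeature",
    "SignificanceRecord",
    "trim_percentiles",
    "kruskal_dunn",
    "significance_matrix",
    "normality_report",
    "categorize",
]

HIGH_ALPHA = 0.001
ALPHA = 0.05


@dataclass
class GroupedFeature:
    """Values of one feature split by tissue group."""

    parameter: str
    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        usable = [k for k, v in self.groups.items() if v.size >= 2]
        if len(usable) < 2:
            raise ValueError(
                f"feature {self.parameter!r}: need >=2 groups with >=2 values"
            )


@dataclass
class SignificanceRecord:
    parameter: str
    group_a: str
    group_b: str
    p_adjusted: float
    category: str  # highly_significant | significant | ns


def categorize(p: float) -> str:
    if p < HIGH_ALPHA:
        return "highly_significant"
    if p < ALPHA:
        return "significant"
    return "ns"


def trim_percentiles(
    values: np.ndarray, lo_pct: float = 1.0, hi_pct: float = 99.0
) -> np.ndarray:
    """Drop values strictly outside the [lo_pct, hi_pct] percentile band.

    Percentiles use linear interpolation (numpy default).  Vectors with
    fewer than 10 values are returned unchanged with a warning, since the
    percentile estimates would be meaningless.
    """
    if lo_pct >= hi_pct:
        raise ValueError("lo_pct must be < hi_pct")
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        warnings.warn("fewer than 10 values; percentile trimming skipped")
        return values
    lo, hi = np.percentile(values, (lo_pct, hi_pct))
    return values[(values >= lo) & (values <= hi)]


def _dunn_pairs(groups: dict[str, np.ndarray]) -> list[tuple[str, str, float]]:
    """Dunn pairwise raw two-sided p-values from pooled mean ranks."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in names:
        n = groups[g].size
        mean_ranks[g] = ranks[start : start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    out = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / groups[a].size + 1.0 / groups[b].size))
        if se == 0:  # every pooled value tied
            p = 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * sps.norm.sf(abs(z))
        out.append((a, b, p))
    return out


def kruskal_dunn(gf: GroupedFeature) -> list[SignificanceRecord]:
    """Kruskal-Wallis omnibus test + Dunn-Bonferroni pairwise records.

    The omnibus H statistic (tie-corrected, k-1 degrees of freedom) is
    computed for reference; pairwise records carry Dunn z-test p-values
    Bonferroni-multiplied by the number of pairs within this feature and
    capped at 1.  If every value is tied across all groups, all pairs are
    ``ns`` with p = 1.
    """
    arrays = [v for v in gf.groups.values() if v.size >= 2]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return [
            SignificanceRecord(gf.parameter, a, b, 1.0, "ns")
            for a, b in itertools.combinations(gf.groups, 2)
        ]
    raw = _dunn_pairs({k: v for k, v in gf.groups.items() if v.size >= 2})
    m = len(raw)
    records = []
    for a, b, p in raw:
        p_adj = min(p * m, 1.0)
        records.append(SignificanceRecord(gf.parameter, a, b, p_adj, categorize(p_adj)))
    return records


def kruskal_h(gf: GroupedFeature) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (df = k-1)."""
    arrays = [v for v in gf.groups.values() if v.size >= 2]
    try:
        h, p = sps.kruskal(*arrays)
    except ValueError:  # all values identical
        return 0.0, 1.0
    return float(h), float(p)


def significance_matrix(
    table: pd.DataFrame,
    feature_cols: list[str],
    group_col: str = "label",
    reference_group: str = "normal",
    trim: tuple[float, float] | None = (1.0, 99.0),
) -> tuple[pd.DataFrame, list[str]]:
    """Full feature x group-pair significance table plus exclusion list.

    Per feature: optional per-group percentile trimming, then
    :func:`kruskal_dunn`.  The exclusion list collects features with no
    significant pair between ``reference_group`` and any other group —
    features that carry no reference-vs-disease signal and are omitted
    from classification.
    """
    if not feature_cols:
        raise ValueError("need at least one feature column")
    group_names = list(table[group_col].unique())
    rows = []
    excluded: list[str] = []
    for feat in feature_cols:
        groups = {}
        for g in group_names:
            vals = table.loc[table[group_col] == g, feat].dropna().to_numpy()
            if trim is not None and vals.size >= 10:
                vals = trim_percentiles(vals, *trim)
            groups[g] = vals
        gf = GroupedFeature(parameter=feat, groups=groups)
        recs = kruskal_dunn(gf)
        h, p_omnibus = kruskal_h(gf)
        ref_significant = False
        for r in recs:
            rows.append(
                {
                    "parameter": r.parameter,
                    "group_a": r.group_a,
                    "group_b": r.group_b,
                    "p_adjusted": r.p_adjusted,
                    "category": r.category,
                    "kw_h": h,
                    "kw_p": p_omnibus,
                }
            )
            if reference_group in (r.group_a, r.group_b) and r.category != "ns":
                ref_significant = True
        if not ref_significant:
            excluded.append(feat)
    return pd.DataFrame(rows), excluded


def normality_report(
    table: pd.DataFrame,
    feature_cols: list[str],
    group_col: str = "label",
    max_n: int = 500,
) -> pd.DataFrame:
    """Shapiro-Wilk screening per feature and group (reporting only).

    Justifies the nonparametric choice; gates nothing.  Samples larger
    than ``max_n`` are subsampled deterministically for the test's
    validity range.
    """
    rows = []
    for feat in feature_cols:
        for g, sub in table.groupby(group_col):
            vals = sub[feat].dropna().to_numpy()
            if vals.size < 3:
                continue
            if vals.size > max_n:
                idx = np.linspace(0, vals.size - 1, max_n).astype(int)
                vals = np.sort(vals)[idx]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w, p = sps.shapiro(vals)
            rows.append({"parameter": feat, "group": g, "shapiro_w": w, "shapiro_p": p})
    return pd.DataFrame(rows)
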