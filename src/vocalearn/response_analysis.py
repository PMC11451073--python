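"""Pre/post comparison of response acoustics.

After an animal has learned to answer playbacks with its own call types, the
responses themselves may drift acoustically.  This module quantifies that
drift: per-type Mann-Whitney comparisons of each parameter between the
pre-experimental repertoire and the experimental responses, a two-way ANOVA
decomposing each parameter's variance into vocal-type and experimental-stage
contributions (sums of squares), and a PCA of the standardized parameters
for visual inspection of category structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .acoustics import FEATURE_NAMES

__all__ = [
    "StageLabeledFeatures",
    "mann_whitney_u",
    "two_way_anova_ss",
    "pca_project",
    "compare_pre_post",
]

STAGES = ("pre", "post")


@dataclass
class StageLabeledFeatures:
    """Feature rows labelled by vocal type (1/2) and stage (pre/post).

    ``table`` columns: ``type``, ``stage`` plus one column per parameter.
    All four type-by-stage cells must be non-empty (they may be unbalanced).
    """

    table: pd.DataFrame
    parameters: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self) -> None:
        missing = [c for c in ["type", "stage", *self.parameters] if c not in self.table.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        bad = set(self.table["stage"]) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        for vtype in sorted(self.table["type"].unique()):
            for stage in STAGES:
                if ((self.table["type"] == vtype) & (self.table["stage"] == stage)).sum() == 0:
                    raise ValueError(f"empty cell: type {vtype}, stage {stage}")

    def cell(self, vtype: int, stage: str, parameter: str) -> np.ndarray:
        mask = (self.table["type"] == vtype) & (self.table["stage"] == stage)
        return self.table.loc[mask, parameter].to_numpy(float)


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is reported for the first sample.

    ``method='auto'`` enumerates exactly for combined samples of up to 20
    observations without ties, and otherwise uses the tie-corrected normal
    approximation with continuity correction.  U_x + U_y = n1*n2 links the
    two reporting conventions.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def two_way_anova_ss(
    data: StageLabeledFeatures,
    parameter: str,
    ss_type: int = 2,
    include_interaction: bool = True,
) -> pd.DataFrame:
    """Sum-of-squares table for vocal type and stage on one parameter.

    Type-II sums of squares by default (each main effect adjusted for the
    other, not for the interaction); configurable to Type I or III.  For
    balanced designs the four components add up to the total SS.  Rows:
    ``type``, ``stage``, optionally ``type:stage``, and ``residual``; columns
    ``sum_sq`` and ``df``.
    """
    if parameter not in data.parameters:
        raise ValueError(f"unknown parameter {parameter!r}")
    df = data.table.rename(columns={parameter: "value"})[["type", "stage", "value"]].copy()
    if np.ptp(df["value"].to_numpy(float)) == 0:
        raise ValueError(f"{parameter!r} has zero variance; ANOVA undefined")
    formula = "value ~ C(type) + C(stage)"
    if include_interaction:
        formula += " + C(type):C(stage)"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    rename = {
        "C(type)": "type",
        "C(stage)": "stage",
        "C(type):C(stage)": "type:stage",
        "Residual": "residual",
    }
    out = table.rename(index=rename)[["sum_sq", "df"]]
    return out


def pca_project(
    matrix: pd.DataFrame | np.ndarray, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """PCA of standardized parameters (correlation-matrix PCA).

    Parameters are standardized to zero mean and unit variance first, since
    they carry incommensurate units (s, Hz, %, dB).  Constant columns are
    dropped with a note in the loadings index.  Returns (loadings, scores,
    explained-variance fractions); loadings are orthonormal columns.
    """
    from sklearn.decomposition import PCA

    df = pd.DataFrame(matrix)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    keep = [c for c in df.columns if np.ptp(df[c].to_numpy(float)) > 0]
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-constant columns")
    X = df[keep].to_numpy(float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    k = min(n_components, X.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    loadings = pd.DataFrame(
        pca.components_.T, index=keep, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return loadings, scores, pca.explained_variance_ratio_


def compare_pre_post(data: StageLabeledFeatures) -> dict:
    """The full pre/post battery as one report.

    Per vocal type and parameter: stage medians and the Mann-Whitney test;
    per parameter: the two-way (type x stage) SS table; per stage: a PCA of
    the standardized parameters.
    """
    report: dict = {"per_type": {}, "anova": {}, "pca": {}}
    for vtype in sorted(data.table["type"].unique()):
        per_param = {}
        for param in data.parameters:
            pre = data.cell(vtype, "pre", param)
            post = data.cell(vtype, "post", param)
            pre = pre[np.isfinite(pre)]
            post = post[np.isfinite(post)]
            u, p = mann_whitney_u(pre, post)
            per_param[param] = {
                "median_pre": float(np.median(pre)),
                "median_post": float(np.median(post)),
                "median_shift": float(np.median(post) - np.median(pre)),
                "U": u,
                "p": p,
            }
        report["per_type"][int(vtype)] = per_param
    for param in data.parameters:
        try:
            ss = two_way_anova_ss(data, param)
        except ValueError:
            continue
        report["anova"][param] = {
            row: {"sum_sq": float(ss.loc[row, "sum_sq"]), "df": float(ss.loc[row, "df"])}
            for row in ss.index
        }
    for stage in STAGES:
        sub = data.table.loc[data.table["stage"] == stage, data.parameters].dropna()
        if len(sub) >= 2:
            loadings, scores, evr = pca_project(sub)
            report["pca"][stage] = {
                "explained_variance_ratio": [float(v) for v in evr],
                "loadings": loadings.to_dict(),
            }
    return report
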