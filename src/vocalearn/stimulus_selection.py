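"""Select clearly distinguishable playback stimuli from a labelled repertoire.

Two steps mirror the stimulus-preparation procedure of a two-class playback
experiment: (1) rank the acoustic parameters by how much information they
carry about the vocal-type label (binned plug-in mutual information, bits);
(2) for the top parameters, find the equal-percentile threshold p_eq — the
percentile at which the lower class's upper tail meets the upper class's
complementary lower tail — and drop every call on the wrong side, leaving a
pool whose classes no longer overlap on those parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acoustics import FEATURE_NAMES

__all__ = [
    "LabeledFeatureSet",
    "ThresholdResult",
    "mutual_information_ranking",
    "equal_percentile_threshold",
    "filter_pool",
    "select_stimulus_pool",
]


@dataclass
class LabeledFeatureSet:
    """Feature rows for a two-type repertoire.

    ``table`` columns: ``id``, ``type`` (1 or 2) plus one column per acoustic
    parameter.  Exactly two type labels must be present, each with >= 2 rows.
    """

    table: pd.DataFrame
    parameters: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self) -> None:
        missing = [c for c in ["id", "type", *self.parameters] if c not in self.table.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        counts = self.table["type"].value_counts()
        if len(counts) != 2:
            raise ValueError(f"need exactly two type labels, found {sorted(counts.index)}")
        if counts.min() < 2:
            raise ValueError("each vocal type needs at least two rows")

    @property
    def types(self) -> tuple[int, int]:
        a, b = sorted(self.table["type"].unique())
        return int(a), int(b)

    def values(self, parameter: str, vtype: int) -> np.ndarray:
        return self.table.loc[self.table["type"] == vtype, parameter].to_numpy(float)


@dataclass(frozen=True)
class ThresholdResult:
    """Equal-percentile separation threshold for one parameter.

    ``p_eq`` is the common percentile (0..1); ``threshold`` the parameter
    value at which the two empirical quantile functions cross; ``higher_type``
    the class lying above the threshold.  ``units`` records the parameter's
    unit explicitly, since thresholds on proportions-vs-percent scales are a
    classic source of confusion.
    """

    parameter: str
    p_eq: float
    threshold: float
    higher_type: int
    lower_type: int
    units: str = ""


# --------------------------------------------------------------------------
# Mutual information
# --------------------------------------------------------------------------


def _binned_mi_bits(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Plug-in MI between an equal-frequency binning of x and the labels y."""
    ranks = pd.Series(x).rank(method="average").to_numpy()
    edges = np.linspace(0, len(x), n_bins + 1)
    bins = np.clip(np.searchsorted(edges, ranks, side="left") - 1, 0, n_bins - 1)
    joint = pd.crosstab(bins, y).to_numpy(float)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


def mutual_information_ranking(
    fs: LabeledFeatureSet, n_bins: int = 16
) -> list[tuple[str, float]]:
    """Parameters ordered by MI (bits) with the vocal-type label, descending.

    Estimator: equal-frequency binning (default 16 bins) of each parameter,
    then the plug-in MI of the binned variable with the label.  MI of a
    constant parameter is 0.  Ranking ties break alphabetically.
    """
    y = fs.table["type"].to_numpy()
    scores = []
    for param in fs.parameters:
        x = fs.table[param].to_numpy(float)
        ok = np.isfinite(x)
        mi = _binned_mi_bits(x[ok], y[ok], n_bins) if ok.sum() >= 2 and np.ptp(x[ok]) > 0 else 0.0
        scores.append((param, max(mi, 0.0)))
    return sorted(scores, key=lambda kv: (-kv[1], kv[0]))


# --------------------------------------------------------------------------
# Equal-percentile threshold
# --------------------------------------------------------------------------


def equal_percentile_threshold(
    lower: np.ndarray,
    upper: np.ndarray,
    parameter: str = "",
    lower_type: int = 0,
    upper_type: int = 0,
    units: str = "",
) -> ThresholdResult:
    """Solve Q_lower(p) = Q_upper(1-p) for the common percentile p_eq.

    Quantiles are linear-interpolation empirical quantiles (type 7); the
    crossing is found by bisection to |dp| < 1e-9.  When the samples do not
    overlap, p_eq = 1 and the threshold is the midpoint of the gap.
    """
    lo = np.sort(np.asarray(lower, float))
    up = np.sort(np.asarray(upper, float))
    if lo.size == 0 or up.size == 0:
        raise ValueError("both samples must be non-empty")
    if lo.size > 1 and up.size > 1 and np.mean(up) <= np.mean(lo):
        raise ValueError("expected mean(upper) > mean(lower); swap the samples")
    if lo[0] == lo[-1] == up[0] == up[-1]:
        raise ValueError("degenerate samples: all values identical in both classes")

    if lo[-1] <= up[0]:  # disjoint (or touching) supports
        return ThresholdResult(
            parameter=parameter,
            p_eq=1.0,
            threshold=float((lo[-1] + up[0]) / 2.0),
            higher_type=upper_type,
            lower_type=lower_type,
            units=units,
        )

    def g(p: float) -> float:
        return float(np.quantile(lo, p) - np.quantile(up, 1.0 - p))

    a, b = 0.0, 1.0  # g(0) < 0 <= g(1) since supports overlap
    while b - a > 1e-9:
        mid = 0.5 * (a + b)
        if g(mid) < 0:
            a = mid
        else:
            b = mid
    p_eq = 0.5 * (a + b)
    threshold = 0.5 * (np.quantile(lo, p_eq) + np.quantile(up, 1.0 - p_eq))
    return ThresholdResult(
        parameter=parameter,
        p_eq=float(p_eq),
        threshold=float(threshold),
        higher_type=upper_type,
        lower_type=lower_type,
        units=units,
    )


def filter_pool(fs: LabeledFeatureSet, tr: ThresholdResult) -> LabeledFeatureSet:
    """Keep upper-type rows strictly above and lower-type rows strictly below
    the threshold; rows exactly at the threshold are dropped.
    """
    t = fs.table
    vals = t[tr.parameter].to_numpy(float)
    keep = np.where(
        t["type"].to_numpy() == tr.higher_type, vals > tr.threshold, vals < tr.threshold
    )
    out = t.loc[keep].reset_index(drop=True)
    for vtype in fs.types:
        if (out["type"] == vtype).sum() == 0:
            raise ValueError(
                f"filtering on {tr.parameter!r} at {tr.threshold:g} removed every "
                f"type-{vtype} vocalization"
            )
    return LabeledFeatureSet(out, parameters=fs.parameters)


def select_stimulus_pool(
    fs: LabeledFeatureSet, n_bins: int = 16, top_k_parameters: int = 2
) -> tuple[LabeledFeatureSet, list[ThresholdResult]]:
    """Full selection: rank parameters by MI, threshold the top k conjunctively.

    For each selected parameter the class with the larger mean sits above the
    threshold.  Filters are applied in ranking order; each must leave both
    classes non-empty.  Returns the filtered pool and the thresholds used.
    """
    ranking = mutual_information_ranking(fs, n_bins=n_bins)
    t1, t2 = fs.types
    pool = fs
    thresholds: list[ThresholdResult] = []
    for param, _mi in ranking[:top_k_parameters]:
        v1 = pool.values(param, t1)
        v2 = pool.values(param, t2)
        if np.mean(v1) <= np.mean(v2):
            lower, upper, lo_t, up_t = v1, v2, t1, t2
        else:
            lower, upper, lo_t, up_t = v2, v1, t2, t1
        tr = equal_percentile_threshold(
            lower, upper, parameter=param, lower_type=lo_t, upper_type=up_t
        )
        pool = filter_pool(pool, tr)
        thresholds.append(tr)
    return pool, thresholds
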