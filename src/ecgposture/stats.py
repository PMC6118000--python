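"""Per-position descriptive statistics and pairwise significance analysis.

The unit of inference is the subject, not the epoch: per-subject
per-position feature means are computed first and the position contrast
is tested with a paired two-sided t-test across subjects. (Pooling
thousands of correlated epochs would produce vanishing P values; the
subject level is the scale at which overnight position contrasts are
meaningfully replicated.) Stars follow the usual thresholds:
*** P <= 0.001, ** P <= 0.01, * P <= 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import POSITIONS
from .features import FEATURE_NAMES, SELECTED_FEATURES

__all__ = [
    "POSITION_PAIRS",
    "SignificanceResult",
    "position_summary",
    "pairwise_significance",
    "significance_table",
    "stars",
    "select_features",
]

POSITION_PAIRS = (("left", "supine"), ("left", "right"), ("supine", "right"))

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Significance stars for a P value ('' when P > 0.05 or missing)."""
    if not np.isfinite(p):
        return ""
    for threshold, mark in STAR_THRESHOLDS:
        if p <= threshold:
            return mark
    return ""


@dataclass(frozen=True)
class SignificanceResult:
    feature: str
    pair: tuple[str, str]
    p_value: float
    n_subjects: int

    @property
    def stars(self) -> str:
        return stars(self.p_value)


def position_summary(
    records: pd.DataFrame,
    features: tuple[str, ...] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Mean, SD and n of every feature per lying position.

    ``records`` is an epoch-level table with a ``position`` column.
    Returns a table indexed by feature with one (mean, sd, n) column
    triple per position; a position with no epochs gets n=0 and missing
    mean/SD.
    """
    if len(records) == 0:
        raise ValueError("need at least one epoch record")
    out: dict[str, dict] = {}
    for pos in POSITIONS:
        sub = records.loc[records["position"] == pos, list(features)]
        for feat in features:
            vals = sub[feat].dropna() if len(sub) else pd.Series(dtype=float)
            row = out.setdefault(feat, {})
            row[(pos, "n")] = int(vals.size)
            row[(pos, "mean")] = float(vals.mean()) if vals.size else math.nan
            row[(pos, "sd")] = float(vals.std(ddof=1)) if vals.size > 1 else math.nan
    frame = pd.DataFrame.from_dict(out, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    return frame.loc[list(features)]


def _subject_position_means(records: pd.DataFrame, feature: str) -> pd.DataFrame:
    return (records.groupby(["subject_id", "position"], observed=True)[feature]
            .mean().unstack("position"))


def pairwise_significance(
    records: pd.DataFrame,
    feature: str,
    pair: tuple[str, str],
    min_subjects: int = 3,
) -> SignificanceResult:
    """Paired two-sided t-test of one feature between two positions.

    Subjects contribute one mean per position; subjects lacking either
    position are dropped. Fewer than ``min_subjects`` complete pairs
    yields a missing P. All-zero differences (t = 0/0) are reported as
    P = 1: no evidence against the null.
    """
    a, b = pair
    means = _subject_position_means(records, feature)
    if a not in means.columns or b not in means.columns:
        return SignificanceResult(feature, pair, math.nan, 0)
    paired = means[[a, b]].dropna()
    n = len(paired)
    if n < min_subjects:
        return SignificanceResult(feature, pair, math.nan, n)
    diffs = paired[a].to_numpy() - paired[b].to_numpy()
    if np.allclose(diffs, 0.0):
        return SignificanceResult(feature, pair, 1.0, n)
    t = sps.ttest_rel(paired[a], paired[b])
    p = float(t.pvalue)
    if not np.isfinite(p):
        p = 1.0
    return SignificanceResult(feature, pair, p, n)


def significance_table(
    records: pd.DataFrame,
    features: tuple[str, ...] = FEATURE_NAMES,
    fdr: bool = False,
) -> pd.DataFrame:
    """All features x all three position pairs; columns hold P values and
    stars. ``fdr=True`` additionally applies a Benjamini-Hochberg
    correction per pair (off by default)."""
    rows = []
    for feat in features:
        row: dict = {"feature": feat}
        for pair in POSITION_PAIRS:
            res = pairwise_significance(records, feat, pair)
            key = f"{pair[0]}-{pair[1]}"
            row[f"P_{key}"] = res.p_value
            row[f"stars_{key}"] = res.stars
        rows.append(row)
    table = pd.DataFrame(rows).set_index("feature")
    if fdr:
        for pair in POSITION_PAIRS:
            key = f"P_{pair[0]}-{pair[1]}"
            p = table[key].to_numpy(dtype=float)
            ok = np.isfinite(p)
            adj = np.full_like(p, math.nan)
            if ok.any():
                adj[ok] = sps.false_discovery_control(p[ok], method="bh")
            table[key + "_fdr"] = adj
    return table


def select_features() -> tuple[str, ...]:
    """The fixed 12-feature subset used for classification.

    The selection is adopted verbatim from the significance analysis of
    the reference study (strongly position-dependent features), not
    re-derived from the data at hand.
    """
    return SELECTED_FEATURES
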