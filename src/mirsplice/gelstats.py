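"""Exon-inclusion rates from gel densitometry and normality-gated testing.

The inclusion rate divides each band's integrated volume V by its amplicon
length N (longer products bind more stain per molecule) before forming the
molar ratio:

    rate = (V_inc / N_inc) / (V_inc / N_inc + V_skip / N_skip)

Group comparisons follow a normality gate: Shapiro-Wilk on each group at
alpha 0.05; when both groups pass, a classical pooled-variance two-sample
Student's t-test (Welch available behind ``equal_var=False``), otherwise a
two-sided Mann-Whitney U (exact for small tie-free samples, normal
approximation with continuity and tie correction otherwise).  Significance
stars: ``**`` for p < 0.01, ``*`` for 0.01 <= p < 0.05, strict at both
cut points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class BandMeasurement:
    """One gel band: sample, isoform, volume V (densitometry units), length N (nt)."""

    sample: str
    isoform: str  # "included" | "skipped"
    volume: float
    length_nt: float
    group: str = ""

    def __post_init__(self):
        if self.isoform not in ("included", "skipped"):
            raise ValueError(f"isoform must be included/skipped, got {self.isoform!r}")
        if self.length_nt <= 0:
            raise ValueError(f"band {self.sample}/{self.isoform}: length must be > 0")
        if not np.isfinite(self.volume) or self.volume < 0:
            raise ValueError(f"band {self.sample}/{self.isoform}: invalid volume")


@dataclass(frozen=True)
class GroupComparison:
    test_used: str  # "student_t" | "mann_whitney"
    statistic: float
    p_value: float
    normality_p: tuple
    stars: str


def stars_for(p: float) -> str:
    """Significance annotation: '**' below 0.01, '*' below 0.05, else ''."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def exon_inclusion_rate(included: BandMeasurement, skipped: BandMeasurement) -> float:
    """Length-normalized inclusion rate from one sample's two bands."""
    if included.sample != skipped.sample:
        raise ValueError(
            f"band sample ids differ: {included.sample!r} vs {skipped.sample!r}"
        )
    if included.isoform != "included" or skipped.isoform != "skipped":
        raise ValueError("arguments must be the included and skipped band, in order")
    inc = included.volume / included.length_nt
    skip = skipped.volume / skipped.length_nt
    if inc == 0 and skip == 0:
        raise ValueError(f"sample {included.sample!r}: both band volumes are zero")
    return inc / (inc + skip)


def inclusion_rates(bands: pd.DataFrame) -> pd.DataFrame:
    """Per-sample inclusion rates from a band table.

    Expects columns sample, group, isoform, volume, length_nt with exactly
    one included and one skipped band per sample.
    """
    rows = []
    for sample, sub in bands.groupby("sample", sort=True):
        by_iso = {r.isoform: r for r in sub.itertuples(index=False)}
        if set(by_iso) != {"included", "skipped"} or len(sub) != 2:
            raise ValueError(
                f"sample {sample!r}: need exactly one included and one skipped band"
            )
        inc, skip = by_iso["included"], by_iso["skipped"]
        rate = exon_inclusion_rate(
            BandMeasurement(sample, "included", inc.volume, inc.length_nt, inc.group),
            BandMeasurement(sample, "skipped", skip.volume, skip.length_nt, skip.group),
        )
        rows.append((sample, inc.group, rate))
    return pd.DataFrame(rows, columns=["sample", "group", "inclusion_rate"])


def gated_compare(a, b, alpha_norm: float = 0.05, equal_var: bool = True) -> GroupComparison:
    """Two-sample comparison with a Shapiro-Wilk normality gate.

    Both groups normal at ``alpha_norm`` -> Student's t-test (pooled
    variance unless ``equal_var=False``); otherwise Mann-Whitney U.  Groups
    need >= 3 observations (the normality test is undefined below that).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError(
            f"each group needs >= 3 observations (got {a.size} and {b.size})"
        )

    def _shapiro_p(x):
        if np.ptp(x) == 0:  # constant sample: normality test degenerate
            return 0.0
        return float(stats.shapiro(x).pvalue)

    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # identical constants: no evidence of any difference
        return GroupComparison("student_t", 0.0, 1.0, (1.0, 1.0), "")

    norm_a, norm_b = _shapiro_p(a), _shapiro_p(b)
    if norm_a > alpha_norm and norm_b > alpha_norm:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        test = "student_t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        test = "mann_whitney"
    p = float(res.pvalue)
    return GroupComparison(test, float(res.statistic), p, (norm_a, norm_b), stars_for(p))


def relative_reporter_activity(
    wells: pd.DataFrame, control_group: str
) -> tuple[pd.DataFrame, dict]:
    """Renilla/Firefly ratios normalized to the control group's mean ratio.

    ``wells`` needs columns well, group, renilla, firefly.  Returns the
    per-well normalized ratio table and a dict of
    ``{treatment group: GroupComparison}`` against the control.
    """
    for col in ("well", "group", "renilla", "firefly"):
        if col not in wells.columns:
            raise ValueError(f"wells table missing column {col!r}")
    bad = wells.loc[wells["firefly"] <= 0, "well"].tolist()
    if bad:
        raise ValueError(f"non-positive Firefly signal in well(s): {bad}")
    if control_group not in set(wells["group"]):
        raise ValueError(f"control group {control_group!r} not present")

    out = wells.copy()
    out["ratio"] = out["renilla"] / out["firefly"]
    control_mean = out.loc[out["group"] == control_group, "ratio"].mean()
    out["normalized"] = out["ratio"] / control_mean

    comparisons = {}
    control_vals = out.loc[out["group"] == control_group, "normalized"].to_numpy()
    for group in sorted(set(out["group"]) - {control_group}):
        vals = out.loc[out["group"] == group, "normalized"].to_numpy()
        comparisons[group] = gated_compare(vals, control_vals)
    return out, comparisons
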