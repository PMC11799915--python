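"""Per-week miRNA differential expression and temporal categorization.

The screen is deliberately simple and auditable: counts-per-million with a
pseudocount, a two-sided Welch t-test on log2(CPM + c) between the hypoxia
and normoxia groups of one week, and Benjamini-Hochberg adjustment across
features within that week.  Downstream stages consume only (log2FC, p) and
are agnostic to the test that produced them.

Significance thresholds are strict inequalities: a feature is called at
p < p_thresh AND |log2FC| > lfc_thresh.  miRNA screening conventionally
uses the raw p-value here, gene-level DEG screening the adjusted one; both
are exposed through ``use_adjusted``.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirsplice.simulate import category_of

logger = logging.getLogger(__name__)

_SAMPLE_RE = re.compile(r"^(?P<condition>Nor|IH)_w(?P<week>\d+)_r(?P<replicate>\d+)$")

PSEUDOCOUNT = 0.5


def parse_sample_metadata(columns: Iterable[str]) -> pd.DataFrame:
    """Decode ``<condition>_w<week>_r<rep>`` column names into a metadata frame."""
    rows = []
    for col in columns:
        m = _SAMPLE_RE.match(col)
        if m is None:
            raise ValueError(
                f"sample name {col!r} does not match '<Nor|IH>_w<week>_r<rep>'"
            )
        rows.append((col, m["condition"], int(m["week"]), int(m["replicate"])))
    meta = pd.DataFrame(rows, columns=["sample", "condition", "week", "replicate"])
    return meta.set_index("sample")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million library-size normalization, per sample column."""
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        bad = libsize.index[libsize == 0].tolist()
        raise ValueError(f"zero library size in sample(s): {bad}")
    return counts / libsize * 1e6


def compute_de(
    counts: pd.DataFrame, week: int, pseudocount: float = PSEUDOCOUNT
) -> pd.DataFrame:
    """Differential expression of every feature at one week, IH vs Nor.

    Returns a frame with columns feature, week, log2FC, pvalue, padj,
    direction (direction from the default screen thresholds; re-derive with
    :func:`screen_significant` for other settings).  Features with zero
    counts in every sample of the week are dropped and logged.
    """
    meta = parse_sample_metadata(counts.columns)
    weeks_present = sorted(int(w) for w in meta["week"].unique())
    if week not in weeks_present:
        raise ValueError(f"week {week} not in count matrix; available: {weeks_present}")

    ih_cols = meta.index[(meta["week"] == week) & (meta["condition"] == "IH")]
    nor_cols = meta.index[(meta["week"] == week) & (meta["condition"] == "Nor")]
    if len(ih_cols) < 2 or len(nor_cols) < 2:
        raise ValueError(
            f"week {week}: need >= 2 replicates per condition "
            f"(IH={len(ih_cols)}, Nor={len(nor_cols)})"
        )
    sub = counts[list(ih_cols) + list(nor_cols)]
    allzero = sub.sum(axis=1) == 0
    if allzero.any():
        logger.info(
            "week %d: dropping %d feature(s) with all-zero counts: %s",
            week, int(allzero.sum()), list(sub.index[allzero][:10]),
        )
        sub = sub.loc[~allzero]

    norm = cpm(counts.loc[sub.index])
    log_ih = np.log2(norm[ih_cols] + pseudocount)
    log_nor = np.log2(norm[nor_cols] + pseudocount)
    lfc = np.log2(
        (norm[ih_cols].mean(axis=1) + pseudocount)
        / (norm[nor_cols].mean(axis=1) + pseudocount)
    )

    res = stats.ttest_ind(log_ih, log_nor, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    pvals[~np.isfinite(pvals)] = 1.0  # zero-variance ties: no evidence
    padj = multipletests(pvals, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "feature": sub.index,
            "week": week,
            "log2FC": lfc.to_numpy(),
            "pvalue": pvals,
            "padj": padj,
        }
    ).reset_index(drop=True)
    sig = screen_significant(out, 0.05, 1.0, use_adjusted=False)
    out["direction"] = np.where(
        ~out["feature"].isin(sig), "none", np.where(out["log2FC"] < 0, "down", "up")
    )
    return out


def screen_significant(
    records: pd.DataFrame,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    use_adjusted: bool = False,
) -> set:
    """Features passing (p < p_thresh) AND (|log2FC| > lfc_thresh), both strict."""
    if p_thresh <= 0 or lfc_thresh <= 0:
        raise ValueError("thresholds must be positive")
    pcol = "padj" if use_adjusted else "pvalue"
    mask = (records[pcol] < p_thresh) & (records["log2FC"].abs() > lfc_thresh)
    return set(records.loc[mask, "feature"])


def categorize_temporal(
    per_week_sig: Mapping[int, set], records: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Assign each screened miRNA to one of the three temporal categories.

    Category 1: significant at weeks {1,3,5}, week 7 optional; category 2:
    exactly {3,5,7}; category 3: exactly {5,7}; anything else: none.
    ``direction_consistent`` is true when every significant week shows
    downregulation (requires ``records`` with a direction column; without
    it the flag is left null).
    """
    all_feats = sorted(set().union(*per_week_sig.values()) if per_week_sig else set())
    directions = {}
    if records is not None:
        for row in records.itertuples(index=False):
            directions[(row.feature, row.week)] = row.log2FC

    rows = []
    for feat in all_feats:
        sig_weeks = frozenset(w for w, s in per_week_sig.items() if feat in s)
        cat = category_of(sig_weeks)
        if records is not None:
            consistent = all(
                directions.get((feat, w), 0.0) < 0 for w in sig_weeks
            )
        else:
            consistent = None
        rows.append(
            (
                feat,
                ",".join(str(w) for w in sorted(sig_weeks)),
                cat if cat is not None else "none",
                consistent,
            )
        )
    return pd.DataFrame(
        rows, columns=["mirna", "significant_weeks", "category", "direction_consistent"]
    )
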