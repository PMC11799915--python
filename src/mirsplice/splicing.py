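"""Alternative-splicing event overlap, same-site matching and |dPSI| ranking.

Event tables follow an rMATS-like schema (0-based half-open coordinates,
per-sample inclusion/skipping junction counts, length-normalized inclusion
levels).  The screen intersects the genes carrying significant events of
each type in two tables (treatment-induced vs splicing-factor knockdown),
refines the intersection to events sharing the full coordinate key, filters
by mean junction support, and ranks the survivors by |dPSI|.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_KEY_COLS = ["gene", "event_type", "chrom", "strand", "c1", "c2", "c3", "c4"]


def compute_psi(
    inclusion_counts: int, skipping_counts: int, inc_len: float, skip_len: float
) -> float:
    """Length-normalized inclusion level from junction counts.

    psi = (I / inc_len) / (I / inc_len + S / skip_len).  With both counts
    zero the level is undefined and NaN is returned (callers exclude such
    samples from group means).
    """
    if inc_len <= 0 or skip_len <= 0:
        raise ValueError("form lengths must be positive")
    if inclusion_counts < 0 or skipping_counts < 0:
        raise ValueError("junction counts must be nonnegative")
    if inclusion_counts == 0 and skipping_counts == 0:
        return float("nan")
    inc = inclusion_counts / inc_len
    skip = skipping_counts / skip_len
    return inc / (inc + skip)


def _parse_counts(field: str) -> np.ndarray:
    return np.array([int(x) for x in str(field).split(",")], dtype=int)


def mean_reads(event_row, side: str = "ih", kd_row=None) -> float:
    """Mean per-sample junction support (inclusion + skipping) of an event.

    ``side='ih'`` averages over the treatment table's samples only;
    ``side='both'`` pools in the knockdown-side samples as well.
    """
    totals = _parse_counts(event_row["ijc"]) + _parse_counts(event_row["sjc"])
    if side == "both":
        if kd_row is None:
            raise ValueError("side='both' requires the matched knockdown event")
        totals = np.concatenate(
            [totals, _parse_counts(kd_row["ijc"]) + _parse_counts(kd_row["sjc"])]
        )
    elif side != "ih":
        raise ValueError(f"unknown reads side {side!r}")
    return float(totals.mean())


def overlap_by_gene(
    ih: pd.DataFrame, kd: pd.DataFrame, p_thresh: float = 0.05
) -> dict:
    """Per-event-type gene intersections between two significant-event tables.

    For each event type independently, returns the set of gene symbols
    carrying an event of that type with p < ``p_thresh`` (strict) in both
    tables.
    """
    out = {}
    for etype in sorted(set(ih["event_type"]) | set(kd["event_type"])):
        g_ih = set(ih.loc[(ih["event_type"] == etype) & (ih["pvalue"] < p_thresh), "gene"])
        g_kd = set(kd.loc[(kd["event_type"] == etype) & (kd["pvalue"] < p_thresh), "gene"])
        common = g_ih & g_kd
        if common:
            out[etype] = common
    return out


def match_same_site(
    ih: pd.DataFrame,
    kd: pd.DataFrame,
    gene_overlap: Mapping[str, set] | None = None,
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Pairs of events identical in gene, type, chrom, strand and coordinates.

    Restricted to genes in the per-type overlap (computed on the fly when
    not supplied).  Returns one row per matched pair with the shared key
    plus each side's dPSI and p-value.
    """
    if gene_overlap is None:
        gene_overlap = overlap_by_gene(ih, kd, p_thresh)

    def _restrict(df):
        keep = pd.Series(False, index=df.index)
        for etype, genes in gene_overlap.items():
            keep |= (df["event_type"] == etype) & df["gene"].isin(genes)
        return df[keep & (df["pvalue"] < p_thresh)]

    ih_r, kd_r = _restrict(ih), _restrict(kd)
    kd_side = kd_r[_KEY_COLS + ["ijc", "sjc", "delta_psi", "pvalue"]].rename(
        columns={"ijc": "ijc_kd", "sjc": "sjc_kd"}
    )
    return ih_r.merge(kd_side, on=_KEY_COLS, suffixes=("_ih", "_kd"))


def rank_events(
    matched: pd.DataFrame,
    min_mean_reads: float = 10.0,
    k: int = 3,
    reads_side: str = "ih",
    signed: bool = False,
) -> pd.DataFrame:
    """Filter matched events by mean reads, rank by dPSI magnitude.

    Events whose mean per-sample junction support is <= ``min_mean_reads``
    (strict filter: exactly the threshold is excluded) are dropped; the
    rest are sorted by descending |dPSI| of the treatment-side event
    (signed dPSI descending when ``signed``), ties broken lexicographically
    by gene symbol then coordinates.  The full ranking is returned with a
    ``rank`` column and a ``top`` flag on the first ``k`` rows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = matched.copy()
    if df.empty:
        df["mean_reads"] = pd.Series(dtype=float)
        df["rank"] = pd.Series(dtype=int)
        df["top"] = pd.Series(dtype=bool)
        return df
    if reads_side not in ("ih", "both"):
        raise ValueError(f"unknown reads side {reads_side!r}")
    means = []
    for _, row in df.iterrows():
        totals = _parse_counts(row["ijc"]) + _parse_counts(row["sjc"])
        if reads_side == "both":
            totals = np.concatenate(
                [totals, _parse_counts(row["ijc_kd"]) + _parse_counts(row["sjc_kd"])]
            )
        means.append(float(totals.mean()))
    df["mean_reads"] = means
    df = df[df["mean_reads"] > min_mean_reads].copy()

    key = df["delta_psi_ih"] if signed else df["delta_psi_ih"].abs()
    df["_key"] = -key
    df = df.sort_values(
        by=["_key", "gene", "c1", "c2", "c3", "c4"], kind="mergesort"
    ).drop(columns="_key")
    df["rank"] = np.arange(1, len(df) + 1)
    df["top"] = df["rank"] <= k
    if len(df) < k:
        logger.info("only %d event(s) survive the reads filter (requested top %d)",
                    len(df), k)
    return df.reset_index(drop=True)


def as_screen(
    ih: pd.DataFrame,
    kd: pd.DataFrame,
    p_thresh: float = 0.05,
    min_mean_reads: float = 10.0,
    k: int = 3,
    reads_side: str = "ih",
    signed: bool = False,
) -> dict:
    """Full overlap -> same-site -> filter/rank cascade.

    Returns a dict with ``gene_overlap`` (per-type sets), ``same_site``
    (matched-pair frame) and ``ranked`` (filtered, ranked frame).
    """
    overlap = overlap_by_gene(ih, kd, p_thresh)
    matched = match_same_site(ih, kd, overlap, p_thresh)
    ranked = rank_events(matched, min_mean_reads, k, reads_side=reads_side, signed=signed)
    return {"gene_overlap": overlap, "same_site": matched, "ranked": ranked}
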