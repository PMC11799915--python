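"""Consensus miRNA target prediction and DEG intersection.

A gene is a *candidate* target of a miRNA when the pair is predicted by at
least two of three databases (membership only — no database-specific
scores).  A candidate becomes a *predicted* target at a week when it is
also upregulated among that week's DEGs, evaluated only at the weeks where
the miRNA itself changed.  Gene symbols are matched case-insensitively;
the first-seen spelling is reported.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd


def _normalize_pairs(db: pd.DataFrame) -> set:
    return {
        (str(m).casefold(), str(g).casefold())
        for m, g in zip(db["mirna"], db["gene"])
    }


def candidate_targets(mirna: str, dbs: Mapping[str, pd.DataFrame]) -> set:
    """Genes predicted as targets of ``mirna`` by >= 2 of the three databases.

    ``dbs`` maps database ids (three distinct keys) to frames with columns
    ``mirna`` and ``gene``.
    """
    if len(dbs) != 3:
        raise ValueError(f"exactly three databases required, got {sorted(dbs)}")
    mkey = mirna.casefold()
    votes: dict[str, int] = {}
    spelling: dict[str, str] = {}
    for db in dbs.values():
        seen_here = set()
        for m, g in zip(db["mirna"], db["gene"]):
            if str(m).casefold() != mkey:
                continue
            gkey = str(g).casefold()
            if gkey in seen_here:  # duplicates within one db count once
                continue
            seen_here.add(gkey)
            votes[gkey] = votes.get(gkey, 0) + 1
            spelling.setdefault(gkey, str(g))
    return {spelling[g] for g, n in votes.items() if n >= 2}


def load_target_dbs(frames: Mapping[str, pd.DataFrame]) -> Mapping[str, pd.DataFrame]:
    """Validate a db-id -> pair-list mapping (distinct ids, required columns)."""
    if len(set(frames)) != len(frames):
        raise ValueError("duplicate database ids")
    for db_id, frame in frames.items():
        missing = {"mirna", "gene"} - set(frame.columns)
        if missing:
            raise ValueError(f"database {db_id!r} missing columns {sorted(missing)}")
    return frames


def predicted_targets(
    mirna: str,
    candidates: set,
    up_degs_by_week: Mapping[int, set],
    sig_weeks: set,
) -> dict:
    """Candidates upregulated at each week where the miRNA changed.

    Returns ``{week: gene set}`` over ``sig_weeks`` only; a week with no
    DEG table entry yields an empty set.  An empty result at every week
    flags the miRNA as target-less at its change points.
    """
    cand_keys = {g.casefold(): g for g in candidates}
    out = {}
    for week in sorted(sig_weeks):
        up = {str(g).casefold() for g in up_degs_by_week.get(week, set())}
        out[week] = {orig for key, orig in cand_keys.items() if key in up}
    return out


def shared_targets(
    sets_a: Mapping[int, set], sets_b: Mapping[int, set], week: int
) -> set:
    """Intersection of two miRNAs' predicted targets at one week."""
    for label, sets_ in (("first", sets_a), ("second", sets_b)):
        if week not in sets_:
            raise ValueError(
                f"week {week} absent from the {label} miRNA's predicted targets "
                f"(available: {sorted(sets_)})"
            )
    a = {g.casefold(): g for g in sets_a[week]}
    return {a[k] for k in a.keys() & {g.casefold() for g in sets_b[week]}}


def target_screen(
    dbs: Mapping[str, pd.DataFrame],
    categories: pd.DataFrame,
    up_degs_by_week: Mapping[int, set],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full consensus screen for every categorized miRNA.

    Returns (per-miRNA target table, pairwise shared-target table).  The
    target table reports, per miRNA and week, the candidate and predicted
    sets; the shared table lists genes common to two miRNAs' predictions
    at one week.
    """
    dbs = load_target_dbs(dbs)
    cat = categories[categories["category"] != "none"]

    per_mirna: dict[str, dict[int, set]] = {}
    rows = []
    for row in cat.itertuples(index=False):
        sig_weeks = {int(w) for w in str(row.significant_weeks).split(",") if w}
        cands = candidate_targets(row.mirna, dbs)
        preds = predicted_targets(row.mirna, cands, up_degs_by_week, sig_weeks)
        per_mirna[row.mirna] = preds
        for week in sorted(sig_weeks):
            rows.append(
                (
                    row.mirna,
                    week,
                    ";".join(sorted(cands)),
                    ";".join(sorted(preds[week])),
                )
            )
    targets = pd.DataFrame(
        rows, columns=["mirna", "week", "candidate_targets", "predicted_targets"]
    )

    shared_rows = []
    mirnas = sorted(per_mirna)
    for i, ma in enumerate(mirnas):
        for mb in mirnas[i + 1 :]:
            for week in sorted(set(per_mirna[ma]) & set(per_mirna[mb])):
                common = shared_targets(per_mirna[ma], per_mirna[mb], week)
                if common:
                    shared_rows.append((ma, mb, week, ";".join(sorted(common))))
    shared = pd.DataFrame(
        shared_rows, columns=["mirna_a", "mirna_b", "week", "shared_targets"]
    )
    return targets, shared
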