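"""Synthetic inputs with planted ground truth.

Every pipeline input — miRNA count matrix, per-week DEG tables, three
target-prediction pair lists, two differential-splicing event tables, gel
band densitometry — is generated from a single :class:`SimConfig` whose
seed fully determines the output.  A :class:`GroundTruth` sidecar records
what was planted, so downstream stages can be checked against it without
re-deriving anything from the generator's internals.

Count model
-----------
miRNA counts are negative-binomial with a single shared dispersion
``alpha`` (variance ``mu + alpha * mu**2``).  A miRNA planted with
``log2_effect`` at a set of affected weeks has its hypoxia-group mean
multiplied by ``2**log2_effect`` at those weeks only; all other means are
shared between groups.  Gel band volumes are the true isoform abundance
times amplicon length times multiplicative lognormal noise, mirroring how
densitometry error scales with band intensity.

All randomness flows from the config seed through one independent
generator stream per output artifact, so adding an artifact never perturbs
another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DB_IDS = ("A", "B", "C")
EVENT_TYPES = ("SE", "RI", "MXE", "A5SS", "A3SS")
CONDITIONS = ("Nor", "IH")

# fixed order: spawn index per artifact; append-only so streams are stable
_STREAMS = ("counts", "degs", "target_dbs", "as_events", "gel_bands")

# temporal category templates (weeks at which expression must change);
# category 1 tolerates week 7 because two of its members also change there
CATEGORY_CORE = {1: frozenset({1, 3, 5}), 2: frozenset({3, 5, 7}), 3: frozenset({5, 7})}
CATEGORY_OPTIONAL = {1: frozenset({7}), 2: frozenset(), 3: frozenset()}


def category_of(significant_weeks: Iterable[int]) -> int | None:
    """Map a set of significant weeks onto a temporal category.

    Category 1: weeks {1,3,5} all significant (7 optional); category 2:
    exactly {3,5,7}; category 3: exactly {5,7}.  Any other pattern maps to
    ``None`` rather than the nearest template.
    """
    sw = frozenset(significant_weeks)
    for cat in (1, 2, 3):
        core, optional = CATEGORY_CORE[cat], CATEGORY_OPTIONAL[cat]
        if core <= sw and sw <= (core | optional):
            return cat
    return None


@dataclass(frozen=True)
class PlantedMirna:
    """A miRNA planted as differentially expressed at given weeks."""

    name: str
    category: int
    log2_effect: float  # <= -1: downregulation under hypoxia
    affected_weeks: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "affected_weeks", frozenset(self.affected_weeks))
        if self.log2_effect > -1:
            raise ValueError(
                f"planted miRNA {self.name!r}: log2_effect must be <= -1, "
                f"got {self.log2_effect}"
            )
        if category_of(self.affected_weeks) != self.category:
            raise ValueError(
                f"planted miRNA {self.name!r}: affected_weeks "
                f"{sorted(self.affected_weeks)} inconsistent with category "
                f"{self.category}"
            )


@dataclass(frozen=True)
class PlantedTarget:
    """A miRNA->gene pair planted in prediction databases and DEG tables."""

    mirna: str
    gene: str
    db_membership: frozenset = frozenset()  # subset of {A, B, C}, nonempty
    upregulated_weeks: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "db_membership", frozenset(self.db_membership))
        object.__setattr__(self, "upregulated_weeks", frozenset(self.upregulated_weeks))
        if not self.db_membership:
            raise ValueError(
                f"planted target ({self.mirna}, {self.gene}): db_membership empty"
            )
        if not self.db_membership <= set(DB_IDS):
            raise ValueError(
                f"planted target ({self.mirna}, {self.gene}): unknown db in "
                f"{sorted(self.db_membership)}"
            )


@dataclass(frozen=True)
class PlantedEvent:
    """A differential splicing event planted in the hypoxia event table.

    ``same_site_in_kd`` plants the identical coordinate key in the
    knockdown table; otherwise the knockdown table carries an event of the
    same type in the same gene at shifted coordinates (gene-level overlap
    only).  ``in_kd=False`` keeps the event out of the knockdown table
    entirely.
    """

    gene: str
    event_type: str
    chrom: str
    strand: str
    coords: tuple  # 0-based half-open, ascending
    delta_psi: float
    mean_reads: float
    same_site_in_kd: bool = False
    in_kd: bool = True

    def __post_init__(self):
        object.__setattr__(self, "coords", tuple(int(c) for c in self.coords))
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if len(self.coords) != 4 or list(self.coords) != sorted(self.coords):
            raise ValueError(
                f"event {self.gene}: coordinates must be an ascending 4-tuple, "
                f"got {self.coords}"
            )
        if not -1 <= self.delta_psi <= 1:
            raise ValueError(f"event {self.gene}: delta_psi outside [-1, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic dataset.

    Defaults follow the study design being emulated: four exposure weeks
    (1, 3, 5, 7), three replicates per group per week, and thresholds that
    planted effects clear by construction.
    """

    seed: int = 0
    n_replicates: int = 3
    weeks: tuple = (1, 3, 5, 7)
    n_mirnas: int = 300
    n_genes: int = 2000
    nb_dispersion: float = 0.1
    baseline_mean: float = 200.0
    planted_mirnas: tuple = ()
    planted_targets: tuple = ()
    planted_events: tuple = ()
    gel_noise_cv: float = 0.1
    # gel design: true inclusion rate per group, samples per group
    gel_true_psi: tuple = (("Nor", 0.70), ("IH", 0.35))
    n_gel_samples: int = 3
    gel_inc_len: int = 300
    gel_skip_len: int = 200
    # decoy structure
    n_decoy_targets_per_db: int = 20
    n_background_events: int = 40

    def __post_init__(self):
        object.__setattr__(self, "weeks", tuple(sorted(self.weeks)))
        object.__setattr__(self, "planted_mirnas", tuple(self.planted_mirnas))
        object.__setattr__(self, "planted_targets", tuple(self.planted_targets))
        object.__setattr__(self, "planted_events", tuple(self.planted_events))
        object.__setattr__(self, "gel_true_psi", tuple(self.gel_true_psi))
        if self.n_replicates < 2:
            raise ValueError(f"n_replicates must be >= 2, got {self.n_replicates}")
        if not self.weeks:
            raise ValueError("weeks must be nonempty")
        if self.nb_dispersion <= 0:
            raise ValueError(f"nb_dispersion must be positive, got {self.nb_dispersion}")
        if self.baseline_mean <= 0:
            raise ValueError(f"baseline_mean must be positive, got {self.baseline_mean}")
        if self.gel_noise_cv < 0:
            raise ValueError(f"gel_noise_cv must be >= 0, got {self.gel_noise_cv}")
        for pm in self.planted_mirnas:
            if not pm.affected_weeks <= set(self.weeks):
                raise ValueError(
                    f"planted miRNA {pm.name!r}: affected_weeks outside "
                    f"configured weeks {self.weeks}"
                )


@dataclass
class GroundTruth:
    """What was planted, in the terms the downstream screen reports.

    Derivable from the config alone; written as a JSON sidecar next to
    every generated dataset.
    """

    mirna_categories: dict = field(default_factory=dict)  # name -> category
    de_sets: dict = field(default_factory=dict)  # week -> sorted miRNA names
    up_deg_sets: dict = field(default_factory=dict)  # week -> sorted gene names
    candidate_targets: dict = field(default_factory=dict)  # mirna -> sorted genes
    predicted_targets: dict = field(default_factory=dict)  # mirna -> {week: genes}
    shared_targets: dict = field(default_factory=dict)  # "mA|mB|week" -> genes
    gene_overlap: dict = field(default_factory=dict)  # event_type -> sorted genes
    same_site_genes: list = field(default_factory=list)
    ranked_events: list = field(default_factory=list)  # post-filter, |dPSI| desc
    top_event_types: list = field(default_factory=list)
    gel_psi: dict = field(default_factory=dict)  # sample id -> true inclusion rate

    def to_json(self) -> str:
        def _convert(obj):
            if isinstance(obj, dict):
                return {str(k): _convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_convert(v) for v in obj]
            return obj

        return json.dumps(_convert(asdict(self)), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        gt = cls(**raw)
        gt.de_sets = {int(k): v for k, v in gt.de_sets.items()}
        gt.up_deg_sets = {int(k): v for k, v in gt.up_deg_sets.items()}
        gt.predicted_targets = {
            m: {int(w): g for w, g in by_week.items()}
            for m, by_week in gt.predicted_targets.items()
        }
        return gt


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


def _nb_draw(rng: np.random.Generator, mean, dispersion: float):
    """Negative-binomial counts with variance mean + dispersion * mean**2."""
    size = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _mirna_names(config: SimConfig) -> list:
    names = [pm.name for pm in config.planted_mirnas]
    i = 0
    while len(names) < config.n_mirnas:
        cand = f"mmu-mir-sim-{i:04d}"
        if cand not in names:
            names.append(cand)
        i += 1
    return names


def _gene_names(config: SimConfig) -> list:
    uniq, seen = [], set()
    for n in (pt.gene for pt in config.planted_targets):
        if n not in seen:
            uniq.append(n)
            seen.add(n)
    i = 0
    while len(uniq) < config.n_genes:
        cand = f"Gene{i:05d}"
        if cand not in seen:
            uniq.append(cand)
            seen.add(cand)
        i += 1
    return uniq


def sample_name(condition: str, week: int, replicate: int) -> str:
    return f"{condition}_w{week}_r{replicate}"


def simulate_mirna_counts(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the miRNA count matrix (features x samples).

    Column names encode condition, week and replicate as ``IH_w3_r2``.
    Returns the matrix and a truth object holding planted categories and
    per-week true DE sets.
    """
    rng = _rng(config, "counts")
    names = _mirna_names(config)
    planted = {pm.name: pm for pm in config.planted_mirnas}

    # per-feature baseline expression, shared between groups and weeks
    base = config.baseline_mean * rng.lognormal(mean=0.0, sigma=0.8, size=len(names))

    columns, data = [], []
    for week in config.weeks:
        for cond in CONDITIONS:
            effect = np.ones(len(names))
            if cond == "IH":
                for i, name in enumerate(names):
                    pm = planted.get(name)
                    if pm is not None and week in pm.affected_weeks:
                        effect[i] = 2.0 ** pm.log2_effect
            for rep in range(1, config.n_replicates + 1):
                columns.append(sample_name(cond, week, rep))
                data.append(_nb_draw(rng, base * effect, config.nb_dispersion))
    counts = pd.DataFrame(
        np.column_stack(data), index=pd.Index(names, name="feature"), columns=columns
    )

    truth = GroundTruth(
        mirna_categories={pm.name: pm.category for pm in config.planted_mirnas},
        de_sets={
            w: sorted(pm.name for pm in config.planted_mirnas if w in pm.affected_weeks)
            for w in config.weeks
        },
    )
    return counts, truth


def simulate_deg_tables(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate per-week DEG tables as one tidy frame (gene, week, log2FC, pvalue, padj).

    Planted (gene, week) upregulations pass log2FC > 1 and padj < 0.05 by
    construction; every decoy row fails at least one of the two thresholds.
    """
    rng = _rng(config, "degs")
    genes = _gene_names(config)
    up_by_week = {w: set() for w in config.weeks}
    for pt in config.planted_targets:
        for w in pt.upregulated_weeks:
            if w in up_by_week:
                up_by_week[w].add(pt.gene)

    rows = []
    for week in config.weeks:
        seen = set()
        for gene in genes:
            if gene in seen:
                raise ValueError(f"duplicate gene id {gene!r} in week {week} table")
            seen.add(gene)
            if gene in up_by_week[week]:
                lfc = rng.uniform(1.2, 4.0)
                padj = rng.uniform(1e-8, 0.04)
            else:
                mode = rng.random()
                if mode < 0.5:  # small fold change, any p
                    lfc = rng.uniform(-1.0, 1.0)
                    padj = rng.uniform(0.0, 1.0)
                elif mode < 0.75:  # non-significant, any fold change
                    lfc = rng.uniform(-4.0, 4.0)
                    padj = rng.uniform(0.05, 1.0)
                else:  # significantly downregulated: fails the "up" screen
                    lfc = rng.uniform(-4.0, -1.2)
                    padj = rng.uniform(1e-8, 0.04)
            pval = padj * rng.uniform(0.05, 1.0)
            rows.append((gene, week, lfc, pval, padj))
    degs = pd.DataFrame(rows, columns=["gene", "week", "log2FC", "pvalue", "padj"])

    truth = GroundTruth(up_deg_sets={w: sorted(s) for w, s in up_by_week.items()})
    return degs, truth


def simulate_target_dbs(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the three target-prediction pair lists as one tidy frame
    (db, mirna, gene).

    Planted pairs appear in exactly their stated databases; decoy pairs
    appear in exactly one database, so the 2-of-3 consensus recovers the
    planted candidates and nothing else.
    """
    rng = _rng(config, "target_dbs")
    genes = _gene_names(config)
    planted_genes = {pt.gene for pt in config.planted_targets}
    decoy_pool = [g for g in genes if g not in planted_genes]

    rows = []
    for pt in config.planted_targets:
        for db in sorted(pt.db_membership):
            rows.append((db, pt.mirna, pt.gene))

    mirnas = sorted({pt.mirna for pt in config.planted_targets})
    n_decoy = config.n_decoy_targets_per_db
    for mirna in mirnas:
        if 3 * n_decoy > len(decoy_pool):
            raise ValueError("n_genes too small for requested decoy targets")
        picked = rng.choice(len(decoy_pool), size=3 * n_decoy, replace=False)
        for j, db in enumerate(DB_IDS):
            for idx in picked[j * n_decoy : (j + 1) * n_decoy]:
                rows.append((db, mirna, decoy_pool[idx]))
    dbs = pd.DataFrame(rows, columns=["db", "mirna", "gene"]).drop_duplicates()

    # brute-force truth: candidates = pairs in >= 2 databases
    candidates = {}
    for pt in config.planted_targets:
        if len(pt.db_membership) >= 2:
            candidates.setdefault(pt.mirna, set()).add(pt.gene)
    up_by_week = {w: set() for w in config.weeks}
    for pt in config.planted_targets:
        for w in pt.upregulated_weeks:
            if w in up_by_week:
                up_by_week[w].add(pt.gene)
    sig_weeks = {pm.name: pm.affected_weeks for pm in config.planted_mirnas}
    predicted = {
        m: {
            w: sorted(candidates.get(m, set()) & up_by_week[w])
            for w in sorted(sig_weeks.get(m, config.weeks))
        }
        for m in candidates
    }
    shared = {}
    mlist = sorted(predicted)
    for i, ma in enumerate(mlist):
        for mb in mlist[i + 1 :]:
            for w in config.weeks:
                common = set(predicted[ma].get(w, [])) & set(predicted[mb].get(w, []))
                if common:
                    shared[f"{ma}|{mb}|{w}"] = sorted(common)

    truth = GroundTruth(
        candidate_targets={m: sorted(s) for m, s in candidates.items()},
        predicted_targets=predicted,
        shared_targets=shared,
    )
    return dbs, truth


def _junction_counts(
    rng: np.random.Generator,
    psi: float,
    mean_reads: float,
    n_samples: int,
    inc_len: int,
    skip_len: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a fixed total read budget into per-sample inclusion/skipping counts.

    The grand total is ``round(mean_reads * n_samples)`` so the realized
    mean reads per sample equals the planted value whenever that product is
    integral (the filter-boundary plants rely on this).  Counts are
    allocated to samples by a uniform multinomial; each sample's inclusion
    count is binomial with the count-space probability implied by the
    length-normalized inclusion level.
    """
    total = int(round(mean_reads * n_samples))
    per_sample = rng.multinomial(total, np.full(n_samples, 1.0 / n_samples))
    # invert length normalization: P(read supports inclusion form)
    q = psi * inc_len / (psi * inc_len + (1.0 - psi) * skip_len)
    ijc = rng.binomial(per_sample, q)
    sjc = per_sample - ijc
    return ijc, sjc


_EVENT_COLUMNS = [
    "gene", "event_type", "chrom", "strand", "c1", "c2", "c3", "c4",
    "ijc", "sjc", "inc_len", "skip_len", "psi_g1", "psi_g2", "delta_psi", "pvalue",
]


def _event_row(rng, gene, etype, chrom, strand, coords, delta_psi, mean_reads,
               n_samples, significant=True, inc_len=200, skip_len=100):
    # draw the baseline level from the feasible window so the planted
    # delta is realized exactly rather than clipped away
    lo = max(0.02, 0.02 - delta_psi)
    hi = min(0.98, 0.98 - delta_psi)
    psi_g2 = rng.uniform(max(lo, min(0.25, hi)), min(hi, max(0.75, lo)))
    psi_g1 = psi_g2 + delta_psi
    delta = delta_psi
    ijc, sjc = _junction_counts(rng, psi_g1, mean_reads, n_samples, inc_len, skip_len)
    pval = rng.uniform(1e-6, 0.04) if significant else rng.uniform(0.06, 1.0)
    return dict(
        gene=gene, event_type=etype, chrom=chrom, strand=strand,
        c1=coords[0], c2=coords[1], c3=coords[2], c4=coords[3],
        ijc=",".join(map(str, ijc)), sjc=",".join(map(str, sjc)),
        inc_len=inc_len, skip_len=skip_len,
        psi_g1=round(psi_g1, 4), psi_g2=round(psi_g2, 4),
        delta_psi=round(delta, 4), pvalue=pval,
    )


def simulate_as_tables(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the hypoxia and knockdown differential-splicing event tables.

    Planted events marked ``same_site_in_kd`` share the full coordinate key
    between the two tables; other planted events with ``in_kd`` recur in
    the knockdown table at shifted coordinates, giving gene-level overlap
    only.  Background events use gene pools disjoint between tables.
    """
    rng = _rng(config, "as_events")
    n = config.n_replicates

    ih_rows, kd_rows = [], []
    for ev in config.planted_events:
        ih_rows.append(
            _event_row(rng, ev.gene, ev.event_type, ev.chrom, ev.strand, ev.coords,
                       ev.delta_psi, ev.mean_reads, n)
        )
        if ev.in_kd:
            if ev.same_site_in_kd:
                coords = ev.coords
            else:
                coords = tuple(c + 500 for c in ev.coords)
            kd_delta = float(rng.uniform(0.05, 0.5) * rng.choice([-1.0, 1.0]))
            kd_rows.append(
                _event_row(rng, ev.gene, ev.event_type, ev.chrom, ev.strand, coords,
                           kd_delta, max(ev.mean_reads, 15.0), n)
            )

    for side, rows in (("ih", ih_rows), ("kd", kd_rows)):
        for i in range(config.n_background_events):
            gene = f"{side.upper()}bg{i:04d}"
            etype = EVENT_TYPES[int(rng.integers(len(EVENT_TYPES)))]
            start = int(rng.integers(1_000, 5_000_000))
            coords = (start, start + 200, start + 350, start + 600)
            delta = float(rng.uniform(-0.4, 0.4))
            sig = bool(rng.random() < 0.6)
            rows.append(
                _event_row(rng, gene, etype, f"chr{int(rng.integers(1, 20))}",
                           rng.choice(["+", "-"]), coords, delta,
                           float(rng.uniform(12, 80)), n, significant=sig)
            )

    ih = pd.DataFrame(ih_rows, columns=_EVENT_COLUMNS)
    kd = pd.DataFrame(kd_rows, columns=_EVENT_COLUMNS)

    # truth, by brute force from the plant
    overlap: dict[str, set] = {}
    same_site = []
    survivors = []
    for ev in config.planted_events:
        if ev.in_kd:
            overlap.setdefault(ev.event_type, set()).add(ev.gene)
        if ev.in_kd and ev.same_site_in_kd:
            same_site.append(ev.gene)
            realized_mean = round(ev.mean_reads * n) / n
            if realized_mean > 10.0:
                survivors.append(ev)
    # recover the realized delta_psi (clipping may shrink planted values)
    realized_delta = {}
    for ev, row in zip(config.planted_events, ih_rows):
        realized_delta[(ev.gene, ev.coords)] = row["delta_psi"]
    survivors.sort(
        key=lambda ev: (-abs(realized_delta[(ev.gene, ev.coords)]), ev.gene, ev.coords)
    )
    truth = GroundTruth(
        gene_overlap={t: sorted(s) for t, s in overlap.items()},
        same_site_genes=sorted(same_site),
        ranked_events=[
            [ev.gene, ev.event_type, list(ev.coords)] for ev in survivors
        ],
        top_event_types=[ev.event_type for ev in survivors[:3]],
    )
    return ih, kd, truth


def simulate_gel_bands(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a gel band densitometry table (sample, group, isoform, volume, length_nt).

    Band volume is true isoform abundance x amplicon length x lognormal
    multiplicative noise with the configured coefficient of variation; the
    true inclusion rate per sample goes into the truth sidecar.
    """
    rng = _rng(config, "gel_bands")
    cv = config.gel_noise_cv
    sigma = np.sqrt(np.log1p(cv * cv))
    mu = -0.5 * sigma * sigma  # lognormal mean exactly 1

    abundance = 1000.0
    rows, gel_psi = [], {}
    for group, psi in config.gel_true_psi:
        for i in range(1, config.n_gel_samples + 1):
            sample = f"{group}_{i}"
            gel_psi[sample] = psi
            for isoform, frac, length in (
                ("included", psi, config.gel_inc_len),
                ("skipped", 1.0 - psi, config.gel_skip_len),
            ):
                noise = float(rng.lognormal(mu, sigma)) if cv > 0 else 1.0
                rows.append((sample, group, isoform, abundance * frac * length * noise, length))
    bands = pd.DataFrame(
        rows, columns=["sample", "group", "isoform", "volume", "length_nt"]
    )
    return bands, GroundTruth(gel_psi=gel_psi)


def merge_truth(*parts: GroundTruth) -> GroundTruth:
    merged = GroundTruth()
    for part in parts:
        for key, val in asdict(part).items():
            if not val:
                continue
            if isinstance(val, dict):
                getattr(merged, key).update(val)
            else:
                setattr(merged, key, val)
    return merged


def simulate_bundle(config: SimConfig) -> dict:
    """Generate every input artifact plus the merged truth sidecar.

    Returns a dict with keys ``counts``, ``degs``, ``dbs``, ``ih_events``,
    ``kd_events``, ``bands`` (DataFrames) and ``truth`` (:class:`GroundTruth`).
    """
    counts, t1 = simulate_mirna_counts(config)
    degs, t2 = simulate_deg_tables(config)
    dbs, t3 = simulate_target_dbs(config)
    ih, kd, t4 = simulate_as_tables(config)
    bands, t5 = simulate_gel_bands(config)
    return dict(
        counts=counts, degs=degs, dbs=dbs, ih_events=ih, kd_events=kd, bands=bands,
        truth=merge_truth(t1, t2, t3, t4, t5),
    )


def write_bundle(config: SimConfig, outdir: str | Path) -> dict:
    """Write a full synthetic bundle to ``outdir`` and return it."""
    from mirsplice import tableio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_bundle(config)
    bundle["counts"].to_csv(outdir / "mirna_counts.tsv", sep="\t")
    tableio.write_table(bundle["degs"], outdir / "degs.tsv", "deg")
    for db in DB_IDS:
        sub = bundle["dbs"][bundle["dbs"]["db"] == db]
        tableio.write_table(sub, outdir / f"targets_{db}.tsv", "target_db")
    tableio.write_table(bundle["ih_events"], outdir / "events_ih.tsv", "event")
    tableio.write_table(bundle["kd_events"], outdir / "events_kd.tsv", "event")
    tableio.write_table(bundle["bands"], outdir / "gel_bands.csv", "band")
    (outdir / "truth.json").write_text(bundle["truth"].to_json())
    return bundle
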