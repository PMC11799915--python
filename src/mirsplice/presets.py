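"""Ready-made simulation configurations mirroring the study design.

``study_config`` plants the structure the screen is built to recover:
eight downregulated miRNAs split over the three temporal categories, a
target gene (Fam76b) shared by two week-3 miRNAs through 2-of-3 database
consensus, a splicing overlap of 44 skipped-exon genes plus one A5SS
(Fbxl4) and one retained intron (Gas5) with 13 same-site matches, and a
designated skipped-exon top three (Nbr1, Dph3, Ep400) above the mean-reads
filter.
"""

from __future__ import annotations

from mirsplice.simulate import (
    PlantedEvent,
    PlantedMirna,
    PlantedTarget,
    SimConfig,
)

# the three temporal categories of downregulated miRNAs
STUDY_MIRNAS = (
    PlantedMirna("mmu-miR-448-3p", 1, -2.2, frozenset({1, 3, 5})),
    PlantedMirna("mmu-miR-1912-3p", 1, -2.0, frozenset({1, 3, 5, 7})),
    PlantedMirna("mmu-miR-1298-5p", 1, -2.4, frozenset({1, 3, 5, 7})),
    PlantedMirna("mmu-miR-1264-3p", 2, -2.1, frozenset({3, 5, 7})),
    PlantedMirna("mmu-miR-1264-5p", 2, -2.3, frozenset({3, 5, 7})),
    PlantedMirna("mmu-miR-34c-3p", 3, -2.0, frozenset({5, 7})),
    PlantedMirna("mmu-miR-34b-3p", 3, -2.2, frozenset({5, 7})),
    PlantedMirna("mmu-miR-3091-3p", 3, -2.5, frozenset({5, 7})),
)

# Fam76b: consensus target of both week-3 miRNAs, upregulated at week 3;
# miR-1298-5p gets a consensus candidate that is never upregulated, so it
# ends the screen target-less at its change points.
STUDY_TARGETS = (
    PlantedTarget("mmu-miR-448-3p", "Fam76b", frozenset("ABC"), frozenset({3})),
    PlantedTarget("mmu-miR-1264-3p", "Fam76b", frozenset("AB"), frozenset({3})),
    PlantedTarget("mmu-miR-448-3p", "Ctdsp2", frozenset("AC"), frozenset({1})),
    PlantedTarget("mmu-miR-1912-3p", "Slc7a11", frozenset("BC"), frozenset({5})),
    PlantedTarget("mmu-miR-1264-5p", "Arl4c", frozenset("AB"), frozenset({7})),
    PlantedTarget("mmu-miR-34c-3p", "Bdnf", frozenset("ABC"), frozenset({5})),
    PlantedTarget("mmu-miR-34b-3p", "Mef2c", frozenset("AC"), frozenset({7})),
    PlantedTarget("mmu-miR-1298-5p", "Gpr85", frozenset("AB"), frozenset()),
    PlantedTarget("mmu-miR-3091-3p", "Nptx1", frozenset("C"), frozenset({5})),
)


def study_events() -> tuple:
    """44 shared SE genes + 1 A5SS + 1 RI; 13 of the 46 same-site.

    The designated top three by |dPSI| above the reads filter are the
    skipped-exon events of Nbr1, Dph3 and Ep400.
    """
    events = []

    def se(gene, i, dpsi, reads, same_site):
        start = 1_000_000 + 10_000 * i
        return PlantedEvent(
            gene, "SE", f"chr{(i % 19) + 1}", "+" if i % 2 == 0 else "-",
            (start, start + 150, start + 250, start + 400),
            dpsi, reads, same_site_in_kd=same_site,
        )

    # top three: largest |dPSI|, comfortably above the reads filter
    events.append(se("Nbr1", 0, -0.62, 40.0, True))
    events.append(se("Dph3", 1, 0.55, 55.0, True))
    events.append(se("Ep400", 2, -0.48, 35.0, True))
    # ten further same-site SE genes with smaller |dPSI|
    for j in range(10):
        events.append(se(f"Sameg{j:02d}", 3 + j, 0.30 - 0.02 * j, 25.0, True))
    # remaining 31 SE genes overlap at the gene level only
    for j in range(31):
        events.append(se(f"Geneov{j:02d}", 13 + j, 0.25 - 0.005 * j, 20.0, False))
    # one A5SS and one RI gene-level overlap
    events.append(
        PlantedEvent("Fbxl4", "A5SS", "chr17", "-",
                     (2_000_000, 2_000_120, 2_000_200, 2_000_500), 0.35, 30.0)
    )
    events.append(
        PlantedEvent("Gas5", "RI", "chr1", "+",
                     (3_000_000, 3_000_100, 3_000_400, 3_000_600), -0.28, 45.0)
    )
    return tuple(events)


def study_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study-scale simulation: all plants wired together."""
    kwargs = dict(
        seed=seed,
        n_replicates=3,
        n_mirnas=300,
        n_genes=2000,
        nb_dispersion=0.1,
        baseline_mean=200.0,
        planted_mirnas=STUDY_MIRNAS,
        planted_targets=STUDY_TARGETS,
        planted_events=study_events(),
        gel_noise_cv=0.1,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)
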