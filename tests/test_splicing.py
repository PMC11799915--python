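"""Splicing screen: PSI arithmetic, overlap, same-site matching, ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirsplice.splicing import (
    as_screen,
    compute_psi,
    match_same_site,
    overlap_by_gene,
    rank_events,
)
from tests.conftest import random_event_table


class TestComputePsi:
    def test_direct_arithmetic(self):
        assert compute_psi(100, 100, 200, 100) == pytest.approx(1 / 3)

    def test_boundaries(self):
        assert compute_psi(50, 0, 200, 100) == 1.0
        assert compute_psi(0, 50, 200, 100) == 0.0

    def test_scaling_counts_leaves_value_unchanged(self):
        a = compute_psi(30, 20, 200, 100)
        b = compute_psi(30 * 7, 20 * 7, 200, 100)
        assert a == pytest.approx(b)

    def test_both_zero_is_missing(self):
        assert np.isnan(compute_psi(0, 0, 200, 100))

    def test_bad_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            compute_psi(1, 1, 0, 100)

    @given(
        i=st.integers(0, 1000), s=st.integers(0, 1000),
        il=st.integers(1, 500), sl=st.integers(1, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, i, s, il, sl):
        if i == 0 and s == 0:
            return
        v = compute_psi(i, s, il, sl)
        assert 0.0 <= v <= 1.0
        assert compute_psi(i + 1, s, il, sl) > v or s == 0
        assert compute_psi(i, s + 1, il, sl) < v or i == 0


def brute_force_overlap(ih, kd, p=0.05):
    out = {}
    for etype in {*ih["event_type"], *kd["event_type"]}:
        a = {r.gene for r in ih.itertuples() if r.event_type == etype and r.pvalue < p}
        b = {r.gene for r in kd.itertuples() if r.event_type == etype and r.pvalue < p}
        if a & b:
            out[etype] = a & b
    return out


class TestOverlap:
    def test_disjoint_genes_empty(self):
        rng = np.random.default_rng(0)
        ih = random_event_table(rng, [f"a{i}" for i in range(5)], 10)
        kd = random_event_table(rng, [f"b{i}" for i in range(5)], 10)
        assert overlap_by_gene(ih, kd) == {}

    def test_significance_required_on_both_sides(self):
        rng = np.random.default_rng(1)
        ih = random_event_table(rng, ["g"], 1)
        kd = ih.copy()
        ih.loc[0, "pvalue"] = 0.01
        kd.loc[0, "pvalue"] = 0.5
        assert overlap_by_gene(ih, kd) == {}
        kd.loc[0, "pvalue"] = 0.04
        assert overlap_by_gene(ih, kd) == {ih.loc[0, "event_type"]: {"g"}}

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(8)]
        for _ in range(200):
            ih = random_event_table(rng, genes, int(rng.integers(1, 15)))
            kd = random_event_table(rng, genes, int(rng.integers(1, 15)))
            assert overlap_by_gene(ih, kd) == brute_force_overlap(ih, kd)


def make_pair(gene="g", etype="SE", coords=(100, 200, 300, 400), shift=0,
              dpsi_ih=-0.4, p_ih=0.01, p_kd=0.01, ijc="20,20,20", sjc="10,10,10"):
    base = dict(gene=gene, event_type=etype, chrom="chr1", strand="+",
                inc_len=200, skip_len=100, psi_g1=0.5, psi_g2=0.5)
    ih = pd.DataFrame([{**base, "c1": coords[0], "c2": coords[1], "c3": coords[2],
                        "c4": coords[3], "ijc": ijc, "sjc": sjc,
                        "delta_psi": dpsi_ih, "pvalue": p_ih}])
    kd = pd.DataFrame([{**base, "c1": coords[0] + shift, "c2": coords[1] + shift,
                        "c3": coords[2] + shift, "c4": coords[3] + shift,
                        "ijc": ijc, "sjc": sjc, "delta_psi": 0.2, "pvalue": p_kd}])
    return ih, kd


class TestSameSite:
    def test_identical_key_matches(self):
        ih, kd = make_pair()
        matched = match_same_site(ih, kd)
        assert len(matched) == 1
        assert matched.loc[0, "gene"] == "g"

    def test_one_base_shift_no_match(self):
        ih, kd = make_pair(shift=1)
        assert match_same_site(ih, kd).empty

    def test_symmetric_in_inputs(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(6)]
        for _ in range(50):
            a = random_event_table(rng, genes, 10)
            b = random_event_table(rng, genes, 10)
            ab = match_same_site(a, b)
            ba = match_same_site(b, a)
            key = ["gene", "event_type", "chrom", "strand", "c1", "c2", "c3", "c4"]
            assert sorted(map(tuple, ab[key].to_numpy().tolist())) == sorted(
                map(tuple, ba[key].to_numpy().tolist())
            )

    def test_matches_brute_force_pairwise(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(4)]
        key = ("gene", "event_type", "chrom", "strand", "c1", "c2", "c3", "c4")
        for _ in range(100):
            ih = random_event_table(rng, genes, 12)
            kd = random_event_table(rng, genes, 12)
            overlap = brute_force_overlap(ih, kd)
            expected = set()
            for a in ih.itertuples():
                for b in kd.itertuples():
                    if (
                        all(getattr(a, k) == getattr(b, k) for k in key)
                        and a.pvalue < 0.05 and b.pvalue < 0.05
                        and a.gene in overlap.get(a.event_type, set())
                    ):
                        expected.add(tuple(getattr(a, k) for k in key))
            got = match_same_site(ih, kd)
            got_keys = set(map(tuple, got[list(key)].to_numpy().tolist()))
            assert got_keys == expected


class TestRanking:
    def test_mean_reads_exactly_at_threshold_excluded(self):
        ih, kd = make_pair(ijc="7,7,7", sjc="3,3,3")  # mean reads 10.0
        ranked = rank_events(match_same_site(ih, kd), min_mean_reads=10.0)
        assert ranked.empty

    def test_just_above_threshold_kept(self):
        ih, kd = make_pair(ijc="7,7,8", sjc="3,3,3")  # mean 31/3 > 10
        ranked = rank_events(match_same_site(ih, kd), min_mean_reads=10.0)
        assert len(ranked) == 1

    def test_order_by_magnitude(self):
        frames = []
        for i, dpsi in enumerate([-0.40, 0.30, -0.25]):
            ih, kd = make_pair(gene=f"g{i}", coords=(100 + i, 200 + i, 300 + i, 400 + i),
                               dpsi_ih=dpsi)
            frames.append((ih, kd))
        ih = pd.concat([f[0] for f in frames], ignore_index=True)
        kd = pd.concat([f[1] for f in frames], ignore_index=True)
        ranked = rank_events(match_same_site(ih, kd))
        assert list(ranked["delta_psi_ih"]) == [-0.40, 0.30, -0.25]

    def test_ties_broken_lexicographically(self):
        frames = []
        for gene in ("zeta", "alpha"):
            ih, kd = make_pair(gene=gene, dpsi_ih=0.3)
            frames.append((ih, kd))
        ih = pd.concat([f[0] for f in frames], ignore_index=True)
        kd = pd.concat([f[1] for f in frames], ignore_index=True)
        ranked = rank_events(match_same_site(ih, kd))
        assert list(ranked["gene"]) == ["alpha", "zeta"]

    def test_fewer_survivors_than_k_returns_all(self):
        ih, kd = make_pair()
        ranked = rank_events(match_same_site(ih, kd), k=5)
        assert len(ranked) == 1 and ranked["top"].all()

    def test_filter_and_rank_commute(self):
        rng = np.random.default_rng(5)
        frames = []
        for i in range(12):
            counts = rng.integers(0, 15, size=(2, 3))
            ih, kd = make_pair(
                gene=f"g{i:02d}", coords=(100 + i, 200 + i, 300 + i, 400 + i),
                dpsi_ih=float(rng.uniform(-0.8, 0.8)),
                ijc=",".join(map(str, counts[0])), sjc=",".join(map(str, counts[1])),
            )
            frames.append((ih, kd))
        ih = pd.concat([f[0] for f in frames], ignore_index=True)
        kd = pd.concat([f[1] for f in frames], ignore_index=True)
        matched = match_same_site(ih, kd)
        assert len(matched) == 12
        ranked = rank_events(matched, min_mean_reads=10)
        rank_first = rank_events(matched, min_mean_reads=0)
        refiltered = rank_first[rank_first["mean_reads"] > 10].reset_index(drop=True)
        assert list(ranked["gene"]) == list(refiltered["gene"])


class TestEndToEndRecovery:
    def test_study_plant_recovered_exactly(self, study_bundle):
        truth = study_bundle["truth"]
        screen = as_screen(study_bundle["ih_events"], study_bundle["kd_events"])
        got_overlap = {t: sorted(g) for t, g in screen["gene_overlap"].items()}
        assert got_overlap == truth.gene_overlap
        assert sorted(screen["same_site"]["gene"]) == truth.same_site_genes
        ranked = screen["ranked"]
        got_order = [
            [r.gene, r.event_type, [r.c1, r.c2, r.c3, r.c4]]
            for r in ranked.itertuples(index=False)
        ]
        assert got_order == truth.ranked_events
        assert list(ranked.loc[ranked["top"], "event_type"]) == truth.top_event_types
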