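"""Derivative-domain rewiring: worked examples and oracle equivalence."""

from __future__ import annotations

import numpy as np
import pytest

from tadmil import (
    StructuralVariant,
    build_sv_gene_pairs,
    rewire_deletion,
    rewire_duplication,
    rewire_inversion,
    rewire_translocation,
    select_boundary_disrupting_svs,
)

from .conftest import make_domains, make_elements, make_gene, record_set, random_toy_genome, to_package_inputs
from .oracles import (
    oracle_deletion,
    oracle_duplication,
    oracle_inversion,
    oracle_translocation,
)


def sv(sv_type, pos1, pos2, chrom1="1", chrom2=None, o1="+", o2="-", patient="p0", sv_id="sv1"):
    return StructuralVariant(
        sv_id, patient, sv_type, chrom1, pos1, o1, chrom2 or chrom1, pos2, o2
    )


class TestSelection:
    def test_boundary_crossing_deletion_selected(self):
        domains = make_domains((0, 100), (100, 200))
        assert select_boundary_disrupting_svs([sv("DEL", 90, 110)], domains)

    def test_intra_domain_sv_excluded(self):
        domains = make_domains((0, 100), (100, 200))
        assert select_boundary_disrupting_svs([sv("DEL", 10, 20)], domains) == []

    def test_translocation_always_crosses(self):
        domains = make_domains(("1", 0, 100), ("2", 0, 100))
        assert select_boundary_disrupting_svs(
            [sv("TRA", 50, 50, chrom1="1", chrom2="2")], domains
        )

    def test_breakpoint_in_gap_excluded(self):
        domains = make_domains((0, 100), (150, 250))
        assert select_boundary_disrupting_svs([sv("DEL", 120, 200)], domains) == []

    def test_single_whole_chromosome_domain_yields_no_pairs(self):
        domains = make_domains((0, 1000))
        genes = [make_gene("g1", 10, 20)]
        elements = make_elements(enhancer=[(500, 600)])
        pairs = build_sv_gene_pairs([sv("DEL", 100, 700)], domains, genes, elements)
        assert pairs == []


class TestDeletion:
    domains = make_domains((0, 100), (100, 200))

    def test_gene_gains_enhancer_across_fused_boundary(self):
        genes = [make_gene("g1", 10, 20)]
        elements = make_elements(enhancer=[(150, 160)])
        recs = rewire_deletion(sv("DEL", 90, 110), self.domains, genes, elements)
        assert record_set(recs) == {("g1", "1", 150, 160, "enhancer", "gain")}

    def test_element_inside_deletion_not_counted(self):
        genes = [make_gene("g1", 10, 20)]
        elements = make_elements(enhancer=[(95, 105)])
        recs = rewire_deletion(sv("DEL", 90, 110), self.domains, genes, elements)
        assert recs == []

    def test_gene_inside_deletion_emits_nothing(self):
        genes = [make_gene("g1", 95, 99)]
        elements = make_elements(enhancer=[(150, 160)])
        recs = rewire_deletion(sv("DEL", 90, 110), self.domains, genes, elements)
        assert recs == []

    def test_deletion_produces_only_gains(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            domain_triples, genomes, genes, elements = random_toy_genome(rng)
            chrom, ds = sorted(genomes.items())[0]
            if len(ds) < 2:
                continue
            s = int(rng.integers(ds[0][1] + 1, ds[0][2] - 1))
            e = int(rng.integers(ds[-1][1] + 1, ds[-1][2] - 1))
            domains, pk_genes, tracks = to_package_inputs(domain_triples, genes, elements)
            recs = rewire_deletion(sv("DEL", s, e, chrom1=chrom), domains, pk_genes, tracks)
            assert all(r.direction == "gain" for r in recs)


class TestDuplication:
    domains = make_domains((0, 100), (100, 200))

    def test_gene_gains_enhancer_across_duplicated_boundary(self):
        genes = [make_gene("g1", 60, 70)]
        elements = make_elements(enhancer=[(110, 120)])
        recs = rewire_duplication(sv("DUP", 50, 150), self.domains, genes, elements)
        assert record_set(recs) == {("g1", "1", 110, 120, "enhancer", "gain")}

    def test_gene_outside_duplication_gets_no_records(self):
        genes = [make_gene("g1", 10, 20)]
        elements = make_elements(enhancer=[(110, 120)])
        recs = rewire_duplication(sv("DUP", 50, 150), self.domains, genes, elements)
        assert recs == []

    def test_one_bp_overlap_with_duplication_counts(self):
        genes = [make_gene("g1", 60, 70)]
        elements = make_elements(enhancer=[(149, 155)])  # 1 bp inside [50,150)
        recs = rewire_duplication(sv("DUP", 50, 150), self.domains, genes, elements)
        assert record_set(recs) == {("g1", "1", 149, 155, "enhancer", "gain")}


class TestInversion:
    domains = make_domains((0, 100), (100, 200))

    def test_enhancer_inverted_into_left_domain_is_gained(self):
        genes = [make_gene("g1", 10, 20)]
        elements = make_elements(enhancer=[(110, 140)])
        recs = rewire_inversion(sv("INV", 50, 150), self.domains, genes, elements)
        # [110,140) reflects to [60,90), entering the left domain
        assert record_set(recs) == {("g1", "1", 110, 140, "enhancer", "gain")}

    def test_gene_inverted_out_loses_left_domain_elements(self):
        genes = [make_gene("g1", 60, 70)]  # reflects to [130,140): into right domain
        elements = make_elements(enhancer=[(10, 40)])
        recs = rewire_inversion(sv("INV", 50, 150), self.domains, genes, elements)
        assert record_set(recs) == {("g1", "1", 10, 40, "enhancer", "loss")}


class TestTranslocation:
    domains = make_domains(("1", 0, 100), ("2", 0, 100))

    def tra(self, o1="+", o2="-"):
        return sv("TRA", 50, 40, chrom1="1", chrom2="2", o1=o1, o2=o2)

    def test_gene_gains_element_from_other_retained_segment(self):
        genes = [make_gene("g1", 10, 20, chrom="1")]
        elements = make_elements(enhancer=[("2", 60, 70)])
        recs = rewire_translocation(self.tra(), self.domains, genes, elements)
        assert record_set(recs) == {("g1", "2", 60, 70, "enhancer", "gain")}

    def test_gene_loses_element_on_lost_segment(self):
        genes = [make_gene("g1", 10, 20, chrom="1")]
        elements = make_elements(enhancer=[("1", 60, 70)])
        recs = rewire_translocation(self.tra(), self.domains, genes, elements)
        assert record_set(recs) == {("g1", "1", 60, 70, "enhancer", "loss")}

    def test_join_is_symmetric(self):
        genes = [make_gene("g2", 60, 70, chrom="2")]
        elements = make_elements(eqtl=[("1", 10, 20)])
        recs = rewire_translocation(self.tra(), self.domains, genes, elements)
        assert record_set(recs) == {("g2", "1", 10, 20, "eqtl", "gain")}

    def test_missing_orientation_rejected(self):
        with pytest.raises(ValueError):
            StructuralVariant("s", "p", "TRA", "1", 50, ".", "2", 40, "-")


class TestPairConstruction:
    def test_pairs_sorted_and_nonempty(self):
        domains = make_domains((0, 100), (100, 200))
        genes = [make_gene("g1", 10, 20), make_gene("g2", 150, 160)]
        elements = make_elements(enhancer=[(170, 180)], eqtl=[(30, 35)])
        pairs = build_sv_gene_pairs([sv("DEL", 90, 110)], domains, genes, elements)
        assert [p.gene_id for p in pairs] == ["g1", "g2"]
        assert all(p.records for p in pairs)

    def test_order_invariance(self):
        domains = make_domains((0, 100), (100, 200))
        genes = [make_gene("g1", 10, 20), make_gene("g2", 150, 160)]
        elements = make_elements(enhancer=[(170, 180)], eqtl=[(30, 35)])
        fwd = build_sv_gene_pairs([sv("DEL", 90, 110)], domains, genes, elements)
        rev = build_sv_gene_pairs(
            [sv("DEL", 90, 110)], domains, list(reversed(genes)),
            {k: type(v)(v.kind, list(reversed(v.intervals))) for k, v in elements.items()},
        )
        assert [(p.gene_id, record_set(p.records)) for p in fwd] == [
            (p.gene_id, record_set(p.records)) for p in rev
        ]


def _random_intrachrom_sv(rng, genomes):
    chrom = sorted(genomes)[int(rng.integers(0, len(genomes)))]
    ds = genomes[chrom]
    if len(ds) < 2:
        return None
    i, j = sorted(rng.choice(len(ds), size=2, replace=False))
    if i == j:
        return None
    s = int(rng.integers(ds[i][1] + 1, ds[i][2] - 1))
    e = int(rng.integers(ds[j][1] + 1, ds[j][2] - 1))
    return chrom, s, e


@pytest.mark.parametrize("sv_type", ["DEL", "DUP", "INV", "TRA"])
def test_rewiring_matches_brute_force_oracle(sv_type):
    """Each rewiring operator reproduces a per-basepair derivative-genome
    enumerator on >= 200 random toy genomes."""
    rng = np.random.default_rng(hash(sv_type) % 2**31)
    n_done = 0
    while n_done < 200:
        domain_triples, genomes, genes, elements = random_toy_genome(rng)
        domains, pk_genes, tracks = to_package_inputs(domain_triples, genes, elements)
        if sv_type == "TRA":
            if len(genomes) < 2:
                continue
            c1, c2 = sorted(genomes)[:2]
            d1 = genomes[c1][int(rng.integers(0, len(genomes[c1])))]
            d2 = genomes[c2][int(rng.integers(0, len(genomes[c2])))]
            p1 = int(rng.integers(d1[1] + 1, d1[2] - 1))
            p2 = int(rng.integers(d2[1] + 1, d2[2] - 1))
            o1 = "+" if rng.random() < 0.5 else "-"
            o2 = "+" if rng.random() < 0.5 else "-"
            variant = sv("TRA", p1, p2, chrom1=c1, chrom2=c2, o1=o1, o2=o2)
            got = record_set(rewire_translocation(variant, domains, pk_genes, tracks))
            want = oracle_translocation(domain_triples, genes, elements, variant)
        else:
            drawn = _random_intrachrom_sv(rng, genomes)
            if drawn is None:
                continue
            chrom, s, e = drawn
            variant = sv(sv_type, s, e, chrom1=chrom)
            impl = {"DEL": rewire_deletion, "DUP": rewire_duplication, "INV": rewire_inversion}[sv_type]
            oracle = {"DEL": oracle_deletion, "DUP": oracle_duplication, "INV": oracle_inversion}[sv_type]
            got = record_set(impl(variant, domains, pk_genes, tracks))
            want = {
                (gid, chrom_, s_, e_, kind, direction)
                for gid, chrom_, s_, e_, kind, direction in oracle(
                    domain_triples, genes, elements, chrom, s, e
                )
            }
        assert got == want, f"{sv_type} mismatch on genome {n_done}: impl^oracle={got ^ want}"
        n_done += 1


def test_no_element_both_gained_and_lost():
    """Conservation: per (gene, element), a rewiring op never emits both
    directions."""
    rng = np.random.default_rng(99)
    for _ in range(60):
        domain_triples, genomes, genes, elements = random_toy_genome(rng)
        domains, pk_genes, tracks = to_package_inputs(domain_triples, genes, elements)
        drawn = _random_intrachrom_sv(rng, genomes)
        if drawn is None:
            continue
        chrom, s, e = drawn
        recs = rewire_inversion(sv("INV", s, e, chrom1=chrom), domains, pk_genes, tracks)
        keys = [(r.gene_id, r.element, r.element_kind) for r in recs]
        assert len(keys) == len(set(keys))
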