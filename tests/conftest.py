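from __future__ import annotations

import numpy as np
import pytest

from tadmil import (
    AnnotationTrack,
    Domain,
    DomainSet,
    Gene,
    GenomicInterval,
    SimConfig,
    run_study,
    simulate_cohort,
    simulate_reference,
)

from .oracles import ToyEntity


def make_domains(*spans, chrom="1"):
    """DomainSet from (start, end) tuples, or (chrom, start, end) triples."""
    ds = []
    for sp in spans:
        if len(sp) == 2:
            ds.append(Domain(GenomicInterval(chrom, *sp)))
        else:
            ds.append(Domain(GenomicInterval(sp[0], sp[1], sp[2])))
    return DomainSet(ds)


def make_gene(gene_id, start, end, chrom="1"):
    return Gene(gene_id, GenomicInterval(chrom, start, end))


def make_elements(**kinds):
    """Element tracks from kind=[(start, end) or (chrom, start, end)] lists."""
    out = {k: AnnotationTrack(k) for k in ("eqtl", "enhancer", "super_enhancer")}
    for kind, spans in kinds.items():
        for sp in spans:
            if len(sp) == 2:
                out[kind].add(GenomicInterval("1", *sp))
            else:
                out[kind].add(GenomicInterval(sp[0], sp[1], sp[2]))
    return out


def random_toy_genome(rng: np.random.Generator):
    """A random toy genome (<= 10 kb, <= 6 abutting domains per chromosome)
    with genes and elements that may straddle boundaries."""
    n_chrom = int(rng.integers(1, 3))
    genomes = {}
    for ci in range(n_chrom):
        chrom = str(ci + 1)
        n_dom = int(rng.integers(2, 7))
        width = int(rng.integers(300, 10_000 // n_dom))
        genomes[chrom] = [(chrom, i * width, (i + 1) * width) for i in range(n_dom)]
    domain_triples = [d for ds in genomes.values() for d in ds]
    chroms = sorted(genomes)

    genes, elements = [], []
    for i in range(int(rng.integers(4, 14))):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        limit = genomes[chrom][-1][2]
        length = int(rng.integers(20, 400))
        start = int(rng.integers(0, limit - length))
        genes.append(ToyEntity(f"g{i}", chrom, start, start + length))
    for i in range(int(rng.integers(6, 25))):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        limit = genomes[chrom][-1][2]
        length = int(rng.integers(1, 300))
        start = int(rng.integers(0, limit - length))
        kind = ("eqtl", "enhancer", "super_enhancer")[int(rng.integers(0, 3))]
        elements.append(ToyEntity(f"e{i}", chrom, start, start + length, kind))
    return domain_triples, genomes, genes, elements


def to_package_inputs(domain_triples, genes, elements):
    domains = DomainSet(
        Domain(GenomicInterval(c, s, e)) for c, s, e in domain_triples
    )
    pk_genes = [Gene(g.eid, GenomicInterval(g.chrom, g.start, g.end)) for g in genes]
    tracks = {k: AnnotationTrack(k) for k in ("eqtl", "enhancer", "super_enhancer")}
    for el in elements:
        tracks[el.kind].add(GenomicInterval(el.chrom, el.start, el.end))
    return domains, pk_genes, tracks


def record_set(records):
    """Canonical comparable form of GainLossRecords."""
    return {
        (r.gene_id, r.element.chrom, r.element.start, r.element.end, r.element_kind, r.direction)
        for r in records
    }


# ---------------------------------------------------------------------------
# Shared simulated study (the planted-signal conditions)
# ---------------------------------------------------------------------------

def run_replicate(genome_seed: int, cohort_seed: int, model_seed: int):
    """One full planted-signal study under the default conditions."""
    cfg = SimConfig()
    genome = simulate_reference(cfg, seed=genome_seed)
    cohort = simulate_cohort(cfg, genome, seed=cohort_seed)
    result = run_study(
        cohort.svs,
        genome.domains,
        genome.genes,
        genome.elements,
        genome.tracks,
        cohort.expression,
        cohort.mutation_index,
        seed=model_seed,
        pairs=cohort.pairs,
    )
    return genome, cohort, result


@pytest.fixture(scope="session")
def study():
    return run_replicate(11, 12, 13)


@pytest.fixture(scope="session")
def study_replicate():
    """An independent replicate cohort; pooled with ``study`` where a
    single-cohort statistic would be dominated by seed noise."""
    return run_replicate(1, 2, 3)


@pytest.fixture(scope="session")
def small_sim():
    """A reduced cohort for fast pipeline-level tests."""
    cfg = SimConfig(
        n_chromosomes=2,
        n_domains=10,
        n_patients=14,
        svs_per_patient={"DEL": 2, "DUP": 1},
    )
    genome = simulate_reference(cfg, seed=21)
    cohort = simulate_cohort(cfg, genome, seed=22)
    return cfg, genome, cohort
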