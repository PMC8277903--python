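"""Synthetic genomes and cohorts with planted pathogenic structure.

The generator emulates the study conditions end to end without any external
data: a genome of abutting regulatory domains carrying genes and regulatory
elements; a subset of "active" domains (in adjacent pairs) whose enhancers
are element-rich and marked by high-signal h3k27ac/DNase peaks; and a patient
cohort whose planted pathogenic SVs cross active-active domain boundaries so
that the genes pairing with them gain active elements and have their
expression shifted. Background SVs cross boundaries between inactive domains
and leave expression at baseline, so their pairs are labeled positive only at
the irreducible outlier rate of the z > 1.5 rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    AnnotationTrack,
    Domain,
    DomainSet,
    Gene,
    GenomicInterval,
    PatientMutationIndex,
    StructuralVariant,
    SVGenePair,
)
from .io import SnvCall, build_mutation_index, write_bed, write_expression, write_genes_bed, write_sv_tsv
from .rewiring import build_sv_gene_pairs

CHROMHMM_STATES_SIM = (
    "ctcf",
    "ctcf_enhancer",
    "ctcf_promoter",
    "promoter",
    "poised_promoter",
    "heterochromatin",
    "repressed",
    "transcribed",
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome and cohort."""

    n_chromosomes: int = 4
    chrom_length: int = 2_000_000
    n_domains: int = 20  # per chromosome, abutting tiles
    active_fraction: float = 0.25  # of domains, allocated in adjacent pairs
    genes_per_domain: int = 2
    gene_length: int = 5_000
    enhancers_per_domain: int = 2
    eqtls_per_domain: int = 2
    super_enhancers_per_domain: int = 1
    active_density: int = 3  # gene/element-count multiplier in active domains
    active_bias: float = 0.9  # P(active enhancer carries h3k27ac + DNase peak)
    peaks_per_chrom: int = 30  # background peaks per mark per chromosome
    n_patients: int = 40
    svs_per_patient: dict = field(
        default_factory=lambda: {"DEL": 2, "DUP": 2, "INV": 2, "TRA": 2}
    )
    planted_fraction: float = 0.3
    effect_size: float = 4.0  # expression shift in noise-sd units
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    snvs_per_patient: int = 3
    cnv_events_per_patient: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")
        for name in ("n_chromosomes", "n_domains", "genes_per_domain", "n_patients"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        needed = self.genes_per_domain * self.gene_length * 2
        if self.chrom_length // self.n_domains < needed:
            raise ValueError("domains too small to place the requested genes")


@dataclass
class GenomeBundle:
    config: SimConfig
    domains: DomainSet
    genes: list[Gene]
    elements: dict[str, AnnotationTrack]
    tracks: dict[str, AnnotationTrack]
    active_domains: list[Domain]
    #: peak-marked (h3k27ac + DNase) enhancers/super-enhancers; the planted
    #: pathogenic signature elements
    active_elements: set  # (chrom, start, end, kind)


@dataclass
class CohortBundle:
    config: SimConfig
    svs: list[StructuralVariant]
    snv_calls: dict[str, list[SnvCall]]
    cnv_tables: dict[str, dict[str, float]]
    expression: pd.DataFrame
    truth: list[tuple[str, str, str]]  # (patient, sv_id, gene_id)
    mutation_index: PatientMutationIndex
    pairs: list[SVGenePair]


def _place(rng: np.random.Generator, lo: int, hi: int, length: int) -> tuple[int, int]:
    start = int(rng.integers(lo, hi - length))
    return start, start + length


def simulate_reference(config: SimConfig, seed: int = 0) -> GenomeBundle:
    """Generate the genome bundle: domains, genes, elements, and all peak /
    state tracks. Deterministic under the seed."""
    rng = np.random.default_rng(seed)
    domain_len = config.chrom_length // config.n_domains
    chroms = [str(i + 1) for i in range(config.n_chromosomes)]

    domains: list[Domain] = []
    active_flags: dict[tuple[str, int], bool] = {}
    n_pairs = max(1, int(round(config.active_fraction * config.n_domains / 2)))
    for chrom in chroms:
        # active domains come in adjacent pairs so planted SVs can cross an
        # active-active boundary
        pair_starts = rng.choice(
            np.arange(0, config.n_domains - 1, 2), size=n_pairs, replace=False
        )
        active_idx = set()
        for i in pair_starts:
            active_idx.update((int(i), int(i) + 1))
        for i in range(config.n_domains):
            iv = GenomicInterval(chrom, i * domain_len, (i + 1) * domain_len)
            domains.append(Domain(iv, "tad"))
            active_flags[(chrom, i)] = i in active_idx

    genes: list[Gene] = []
    elements = {k: AnnotationTrack(k) for k in ("eqtl", "enhancer", "super_enhancer")}
    active_elements: set = set()
    tracks = {
        k: AnnotationTrack(k)
        for k in ("h3k4me3", "h3k27me3", "h3k27ac", "h3k4me1", "dnase", "rnapol2", "ctcf", "tfbs", "cpg", "chromhmm")
    }
    active_domains = []

    def add_peak(kind: str, chrom: str, start: int, end: int, signal: float) -> None:
        tracks[kind].add(GenomicInterval(chrom, start, end, signal))

    for dom in domains:
        chrom = dom.interval.chrom
        idx = dom.interval.start // domain_len
        active = active_flags[(chrom, idx)]
        if active:
            active_domains.append(dom)
        lo, hi = dom.interval.start + 100, dom.interval.end - 100
        mult = config.active_density if active else 1
        for j in range(config.genes_per_domain * mult):
            s, e = _place(rng, lo, hi, config.gene_length)
            genes.append(
                Gene(
                    f"g{chrom}_{idx}_{j}",
                    GenomicInterval(chrom, s, e),
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
        specs = (
            ("enhancer", config.enhancers_per_domain * mult, 500),
            ("eqtl", config.eqtls_per_domain * mult, 1),
            ("super_enhancer", config.super_enhancers_per_domain * mult, 3_000),
        )
        for kind, count, length in specs:
            for _ in range(count):
                s, e = _place(rng, lo, hi, length)
                # eQTL signal holds the association p-value (log-uniform)
                sig = 10.0 ** rng.uniform(-8, 0) if kind == "eqtl" else math.nan
                iv = GenomicInterval(chrom, s, e, sig)
                elements[kind].add(iv)
                if active:
                    # the pathogenic signature: enhancers in open chromatin
                    # carrying an active mark; only these define planting
                    if kind in ("enhancer", "super_enhancer") and rng.random() < config.active_bias:
                        active_elements.add((iv.chrom, iv.start, iv.end, kind))
                        add_peak("h3k27ac", chrom, s - 100, e + 100, float(rng.lognormal(3.0, 0.5)))
                        add_peak("dnase", chrom, s - 100, e + 100, float(rng.lognormal(2.5, 0.5)))
                elif kind in ("enhancer", "super_enhancer") and rng.random() < 0.1:
                    add_peak("h3k27ac", chrom, s - 100, e + 100, float(rng.lognormal(0.5, 0.5)))

    for chrom in chroms:
        for kind in ("h3k4me3", "h3k27me3", "h3k4me1", "rnapol2", "ctcf", "tfbs"):
            for _ in range(config.peaks_per_chrom):
                s, e = _place(rng, 0, config.chrom_length, 800)
                add_peak(kind, chrom, s, e, float(rng.lognormal(1.0, 0.5)))
        for _ in range(config.peaks_per_chrom // 2):
            s, e = _place(rng, 0, config.chrom_length, 1_000)
            tracks["cpg"].add(GenomicInterval(chrom, s, e))
        # chromHMM segmentation: 5 kb tiles with heterochromatin-heavy states
        probs = np.array([0.05, 0.03, 0.03, 0.06, 0.04, 0.45, 0.2, 0.14])
        for pos in range(0, config.chrom_length, 5_000):
            state = CHROMHMM_STATES_SIM[int(rng.choice(len(CHROMHMM_STATES_SIM), p=probs))]
            tracks["chromhmm"].add(
                GenomicInterval(chrom, pos, min(pos + 5_000, config.chrom_length), name=state)
            )

    return GenomeBundle(
        config=config,
        domains=DomainSet(domains),
        genes=genes,
        elements=elements,
        tracks=tracks,
        active_domains=active_domains,
        active_elements=active_elements,
    )


def _boundary_pairs(genome: GenomeBundle, active: bool) -> list[tuple[Domain, Domain]]:
    """Adjacent domain pairs whose shared boundary an SV can cross, filtered
    to active-active or inactive-inactive pairs."""
    active_ids = {id(d) for d in genome.active_domains}
    out = []
    for chrom, ds in genome.domains.by_chrom.items():
        for a, b in zip(ds, ds[1:]):
            a_act, b_act = id(a) in active_ids, id(b) in active_ids
            if active and a_act and b_act:
                out.append((a, b))
            elif not active and not a_act and not b_act:
                out.append((a, b))
    return out


def _domains_by_activity(genome: GenomeBundle, active: bool) -> list[Domain]:
    active_ids = {id(d) for d in genome.active_domains}
    return [
        d for d in genome.domains
        if (id(d) in active_ids) == active
    ]


def simulate_cohort(config: SimConfig, genome: GenomeBundle, seed: int = 0) -> CohortBundle:
    """Generate per-patient SVs, SNVs, CNVs, expression, and the planted
    truth table.

    A ``planted_fraction`` of SVs cross active-active boundaries; every gene
    pairing with such an SV and gaining at least one active element has its
    expression shifted by ``effect_size * noise_sd`` and enters the truth
    table. The truth pairs are by construction a subset of the pairs the
    rewiring stage produces on the same inputs.
    """
    rng = np.random.default_rng(seed)
    patients = [f"p{i:03d}" for i in range(config.n_patients)]
    active_pairs = _boundary_pairs(genome, active=True)
    background_pairs = _boundary_pairs(genome, active=False)
    if not active_pairs or not background_pairs:
        raise ValueError("genome lacks active-active or inactive-inactive boundaries")
    active_doms = _domains_by_activity(genome, True)
    inactive_doms = _domains_by_activity(genome, False)

    svs: list[StructuralVariant] = []
    planted_ids: set[str] = set()
    counter = 0

    def breakpoint_in(dom: Domain, margin_frac: float = 0.15) -> int:
        iv = dom.interval
        w = iv.length
        return int(rng.integers(iv.start + int(w * margin_frac), iv.end - int(w * margin_frac)))

    for patient in patients:
        for sv_type, count in sorted(config.svs_per_patient.items()):
            for _ in range(count):
                counter += 1
                sv_id = f"sv{counter:05d}"
                planted = bool(rng.random() < config.planted_fraction)
                if sv_type == "TRA":
                    doms = active_doms if planted else inactive_doms
                    chroms_avail = sorted({d.interval.chrom for d in doms})
                    c1, c2 = rng.choice(chroms_avail, size=2, replace=False)
                    d1 = [d for d in doms if d.interval.chrom == c1][
                        int(rng.integers(0, len([d for d in doms if d.interval.chrom == c1])))
                    ]
                    d2 = [d for d in doms if d.interval.chrom == c2][
                        int(rng.integers(0, len([d for d in doms if d.interval.chrom == c2])))
                    ]
                    sv = StructuralVariant(
                        sv_id,
                        patient,
                        "TRA",
                        d1.interval.chrom,
                        breakpoint_in(d1),
                        "+" if rng.random() < 0.5 else "-",
                        d2.interval.chrom,
                        breakpoint_in(d2),
                        "+" if rng.random() < 0.5 else "-",
                    )
                else:
                    pool = active_pairs if planted else background_pairs
                    left, right = pool[int(rng.integers(0, len(pool)))]
                    s = breakpoint_in(left)
                    e = breakpoint_in(right)
                    sv = StructuralVariant(
                        sv_id, patient, sv_type,
                        left.interval.chrom, s, "+",
                        right.interval.chrom, e, "-",
                    )
                svs.append(sv)
                if planted:
                    planted_ids.add(sv_id)

    gene_ids = [g.gene_id for g in genome.genes]
    snv_calls: dict[str, list[SnvCall]] = {}
    cnv_tables: dict[str, dict[str, float]] = {}
    impacts = ["LOW", "MODERATE", "HIGH"]
    for patient in patients:
        calls = []
        for _ in range(config.snvs_per_patient):
            g = genome.genes[int(rng.integers(0, len(genome.genes)))]
            pos = int(rng.integers(g.interval.start, g.interval.end))
            calls.append(SnvCall(g.interval.chrom, pos, impacts[int(rng.integers(0, 3))]))
        snv_calls[patient] = calls
        table = {gid: float(np.round(rng.normal(2.0, 0.05), 3)) for gid in gene_ids}
        for _ in range(config.cnv_events_per_patient):
            gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
            table[gid] = float(rng.choice([1.0, 3.5]))
        cnv_tables[patient] = table

    mutation_index = build_mutation_index(snv_calls, cnv_tables, svs, genome.genes)
    pairs = build_sv_gene_pairs(svs, genome.domains, genome.genes, genome.elements, mutation_index)

    baseline = {gid: float(rng.normal(config.baseline_mean, config.baseline_sd)) for gid in gene_ids}
    expr = pd.DataFrame(
        rng.normal(0.0, config.noise_sd, size=(len(gene_ids), len(patients))),
        index=gene_ids,
        columns=patients,
    )
    for gid in gene_ids:
        expr.loc[gid] += baseline[gid]

    truth: list[tuple[str, str, str]] = []
    for p in pairs:
        if p.sv_id not in planted_ids:
            continue
        directions = {
            r.direction
            for r in p.records
            if (r.element.chrom, r.element.start, r.element.end, r.element_kind)
            in genome.active_elements
        }
        if "gain" in directions:
            # hijacking an active enhancer upregulates the gene
            expr.at[p.gene_id, p.patient] += config.effect_size * config.noise_sd
            truth.append((p.patient, p.sv_id, p.gene_id))
        elif "loss" in directions:
            # losing an active enhancer downregulates it
            expr.at[p.gene_id, p.patient] -= config.effect_size * config.noise_sd
            truth.append((p.patient, p.sv_id, p.gene_id))

    return CohortBundle(
        config=config,
        svs=svs,
        snv_calls=snv_calls,
        cnv_tables=cnv_tables,
        expression=expr,
        truth=truth,
        mutation_index=mutation_index,
        pairs=pairs,
    )


# ---------------------------------------------------------------------------
# File export (all standard formats, so the readers are exercised end to end)
# ---------------------------------------------------------------------------

def write_genome(genome: GenomeBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tad_track = AnnotationTrack("tad", (d.interval for d in genome.domains))
    write_bed(tad_track, out / "tads.bed")
    write_genes_bed(genome.genes, out / "genes.bed")
    for kind, track in genome.elements.items():
        write_bed(track, out / f"{kind}s.bed")
    for kind, track in genome.tracks.items():
        write_bed(track, out / f"{kind}.bed")


def _write_snv_vcf(calls: Sequence[SnvCall], chrom_length: int, chroms: Sequence[str], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={chrom_length}>\n")
        fh.write('##INFO=<ID=IMPACT,Number=1,Type=String,Description="Predicted functional impact">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, call in enumerate(sorted(calls, key=lambda c: (c.chrom, c.start))):
            fh.write(f"{call.chrom}\t{call.start + 1}\tsnv{i}\tA\tT\t.\tPASS\tIMPACT={call.impact}\n")


def write_cohort(cohort: CohortBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_sv_tsv(cohort.svs, out / "sv_calls.tsv")
    write_expression(cohort.expression, out / "expression.tsv")
    chroms = [str(i + 1) for i in range(cohort.config.n_chromosomes)]
    snv_dir = out / "snv"
    snv_dir.mkdir(exist_ok=True)
    for patient, calls in sorted(cohort.snv_calls.items()):
        _write_snv_vcf(calls, cohort.config.chrom_length, chroms, snv_dir / f"{patient}.vcf")
    cnv_dir = out / "cnv"
    cnv_dir.mkdir(exist_ok=True)
    for patient, table in sorted(cohort.cnv_tables.items()):
        with open(cnv_dir / f"{patient}.tsv", "w") as fh:
            for gid in sorted(table):
                fh.write(f"{gid}\t{table[gid]}\n")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("patient\tsv_id\tgene_id\n")
        for patient, sv_id, gene_id in sorted(cohort.truth):
            fh.write(f"{patient}\t{sv_id}\t{gene_id}\n")
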