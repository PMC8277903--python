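"""Derivative-domain rewiring on a hand-built locus.

Two abutting 100-kb domains; a deletion removes the boundary between them,
fusing the domains so the left-domain gene gains the right-domain enhancer.
An inversion spanning the same boundary instead reflects content across it.
"""

from tadmil import (
    AnnotationTrack,
    Domain,
    DomainSet,
    Gene,
    GenomicInterval,
    StructuralVariant,
    build_sv_gene_pairs,
)

domains = DomainSet(
    [Domain(GenomicInterval("1", 0, 100_000)), Domain(GenomicInterval("1", 100_000, 200_000))]
)
genes = [Gene("MYC_like", GenomicInterval("1", 10_000, 15_000))]
elements = {
    "enhancer": AnnotationTrack("enhancer", [GenomicInterval("1", 150_000, 151_000)]),
    "eqtl": AnnotationTrack("eqtl", [GenomicInterval("1", 30_000, 30_001)]),
    "super_enhancer": AnnotationTrack("super_enhancer"),
}

deletion = StructuralVariant("del1", "patient1", "DEL", "1", 90_000, "+", "1", 110_000, "-")
inversion = StructuralVariant("inv1", "patient1", "INV", "1", 50_000, "+", "1", 150_500, "-")

for sv in (deletion, inversion):
    pairs = build_sv_gene_pairs([sv], domains, genes, elements)
    print(f"{sv.sv_type} {sv.chrom1}:{sv.pos1}-{sv.pos2}")
    for pair in pairs:
        for rec in pair.records:
            print(
                f"  {pair.gene_id} {rec.direction}s {rec.element_kind} "
                f"{rec.element.chrom}:{rec.element.start}-{rec.element.end}"
            )
    if not pairs:
        print("  no SV-gene pairs")

# The deletion fuses the domains: the gene gains the enhancer that used to
# sit behind the boundary. The inversion moves the enhancer's sequence into
# the left domain ([150000,150500) reflects to [50000,50500)), so the gene
# gains the enhancer fragment without any sequence being lost.
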