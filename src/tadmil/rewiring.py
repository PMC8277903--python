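"""Derivative-domain construction for boundary-disrupting SVs.

Each SV type rearranges the regulatory domains (TADs or CTCF-loop domains)
containing its breakpoints. The rules model which regulatory elements a gene
newly shares a domain with (gains) or no longer shares a domain with (losses):

* deletion: the two flanking domains fuse; genes on either side of the
  deleted span gain the elements on the other side. Genes and elements
  overlapped by the deleted span itself are not counted.
* tandem duplication: the duplicated copy re-inserts the overlapped boundary,
  creating a new domain joining the duplicated tail of the right endpoint
  domain to the duplicated head of the left endpoint domain; genes and
  elements overlapped by the duplication on opposite sides of the boundary
  meet there.
* inversion: domain intervals stay fixed while the inverted sequence is
  reflected in place; membership of genes and elements in the two endpoint
  domains is re-evaluated after reflection.
* translocation: the retained side of each breakpoint's domain (given by the
  orientations) joins into one derivative domain; retained genes gain the
  other side's retained elements and lose the elements on the lost side of
  their own domain.

Only the two domains containing the SV endpoints are modeled; a minimum of
1 bp overlap defines membership throughout.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .core import (
    AnnotationTrack,
    Domain,
    DomainSet,
    GainLossRecord,
    Gene,
    GenomicInterval,
    PatientMutationIndex,
    StructuralVariant,
    SVGenePair,
)

logger = logging.getLogger("tadmil")


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def select_boundary_disrupting_svs(
    svs: Sequence[StructuralVariant], domains: DomainSet
) -> list[StructuralVariant]:
    """SVs whose breakpoints both fall inside domains and whose span (or
    junction, for translocations) crosses at least one domain boundary.

    Intra-domain SVs and SVs with a breakpoint outside every domain (e.g. in
    a gap between domains) are excluded.
    """
    selected = []
    for sv in svs:
        d1 = domains.at(sv.chrom1, sv.pos1)
        d2 = domains.at(sv.chrom2, sv.pos2)
        if d1 is None or d2 is None:
            logger.debug("SV %s: breakpoint outside all domains; excluded", sv.sv_id)
            continue
        if sv.sv_type == "TRA":
            selected.append(sv)  # an inter-domain junction by construction
        elif d1 is not d2:
            selected.append(sv)
    return selected


def _element_intervals(elements: dict[str, AnnotationTrack]) -> list[tuple[GenomicInterval, str]]:
    out = []
    for kind, track in elements.items():
        for iv in track:
            out.append((iv, kind))
    return out


def _share_any_domain(
    a: GenomicInterval,
    b: GenomicInterval,
    domains: DomainSet,
    exclude: tuple = (),
) -> bool:
    if a.chrom != b.chrom:
        return False
    skip = {id(d) for d in exclude}
    da = {id(d) for d in domains.overlapping(a.chrom, a.start, a.end)} - skip
    db = {id(d) for d in domains.overlapping(b.chrom, b.start, b.end)} - skip
    return bool(da & db)


def rewire_deletion(
    sv: StructuralVariant,
    domains: DomainSet,
    genes: Sequence[Gene],
    elements: dict[str, AnnotationTrack],
) -> list[GainLossRecord]:
    """Gains created by fusing the two domains flanking a deletion.

    Deletions only produce gains: nothing is relocated, and elements removed
    by the deletion itself are not counted.
    """
    chrom, s, e = sv.span
    left = domains.at(chrom, s)
    right = domains.at(chrom, e)
    if left is None or right is None or left is right:
        return []

    def survives(iv: GenomicInterval, dom: Domain) -> bool:
        di = dom.interval
        return (
            iv.chrom == chrom
            and _overlap(iv.start, iv.end, di.start, di.end)
            and not _overlap(iv.start, iv.end, s, e)
        )

    genes_left = [g for g in genes if survives(g.interval, left)]
    genes_right = [g for g in genes if survives(g.interval, right)]
    elems = _element_intervals(elements)
    elems_left = [(iv, k) for iv, k in elems if survives(iv, left)]
    elems_right = [(iv, k) for iv, k in elems if survives(iv, right)]

    records = []
    for gs, els in ((genes_left, elems_right), (genes_right, elems_left)):
        for g in gs:
            for iv, kind in els:
                if not _share_any_domain(g.interval, iv, domains):
                    records.append(GainLossRecord(g.gene_id, iv, kind, "gain"))
    return records


def rewire_duplication(
    sv: StructuralVariant,
    domains: DomainSet,
    genes: Sequence[Gene],
    elements: dict[str, AnnotationTrack],
) -> list[GainLossRecord]:
    """Gains inside the new domain created by a tandem duplication.

    The duplicated copy re-inserts the disrupted boundary immediately 3' of
    the original span, so the duplicated tail of the right endpoint domain
    and the duplicated head of the left endpoint domain end up sharing one
    new domain. Genes overlapped by the duplication on one side of the
    boundary gain elements overlapped by the duplication on the other side.
    """
    chrom, s, e = sv.span
    left = domains.at(chrom, s)
    right = domains.at(chrom, e)
    if left is None or right is None or left is right:
        return []
    # portions of the duplicated span lying in each endpoint domain
    side_l = (s, min(e, left.interval.end))
    side_r = (max(s, right.interval.start), e)
    if side_l[0] >= side_l[1] or side_r[0] >= side_r[1]:
        return []  # no boundary strictly inside the duplicated span

    def over(iv: GenomicInterval, span: tuple[int, int]) -> bool:
        return iv.chrom == chrom and _overlap(iv.start, iv.end, *span)

    elems = _element_intervals(elements)
    records = []
    for g_span, e_span in ((side_l, side_r), (side_r, side_l)):
        for g in genes:
            if not over(g.interval, g_span):
                continue
            for iv, kind in elems:
                if over(iv, e_span) and not _share_any_domain(g.interval, iv, domains):
                    records.append(GainLossRecord(g.gene_id, iv, kind, "gain"))
    return _dedup(records)


def _reflect_fragments(
    iv: GenomicInterval, s: int, e: int
) -> list[tuple[int, int]]:
    """Post-inversion fragments of an interval under p -> (s + e - 1) - p for
    the part inside [s, e); parts outside stay in place."""
    frags = []
    if iv.start < s:
        frags.append((iv.start, min(iv.end, s)))
    if iv.end > e:
        frags.append((max(iv.start, e), iv.end))
    c, d = max(iv.start, s), min(iv.end, e)
    if c < d:
        frags.append((s + e - d, s + e - c))
    return frags


def rewire_inversion(
    sv: StructuralVariant,
    domains: DomainSet,
    genes: Sequence[Gene],
    elements: dict[str, AnnotationTrack],
) -> list[GainLossRecord]:
    """Gains and losses from reflecting the inverted sequence in place.

    Domain intervals are fixed; genes and elements are mapped through the
    reflection and their membership in the two endpoint domains re-evaluated.
    A gene gains an element it newly shares an endpoint domain with and loses
    one it no longer shares an endpoint domain with.
    """
    chrom, s, e = sv.span
    left = domains.at(chrom, s)
    right = domains.at(chrom, e)
    if left is None or right is None or left is right:
        return []
    world = (left.interval, right.interval)

    def membership(frags: list[tuple[int, int]]) -> frozenset[int]:
        out = set()
        for i, dom in enumerate(world):
            if any(_overlap(a, b, dom.start, dom.end) for a, b in frags):
                out.add(i)
        return frozenset(out)

    def states(iv: GenomicInterval) -> tuple[frozenset[int], frozenset[int]]:
        if iv.chrom != chrom:
            return frozenset(), frozenset()
        before = membership([(iv.start, iv.end)])
        after = membership(_reflect_fragments(iv, s, e))
        return before, after

    gene_states = [(g, *states(g.interval)) for g in genes]
    gene_states = [t for t in gene_states if t[1] or t[2]]
    elem_states = [(iv, k, *states(iv)) for iv, k in _element_intervals(elements)]
    elem_states = [t for t in elem_states if t[2] or t[3]]

    records = []
    for g, g_before, g_after in gene_states:
        for iv, kind, e_before, e_after in elem_states:
            shared_before = bool(g_before & e_before)
            shared_after = bool(g_after & e_after)
            if shared_after and not shared_before:
                records.append(GainLossRecord(g.gene_id, iv, kind, "gain"))
            elif shared_before and not shared_after:
                records.append(GainLossRecord(g.gene_id, iv, kind, "loss"))
    return records


def _retained_lost(
    dom: Domain, pos: int, orient: str
) -> tuple[tuple[int, int], tuple[int, int]]:
    di = dom.interval
    if orient == "+":  # 5' side retained
        return (di.start, pos), (pos, di.end)
    return (pos, di.end), (di.start, pos)


def rewire_translocation(
    sv: StructuralVariant,
    domains: DomainSet,
    genes: Sequence[Gene],
    elements: dict[str, AnnotationTrack],
) -> list[GainLossRecord]:
    """Gains and losses in the derivative domain joining the retained sides
    of the two breakpoint domains (per the SV orientations).

    Genes on each retained segment gain the elements of the other retained
    segment, and lose the elements of the lost segment of their own domain
    (unless the element itself partially survives on a retained segment).
    """
    if sv.orient1 not in "+-" or sv.orient2 not in "+-":
        raise ValueError(f"TRA {sv.sv_id} is missing an orientation")
    d1 = domains.at(sv.chrom1, sv.pos1)
    d2 = domains.at(sv.chrom2, sv.pos2)
    if d1 is None or d2 is None:
        return []
    ret1, lost1 = _retained_lost(d1, sv.pos1, sv.orient1)
    ret2, lost2 = _retained_lost(d2, sv.pos2, sv.orient2)
    sides = (
        (sv.chrom1, ret1, lost1, sv.chrom2, ret2),
        (sv.chrom2, ret2, lost2, sv.chrom1, ret1),
    )
    untouched = lambda a, b: _share_any_domain(a, b, domains, exclude=(d1, d2))

    def over(iv: GenomicInterval, chrom: str, span: tuple[int, int]) -> bool:
        return iv.chrom == chrom and span[0] < span[1] and _overlap(iv.start, iv.end, *span)

    elems = _element_intervals(elements)
    records = []
    for g_chrom, g_ret, g_lost, o_chrom, o_ret in sides:
        for g in genes:
            if not over(g.interval, g_chrom, g_ret):
                continue
            for iv, kind in elems:
                if over(iv, o_chrom, o_ret):
                    if not _share_any_domain(g.interval, iv, domains):
                        records.append(GainLossRecord(g.gene_id, iv, kind, "gain"))
                elif (
                    over(iv, g_chrom, g_lost)
                    and not over(iv, g_chrom, g_ret)
                    and not over(iv, o_chrom, o_ret)
                    and not untouched(g.interval, iv)
                ):
                    # still a shared home if both also touch a domain the
                    # translocation leaves intact
                    records.append(GainLossRecord(g.gene_id, iv, kind, "loss"))
    return _dedup(records)


def _dedup(records: list[GainLossRecord]) -> list[GainLossRecord]:
    seen: set = set()
    out = []
    for r in records:
        key = (r.gene_id, r.element, r.element_kind, r.direction)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


_REWIRERS = {
    "DEL": rewire_deletion,
    "DUP": rewire_duplication,
    "INV": rewire_inversion,
    "TRA": rewire_translocation,
}


def rewire_sv(
    sv: StructuralVariant,
    domains: DomainSet,
    genes: Sequence[Gene],
    elements: dict[str, AnnotationTrack],
) -> list[GainLossRecord]:
    return _REWIRERS[sv.sv_type](sv, domains, genes, elements)


def build_sv_gene_pairs(
    svs: Sequence[StructuralVariant],
    domains: DomainSet,
    genes: Sequence[Gene],
    elements: dict[str, AnnotationTrack],
    mutation_index: Optional[PatientMutationIndex] = None,
) -> list[SVGenePair]:
    """Construct one bag per (boundary-disrupting SV, gene) with at least one
    gained or lost element.

    Pairs are dropped when the gene carries a coding mutation in that patient
    (moderate/high-impact SNV, copy number outside [1.7, 2.3], or overlap by
    any SV span) -- except that a duplication or inversion may overlap the
    very gene it pairs with. Genes entering any surviving pair are flagged
    ``noncoding_sv`` in the mutation index so they are excluded from
    expression reference panels downstream.
    """
    selected = select_boundary_disrupting_svs(svs, domains)
    pairs: list[SVGenePair] = []
    for sv in selected:
        records = rewire_sv(sv, domains, genes, elements)
        by_gene: dict[str, list[GainLossRecord]] = {}
        for r in records:
            by_gene.setdefault(r.gene_id, []).append(r)
        for gene_id in sorted(by_gene):
            if mutation_index is not None:
                flags = mutation_index.get(sv.patient, gene_id)
                if flags.coding_snv or flags.cnv_out_of_range:
                    continue
                blocking = set(flags.coding_sv_ids)
                if sv.sv_type in ("DUP", "INV"):
                    blocking.discard(sv.sv_id)
                if blocking:
                    continue
            pairs.append(
                SVGenePair(
                    sv_id=sv.sv_id,
                    patient=sv.patient,
                    gene_id=gene_id,
                    sv_type=sv.sv_type,
                    records=sorted(
                        by_gene[gene_id],
                        key=lambda r: (
                            r.element_kind,
                            r.element.chrom,
                            r.element.start,
                            r.element.end,
                            r.direction,
                        ),
                    ),
                )
            )
    pairs.sort(key=lambda p: (p.patient, p.sv_id, p.gene_id))
    if mutation_index is not None:
        for p in pairs:
            mutation_index.mark_noncoding(p.patient, p.gene_id)
    return pairs
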