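"""Independent brute-force oracles used by the test suite.

The rewiring oracle materializes the derivative genome per basepair: it
builds the derivative coordinate map for each SV type, re-derives domain
membership for every gene and element position by position, and diffs the
shared-domain sets. It shares no code with the package implementation.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ToyEntity:
    eid: str
    chrom: str
    start: int
    end: int
    kind: str = ""  # "" for genes


def positions(e: ToyEntity) -> list[tuple[str, int]]:
    return [(e.chrom, p) for p in range(e.start, e.end)]


def _domain_of(boundaries: dict[str, list[int]], chrom: str, pos: int):
    """Index of the domain containing pos among intervals between consecutive
    boundary positions; None outside the covered range."""
    bs = boundaries.get(chrom, [])
    for i in range(len(bs) - 1):
        if bs[i] <= pos < bs[i + 1]:
            return (chrom, i)
    return None


def _original_membership(domains: list[tuple[str, int, int]], e: ToyEntity) -> set:
    out = set()
    for i, (chrom, s, t) in enumerate(domains):
        if e.chrom == chrom and any(s <= p < t for _, p in positions(e)):
            out.add(i)
    return out


def _records(genes, elements, old_m, new_m) -> set:
    recs = set()
    for g in genes:
        for el in elements:
            before = bool(old_m[g.eid] & old_m[el.eid])
            after = bool(new_m[g.eid] & new_m[el.eid])
            if after and not before:
                recs.add((g.eid, el.chrom, el.start, el.end, el.kind, "gain"))
            elif before and not after:
                recs.add((g.eid, el.chrom, el.start, el.end, el.kind, "loss"))
    return recs


def oracle_deletion(domains, genes, elements, chrom, s, e) -> set:
    """domains: list of (chrom, start, end) tiles; genes/elements ToyEntity."""
    # entities touched by the deleted span are not counted at all
    genes = [g for g in genes if not (g.chrom == chrom and g.start < e and s < g.end)]
    elements = [el for el in elements if not (el.chrom == chrom and el.start < e and s < el.end)]

    # surviving boundary cut-positions, shifted through the deletion
    bounds: dict[str, list[int]] = {}
    for dchrom, ds, dt in domains:
        for b in (ds, dt):
            if dchrom == chrom and s < b < e:
                continue
            nb = b if (dchrom != chrom or b <= s) else b - (e - s)
            bounds.setdefault(dchrom, []).append(nb)
    for c in bounds:
        bounds[c] = sorted(set(bounds[c]))

    def map_pos(c, p):
        if c != chrom or p < s:
            return (c, p)
        if p >= e:
            return (c, p - (e - s))
        return None

    old_m = {x.eid: _original_membership(domains, x) for x in genes + elements}
    new_m = {}
    for x in genes + elements:
        mem = set()
        for c, p in positions(x):
            mp = map_pos(c, p)
            if mp is not None:
                d = _domain_of(bounds, *mp)
                if d is not None:
                    mem.add(d)
        new_m[x.eid] = mem
    return _records(genes, elements, old_m, new_m)


def oracle_duplication(domains, genes, elements, chrom, s, e) -> set:
    ln = e - s
    bounds: dict[str, list[int]] = {}
    for dchrom, ds, dt in domains:
        for b in (ds, dt):
            if dchrom != chrom:
                bounds.setdefault(dchrom, []).append(b)
                continue
            bounds.setdefault(dchrom, []).append(b if b <= e else b + ln)
            if s < b < e:  # the duplicated copy re-inserts this boundary
                bounds.setdefault(dchrom, []).append(e + (b - s))
    for c in bounds:
        bounds[c] = sorted(set(bounds[c]))

    def map_pos(c, p):
        if c != chrom:
            return [(c, p)]
        out = [(c, p) if p < e else (c, p + ln)]
        if s <= p < e:
            out.append((c, e + (p - s)))
        return out

    old_m = {x.eid: _original_membership(domains, x) for x in genes + elements}
    new_m = {}
    for x in genes + elements:
        mem = set()
        for c, p in positions(x):
            for mp in map_pos(c, p):
                d = _domain_of(bounds, *mp)
                if d is not None:
                    mem.add(d)
        new_m[x.eid] = mem
    return _records(genes, elements, old_m, new_m)


def oracle_inversion(domains, genes, elements, chrom, s, e) -> set:
    """Domain intervals stay fixed; only membership in the two endpoint
    domains is modeled."""
    endpoint = [
        i
        for i, (dchrom, ds, dt) in enumerate(domains)
        if dchrom == chrom and (ds <= s < dt or ds <= e < dt)
    ]

    def member(bp_list) -> set:
        mem = set()
        for i in endpoint:
            dchrom, ds, dt = domains[i]
            if any(c == dchrom and ds <= p < dt for c, p in bp_list):
                mem.add(i)
        return mem

    def mapped(x: ToyEntity):
        out = []
        for c, p in positions(x):
            if c == chrom and s <= p < e:
                out.append((c, (s + e - 1) - p))
            else:
                out.append((c, p))
        return out

    old_m = {x.eid: member(positions(x)) for x in genes + elements}
    new_m = {x.eid: member(mapped(x)) for x in genes + elements}
    return _records(genes, elements, old_m, new_m)


def oracle_translocation(domains, genes, elements, sv) -> set:
    """sv: object with chrom1/pos1/orient1, chrom2/pos2/orient2; '+' retains
    the 5' side of the breakpoint."""

    def endpoint_domain(chrom, pos):
        for i, (dchrom, ds, dt) in enumerate(domains):
            if dchrom == chrom and ds <= pos < dt:
                return i
        return None

    i1 = endpoint_domain(sv.chrom1, sv.pos1)
    i2 = endpoint_domain(sv.chrom2, sv.pos2)
    if i1 is None or i2 is None:
        return set()

    def retained(i, pos, orient):
        chrom, ds, dt = domains[i]
        return (chrom, ds, pos) if orient == "+" else (chrom, pos, dt)

    r1 = retained(i1, sv.pos1, sv.orient1)
    r2 = retained(i2, sv.pos2, sv.orient2)

    def in_new(x: ToyEntity) -> bool:
        for c, p in positions(x):
            for rc, rs, rt in (r1, r2):
                if c == rc and rs <= p < rt:
                    return True
        return False

    old_m = {x.eid: _original_membership(domains, x) for x in genes + elements}
    # domains other than the two breakpoint domains are untouched; the lost
    # segments join the unmodeled reciprocal product and so have no new home
    new_m = {}
    for x in genes + elements:
        mem = {d for d in old_m[x.eid] if d not in (i1, i2)}
        if in_new(x):
            mem.add("new")
        new_m[x.eid] = mem
    # only genes on a retained segment produce records
    genes = [g for g in genes if in_new(g)]
    return _records(genes, elements, old_m, new_m)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def brute_force_auc(labels, scores) -> float:
    """Pairwise-comparison AUC; ties contribute one half."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_overlaps(intervals, chrom, start, end):
    """O(n) scan for intervals sharing >= 1 bp with [start, end)."""
    return [
        iv
        for iv in intervals
        if iv.chrom == chrom and iv.start < end and start < iv.end
    ]
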