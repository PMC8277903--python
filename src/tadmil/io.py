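"""Readers and writers for the standard-format inputs.

BED 3/5-column for regulatory tracks (chromHMM as BED4 with the state in the
name column), VCF 4.2 for SVs (symbolic SVTYPE alleles plus BND breakends) and
for impact-annotated SNVs, a simple TSV dialect for SVs, and gene x patient
TSV matrices for copy number and expression. All VCF coordinates (1-based) are
converted to the internal 0-based half-open convention on read.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .core import (
    AnnotationTrack,
    Gene,
    GenomicInterval,
    PatientMutationIndex,
    StructuralVariant,
    SVGenePair,
    norm_chrom,
)

logger = logging.getLogger("tadmil")

#: copy-number tolerance around the diploid state; outside [2-delta, 2+delta]
#: a gene is considered copy-number disturbed
CNV_DELTA = 0.3

HIGH_IMPACT = frozenset({"MODERATE", "HIGH"})


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, kind: str) -> AnnotationTrack:
    """Read a BED3/4/5 file into an :class:`AnnotationTrack`.

    Column 4 maps to ``name`` (the chromHMM state for chromhmm tracks) and
    column 5 to ``signal``. Raises on malformed lines, naming the line number.
    """
    track = AnnotationTrack(kind)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            signal = math.nan
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    signal = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad score field") from exc
            try:
                track.add(GenomicInterval(fields[0], start, end, signal, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return track


def _fmt_score(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


def write_bed(track: AnnotationTrack, path: str | Path) -> None:
    """Write a track back to canonical BED.

    Intervals with neither name nor signal are written as BED3; a name alone
    as BED4; a signal always forces five columns (name ``.`` when absent), so
    ``write_bed(read_bed(x))`` is byte-identical for canonical 3/5-column BED.
    """
    with open(path, "w") as fh:
        for iv in track:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            has_signal = not math.isnan(iv.signal)
            if iv.name is not None or has_signal:
                cols.append(iv.name if iv.name is not None else ".")
            if has_signal:
                cols.append(_fmt_score(iv.signal))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

_BND_RE = re.compile(r"^(?P<head>[ACGTNacgtn]*)(?P<b1>[\[\]])(?P<chrom>[^:]+):(?P<pos>\d+)(?P<b2>[\[\]])(?P<tail>[ACGTNacgtn]*)$")


def read_sv_calls(path: str | Path, dialect: str = "tsv", patient: Optional[str] = None) -> list[StructuralVariant]:
    """Read somatic SV calls from ``tsv`` or ``vcf_bnd`` input.

    The TSV dialect has columns patient, sv_type, chrom1, pos1, orient1,
    chrom2, pos2, orient2 (0-based positions, no header required). VCF input
    is 1-based and converted; BND mate pairs are merged into single TRA
    records, and unmatched mates or unknown SVTYPEs are dropped with a log
    entry.
    """
    if dialect == "tsv":
        return _read_sv_tsv(path)
    if dialect == "vcf_bnd":
        return _read_sv_vcf(path, patient=patient)
    raise ValueError(f"unknown SV dialect {dialect!r}")


def _read_sv_tsv(path: str | Path) -> list[StructuralVariant]:
    svs: list[StructuralVariant] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0] == "patient":  # optional header
                continue
            if len(f) < 8:
                raise ValueError(f"{path}:{lineno}: expected 8 columns")
            svs.append(
                StructuralVariant(
                    sv_id=f[8] if len(f) > 8 else f"sv{lineno}",
                    patient=f[0],
                    sv_type=f[1],
                    chrom1=f[2],
                    pos1=int(f[3]),
                    orient1=f[4],
                    chrom2=f[5],
                    pos2=int(f[6]),
                    orient2=f[7],
                )
            )
    return svs


def write_sv_tsv(svs: Sequence[StructuralVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("patient\tsv_type\tchrom1\tpos1\torient1\tchrom2\tpos2\torient2\tsv_id\n")
        for sv in svs:
            fh.write(
                f"{sv.patient}\t{sv.sv_type}\t{sv.chrom1}\t{sv.pos1}\t{sv.orient1}\t"
                f"{sv.chrom2}\t{sv.pos2}\t{sv.orient2}\t{sv.sv_id}\n"
            )


def _parse_bnd_alt(alt: str) -> Optional[tuple[str, int, str, str]]:
    """Parse a breakend ALT into (mate_chrom, mate_pos0, local_orient,
    mate_orient). ``+`` retains the 5' side of the breakpoint."""
    m = _BND_RE.match(alt)
    if not m:
        return None
    local_orient = "+" if m.group("head") else "-"
    # "[p[": junction continues with the sequence right of p -> mate keeps 3'
    mate_orient = "-" if m.group("b1") == "[" else "+"
    return norm_chrom(m.group("chrom")), int(m.group("pos")) - 1, local_orient, mate_orient


def _read_sv_vcf(path: str | Path, patient: Optional[str] = None) -> list[StructuralVariant]:
    svs: list[StructuralVariant] = []
    pending: dict[tuple, tuple] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            pat = patient or rec.info.get("PATIENT") or Path(path).stem
            if svtype in ("DEL", "DUP", "INV"):
                # POS is the base before the event; END the last affected base
                start = rec.pos - 1
                end = rec.stop
                svs.append(
                    StructuralVariant(
                        sv_id=rec.id or f"{svtype}_{rec.chrom}_{rec.pos}",
                        patient=pat,
                        sv_type=svtype,
                        chrom1=rec.chrom,
                        pos1=start,
                        orient1="+",
                        chrom2=rec.chrom,
                        pos2=end,
                        orient2="-",
                    )
                )
            elif svtype == "BND":
                parsed = _parse_bnd_alt(rec.alts[0])
                if parsed is None:
                    logger.warning("unparseable BND ALT %s at %s:%s", rec.alts[0], rec.chrom, rec.pos)
                    continue
                mate_chrom, mate_pos, local_orient, mate_orient = parsed
                here = (norm_chrom(rec.chrom), rec.pos - 1)
                mate_key = (mate_chrom, mate_pos)
                if mate_key in pending:
                    first_id, first_here, first_orients = pending.pop(mate_key)
                    svs.append(
                        StructuralVariant(
                            sv_id=first_id,
                            patient=pat,
                            sv_type="TRA",
                            chrom1=first_here[0],
                            pos1=first_here[1],
                            orient1=first_orients[0],
                            chrom2=here[0],
                            pos2=here[1],
                            orient2=local_orient,
                        )
                    )
                else:
                    pending[here] = (rec.id or f"bnd_{rec.chrom}_{rec.pos}", here, (local_orient, mate_orient))
            else:
                logger.warning("dropping record with unknown SVTYPE %r at %s:%s", svtype, rec.chrom, rec.pos)
    for key, (sv_id, _, _) in pending.items():
        logger.warning("unmatched BND mate %s (%s:%d); dropped", sv_id, key[0], key[1])
    return svs


# ---------------------------------------------------------------------------
# Genes, SNVs, CNVs, expression
# ---------------------------------------------------------------------------

def read_genes_bed(path: str | Path) -> list[Gene]:
    """Gene annotation as BED4(+strand): chrom, start, end, gene_id[, score, strand]."""
    genes: list[Gene] = []
    seen: set[str] = set()
    track = read_bed(path, kind="tad")  # reuse the BED parser; kind unused
    with open(path) as fh:
        lines = [l.rstrip("\n").split("\t") for l in fh if l.strip() and not l.startswith("#")]
    for iv, fields in zip(track, lines):
        gene_id = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id!r} in {path}")
        seen.add(gene_id)
        strand = fields[5] if len(fields) > 5 else "+"
        genes.append(Gene(gene_id, iv, strand))
    return genes


def write_genes_bed(genes: Sequence[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{g.strand}\n")


@dataclass(frozen=True)
class SnvCall:
    """A coding SNV with its annotated functional impact."""

    chrom: str
    start: int  # 0-based
    impact: str

    @property
    def end(self) -> int:
        return self.start + 1


def read_snv_vcf(path: str | Path) -> list[SnvCall]:
    """Read a per-patient SNV VCF carrying an ``IMPACT`` INFO field."""
    calls: list[SnvCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            impact = rec.info.get("IMPACT", "")
            if isinstance(impact, tuple):
                impact = impact[0] if impact else ""
            calls.append(SnvCall(norm_chrom(rec.chrom), rec.pos - 1, str(impact).upper()))
    return calls


def read_cnv_table(path: str | Path) -> dict[str, float]:
    """Per-patient TSV of gene_id -> copy number."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["gene_id", "copy_number"])
    if df["gene_id"].iloc[0] == "gene_id":
        df = df.iloc[1:]
    return dict(zip(df["gene_id"], df["copy_number"].astype(float)))


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x patient expression TSV (first column gene id, header = patients).

    Missing cells become NaN; the gene is then excluded for that patient
    downstream. Duplicate gene ids raise.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in {path}: {dupes}")
    return df.astype(float)


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Mutation index
# ---------------------------------------------------------------------------

def build_mutation_index(
    snv_calls: Mapping[str, Sequence[SnvCall]],
    cnv_tables: Mapping[str, Mapping[str, float]],
    sv_calls: Sequence[StructuralVariant],
    genes: Sequence[Gene],
) -> PatientMutationIndex:
    """Flag, per patient and gene, coding SNVs (moderate/high impact within
    the gene body), out-of-range copy number (< 1.7 or > 2.3), and SVs whose
    breakpoint-to-breakpoint span touches the gene body (>= 1 bp).

    Patients present in one input but absent from another are warned about
    and treated as having no mutations of the missing kind.
    """
    patients = set(snv_calls) | set(cnv_tables) | {sv.patient for sv in sv_calls}
    for name, keys in (("SNV", set(snv_calls)), ("CNV", set(cnv_tables))):
        missing = patients - keys
        if missing and keys:
            logger.warning("%d patient(s) missing from %s input: %s", len(missing), name, sorted(missing)[:5])

    index = PatientMutationIndex(patients)
    id_set = {g.gene_id for g in genes}
    gene_index = AnnotationTrack("tad")
    for g in genes:
        gene_index.add(GenomicInterval(g.interval.chrom, g.interval.start, g.interval.end, name=g.gene_id))

    def hit_gene_ids(chrom: str, start: int, end: int) -> list[str]:
        return [iv.name for iv in gene_index.overlapping(chrom, start, end)]

    for patient, calls in snv_calls.items():
        for call in calls:
            if call.impact in HIGH_IMPACT:
                for gid in hit_gene_ids(call.chrom, call.start, call.end):
                    index.flags(patient, gid).coding_snv = True

    lo, hi = 2 - CNV_DELTA, 2 + CNV_DELTA
    for patient, table in cnv_tables.items():
        for gid, cn in table.items():
            if gid not in id_set:
                continue
            if cn < lo or cn > hi:
                index.flags(patient, gid).cnv_out_of_range = True

    for sv in sv_calls:
        if sv.sv_type == "TRA":
            loci = [(sv.chrom1, sv.pos1, sv.pos1 + 1), (sv.chrom2, sv.pos2, sv.pos2 + 1)]
        else:
            loci = [(sv.chrom1, sv.pos1, sv.pos2)]
        for chrom, start, end in loci:
            for gid in hit_gene_ids(chrom, start, end):
                index.flags(sv.patient, gid).coding_sv_ids.add(sv.sv_id)

    return index


# ---------------------------------------------------------------------------
# Pair export
# ---------------------------------------------------------------------------

def write_pairs_tsv(pairs: Iterable[SVGenePair], path: str | Path) -> None:
    """Export SV-gene pairs: one row per pair, elements semicolon-joined as
    kind:chrom:start-end:direction."""
    with open(path, "w") as fh:
        fh.write("patient\tsv_id\tsv_type\tgene_id\tn_gains\tn_losses\telements\n")
        for p in sorted(pairs, key=lambda p: (p.patient, p.sv_id, p.gene_id)):
            elems = ";".join(
                f"{r.element_kind}:{r.element.chrom}:{r.element.start}-{r.element.end}:{r.direction}"
                for r in sorted(
                    p.records,
                    key=lambda r: (r.element_kind, r.element.chrom, r.element.start, r.element.end, r.direction),
                )
            )
            fh.write(
                f"{p.patient}\t{p.sv_id}\t{p.sv_type}\t{p.gene_id}\t{p.n_gains}\t{p.n_losses}\t{elems}\n"
            )
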