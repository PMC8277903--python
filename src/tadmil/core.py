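"""Core genomic data model.

All coordinates are 0-based half-open (BED native). VCF input is converted on
read. "Overlap" always means at least one shared basepair between half-open
intervals. Chromosome names are normalized by stripping an optional ``chr``
prefix, so ``chr1`` and ``1`` refer to the same chromosome in every input.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

SV_TYPES = ("DEL", "DUP", "INV", "TRA")

TRACK_KINDS = (
    "tad",
    "eqtl",
    "enhancer",
    "super_enhancer",
    "h3k4me3",
    "h3k27me3",
    "h3k27ac",
    "h3k4me1",
    "dnase",
    "rnapol2",
    "ctcf",
    "tfbs",
    "cpg",
    "chromhmm",
)

#: regulatory element kinds that become MIL instances
ELEMENT_KINDS = ("eqtl", "enhancer", "super_enhancer")


def norm_chrom(chrom: str) -> str:
    """Normalize a chromosome name by stripping an optional ``chr`` prefix."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval with an optional scalar signal.

    ``signal`` carries a peak intensity (or an eQTL p-value for eqtl tracks)
    and is NaN when absent; it must otherwise be non-negative.
    """

    chrom: str
    start: int
    end: int
    signal: float = math.nan
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if not math.isnan(self.signal) and self.signal < 0:
            raise ValueError(f"negative signal: {self.signal}")
        object.__setattr__(self, "chrom", norm_chrom(self.chrom))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlaps_span(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == norm_chrom(chrom) and self.start < end and start < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


class AnnotationTrack:
    """A named collection of intervals indexed for overlap queries.

    chromHMM tracks carry a state label per interval in ``interval.name``.
    """

    def __init__(self, kind: str, intervals: Iterable[GenomicInterval] = ()):
        if kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind: {kind!r}")
        self.kind = kind
        self.intervals: list[GenomicInterval] = list(intervals)
        self._trees: Optional[dict[str, IntervalTree]] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def add(self, iv: GenomicInterval) -> None:
        self.intervals.append(iv)
        self._trees = None

    def _index(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for i, iv in enumerate(self.intervals):
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
            self._trees = trees
        return self._trees

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """All intervals sharing >= 1 bp with [start, end) on chrom."""
        tree = self._index().get(norm_chrom(chrom))
        if tree is None:
            return []
        hits = sorted(h.data for h in tree.overlap(start, end))
        return [self.intervals[i] for i in hits]

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        tree = self._index().get(norm_chrom(chrom))
        return bool(tree is not None and tree.overlaps(start, end))

    def max_signal(self, chrom: str, start: int, end: int) -> float:
        """Maximum signal among overlapping intervals; 0.0 when none overlap."""
        best = 0.0
        for iv in self.overlapping(chrom, start, end):
            if not math.isnan(iv.signal) and iv.signal > best:
                best = iv.signal
        return best


@dataclass(frozen=True)
class StructuralVariant:
    """A typed somatic SV owned by one patient.

    Breakpoint orientations follow the derivative-junction convention:
    ``+`` means the 5' side (left of the breakpoint) is retained in the
    derivative product, ``-`` means the 3' side is retained. Orientations are
    only interpreted for translocations.
    """

    sv_id: str
    patient: str
    sv_type: str
    chrom1: str
    pos1: int
    orient1: str
    chrom2: str
    pos2: int
    orient2: str

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        object.__setattr__(self, "chrom1", norm_chrom(self.chrom1))
        object.__setattr__(self, "chrom2", norm_chrom(self.chrom2))
        if self.sv_type != "TRA":
            if self.chrom1 != self.chrom2:
                raise ValueError(f"{self.sv_type} must be intra-chromosomal")
            if not self.pos1 < self.pos2:
                raise ValueError(
                    f"{self.sv_type} requires pos1 < pos2 ({self.pos1} >= {self.pos2})"
                )
        else:
            if self.orient1 not in "+-" or self.orient2 not in "+-":
                raise ValueError("TRA requires both orientations")

    @property
    def span(self) -> tuple[str, int, int]:
        """Breakpoint-to-breakpoint span for intra-chromosomal SVs."""
        if self.sv_type == "TRA":
            raise ValueError("a translocation has no contiguous span")
        return (self.chrom1, self.pos1, self.pos2)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    interval: GenomicInterval
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class Domain:
    """A regulatory domain (TAD or CTCF-loop domain)."""

    interval: GenomicInterval
    source: str = "tad"


class DomainSet:
    """Sorted, non-overlapping domains per chromosome with point lookup."""

    def __init__(self, domains: Iterable[Domain]):
        self.by_chrom: dict[str, list[Domain]] = {}
        for d in domains:
            self.by_chrom.setdefault(d.interval.chrom, []).append(d)
        for chrom, ds in self.by_chrom.items():
            ds.sort(key=lambda d: d.interval.start)
            for a, b in zip(ds, ds[1:]):
                if a.interval.end > b.interval.start:
                    raise ValueError(
                        f"overlapping domains on {chrom}: "
                        f"{a.interval.start}-{a.interval.end} / "
                        f"{b.interval.start}-{b.interval.end}"
                    )
            self.by_chrom[chrom] = ds
        self._starts = {
            chrom: [d.interval.start for d in ds] for chrom, ds in self.by_chrom.items()
        }

    @classmethod
    def from_track(cls, track: AnnotationTrack, source: str = "tad") -> "DomainSet":
        return cls(Domain(iv, source) for iv in track)

    def __iter__(self) -> Iterator[Domain]:
        for ds in self.by_chrom.values():
            yield from ds

    def __len__(self) -> int:
        return sum(len(ds) for ds in self.by_chrom.values())

    def at(self, chrom: str, pos: int) -> Optional[Domain]:
        """The domain containing position ``pos``, or None (e.g. in a gap)."""
        chrom = norm_chrom(chrom)
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return None
        d = self.by_chrom[chrom][i]
        return d if d.interval.start <= pos < d.interval.end else None

    def overlapping(self, chrom: str, start: int, end: int) -> list[Domain]:
        chrom = norm_chrom(chrom)
        return [
            d
            for d in self.by_chrom.get(chrom, [])
            if d.interval.start < end and start < d.interval.end
        ]


@dataclass(frozen=True)
class GainLossRecord:
    """One regulatory element gained or lost by one gene due to one SV."""

    gene_id: str
    element: GenomicInterval
    element_kind: str
    direction: str  # "gain" | "loss"

    def __post_init__(self) -> None:
        if self.element_kind not in ELEMENT_KINDS:
            raise ValueError(f"bad element kind {self.element_kind!r}")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass
class SVGenePair:
    """A MIL bag: one SV x one gene with its gained/lost elements."""

    sv_id: str
    patient: str
    gene_id: str
    sv_type: str
    records: list[GainLossRecord] = field(default_factory=list)

    @property
    def pair_id(self) -> str:
        return f"{self.patient}:{self.sv_id}:{self.gene_id}"

    @property
    def n_gains(self) -> int:
        return sum(1 for r in self.records if r.direction == "gain")

    @property
    def n_losses(self) -> int:
        return sum(1 for r in self.records if r.direction == "loss")


@dataclass
class GeneFlags:
    """Mutation flags for one (patient, gene)."""

    coding_snv: bool = False
    cnv_out_of_range: bool = False
    coding_sv_ids: set = field(default_factory=set)
    noncoding_sv: bool = False

    @property
    def coding_sv(self) -> bool:
        return bool(self.coding_sv_ids)

    @property
    def any_flag(self) -> bool:
        return self.coding_snv or self.cnv_out_of_range or self.coding_sv or self.noncoding_sv


class PatientMutationIndex:
    """Per-patient, per-gene mutation flags used for pair filtering and for
    choosing the reference panel of undisturbed patients when labeling."""

    def __init__(self, patients: Iterable[str] = ()):
        self.patients: set[str] = set(patients)
        self._flags: dict[tuple[str, str], GeneFlags] = {}

    def flags(self, patient: str, gene_id: str) -> GeneFlags:
        key = (patient, gene_id)
        if key not in self._flags:
            self._flags[key] = GeneFlags()
        return self._flags[key]

    def get(self, patient: str, gene_id: str) -> GeneFlags:
        return self._flags.get((patient, gene_id), GeneFlags())

    def disturbed(self, patient: str, gene_id: str) -> bool:
        """True if the gene carries any mutation flag in this patient."""
        return self.get(patient, gene_id).any_flag

    def mark_noncoding(self, patient: str, gene_id: str) -> None:
        self.flags(patient, gene_id).noncoding_sv = True
        self.patients.add(patient)
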