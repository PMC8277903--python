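"""Fixed-length instance feature vectors for gained/lost regulatory elements.

Every instance (one element gained or lost by one SV-gene pair) is described
by: gain/loss indicators, binary >= 1 bp overlap with histone marks, chromHMM
states, TF-binding profiles (DNase, RNA Pol II, CTCF, TFBS) and CpG islands,
peak-intensity "strength" features where signal is available, a one-hot of
the element kind, and the total number of elements disrupted by the parent
SV. Tracks for eQTLs, histone marks and TF binding are binned on a 1 kb grid
beforehand; all features are min-max normalized to [0, 1] on training data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import AnnotationTrack, GainLossRecord, GenomicInterval, SVGenePair

logger = logging.getLogger("tadmil")

HISTONE_MARKS = ("h3k4me3", "h3k27me3", "h3k27ac", "h3k4me1")

#: chromHMM states carried by the current model; the legacy set also keeps
#: the enhancer state that variance-based selection later removed
CHROMHMM_STATES = {
    "svmil2": (
        "ctcf",
        "ctcf_enhancer",
        "ctcf_promoter",
        "promoter",
        "poised_promoter",
        "heterochromatin",
        "repressed",
        "transcribed",
    ),
    "svmil1": (
        "ctcf",
        "ctcf_enhancer",
        "ctcf_promoter",
        "enhancer",
        "promoter",
        "poised_promoter",
        "heterochromatin",
        "repressed",
        "transcribed",
    ),
}

STRENGTH_TRACKS = ("h3k4me3", "h3k27me3", "h3k27ac", "h3k4me1", "rnapol2", "ctcf")

#: tracks binned on the 1 kb grid before encoding
BINNED_TRACKS = ("eqtl", "h3k4me3", "h3k27me3", "h3k27ac", "h3k4me1", "tfbs")


def normalize_state(state: str) -> str:
    return state.strip().lower().replace("+", "_").replace(" ", "_").replace("-", "_")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names for instance vectors."""

    names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def subset(self, keep: Sequence[str]) -> "FeatureSchema":
        keep_set = set(keep)
        return FeatureSchema(tuple(n for n in self.names if n in keep_set))


def build_schema(
    chromhmm_state_set: str = "svmil2", include_ctcf_strength: bool = True
) -> FeatureSchema:
    states = CHROMHMM_STATES[chromhmm_state_set]
    strengths = [f"{t}_strength" for t in STRENGTH_TRACKS]
    if not include_ctcf_strength:
        strengths.remove("ctcf_strength")
    names = (
        ["gain", "loss"]
        + list(HISTONE_MARKS)
        + [f"chromhmm_{s}" for s in states]
        + ["dnase", "rnapol2", "ctcf_peak", "tfbs", "cpg"]
        + strengths
        + ["is_eqtl", "is_enhancer", "is_super_enhancer", "instance_count"]
    )
    return FeatureSchema(tuple(names))


DEFAULT_SCHEMA = build_schema()


# ---------------------------------------------------------------------------
# Track preparation
# ---------------------------------------------------------------------------

def bin_track(track: AnnotationTrack, width: int = 1000) -> AnnotationTrack:
    """Replace intervals with fixed-width grid bins covering them.

    A bin's signal is the maximum signal of the intervals contributing to it
    (robust to peak fragmentation). Names are dropped.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    bins: dict[tuple[str, int], float] = {}
    for iv in track:
        lo = iv.start // width
        hi = (iv.end - 1) // width
        sig = iv.signal
        for b in range(lo, hi + 1):
            key = (iv.chrom, b)
            prev = bins.get(key)
            if prev is None or (not math.isnan(sig) and (math.isnan(prev) or sig > prev)):
                bins[key] = sig
    out = AnnotationTrack(track.kind)
    for (chrom, b), sig in sorted(bins.items()):
        out.add(GenomicInterval(chrom, b * width, (b + 1) * width, sig))
    return out


def filter_eqtls(track: AnnotationTrack, p_threshold: float = 0.05) -> AnnotationTrack:
    """Keep eQTL records with p-value <= threshold (p stored in ``signal``)."""
    out = AnnotationTrack(track.kind)
    n_missing = 0
    for iv in track:
        if math.isnan(iv.signal):
            n_missing += 1
            continue
        if iv.signal <= p_threshold:
            out.add(iv)
    if n_missing:
        logger.warning("dropped %d eQTL record(s) without a p-value", n_missing)
    return out


def apply_fallback_tracks(
    tracks: dict[str, AnnotationTrack],
    fallback: dict[str, AnnotationTrack],
) -> dict[str, AnnotationTrack]:
    """Fill tissue tracks that are missing with a fallback epigenome (the
    study design uses a ubiquitous cell line when tissue data is absent).
    Every substitution is logged per track."""
    out = dict(tracks)
    for kind, track in fallback.items():
        if kind not in out or len(out[kind]) == 0:
            logger.info("track %r missing; substituting fallback (%d intervals)", kind, len(track))
            out[kind] = track
    return out


def prepare_tracks(
    tracks: dict[str, AnnotationTrack],
    bin_width: int = 1000,
    eqtl_p_threshold: float = 0.05,
    fallback: Optional[dict[str, AnnotationTrack]] = None,
) -> dict[str, AnnotationTrack]:
    """Apply the fallback substitution, the eQTL p-value filter and 1 kb
    binning to the relevant tracks."""
    out = dict(tracks)
    if fallback:
        out = apply_fallback_tracks(out, fallback)
    if "eqtl" in out:
        out["eqtl"] = filter_eqtls(out["eqtl"], eqtl_p_threshold)
    for kind in BINNED_TRACKS:
        if kind in out:
            out[kind] = bin_track(out[kind], bin_width)
    return out


# ---------------------------------------------------------------------------
# Instance encoding
# ---------------------------------------------------------------------------

@dataclass
class Bag:
    """An encoded SV-gene pair: the raw (pre-normalization) instance matrix
    plus the expression label filled in by the labeling stage."""

    pair: SVGenePair
    X: np.ndarray  # (n_instances, n_features), raw scale
    z: Optional[float] = None
    n_reference: Optional[int] = None
    label: Optional[int] = None  # 1 positive / 0 negative

    @property
    def patient(self) -> str:
        return self.pair.patient

    @property
    def sv_type(self) -> str:
        return self.pair.sv_type

    @property
    def pair_id(self) -> str:
        return self.pair.pair_id


def encode_instance(
    record: GainLossRecord,
    tracks: dict[str, AnnotationTrack],
    instance_count: int,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> np.ndarray:
    """Encode one gained/lost element as a raw feature vector."""
    el = record.element
    chrom, start, end = el.chrom, el.start, el.end
    v = np.zeros(len(schema))
    chromhmm = tracks.get("chromhmm")
    chromhmm_states: set[str] = set()
    if chromhmm is not None:
        for iv in chromhmm.overlapping(chrom, start, end):
            if iv.name:
                chromhmm_states.add(normalize_state(iv.name))
    for i, name in enumerate(schema.names):
        if name == "gain":
            v[i] = 1.0 if record.direction == "gain" else 0.0
        elif name == "loss":
            v[i] = 1.0 if record.direction == "loss" else 0.0
        elif name in HISTONE_MARKS or name in ("dnase", "rnapol2", "tfbs", "cpg"):
            track = tracks.get(name)
            v[i] = 1.0 if track is not None and track.overlaps_any(chrom, start, end) else 0.0
        elif name == "ctcf_peak":
            track = tracks.get("ctcf")
            v[i] = 1.0 if track is not None and track.overlaps_any(chrom, start, end) else 0.0
        elif name.startswith("chromhmm_"):
            v[i] = 1.0 if name[len("chromhmm_"):] in chromhmm_states else 0.0
        elif name.endswith("_strength"):
            track = tracks.get(name[: -len("_strength")])
            v[i] = track.max_signal(chrom, start, end) if track is not None else 0.0
        elif name == "is_eqtl":
            v[i] = 1.0 if record.element_kind == "eqtl" else 0.0
        elif name == "is_enhancer":
            v[i] = 1.0 if record.element_kind == "enhancer" else 0.0
        elif name == "is_super_enhancer":
            v[i] = 1.0 if record.element_kind == "super_enhancer" else 0.0
        elif name == "instance_count":
            v[i] = float(instance_count)
        else:  # pragma: no cover - schema is closed
            raise ValueError(f"unknown feature {name!r}")
    return v


def encode_pairs(
    pairs: Sequence[SVGenePair],
    tracks: dict[str, AnnotationTrack],
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> list[Bag]:
    """Encode every pair into a bag of raw instance vectors.

    ``instance_count`` is the total number of elements disrupted by the
    parent SV across all of its pairs.
    """
    per_sv: dict[tuple[str, str], int] = {}
    for p in pairs:
        key = (p.patient, p.sv_id)
        per_sv[key] = per_sv.get(key, 0) + len(p.records)
    bags = []
    for p in pairs:
        count = per_sv[(p.patient, p.sv_id)]
        X = np.array([encode_instance(r, tracks, count, schema) for r in p.records])
        bags.append(Bag(pair=p, X=X))
    return bags


# ---------------------------------------------------------------------------
# Normalization and feature selection
# ---------------------------------------------------------------------------

def fit_minmax(instances: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature min/max over a (n_instances, n_features) training matrix."""
    if instances.size == 0:
        raise ValueError("cannot fit normalization on an empty instance set")
    return instances.min(axis=0), instances.max(axis=0)


def apply_minmax(X: np.ndarray, mn: np.ndarray, mx: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1] with clipping; constant features map to 0."""
    span = mx - mn
    safe = np.where(span > 0, span, 1.0)
    out = (X - mn) / safe
    out = np.where(span > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)


def normalize_features(
    train_bags: Sequence[Bag], apply_bags: Sequence[Bag] = ()
) -> tuple[list[np.ndarray], list[np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Normalize bags using statistics from the training bags only.

    Returns the normalized training matrices, the normalized apply-set
    matrices (values outside the training range are clipped), and the fitted
    (min, max) statistics.
    """
    stacked = np.vstack([b.X for b in train_bags])
    mn, mx = fit_minmax(stacked)
    train = [apply_minmax(b.X, mn, mx) for b in train_bags]
    applied = [apply_minmax(b.X, mn, mx) for b in apply_bags]
    return train, applied, (mn, mx)


def select_features_by_variance(
    instances: np.ndarray,
    schema: FeatureSchema,
    log_var_threshold: float = -10.0,
) -> tuple[FeatureSchema, list[str]]:
    """Drop features whose natural-log variance across instances falls below
    the threshold. Returns the reduced schema and the dropped names."""
    if instances.shape[0] < 2:
        raise ValueError("need at least 2 instances to estimate variance")
    var = instances.var(axis=0)
    with np.errstate(divide="ignore"):
        logvar = np.log(var)
    keep = [n for n, lv in zip(schema.names, logvar) if lv >= log_var_threshold]
    dropped = [n for n in schema.names if n not in keep]
    if dropped:
        logger.info("variance filter dropped %d feature(s): %s", len(dropped), dropped)
    return schema.subset(keep), dropped
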