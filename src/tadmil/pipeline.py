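"""End-to-end orchestration: pairs -> features -> labels -> MIL -> metrics."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .core import AnnotationTrack, DomainSet, Gene, PatientMutationIndex, StructuralVariant, SVGenePair
from .features import (
    Bag,
    FeatureSchema,
    build_schema,
    encode_pairs,
    prepare_tracks,
)
from .io import write_pairs_tsv
from .labeling import MIN_REFERENCE, Z_THRESHOLD, assign_labels, balance_classes, write_labels_tsv
from .mil import BAG_CAP, MIN_PRECISION, CVPrediction, ModelBundle, compute_auc, fit_sv_type_model
from .rewiring import build_sv_gene_pairs

logger = logging.getLogger("tadmil")


@dataclass
class PipelineConfig:
    bin_width: int = 1000
    eqtl_p_threshold: float = 0.05
    z_threshold: float = Z_THRESHOLD
    min_reference: int = MIN_REFERENCE
    bag_cap: int = BAG_CAP
    min_precision: float = MIN_PRECISION
    metric: str = "l1"
    chromhmm_state_set: str = "svmil2"
    include_ctcf_strength: bool = True
    #: re-run variance-based feature selection on the encoded instances
    #: (the default schema is already the post-selection feature set)
    apply_variance_selection: bool = False
    log_var_threshold: float = -10.0

    @property
    def schema(self) -> FeatureSchema:
        return build_schema(self.chromhmm_state_set, self.include_ctcf_strength)


@dataclass
class StudyResult:
    pairs: list[SVGenePair]
    bags: list[Bag]  # labeled, pre-balancing
    balanced: list[Bag]
    bundles: dict[str, ModelBundle]
    auc: dict[str, float]

    def cv_predictions(self, sv_type: str) -> list[CVPrediction]:
        return self.bundles[sv_type].cv_predictions

    def truth_recall(self, truth: Sequence[tuple[str, str, str]], sv_type: str) -> Optional[float]:
        """Recall of planted truth pairs among this SV type's CV bags, at the
        selected operating point."""
        bundle = self.bundles.get(sv_type)
        if bundle is None or bundle.operating_point is None:
            return None
        truth_ids = {f"{p}:{s}:{g}" for p, s, g in truth}
        preds = [p for p in bundle.cv_predictions if p.pair_id in truth_ids]
        if not preds:
            return None
        called = sum(1 for p in preds if p.proba >= bundle.operating_point)
        return called / len(preds)


def run_study(
    svs: Sequence[StructuralVariant],
    domains: DomainSet,
    genes: Sequence[Gene],
    elements: dict[str, AnnotationTrack],
    tracks: dict[str, AnnotationTrack],
    expression: pd.DataFrame,
    mutation_index: PatientMutationIndex,
    seed: int = 0,
    config: Optional[PipelineConfig] = None,
    pairs: Optional[list[SVGenePair]] = None,
) -> StudyResult:
    """Run the full pipeline and fit one model per SV type.

    SV types without positive bags, without both classes, or with fewer than
    two patients are skipped with a warning. Pass precomputed ``pairs`` to
    skip the rewiring stage (e.g. when the simulator already built them).
    """
    cfg = config or PipelineConfig()
    if pairs is None:
        pairs = build_sv_gene_pairs(svs, domains, genes, elements, mutation_index)
    prepared = prepare_tracks(tracks, cfg.bin_width, cfg.eqtl_p_threshold)
    bags = encode_pairs(pairs, prepared, cfg.schema)
    schema_used = cfg.schema
    if cfg.apply_variance_selection and bags:
        import numpy as np

        from .features import select_features_by_variance

        stacked = np.vstack([b.X for b in bags])
        schema_used, _ = select_features_by_variance(stacked, cfg.schema, cfg.log_var_threshold)
        keep = [i for i, n in enumerate(cfg.schema.names) if n in schema_used.names]
        for b in bags:
            b.X = b.X[:, keep]
    labeled = assign_labels(bags, expression, mutation_index, cfg.z_threshold, cfg.min_reference)
    balanced = balance_classes(labeled, seed=seed)

    bundles: dict[str, ModelBundle] = {}
    auc: dict[str, float] = {}
    for sv_type in sorted({b.sv_type for b in balanced}):
        of_type = [b for b in balanced if b.sv_type == sv_type]
        labels = {b.label for b in of_type}
        patients = {b.patient for b in of_type}
        if len(labels) < 2 or len(patients) < 2:
            logger.warning("skipping %s: insufficient classes or patients", sv_type)
            continue
        bundle = fit_sv_type_model(
            of_type,
            sv_type,
            seed=seed,
            min_precision=cfg.min_precision,
            metric=cfg.metric,
            cap=cfg.bag_cap,
            evaluation_bags=labeled,
        )
        bundle.schema = schema_used
        bundles[sv_type] = bundle
        # performance estimate on the class-balanced CV subset
        auc[sv_type] = compute_auc([p for p in bundle.cv_predictions if p.in_balanced])
    return StudyResult(pairs=pairs, bags=labeled, balanced=balanced, bundles=bundles, auc=auc)


def write_cv_predictions(result: StudyResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("sv_type\tpair_id\tpatient\ty_true\tproba\tin_balanced\n")
        for sv_type in sorted(result.bundles):
            for p in sorted(result.bundles[sv_type].cv_predictions, key=lambda p: p.pair_id):
                fh.write(
                    f"{sv_type}\t{p.pair_id}\t{p.patient}\t{p.y_true}\t{p.proba:.6f}\t{int(p.in_balanced)}\n"
                )


def export_study(result: StudyResult, out_dir, manifest: Optional[dict] = None) -> None:
    """Write pairs, labels, CV predictions and per-type AUC as TSVs; when a
    ``manifest`` dict is given (seeds, thresholds, input digests), it is
    stored alongside as run_manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pairs_tsv(result.pairs, out / "pairs.tsv")
    write_labels_tsv(result.bags, out / "labels.tsv")
    write_cv_predictions(result, out / "cv_predictions.tsv")
    if manifest is not None:
        import json

        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    with open(out / "auc.tsv", "w") as fh:
        fh.write("sv_type\tauc\toperating_point\n")
        for sv_type in sorted(result.auc):
            op = result.bundles[sv_type].operating_point
            fh.write(
                f"{sv_type}\t{result.auc[sv_type]:.6f}\t"
                f"{'NA' if op is None else f'{op:.6f}'}\n"
            )
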