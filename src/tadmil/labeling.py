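"""Expression-derived bag labels and class balancing.

A bag (SV-gene pair) is called pathogenic when the focal patient's expression
of the gene is an outlier relative to a reference panel of patients carrying
no disruption of that gene (no coding SNV, no out-of-range copy number, no
overlapping SV and no non-coding SV pairing): z > 1.5 or z < -1.5, strict.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import PatientMutationIndex
from .features import Bag

logger = logging.getLogger("tadmil")

Z_THRESHOLD = 1.5
MIN_REFERENCE = 5


def expression_zscore(
    gene_id: str,
    patient: str,
    expression: pd.DataFrame,
    mutation_index: PatientMutationIndex,
    min_reference: int = MIN_REFERENCE,
) -> Optional[tuple[float, int]]:
    """z-score of the patient's expression of ``gene_id`` against all
    undisturbed patients; sample standard deviation (n-1 denominator).

    Returns None (with a log entry) when the gene is unexpressed in the focal
    patient, the reference panel is smaller than ``min_reference``, or the
    reference standard deviation is zero.
    """
    if gene_id not in expression.index or patient not in expression.columns:
        logger.debug("no expression for %s / %s", gene_id, patient)
        return None
    x = expression.at[gene_id, patient]
    if np.isnan(x):
        return None
    row = expression.loc[gene_id]
    ref = [
        p
        for p in expression.columns
        if p != patient
        and not np.isnan(row[p])
        and not mutation_index.disturbed(p, gene_id)
    ]
    if len(ref) < min_reference:
        logger.debug("reference panel too small for %s (%d)", gene_id, len(ref))
        return None
    vals = row[ref].to_numpy(dtype=float)
    sd = vals.std(ddof=1)
    if sd == 0:
        logger.debug("zero reference sd for %s; bag excluded", gene_id)
        return None
    return float((x - vals.mean()) / sd), len(ref)


def assign_labels(
    bags: Sequence[Bag],
    expression: pd.DataFrame,
    mutation_index: PatientMutationIndex,
    z_threshold: float = Z_THRESHOLD,
    min_reference: int = MIN_REFERENCE,
) -> list[Bag]:
    """Attach z-scores and positive/negative labels; bags without a usable
    z-score are excluded (exclusion reasons are logged per pair)."""
    labeled = []
    n_excluded = 0
    for bag in bags:
        res = expression_zscore(
            bag.pair.gene_id, bag.patient, expression, mutation_index, min_reference
        )
        if res is None:
            n_excluded += 1
            logger.debug("pair %s excluded from labeling", bag.pair_id)
            continue
        z, n_ref = res
        bag.z = z
        bag.n_reference = n_ref
        bag.label = 1 if abs(z) > z_threshold else 0
        labeled.append(bag)
    if n_excluded:
        logger.info("excluded %d bag(s) without a usable expression z-score", n_excluded)
    return labeled


def balance_classes(bags: Sequence[Bag], seed: int = 0) -> list[Bag]:
    """Subsample negatives, per SV type, to the number of positives.

    SV types without positives are skipped with a warning. When negatives
    are already the minority, all bags are kept (no upsampling). The output
    order is deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    out: list[Bag] = []
    for sv_type in sorted({b.sv_type for b in bags}):
        of_type = [b for b in bags if b.sv_type == sv_type]
        pos = [b for b in of_type if b.label == 1]
        neg = [b for b in of_type if b.label == 0]
        if not pos:
            logger.warning("no positive bags for SV type %s; skipped", sv_type)
            continue
        if len(neg) > len(pos):
            idx = rng.choice(len(neg), size=len(pos), replace=False)
            neg = [neg[i] for i in sorted(idx)]
        out.extend(pos)
        out.extend(neg)
    out.sort(key=lambda b: (b.sv_type, b.patient, b.pair.sv_id, b.pair.gene_id))
    return out


def write_labels_tsv(bags: Sequence[Bag], path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tsv_type\tz\tn_reference\tlabel\n")
        for b in sorted(bags, key=lambda b: (b.sv_type, b.patient, b.pair.sv_id, b.pair.gene_id)):
            fh.write(f"{b.pair_id}\t{b.sv_type}\t{b.z:.6f}\t{b.n_reference}\t{b.label}\n")
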