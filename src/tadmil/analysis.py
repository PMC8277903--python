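"""Downstream statistics on the classifier's predictions.

Three analyses: (1) which instance features are enriched among the most
important reference instances relative to instances from predicted
non-pathogenic bags; (2) whether genes called as hit by pathogenic non-coding
SVs carry more moderate/high-impact coding SNVs than random gene sets of the
same size (driver potential); (3) how swapping regulatory tracks between
tissues changes per-SV-type AUC, summarized as z-scores over all swaps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import Bag, apply_minmax
from .mil import ModelBundle, rf_instance_importance

logger = logging.getLogger("tadmil")

Z_CAP = 10.0


# ---------------------------------------------------------------------------
# Instance enrichment
# ---------------------------------------------------------------------------

def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        return 0.0
    return math.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))


def instance_enrichment(
    bundle: ModelBundle,
    bags: Sequence[Bag],
    feature_names: Sequence[str],
    n_top: int = 100,
    n_random: int = 100,
    seed: int = 0,
    n_tests: Optional[int] = None,
    z_cap: float = Z_CAP,
    exclude_features: tuple = ("instance_count",),
) -> pd.DataFrame:
    """Compare the ``n_top`` most important reference instances against
    ``n_random`` instances drawn (without replacement) from bags the model
    predicts non-pathogenic.

    Per feature: a two-sample t-test plus a standardized mean difference
    (mean_top - mean_random) / pooled sd, capped at +/- ``z_cap``. The
    Bonferroni factor ``n_tests`` defaults to the number of tested features;
    pass features x cancer-types when correcting across several runs.

    Bag-level features (``instance_count``) are reported descriptively but
    excluded from testing: they are constant within a bag, so an
    instance-level t-test on them is pseudo-replicated and systematically
    biased toward SVs that contribute many reference columns. Their p-values
    are NaN.
    """
    ranked = rf_instance_importance(bundle)
    if len(ranked) < n_top:
        logger.info("only %d reference instances available (requested %d)", len(ranked), n_top)
    top_idx = []
    id_to_row = {key: i for i, key in enumerate(bundle.reference_ids)}
    for _, pid, inst_i in ranked[:n_top]:
        top_idx.append(id_to_row[(pid, inst_i)])
    top = bundle.reference_instances[top_idx]

    # "predicted non-pathogenic" uses the classifier's own decision boundary
    # rather than the recall-optimized calling threshold, which can sit at the
    # minimum score and leave no negative calls at all
    threshold = 0.5
    proba_by_pair = {p.pair_id: p.proba for p in bundle.cv_predictions}
    mn, mx = bundle.minmax
    pool = []
    for bag in bags:
        proba = proba_by_pair.get(bag.pair_id)
        if proba is not None and proba < threshold:
            pool.append(apply_minmax(bag.X, mn, mx))
    if not pool:
        raise ValueError("no predicted non-pathogenic bags to sample instances from")
    pool_mat = np.vstack(pool)
    rng = np.random.default_rng(seed)
    k = min(n_random, pool_mat.shape[0])
    if k < n_random:
        logger.info("only %d non-pathogenic instances available (requested %d)", k, n_random)
    rand = pool_mat[rng.choice(pool_mat.shape[0], size=k, replace=False)]

    tested = [n for n in feature_names if n not in exclude_features]
    n_tests = n_tests if n_tests is not None else len(tested)
    rows = []
    for j, name in enumerate(feature_names):
        a, b = top[:, j], rand[:, j]
        sd = _pooled_sd(a, b)
        diff = float(a.mean() - b.mean())
        if sd == 0:
            z = 0.0 if diff == 0 else math.copysign(z_cap, diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            z = float(np.clip(diff / sd, -z_cap, z_cap))
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
            if math.isnan(p):
                p = 1.0
        if name in exclude_features:
            p = math.nan
        rows.append(
            {
                "feature": name,
                "z": z,
                "p": p,
                "p_adj": min(1.0, p * n_tests) if not math.isnan(p) else math.nan,
                "direction": "up" if z > 0 else ("down" if z < 0 else "none"),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# Driver potential
# ---------------------------------------------------------------------------

@dataclass
class DriverPotentialResult:
    table: pd.DataFrame  # per gene: count, null_mean, null_sd, t, p, p_adj
    n_draws: int
    mode: str

    def significant(self, alpha: float = 0.05) -> list[str]:
        return self.table.index[self.table["p_adj"] < alpha].tolist()


def driver_potential_test(
    predicted_genes: Sequence[str],
    snv_counts: Mapping[str, int],
    gene_universe: Sequence[str],
    driver_catalog: Optional[set] = None,
    n_draws: int = 10_000,
    seed: int = 0,
    mode: str = "empirical",
) -> DriverPotentialResult:
    """Test whether candidate genes carry more impactful coding SNVs than
    random gene sets of the same size drawn from the universe.

    ``snv_counts`` holds per-gene cohort counts of moderate/high-impact SNVs,
    restricted to ``driver_catalog`` when one is supplied. The default
    ``empirical`` mode computes, per gene, a one-sided tail probability of the
    observed count against individual gene counts pooled from the sampled
    sets (calibrated for single genes); ``set_mean_t`` is the classical
    one-sample t-test of the null set-mean distribution against the observed
    count, which is far more liberal. Both report the descriptive statistic
    t = (count - mean(set means)) / sd(set means) and Bonferroni-adjusted
    p-values across candidates.
    """
    universe = [g for g in gene_universe if driver_catalog is None or g in driver_catalog]
    if not universe:
        raise ValueError("empty gene universe after driver-catalog filtering")
    candidates = []
    for g in predicted_genes:
        if g not in set(universe):
            logger.info("candidate gene %s absent from universe; excluded", g)
        elif driver_catalog is not None and g not in driver_catalog:
            logger.info("candidate gene %s not in driver catalog; excluded", g)
        else:
            candidates.append(g)
    if not candidates:
        raise ValueError("no candidate genes left to test")

    counts = np.array([float(snv_counts.get(g, 0)) for g in universe])
    m = len(candidates)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_draws, m))
    for i in range(n_draws):
        draws[i] = counts[rng.choice(len(universe), size=min(m, len(universe)), replace=False)]
    set_means = draws.mean(axis=1)
    pooled = draws.ravel()
    null_mean = float(set_means.mean())
    null_sd = float(set_means.std(ddof=1))

    rows = []
    for g in candidates:
        c = float(snv_counts.get(g, 0))
        t = (c - null_mean) / null_sd if null_sd > 0 else math.copysign(math.inf, c - null_mean) if c != null_mean else 0.0
        if mode == "empirical":
            p = (1.0 + float((pooled >= c).sum())) / (1.0 + pooled.size)
        elif mode == "set_mean_t":
            p = float(stats.ttest_1samp(set_means, c, alternative="less").pvalue)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append(
            {
                "gene": g,
                "count": c,
                "null_mean": null_mean,
                "null_sd": null_sd,
                "t": t,
                "p": p,
                "p_adj": min(1.0, p * m),
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    return DriverPotentialResult(table=table, n_draws=n_draws, mode=mode)


# ---------------------------------------------------------------------------
# Regulatory-track swaps
# ---------------------------------------------------------------------------

@dataclass
class SwapResult:
    table: pd.DataFrame  # per swap: summed AUC difference, z, class


def regulatory_swap_analysis(
    auc_original: Mapping[str, float],
    auc_swapped: Mapping[str, Mapping[str, float]],
) -> SwapResult:
    """Summed signed AUC differences per swap and their z-scores.

    SV types missing from any swap are dropped symmetrically from all swaps.
    z-scores are standardized over all swaps of the tissue (mean 0, sd 1 by
    construction) and quantized: |z| < 1 not significant, 1 <= |z| < 2
    significant, |z| >= 2 highly significant.
    """
    sv_types = set(auc_original)
    for name, table in auc_swapped.items():
        missing = sv_types - set(table)
        if missing:
            logger.warning("swap %s missing SV types %s; dropped for all swaps", name, sorted(missing))
        sv_types &= set(table)
    if not sv_types:
        raise ValueError("no SV types shared across all swaps")
    sv_types = sorted(sv_types)

    names = sorted(auc_swapped)
    diffs = np.array(
        [sum(auc_swapped[n][t] - auc_original[t] for t in sv_types) for n in names]
    )
    sd = diffs.std(ddof=0)
    z = (diffs - diffs.mean()) / sd if sd > 0 else np.zeros_like(diffs)

    def quantize(zi: float) -> str:
        a = abs(zi)
        if a < 1:
            return "ns"
        if a < 2:
            return "significant"
        return "highly significant"

    table = pd.DataFrame(
        {
            "swap": names,
            "summed_auc_diff": diffs,
            "z": z,
            "class": [quantize(zi) for zi in z],
        }
    ).set_index("swap")
    return SwapResult(table=table)
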