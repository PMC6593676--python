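"""High-level convenience pipeline: depths in, sex predictions out."""

from __future__ import annotations

import pandas as pd

from .classify import DecisionBoundaries, predict_cohort
from .containers import AlleleDepthMatrix, SnpTable, call_genotypes
from .stats import compute_all_stats

__all__ = ["predict_from_depths"]


def predict_from_depths(
    adm: AlleleDepthMatrix,
    snps: SnpTable,
    genders: pd.Series | None = None,
    boundaries: DecisionBoundaries | None = None,
    min_sample_depth: float = 0.3,
    par_start_bp: int | None = 170_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call genotypes, compute (H, P_Y) and classify every sample.

    Uses the kept X and Y SNPs of ``snps``; when ``par_start_bp`` is given,
    X SNPs at or beyond it are additionally excluded (the deterministic PAR
    rule — males are diploid there, so such SNPs inflate male
    heterozygosity).  Pass a table already processed by the training
    filters for the full published workflow, or a raw panel plus
    ``par_start_bp`` when no sexed training cohort is available.
    Returns ``(stats, predictions)``.
    """
    gm = call_genotypes(adm)
    x_ids = snps.ids(chrom="X", kept=True)
    if par_start_bp is not None:
        x_ids = x_ids[snps.position(x_ids) < par_start_bp]
    y_ids = snps.ids(chrom="Y", kept=True)
    stats = compute_all_stats(adm, gm, x_ids, y_ids, min_sample_depth=min_sample_depth)
    preds = predict_cohort(stats, genders, boundaries)
    return stats, preds
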