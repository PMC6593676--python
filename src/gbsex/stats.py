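"""Per-sample sex-assignment statistics.

Two statistics drive the classifier:

* **H**, a depth-adjusted X-chromosome heterozygosity.  At read depth ``d``
  a true heterozygote yields an all-one-allele read stack — and hence a
  homozygous call — with probability ``2K`` where ``K = (1/2)**d``, so it is
  *detected* with probability ``1 - 2K``.  Dividing the raw heterozygous
  call count ``n`` by the summed detection probabilities,

      H = n / sum_j (1 - 2 K_j)   over X SNPs j with depth >= 1,

  gives an estimate of the proportion of truly heterozygous sites that is
  unbiased down to very low depth.  Depth-1 sites carry weight 0 (they can
  never reveal heterozygosity) and depth-0 sites are excluded — including
  them with K = 1 would subtract one from the denominator per missing site,
  which has no probability-of-detection meaning.

* **P_Y**, the proportion of Y-chromosome SNPs with at least one read.
  Near zero for females (only alignment/sequencing leakage), high for
  males.

Samples whose mean depth over the kept allosomal SNPs (zeros included)
falls below a cutoff, default 0.3, are flagged unusable: at such depths Y
SNPs often receive no reads at all and males become unassignable or worse.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AlleleDepthMatrix, Genotype, GenotypeMatrix
from .errors import ConfigError, InputError

__all__ = [
    "depth_weight",
    "adjusted_heterozygosity",
    "y_nonmissing_proportion",
    "mean_sample_depth",
    "compute_all_stats",
    "STATS_COLUMNS",
]

REASON_LOW_DEPTH = "low_depth"
REASON_ZERO_DENOM = "zero_denominator"

STATS_COLUMNS = [
    "sample_id",
    "H",
    "P_Y",
    "mean_depth",
    "n_het",
    "denom",
    "m_x_used",
    "m_y",
    "usable",
    "reasons",
]


def depth_weight(d):
    """Probability a true heterozygote is observed heterozygous at depth d.

    ``1 - 2*(1/2)**d = 1 - (1/2)**(d-1)`` for d >= 1; depth-0 entries map
    to 0 (they are excluded from the denominator sum).  Accepts scalars or
    arrays.
    """
    d = np.asarray(d)
    with np.errstate(over="ignore"):
        w = np.where(d >= 1, 1.0 - np.power(0.5, np.maximum(d, 1) - 1), 0.0)
    return float(w) if w.ndim == 0 else w


def adjusted_heterozygosity(
    gm: GenotypeMatrix, adm: AlleleDepthMatrix, x_snps, sample_id: str
) -> tuple[float, int, float, int]:
    """Depth-adjusted X heterozygosity for one sample.

    Returns ``(H, n_het, denom, m_x_used)`` where ``m_x_used`` counts the
    kept X SNPs with depth >= 1.  ``H`` is NaN when the denominator is 0
    (all depths <= 1); such samples are unusable.
    """
    x_snps = np.asarray(list(x_snps), dtype=object)
    if len(x_snps) == 0:
        raise InputError("empty X SNP set")
    i = adm.sample_index(sample_id)
    cols = adm.snp_indices(x_snps)
    d = adm.depth[i, cols]
    n_het = int((gm.call[i, gm.snp_indices(x_snps)] == Genotype.HET).sum())
    denom = float(depth_weight(d).sum())
    h = n_het / denom if denom > 0 else float("nan")
    return h, n_het, denom, int((d >= 1).sum())


def y_nonmissing_proportion(adm: AlleleDepthMatrix, y_snps, sample_id: str) -> float:
    """Proportion of kept Y SNPs with at least one read for the sample."""
    y_snps = np.asarray(list(y_snps), dtype=object)
    if len(y_snps) == 0:
        raise ConfigError("the Y statistic requires a nonempty kept Y SNP set")
    i = adm.sample_index(sample_id)
    d = adm.depth[i, adm.snp_indices(y_snps)]
    return float((d >= 1).mean())


def mean_sample_depth(adm: AlleleDepthMatrix, kept_snps, sample_id: str) -> float:
    """Mean read depth over the kept allosomal SNPs, zero-depth sites included."""
    kept_snps = np.asarray(list(kept_snps), dtype=object)
    if len(kept_snps) == 0:
        raise InputError("empty kept SNP set")
    i = adm.sample_index(sample_id)
    return float(adm.depth[i, adm.snp_indices(kept_snps)].mean())


def compute_all_stats(
    adm: AlleleDepthMatrix,
    gm: GenotypeMatrix,
    x_snps,
    y_snps,
    min_sample_depth: float = 0.3,
) -> pd.DataFrame:
    """Assemble the per-sample statistics table.

    One row per sample in ``adm`` with columns :data:`STATS_COLUMNS`.
    ``usable`` is False when the sample's mean depth over all kept
    allosomal SNPs is below ``min_sample_depth`` or the heterozygosity
    denominator is zero; reasons are recorded and such samples are kept in
    the table (never silently dropped).
    """
    x_snps = np.asarray(list(x_snps), dtype=object)
    y_snps = np.asarray(list(y_snps), dtype=object)
    if len(adm.sample_ids) == 0:
        return pd.DataFrame(columns=STATS_COLUMNS)
    if len(x_snps) == 0:
        raise InputError("empty kept X SNP set")
    if len(y_snps) == 0:
        raise ConfigError("the method requires a nonempty kept Y SNP set")

    x_cols = adm.snp_indices(x_snps)
    y_cols = adm.snp_indices(y_snps)
    all_cols = np.concatenate([x_cols, y_cols])
    depth = adm.depth
    dx = depth[:, x_cols]
    dy = depth[:, y_cols]

    n_het = (gm.call[:, gm.snp_indices(x_snps)] == Genotype.HET).sum(axis=1)
    denom = depth_weight(dx).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(denom > 0, n_het / np.where(denom > 0, denom, 1.0), np.nan)
    p_y = (dy >= 1).mean(axis=1)
    mean_depth = depth[:, all_cols].mean(axis=1)

    low = mean_depth < min_sample_depth
    zero = denom == 0
    usable = ~(low | zero)
    reasons = [
        ";".join(r for r, f in ((REASON_LOW_DEPTH, lo), (REASON_ZERO_DENOM, ze)) if f)
        for lo, ze in zip(low, zero)
    ]
    return pd.DataFrame(
        {
            "sample_id": adm.sample_ids,
            "H": h,
            "P_Y": p_y,
            "mean_depth": mean_depth,
            "n_het": n_het.astype(int),
            "denom": denom,
            "m_x_used": (dx >= 1).sum(axis=1).astype(int),
            "m_y": len(y_snps),
            "usable": usable,
            "reasons": reasons,
        }
    )
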