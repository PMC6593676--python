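"""SNP-level filters for sex-linked SNP panels, and PAR boundary inference.

The X and Y SNP sets coming out of alignment contain SNPs that behave
inconsistently with their chromosomal assignment (mis-mapped tags,
pseudo-autosomal loci, paralogues).  Using a training cohort with recorded
sexes, an X SNP is discarded if it lies in the pseudo-autosomal region
(PAR), if at least 10% of males are heterozygous at it, or if at least 10%
of females have a missing genotype; a Y SNP is discarded if at least 5% of
females have a non-missing call or at least 50% of males are heterozygous.
Finally SNPs with pooled-read minor allele frequency below 0.015 are
removed.  All "at least" thresholds are inclusive (>=); the MAF rule is a
strict <.

Denominator conventions (configurable in spirit, fixed here and reported):
heterozygosity proportions are taken over samples with a *non-missing* call
at the SNP — at sub-1x depth most genotypes are missing per SNP and an
all-samples denominator would make the rules vacuous — while missingness /
non-missingness proportions are taken over *all* recorded females, since
missingness itself is the measured event.  MAF is computed from pooled read
counts rather than genotype calls, which at depth <= 2 are strongly biased
toward homozygotes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    FEMALE,
    MALE,
    AlleleDepthMatrix,
    Genotype,
    GenotypeMatrix,
    SnpTable,
)
from .errors import ConfigError, InputError

__all__ = [
    "FilterConfig",
    "FilterReport",
    "REASON_PAR",
    "REASON_MALE_HET",
    "REASON_FEMALE_MISSING",
    "REASON_FEMALE_NONMISSING",
    "REASON_MAF",
    "REASON_MAF_UNDEFINED",
    "minor_allele_frequency",
    "filter_x_snps",
    "filter_y_snps",
    "infer_par_boundary",
]

REASON_PAR = "par"
REASON_MALE_HET = "male_het"
REASON_FEMALE_MISSING = "female_missing"
REASON_FEMALE_NONMISSING = "female_nonmissing"
REASON_MAF = "maf"
REASON_MAF_UNDEFINED = "maf_undefined"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the SNP filters and the sample-depth cutoff.

    Defaults are the published operating point for a deer GBS panel; the PAR
    start can be overridden, e.g. from :func:`infer_par_boundary`.
    """

    par_start_bp: int = 170_000_000
    x_male_het_max: float = 0.10
    x_female_missing_max: float = 0.10
    y_female_nonmissing_max: float = 0.05
    y_male_het_max: float = 0.50
    maf_min: float = 0.015
    min_sample_depth: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "x_male_het_max",
            "x_female_missing_max",
            "y_female_nonmissing_max",
            "y_male_het_max",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0,1]")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ConfigError(f"maf_min={self.maf_min} outside [0,0.5]")
        if self.par_start_bp < 1:
            raise ConfigError("par_start_bp must be >= 1")
        if self.min_sample_depth < 0:
            raise ConfigError("min_sample_depth must be >= 0")


@dataclass
class FilterReport:
    """Discard accounting for one chromosome's filter pass.

    ``discard_counts`` attributes each discarded SNP to the *first* rule it
    triggered, in evaluation order, so counts are conserved:
    ``n_kept + sum(discard_counts.values()) == n_input``.
    ``reasons_by_snp`` lists every triggered rule per SNP.
    """

    chrom: str
    n_input: int
    n_kept: int
    discard_counts: dict[str, int] = field(default_factory=dict)
    reasons_by_snp: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def summary(self) -> str:
        parts = [f"{self.chrom}: {self.n_input} in, {self.n_kept} kept"]
        parts += [f"{k}={v}" for k, v in self.discard_counts.items()]
        return "; ".join(parts)


def _sex_masks(adm: AlleleDepthMatrix, genders: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    g = genders.reindex(adm.sample_ids).to_numpy(dtype=object)
    males = g == MALE
    females = g == FEMALE
    if not males.any() or not females.any():
        raise ConfigError(
            "filters need at least one recorded male and one recorded female "
            f"(got {males.sum()} males, {females.sum()} females)"
        )
    return males, females


def minor_allele_frequency(adm: AlleleDepthMatrix, snp_id: str) -> float:
    """Pooled-read minor allele frequency at one SNP.

    p = sum(ref reads) / sum(all reads) over samples; returns min(p, 1-p).
    Raises :class:`InputError` at zero total depth (the frequency is
    undefined; the filters discard such SNPs with a dedicated reason).
    """
    j = adm.snp_indices([snp_id])[0]
    ref = int(adm.ref_count[:, j].sum())
    tot = ref + int(adm.alt_count[:, j].sum())
    if tot == 0:
        raise InputError(f"SNP {snp_id!r} has zero total depth; MAF undefined")
    p = ref / tot
    return min(p, 1.0 - p)


def _maf_all(adm: AlleleDepthMatrix, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized MAF per column; second array flags zero-depth columns."""
    ref = adm.ref_count[:, cols].sum(axis=0).astype(float)
    tot = ref + adm.alt_count[:, cols].sum(axis=0)
    undefined = tot == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ref / tot
    maf = np.minimum(p, 1.0 - p)
    return maf, undefined


def _prop(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """num/den with 0/0 -> 0 (no evidence, rule not triggered)."""
    out = np.zeros(num.shape, dtype=float)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def _apply(
    snps: SnpTable,
    snp_ids: np.ndarray,
    rules: list[tuple[str, np.ndarray]],
    chrom: str,
) -> tuple[SnpTable, FilterReport]:
    """Merge per-rule violation masks into a new table plus a report."""
    reasons_by_snp: dict[str, tuple[str, ...]] = {}
    first_reason_counts: dict[str, int] = {}
    for k, snp_id in enumerate(snp_ids):
        triggered = tuple(name for name, mask in rules if mask[k])
        if triggered:
            reasons_by_snp[str(snp_id)] = triggered
            first = triggered[0]
            first_reason_counts[first] = first_reason_counts.get(first, 0) + 1
    out = snps.with_discards(reasons_by_snp)
    report = FilterReport(
        chrom=chrom,
        n_input=len(snp_ids),
        n_kept=len(snp_ids) - len(reasons_by_snp),
        discard_counts=first_reason_counts,
        reasons_by_snp=reasons_by_snp,
    )
    return out, report


def filter_x_snps(
    gm: GenotypeMatrix,
    adm: AlleleDepthMatrix,
    snps: SnpTable,
    genders: pd.Series,
    cfg: FilterConfig | None = None,
) -> tuple[SnpTable, FilterReport]:
    """Filter the currently-kept X SNPs against a sexed training cohort.

    Rules, in evaluation order: PAR position, male heterozygosity >= 10%,
    female missingness >= 10%, pooled MAF < 0.015 (undefined MAF discards).
    """
    cfg = cfg or FilterConfig()
    males, females = _sex_masks(adm, genders)
    x_ids = snps.ids(chrom="X", kept=True)
    if len(x_ids) == 0:
        return snps, FilterReport(chrom="X", n_input=0, n_kept=0)
    cols = adm.snp_indices(x_ids)
    calls = gm.call[:, cols]
    m_calls = calls[males]
    f_calls = calls[females]
    male_nonmiss = (m_calls != Genotype.MISSING).sum(axis=0)
    male_het = (m_calls == Genotype.HET).sum(axis=0)
    male_het_prop = _prop(male_het, male_nonmiss)
    female_missing_prop = (f_calls == Genotype.MISSING).mean(axis=0)
    maf, maf_undef = _maf_all(adm, cols)
    pos = snps.position(x_ids)

    in_par = pos >= cfg.par_start_bp
    het_bad = male_het_prop >= cfg.x_male_het_max
    miss_bad = female_missing_prop >= cfg.x_female_missing_max
    with np.errstate(invalid="ignore"):
        maf_bad = ~maf_undef & (maf < cfg.maf_min)
    rules = [
        (REASON_PAR, in_par),
        (REASON_MALE_HET, het_bad),
        (REASON_FEMALE_MISSING, miss_bad),
        (REASON_MAF, maf_bad),
        (REASON_MAF_UNDEFINED, maf_undef),
    ]
    return _apply(snps, x_ids, rules, "X")


def filter_y_snps(
    gm: GenotypeMatrix,
    adm: AlleleDepthMatrix,
    snps: SnpTable,
    genders: pd.Series,
    cfg: FilterConfig | None = None,
) -> tuple[SnpTable, FilterReport]:
    """Filter the currently-kept Y SNPs.

    Rules, in order: female non-missingness >= 5%, male heterozygosity
    >= 50%, pooled MAF < 0.015.  Y SNPs are never tested against the PAR —
    any Y-assigned tags inside the PAR show reads in females and fall to
    the first rule.
    """
    cfg = cfg or FilterConfig()
    males, females = _sex_masks(adm, genders)
    y_ids = snps.ids(chrom="Y", kept=True)
    if len(y_ids) == 0:
        return snps, FilterReport(chrom="Y", n_input=0, n_kept=0)
    cols = adm.snp_indices(y_ids)
    calls = gm.call[:, cols]
    m_calls = calls[males]
    f_calls = calls[females]
    female_nonmiss_prop = (f_calls != Genotype.MISSING).mean(axis=0)
    male_nonmiss = (m_calls != Genotype.MISSING).sum(axis=0)
    male_het = (m_calls == Genotype.HET).sum(axis=0)
    male_het_prop = _prop(male_het, male_nonmiss)
    maf, maf_undef = _maf_all(adm, cols)
    with np.errstate(invalid="ignore"):
        maf_bad = ~maf_undef & (maf < cfg.maf_min)

    rules = [
        (REASON_FEMALE_NONMISSING, female_nonmiss_prop >= cfg.y_female_nonmissing_max),
        (REASON_MALE_HET, male_het_prop >= cfg.y_male_het_max),
        (REASON_MAF, maf_bad),
        (REASON_MAF_UNDEFINED, maf_undef),
    ]
    return _apply(snps, y_ids, rules, "Y")


def infer_par_boundary(
    gm: GenotypeMatrix,
    snps: SnpTable,
    genders: pd.Series,
    window_bp: int = 5_000_000,
    het_threshold: float = 0.1,
) -> int | None:
    """Locate the start of the pseudo-autosomal region on the X.

    Males are hemizygous outside the PAR, so their per-SNP heterozygosity
    proportion jumps from ~0 to an autosome-like level at the PAR boundary.
    Per-SNP male heterozygosity (heterozygous males / non-missing males) is
    averaged in non-overlapping ``window_bp`` windows along the X; the
    returned coordinate is the start of the first window from which every
    subsequent informative window's mean exceeds ``het_threshold``.  Windows
    with no informative SNPs are ignored.  Returns ``None`` when no such run
    exists.  The value is advisory: :attr:`FilterConfig.par_start_bp` is
    what the filters actually use.
    """
    g = genders.reindex(gm.sample_ids).to_numpy(dtype=object)
    males = g == MALE
    x_ids = snps.ids(chrom="X")
    if len(x_ids) == 0:
        raise InputError("no X SNPs; cannot infer PAR boundary")
    cols = gm.snp_indices(x_ids)
    m_calls = gm.call[np.ix_(males, cols)]
    nonmiss = (m_calls != Genotype.MISSING).sum(axis=0)
    informative = nonmiss > 0
    if informative.sum() < 2:
        raise InputError("fewer than 2 X SNPs with non-missing male genotypes")
    het_prop = np.full(len(cols), np.nan)
    het_prop[informative] = (
        (m_calls == Genotype.HET).sum(axis=0)[informative] / nonmiss[informative]
    )
    pos = snps.position(x_ids)
    win = (pos - 1) // window_bp
    n_win = int(win.max()) + 1
    means = np.full(n_win, np.nan)
    for w in range(n_win):
        vals = het_prop[(win == w) & informative]
        if len(vals):
            means[w] = vals.mean()
    informative_w = ~np.isnan(means)
    above = means > het_threshold
    # first window from which all later informative windows are above threshold
    candidate: int | None = None
    for w in range(n_win - 1, -1, -1):
        if not informative_w[w]:
            continue
        if above[w]:
            candidate = w
        else:
            break
    if candidate is None:
        return None
    return candidate * window_bp + 1
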