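"""Seeded synthetic low-depth GBS data with sex-linked structure.

The generator reproduces the data-generating process the sex-assignment
method assumes: females carry two X alleles drawn in Hardy–Weinberg
proportions at each X SNP's reference-allele frequency; males are
hemizygous on the X outside the pseudo-autosomal region (PAR) and diploid
inside it; Y SNPs yield reads only in males, apart from a small leakage
process in females representing mis-alignment.  Read depth per (sample,
site) is Poisson with a per-sample mean λ_i drawn from a Gamma
distribution, the canonical model for between-sample library-size spread
in GBS; each read reports the wrong allele with a small per-read error
probability, which is what leaks heterozygous calls into males.

Optional perturbations mirror what real cohorts contain: misrecorded
sexes, XXY and XO karyotypes, and two-sample contamination.  Everything is
driven by one seed and is reproducible byte-for-byte.

Y SNPs are simulated as ordinary biallelic loci segregating among males
(frequency drawn from the same Beta), with the same depth model as the X;
the classifier only uses presence/absence of Y reads, but a polymorphic Y
keeps the minor-allele-frequency filter meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FEMALE, MALE, AlleleDepthMatrix, SnpTable, make_gender_series
from .errors import ConfigError

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "make_filter_fixture", "FilterFixture"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults emulate a deer-scale GBS training cohort.

    ``depth_mean`` is the expected reads per (sample, SNP); ``depth_shape``
    is the Gamma shape for the per-sample λ_i spread (``None`` fixes every
    λ_i to ``depth_mean``).  ``y_leak_rate`` scales the Poisson rate of
    spurious female Y reads as ``y_leak_rate * λ_i`` per SNP.
    """

    n_males: int = 200
    n_females: int = 200
    m_x: int = 1000
    m_y: int = 16
    x_length_bp: int = 200_000_000
    par_start_bp: int = 170_000_000
    par_snp_fraction: float = 0.15
    y_length_bp: int = 60_000_000
    allele_freq_beta: tuple[float, float] = (2.0, 2.0)
    depth_mean: float = 2.89
    depth_shape: float | None = 20.0
    per_read_error: float = 0.002
    y_leak_rate: float = 0.01
    misassigned_fraction: float = 0.0
    aneuploidy: tuple[tuple[str, int], ...] = ()
    contamination: tuple[float, float] | None = None  # (fraction, level)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("per_read_error", "y_leak_rate", "misassigned_fraction", "par_snp_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0,1]")
        for name in ("n_males", "n_females", "m_x", "m_y"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.depth_mean < 0:
            raise ConfigError("depth_mean must be >= 0")
        if self.depth_shape is not None and self.depth_shape <= 0:
            raise ConfigError("depth_shape must be positive or None")
        if self.par_snp_fraction > 0 and self.par_start_bp >= self.x_length_bp:
            raise ConfigError(
                "par_snp_fraction > 0 requires par_start_bp < x_length_bp "
                f"({self.par_start_bp} >= {self.x_length_bp})"
            )
        a, b = self.allele_freq_beta
        if a <= 0 or b <= 0:
            raise ConfigError("allele_freq_beta parameters must be positive")
        n_aneu = {"XXY": 0, "XO": 0}
        for kind, count in self.aneuploidy:
            if kind not in n_aneu:
                raise ConfigError(f"unknown aneuploidy kind {kind!r}")
            if count < 0:
                raise ConfigError("aneuploidy counts must be >= 0")
            n_aneu[kind] += count
        if n_aneu["XXY"] > self.n_males or n_aneu["XO"] > self.n_females:
            raise ConfigError("more aneuploid samples than samples of that sex")
        if self.contamination is not None:
            frac, level = self.contamination
            if not (0.0 <= frac <= 1.0 and 0.0 <= level <= 1.0):
                raise ConfigError("contamination fraction and level must be in [0,1]")


@dataclass
class SimulatedDataset:
    """A simulated cohort: depths, SNP map, recorded sexes, and the truth."""

    adm: AlleleDepthMatrix
    snps: SnpTable
    recorded: pd.Series
    truth: pd.DataFrame


def _karyotypes(cfg: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    n_xxy = sum(c for k, c in cfg.aneuploidy if k == "XXY")
    n_xo = sum(c for k, c in cfg.aneuploidy if k == "XO")
    male_karyo = ["XXY"] * n_xxy + ["XY"] * (cfg.n_males - n_xxy)
    female_karyo = ["XO"] * n_xo + ["XX"] * (cfg.n_females - n_xo)
    ids = [f"M{i + 1:04d}" for i in range(cfg.n_males)] + [
        f"F{i + 1:04d}" for i in range(cfg.n_females)
    ]
    sexes = [MALE] * cfg.n_males + [FEMALE] * cfg.n_females
    return ids, sexes, male_karyo + female_karyo


def simulate(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate one cohort under ``cfg``; same config => identical output."""
    rng = np.random.default_rng(cfg.seed)
    ids, sexes, karyo = _karyotypes(cfg)
    n = len(ids)
    sexes_arr = np.array(sexes, dtype=object)
    karyo_arr = np.array(karyo, dtype=object)

    if cfg.depth_shape is None:
        lam = np.full(n, float(cfg.depth_mean))
    else:
        lam = rng.gamma(cfg.depth_shape, cfg.depth_mean / cfg.depth_shape, size=n)

    # --- X chromosome ---
    n_par = int(round(cfg.par_snp_fraction * cfg.m_x))
    pos_x = np.concatenate(
        [
            rng.integers(1, max(cfg.par_start_bp, 2), size=cfg.m_x - n_par),
            rng.integers(cfg.par_start_bp, cfg.x_length_bp + 1, size=n_par),
        ]
    )
    in_par = np.zeros(cfg.m_x, dtype=bool)
    in_par[cfg.m_x - n_par :] = True
    a, b = cfg.allele_freq_beta
    p_ref = rng.beta(a, b, size=cfg.m_x)

    ploidy = np.full((n, cfg.m_x), 2, dtype=np.int64)
    hemi = (karyo_arr == "XY")[:, None] & ~in_par[None, :]
    hemi |= (karyo_arr == "XO")[:, None]
    ploidy[hemi] = 1
    g_ref = rng.binomial(ploidy, p_ref[None, :])  # reference-allele copies
    het_true = (ploidy == 2) & (g_ref == 1)
    true_het_prop = het_true.mean(axis=1)

    d_x = rng.poisson(lam[:, None], size=(n, cfg.m_x))
    f = g_ref / ploidy
    e = cfg.per_read_error
    f_read = f * (1 - e) + (1 - f) * e  # per-read P(reports reference)
    ref_x = rng.binomial(d_x, f_read)

    # --- Y chromosome ---
    pos_y = rng.integers(1, cfg.y_length_bp + 1, size=cfg.m_y)
    has_y = np.isin(karyo_arr, ("XY", "XXY"))
    p_ref_y = rng.beta(a, b, size=cfg.m_y)
    rate_y = np.where(has_y, lam, cfg.y_leak_rate * lam)
    g_y = rng.binomial(1, p_ref_y[None, :], size=(n, cfg.m_y))  # haploid male allele
    f_y = np.where(has_y[:, None], g_y * (1 - e) + (1 - g_y) * e, 0.5)
    d_y = rng.poisson(rate_y[:, None], size=(n, cfg.m_y))
    ref_y = rng.binomial(d_y, f_y)

    # --- contamination: mix a fraction of each contaminated sample's reads
    # with reads generated from a random donor's genotype ---
    if cfg.contamination is not None:
        frac, level = cfg.contamination
        k = int(round(frac * n))
        if k > 0 and n > 1 and level > 0:
            targets = rng.choice(n, size=k, replace=False)
            for i in targets:
                donor = int(rng.integers(n - 1))
                donor += donor >= i
                n_cont = rng.binomial(d_x[i], level)
                ref_x[i] = rng.binomial(d_x[i] - n_cont, f_read[i]) + rng.binomial(
                    n_cont, f_read[donor]
                )
                d_own = rng.poisson((1 - level) * rate_y[i], size=cfg.m_y)
                d_don = rng.poisson(level * rate_y[donor], size=cfg.m_y)
                d_y[i] = d_own + d_don
                ref_y[i] = rng.binomial(d_own, f_y[i]) + rng.binomial(d_don, f_y[donor])

    flipped = rng.random(n) < cfg.misassigned_fraction
    recorded_arr = sexes_arr.copy()
    recorded_arr[flipped] = np.where(sexes_arr[flipped] == MALE, FEMALE, MALE)

    snp_ids = [f"X{j + 1:06d}" for j in range(cfg.m_x)] + [
        f"Y{j + 1:04d}" for j in range(cfg.m_y)
    ]
    adm = AlleleDepthMatrix(
        np.array(ids, dtype=object),
        np.array(snp_ids, dtype=object),
        np.hstack([ref_x, ref_y]),
        np.hstack([d_x - ref_x, d_y - ref_y]),
    )
    snps = SnpTable.from_arrays(
        snp_ids,
        ["X"] * cfg.m_x + ["Y"] * cfg.m_y,
        np.concatenate([pos_x, pos_y]),
    )
    truth = pd.DataFrame(
        {
            "sample_id": ids,
            "true_gender": sexes_arr,
            "karyotype": karyo_arr,
            "recorded_gender": recorded_arr,
            "flipped": flipped,
            "true_x_het_prop": true_het_prop,
            "lambda_": lam,
        }
    )
    recorded = make_gender_series(ids, recorded_arr)
    return SimulatedDataset(adm=adm, snps=snps, recorded=recorded, truth=truth)


@dataclass
class FilterFixture:
    """Hand-built dataset with exactly one filter violation per rule."""

    adm: AlleleDepthMatrix
    snps: SnpTable
    genders: pd.Series
    expected_x_reasons: dict[str, str]
    expected_y_reasons: dict[str, str]
    kept_x: tuple[str, ...]
    kept_y: tuple[str, ...]


def make_filter_fixture() -> FilterFixture:
    """Deterministic 30-sample, 9-SNP dataset exercising every filter rule.

    10 males, 20 females.  X SNPs: one clean, one in the PAR, one with
    exactly 10% heterozygous males, one with exactly 10% of females
    missing, one with pooled MAF < 0.015.  Y SNPs: one clean (polymorphic
    among males, silent in females), one with exactly 5% of females
    non-missing, one with 50% heterozygous males, one with MAF < 0.015.
    """
    males = [f"M{i + 1:02d}" for i in range(10)]
    females = [f"F{i + 1:02d}" for i in range(20)]
    samples = males + females
    n = len(samples)

    snp_ids = [
        "X_clean",
        "X_par",
        "X_malehet",
        "X_femmiss",
        "X_maf",
        "Y_clean",
        "Y_femnonmiss",
        "Y_malehet",
        "Y_maf",
    ]
    chrom = ["X"] * 5 + ["Y"] * 4
    pos = [1_000_000, 171_000_000, 2_000_000, 3_000_000, 4_000_000, 1_000, 2_000, 3_000, 4_000]
    ref = np.zeros((n, len(snp_ids)), dtype=np.int64)
    alt = np.zeros_like(ref)

    def set_cell(sample: str, snp: str, r: int, a: int) -> None:
        ref[samples.index(sample), snp_ids.index(snp)] = r
        alt[samples.index(sample), snp_ids.index(snp)] = a

    def set_col(snp: str, rows: list[str], r: int, a: int) -> None:
        for s in rows:
            set_cell(s, snp, r, a)

    # X_clean and X_par: males hemizygous hom-ref, females heterozygous
    for snp in ("X_clean", "X_par"):
        set_col(snp, males, 4, 0)
        set_col(snp, females, 2, 2)
    # X_malehet: 1 of 10 males heterozygous (10%)
    set_col("X_malehet", males, 4, 0)
    set_cell("M01", "X_malehet", 2, 2)
    set_col("X_malehet", females, 2, 2)
    # X_femmiss: 2 of 20 females missing (10%)
    set_col("X_femmiss", males, 4, 0)
    set_col("X_femmiss", females[2:], 2, 2)  # F01, F02 stay at depth 0
    # X_maf: essentially monomorphic; one stray alt read (MAF 1/120)
    set_col("X_maf", males, 4, 0)
    set_col("X_maf", females, 4, 0)
    set_cell("F01", "X_maf", 3, 1)

    # Y_clean: polymorphic among males, all females missing
    set_col("Y_clean", males[:5], 4, 0)
    set_col("Y_clean", males[5:], 0, 4)
    # Y_femnonmiss: as clean but 1 of 20 females (5%) has a read
    set_col("Y_femnonmiss", males[:5], 4, 0)
    set_col("Y_femnonmiss", males[5:], 0, 4)
    set_cell("F01", "Y_femnonmiss", 1, 0)
    # Y_malehet: 5 of 10 males heterozygous (50%)
    set_col("Y_malehet", males[:5], 2, 2)
    set_col("Y_malehet", males[5:], 4, 0)
    # Y_maf: one alt read among 70 (MAF ~0.014), only 10% male het
    set_col("Y_maf", males, 7, 0)
    set_cell("M01", "Y_maf", 6, 1)

    adm = AlleleDepthMatrix(
        np.array(samples, dtype=object), np.array(snp_ids, dtype=object), ref, alt
    )
    snps = SnpTable.from_arrays(snp_ids, chrom, pos)
    genders = make_gender_series(samples, [MALE] * 10 + [FEMALE] * 20)
    return FilterFixture(
        adm=adm,
        snps=snps,
        genders=genders,
        expected_x_reasons={
            "X_par": "par",
            "X_malehet": "male_het",
            "X_femmiss": "female_missing",
            "X_maf": "maf",
        },
        expected_y_reasons={
            "Y_femnonmiss": "female_nonmissing",
            "Y_malehet": "male_het",
            "Y_maf": "maf",
        },
        kept_x=("X_clean",),
        kept_y=("Y_clean",),
    )
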