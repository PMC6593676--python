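"""In-memory containers for allele-depth genotype data.

The raw observable of the method is, per (sample, SNP) cell, the number of
sequencing reads supporting the reference and the alternate allele
(:class:`AlleleDepthMatrix`).  Genotypes are *called* from those depths with
the naive rule used by low-depth GBS pipelines: any cell where both alleles
are observed is heterozygous, a cell with reads for only one allele is the
corresponding homozygote, and a cell with no reads is missing.  At read
depth ``d`` a true heterozygote is therefore miscalled homozygous with
probability ``2 * (1/2)**d`` — the failure mode the downstream
heterozygosity estimator corrects for.

SNP annotations (chromosome, position, filter status) live in
:class:`SnpTable`; recorded sexes in a plain :class:`pandas.Series`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError

__all__ = [
    "Genotype",
    "Chrom",
    "MALE",
    "FEMALE",
    "UNKNOWN",
    "UNASSIGNED",
    "AlleleDepthMatrix",
    "GenotypeMatrix",
    "SnpTable",
    "call_genotypes",
    "make_gender_series",
]


class Genotype(enum.IntEnum):
    """Naive genotype calls; MISSING is a depth-0 cell."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


class Chrom(str, enum.Enum):
    X = "X"
    Y = "Y"
    AUTOSOME = "AUTOSOME"
    UNPLACED = "UNPLACED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Sex / prediction labels used throughout the tables.
MALE = "M"
FEMALE = "F"
UNKNOWN = "U"  # recorded sex absent
UNASSIGNED = "U"  # prediction withheld


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        dup = pd.Index(ids)
        offenders = sorted(set(dup[dup.duplicated()]))
        raise ConsistencyError(f"duplicated {what}: {offenders[:5]}")


@dataclass
class AlleleDepthMatrix:
    """Per-(sample, SNP) reference/alternate read counts.

    ``ref_count`` and ``alt_count`` are ``(n_samples, n_snps)`` non-negative
    integer arrays; ``depth = ref_count + alt_count``.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    ref_count: np.ndarray
    alt_count: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.ref_count = np.asarray(self.ref_count)
        self.alt_count = np.asarray(self.alt_count)
        shape = (len(self.sample_ids), len(self.snp_ids))
        if self.ref_count.shape != shape or self.alt_count.shape != shape:
            raise ConsistencyError(
                f"count matrices {self.ref_count.shape}/{self.alt_count.shape} "
                f"do not match ids {shape}"
            )
        if (self.ref_count < 0).any() or (self.alt_count < 0).any():
            raise ConsistencyError("negative read counts")
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.snp_ids, "snp_ids")
        self._sample_idx = {s: i for i, s in enumerate(self.sample_ids)}
        self._snp_idx = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_idx[sample_id]
        except KeyError:
            raise ConsistencyError(f"unknown sample {sample_id!r}") from None

    def snp_indices(self, snp_ids) -> np.ndarray:
        try:
            return np.array([self._snp_idx[s] for s in snp_ids], dtype=np.intp)
        except KeyError as exc:
            raise ConsistencyError(f"unknown SNP {exc.args[0]!r}") from None


@dataclass
class GenotypeMatrix:
    """Called genotypes as an ``int8`` matrix of :class:`Genotype` codes."""

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    call: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.call = np.asarray(self.call, dtype=np.int8)
        if self.call.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ConsistencyError("call matrix shape does not match ids")
        self._sample_idx = {s: i for i, s in enumerate(self.sample_ids)}
        self._snp_idx = {s: j for j, s in enumerate(self.snp_ids)}

    def sample_index(self, sample_id: str) -> int:
        return self._sample_idx[sample_id]

    def snp_indices(self, snp_ids) -> np.ndarray:
        return np.array([self._snp_idx[s] for s in snp_ids], dtype=np.intp)


def call_genotypes(adm: AlleleDepthMatrix) -> GenotypeMatrix:
    """Naive elementwise genotype calling from allele depths.

    depth 0 -> MISSING; both alleles seen -> HET (regardless of imbalance,
    matching the ``1 - 2K`` detection model); otherwise the homozygote of
    the observed allele.  A HET call therefore requires depth >= 2.
    """
    ref, alt = adm.ref_count, adm.alt_count
    call = np.full(ref.shape, Genotype.MISSING, dtype=np.int8)
    call[(ref > 0) & (alt == 0)] = Genotype.HOM_REF
    call[(ref == 0) & (alt > 0)] = Genotype.HOM_ALT
    call[(ref > 0) & (alt > 0)] = Genotype.HET
    return GenotypeMatrix(adm.sample_ids, adm.snp_ids, call)


class SnpTable:
    """Per-SNP chromosome, position and filter status.

    Backed by a DataFrame indexed by ``snp_id`` with columns ``chrom``
    (values from :class:`Chrom`), ``position_bp`` (1-based), and ``reasons``
    (tuple of filter reason codes).  A SNP is *kept* iff its reason tuple is
    empty.
    """

    COLUMNS = ("chrom", "position_bp", "reasons")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ("chrom", "position_bp") if c not in df.columns]
        if missing:
            raise ConsistencyError(f"SnpTable missing columns {missing}")
        df = df.copy()
        if "reasons" not in df.columns:
            df["reasons"] = [() for _ in range(len(df))]
        df["chrom"] = [str(c) for c in df["chrom"]]
        bad = set(df["chrom"]) - {c.value for c in Chrom}
        if bad:
            raise ConsistencyError(f"unknown chromosome labels {sorted(bad)}")
        if (df["position_bp"] < 1).any():
            raise ConsistencyError("position_bp must be >= 1")
        _check_unique(df.index.to_numpy(dtype=object), "snp_ids")
        self.df = df[list(self.COLUMNS)]

    @classmethod
    def from_arrays(cls, snp_ids, chrom, position_bp) -> "SnpTable":
        return cls(
            pd.DataFrame(
                {"chrom": list(chrom), "position_bp": np.asarray(position_bp, dtype=np.int64)},
                index=pd.Index(snp_ids, name="snp_id"),
            )
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def kept(self) -> pd.Series:
        return self.df["reasons"].map(len) == 0

    def ids(self, chrom: str | Chrom | None = None, kept: bool | None = None) -> np.ndarray:
        mask = pd.Series(True, index=self.df.index)
        if chrom is not None:
            mask &= self.df["chrom"] == str(chrom)
        if kept is not None:
            mask &= self.kept == kept
        return self.df.index[mask].to_numpy(dtype=object)

    def position(self, snp_ids) -> np.ndarray:
        return self.df.loc[list(snp_ids), "position_bp"].to_numpy(dtype=np.int64)

    def with_discards(self, reasons_by_snp: dict[str, tuple[str, ...]]) -> "SnpTable":
        """Return a copy where each listed SNP gains the given reason codes."""
        df = self.df.copy()
        reasons = df["reasons"].to_dict()
        for snp_id, new in reasons_by_snp.items():
            if snp_id not in reasons:
                raise ConsistencyError(f"unknown SNP {snp_id!r}")
            merged = tuple(reasons[snp_id]) + tuple(r for r in new if r not in reasons[snp_id])
            reasons[snp_id] = merged
        df["reasons"] = pd.Series([reasons[s] for s in df.index], index=df.index, dtype=object)
        return SnpTable(df)

    def to_frame(self) -> pd.DataFrame:
        """Flat export: reasons joined with ';', plus a ``kept`` column."""
        out = self.df.copy()
        out["kept"] = self.kept
        out["reasons"] = out["reasons"].map(";".join)
        return out.reset_index().rename(columns={"index": "snp_id"})


def make_gender_series(sample_ids, genders) -> pd.Series:
    """Build a recorded-sex Series (values M/F/U) indexed by sample id."""
    s = pd.Series(list(genders), index=pd.Index(sample_ids, name="sample_id"), dtype=object)
    if s.index.duplicated().any():
        dups = sorted(set(s.index[s.index.duplicated()]))
        raise ConsistencyError(f"duplicated sample_id in gender table: {dups[:5]}")
    bad = set(s) - {MALE, FEMALE, UNKNOWN}
    if bad:
        raise ConsistencyError(f"invalid gender codes {sorted(bad)} (expected M/F/U)")
    return s
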