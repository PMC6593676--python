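"""File input/output: VCF and TSV count-matrix dialects, SNP maps, sex records.

VCF input is parsed with cyvcf2 and must carry a per-sample ``AD`` (allele
depth) FORMAT field on biallelic SNP records.  The TSV dialect mirrors the
count matrices GBS pipelines emit: two congruent SNP x sample integer
matrices (reference and alternate reads) plus a three-column SNP map
(snp_id, chrom, position_bp).  Coordinates are 1-based throughout, as in
VCF.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AlleleDepthMatrix,
    Chrom,
    SnpTable,
    make_gender_series,
)
from .errors import ConsistencyError, FormatError

log = logging.getLogger(__name__)

__all__ = [
    "normalize_chrom",
    "read_vcf_allele_depths",
    "write_vcf",
    "read_count_tsv",
    "write_count_tsv",
    "read_snp_map",
    "write_snp_map",
    "read_gender_tsv",
    "write_gender_tsv",
    "write_predictions",
]

# Reference genomes name sex chromosomes inconsistently; these aliases are
# matched after stripping an optional "chr"/"chr_" prefix, case-insensitively.
X_ALIASES = {"x", "23"}
Y_ALIASES = {"y", "24"}
_UNPLACED_RE = re.compile(r"^(un|scaffold|contig|random|chrun)", re.IGNORECASE)


def normalize_chrom(name: str, aliases: dict[str, str] | None = None) -> str:
    """Map a contig name to X / Y / AUTOSOME / UNPLACED.

    ``aliases`` overrides the default: an exact-match dict from raw contig
    name to one of the four labels.
    """
    if aliases and name in aliases:
        return str(Chrom(aliases[name]))
    stripped = re.sub(r"^chr_?", "", name, flags=re.IGNORECASE).lower()
    if stripped in X_ALIASES:
        return Chrom.X.value
    if stripped in Y_ALIASES:
        return Chrom.Y.value
    if stripped.isdigit():
        return Chrom.AUTOSOME.value
    if _UNPLACED_RE.match(name):
        return Chrom.UNPLACED.value
    return Chrom.AUTOSOME.value


def read_vcf_allele_depths(
    path: str | Path,
    chrom_aliases: dict[str, str] | None = None,
    strict: bool = True,
) -> tuple[AlleleDepthMatrix, SnpTable]:
    """Read per-sample allele depths from a VCF with AD FORMAT fields.

    Multi-allelic records raise :class:`FormatError` under ``strict``;
    otherwise they are skipped and counted in the log.  Missing AD values
    (``.``) become depth 0.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[np.ndarray] = []
    alts: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            desc = f"{var.CHROM}:{var.POS}"
            if strict:
                raise FormatError(f"multi-allelic record at {desc} (strict mode)")
            n_skipped += 1
            continue
        ad = var.format("AD")
        if ad is None:
            raise FormatError(
                f"record {var.CHROM}:{var.POS} lacks the per-sample AD field"
            )
        ad = np.asarray(ad)
        if ad.shape[1] < 2:
            raise FormatError(
                f"record {var.CHROM}:{var.POS} has AD with {ad.shape[1]} values"
            )
        # cyvcf2 encodes missing AD entries as negative sentinels
        ref = np.clip(ad[:, 0], 0, None).astype(np.int64)
        alt = np.clip(ad[:, 1], 0, None).astype(np.int64)
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        snp_ids.append(snp_id)
        chroms.append(normalize_chrom(var.CHROM, chrom_aliases))
        positions.append(var.POS)
        refs.append(ref)
        alts.append(alt)
    if n_skipped:
        log.info("skipped %d multi-allelic records", n_skipped)
    if snp_ids:
        ref_mat = np.stack(refs, axis=1)
        alt_mat = np.stack(alts, axis=1)
    else:
        ref_mat = np.zeros((len(samples), 0), dtype=np.int64)
        alt_mat = np.zeros((len(samples), 0), dtype=np.int64)
    adm = AlleleDepthMatrix(np.array(samples, dtype=object), np.array(snp_ids, dtype=object), ref_mat, alt_mat)
    snps = SnpTable.from_arrays(snp_ids, chroms, positions)
    return adm, snps


_VCF_CONTIG = {"X": "X", "Y": "Y", "AUTOSOME": "1", "UNPLACED": "Un"}


def write_vcf(adm: AlleleDepthMatrix, snps: SnpTable, path: str | Path) -> None:
    """Write allele depths as a minimal biallelic VCF with GT and AD fields.

    Chromosome labels are emitted as contig names X / Y / 1 / Un; alleles are
    placeholders (A/C) since the method never uses base identity.  Output is
    deterministic for identical inputs.
    """
    order = list(adm.snp_ids)
    chrom = {s: c for s, c in zip(snps.df.index, snps.df["chrom"])}
    pos = {s: p for s, p in zip(snps.df.index, snps.df["position_bp"])}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in ("X", "Y", "1", "Un"):
            fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in adm.sample_ids)
            + "\n"
        )
        for j, snp_id in enumerate(order):
            cells = []
            for i in range(adm.n_samples):
                r, a = int(adm.ref_count[i, j]), int(adm.alt_count[i, j])
                if r + a == 0:
                    gt = "./."
                elif r > 0 and a > 0:
                    gt = "0/1"
                elif r > 0:
                    gt = "0/0"
                else:
                    gt = "1/1"
                cells.append(f"{gt}:{r},{a}")
            fh.write(
                f"{_VCF_CONTIG[chrom[snp_id]]}\t{pos[snp_id]}\t{snp_id}\tA\tC\t.\tPASS\t.\tGT:AD\t"
                + "\t".join(cells)
                + "\n"
            )


def read_snp_map(path: str | Path) -> SnpTable:
    """Read a 3-column TSV SNP map (snp_id, chrom, position_bp)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = {"snp_id", "chrom", "position_bp"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"SNP map {path} must have columns snp_id/chrom/position_bp, got {list(df.columns)}"
        )
    chroms = [normalize_chrom(str(c)) if str(c) not in {c2.value for c2 in Chrom} else str(c) for c in df["chrom"]]
    return SnpTable.from_arrays(df["snp_id"].astype(str), chroms, df["position_bp"].astype(np.int64))


def write_snp_map(snps: SnpTable, path: str | Path) -> None:
    out = snps.df.reset_index()
    out.columns = ["snp_id", "chrom", "position_bp", "reasons"]
    out[["snp_id", "chrom", "position_bp"]].to_csv(path, sep="\t", index=False)


def read_count_tsv(
    ref_path: str | Path, alt_path: str | Path, map_path: str | Path
) -> tuple[AlleleDepthMatrix, SnpTable]:
    """Read the TSV dialect: two SNP x sample matrices plus a SNP map.

    The two matrices must have identical SNP rows and sample columns, and
    the map must reference exactly the matrices' SNP set; any mismatch
    raises :class:`ConsistencyError` listing the offenders.
    """
    ref = pd.read_csv(ref_path, sep="\t", index_col=0)
    alt = pd.read_csv(alt_path, sep="\t", index_col=0)
    ref.index = ref.index.astype(str)
    alt.index = alt.index.astype(str)
    if list(ref.columns) != list(alt.columns) or list(ref.index) != list(alt.index):
        extra_cols = set(ref.columns) ^ set(alt.columns)
        extra_rows = set(ref.index) ^ set(alt.index)
        raise ConsistencyError(
            "ref/alt matrices are not congruent: "
            f"sample mismatch {sorted(extra_cols)[:5]}, SNP mismatch {sorted(extra_rows)[:5]}"
        )
    snps = read_snp_map(map_path)
    map_ids = set(snps.df.index)
    mat_ids = set(ref.index)
    if map_ids != mat_ids:
        raise ConsistencyError(
            "SNP map and matrices disagree: "
            f"map-only {sorted(map_ids - mat_ids)[:5]}, matrix-only {sorted(mat_ids - map_ids)[:5]}"
        )
    # align matrices to the map's SNP order
    order = list(snps.df.index)
    ref = ref.loc[order]
    alt = alt.loc[order]
    adm = AlleleDepthMatrix(
        np.array(ref.columns, dtype=object),
        np.array(order, dtype=object),
        ref.to_numpy(dtype=np.int64).T,
        alt.to_numpy(dtype=np.int64).T,
    )
    return adm, snps


def write_count_tsv(
    adm: AlleleDepthMatrix, snps: SnpTable, ref_path: str | Path, alt_path: str | Path, map_path: str | Path
) -> None:
    """Write the TSV dialect (inverse of :func:`read_count_tsv`)."""
    idx = pd.Index(adm.snp_ids, name="snp_id")
    pd.DataFrame(adm.ref_count.T, index=idx, columns=adm.sample_ids).to_csv(ref_path, sep="\t")
    pd.DataFrame(adm.alt_count.T, index=idx, columns=adm.sample_ids).to_csv(alt_path, sep="\t")
    # map rows follow the matrix SNP order so the round trip is exact
    sub = snps.df.loc[list(adm.snp_ids)].reset_index()
    sub.columns = ["snp_id", "chrom", "position_bp", "reasons"]
    sub[["snp_id", "chrom", "position_bp"]].to_csv(map_path, sep="\t", index=False)


def write_snp_table(snps: SnpTable, path: str | Path) -> None:
    """Write the full per-SNP table (chrom, position, kept, reasons)."""
    snps.to_frame().to_csv(path, sep="\t", index=False)


def read_snp_table(path: str | Path) -> SnpTable:
    """Read a table written by :func:`write_snp_table` (kept column ignored;
    kept status is derived from the reasons)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "reasons": str})
    required = {"snp_id", "chrom", "position_bp"}
    if not required.issubset(df.columns):
        raise FormatError(f"SNP table {path} must have columns {sorted(required)}")
    reasons = df.get("reasons")
    if reasons is None:
        reasons = pd.Series([""] * len(df))
    df = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str).to_numpy(),
            "position_bp": df["position_bp"].to_numpy(np.int64),
            "reasons": [tuple(r.split(";")) if isinstance(r, str) and r else () for r in reasons],
        },
        index=pd.Index(df["snp_id"].to_numpy(), name="snp_id"),
    )
    return SnpTable(df)


def read_gender_tsv(path: str | Path) -> pd.Series:
    """Read a 2-column TSV of recorded sexes (sample_id, M/F/U)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "gender"}.issubset(df.columns):
        raise FormatError(f"gender table {path} must have columns sample_id, gender")
    return make_gender_series(df["sample_id"], df["gender"].str.upper())


def write_gender_tsv(genders: pd.Series, path: str | Path) -> None:
    genders.rename("gender").rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def write_predictions(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-sample prediction TSV.

    Expects columns sample_id, H, P_Y, mean_depth, predicted, recorded,
    concordant (one row per retained sample).  Output is bit-stable for
    identical inputs: floats are rendered with repr-round-tripping %.10g.
    """
    cols = ["sample_id", "H", "P_Y", "mean_depth", "predicted", "recorded", "concordant"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ConsistencyError(f"prediction table missing columns {missing}")
    out = table[cols].copy()
    for c in ("H", "P_Y", "mean_depth"):
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else f"{v:.10g}")
    out["concordant"] = out["concordant"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)
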