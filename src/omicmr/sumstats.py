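"""Reading, validation, writing and allele harmonization of GWAS/QTL summary statistics.

Summary-statistic tables are plain tab-delimited files with the canonical
header ``SNP CHR POS EA OA EAF BETA SE P N N_CASE N_CONTROL``.  In memory a
table is a :class:`pandas.DataFrame` with those columns; per-row invariants
(valid alleles, ``SE > 0``, ``P`` in (0, 1], ``EAF`` in [0, 1]) are enforced
at read time and invalid rows are dropped with a reason code, never silently.

Coordinates are 1-based GRCh37; BETA is a per-allele effect of the effect
allele EA (log-odds for case-control traits, roughly SD units for molecular
traits).  The canonical missing-value token in files is ``"NA"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("omicmr.sumstats")

#: canonical column order for summary-statistic files
CANONICAL_COLUMNS = [
    "SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P",
    "N", "N_CASE", "N_CONTROL",
]

#: columns that must be present (and non-missing) in every valid record
REQUIRED_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "BETA", "SE", "P"]

VALID_ALLELES = frozenset("ACGT")

MISSING_TOKEN = "NA"


class SumStatsError(ValueError):
    """Raised on unreadable or structurally unusable summary-statistic input."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: identifier, symbol, chromosome and transcription start site (1-based, GRCh37)."""

    gene_id: str
    symbol: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"tss must be >= 1, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class LDMatrix:
    """Signed pairwise LD correlations (r) for an ordered SNP panel.

    ``r`` is symmetric with unit diagonal; ``r**2`` is the r-squared used for
    clumping.
    """

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {k} SNP ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("LD correlations outside [-1, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if len(self._index) != k:
            raise ValueError("duplicate SNP ids in LD panel")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two panel SNPs."""
        return float(self.r[self._index[a], self._index[b]] ** 2)


def read_ld_matrix(matrix_path: str | Path, ids_path: str | Path) -> LDMatrix:
    """Read a whitespace-delimited square LD matrix plus its sidecar id list."""
    ids = [line.strip() for line in Path(ids_path).read_text().splitlines() if line.strip()]
    r = np.loadtxt(matrix_path, ndmin=2)
    return LDMatrix(ids, r)


def write_ld_matrix(ld: LDMatrix, matrix_path: str | Path, ids_path: str | Path) -> None:
    np.savetxt(matrix_path, ld.r, fmt="%.6g")
    Path(ids_path).write_text("\n".join(ld.snp_ids) + "\n")


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation TSV with columns gene_id, symbol, chr, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    return [
        GeneAnnotation(str(r.gene_id), str(r.symbol), str(r.chr), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# reading / validation / writing
# ---------------------------------------------------------------------------

def _coerce(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    out["SNP"] = df["SNP"].astype("string")
    out["CHR"] = df["CHR"].astype("string").str.replace("^chr", "", regex=True)
    out["POS"] = pd.to_numeric(df["POS"], errors="coerce")
    for col in ("EA", "OA"):
        out[col] = df[col].astype("string").str.upper()
    for col in ("EAF", "BETA", "SE", "P"):
        out[col] = pd.to_numeric(df.get(col), errors="coerce")
    for col in ("N", "N_CASE", "N_CONTROL"):
        out[col] = pd.to_numeric(df.get(col), errors="coerce")
    return out


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate coerced records; return (clean table, rejections).

    Rejections carry one reason code per dropped row.  Reason codes:
    ``missing_field``, ``invalid_allele``, ``same_alleles``, ``bad_pos``,
    ``nonpositive_se``, ``bad_pvalue``, ``bad_eaf``, ``duplicate_snp``.
    Surviving records are returned with numeric fields untouched.
    """
    df = df.reset_index(drop=True)
    reason = pd.Series(pd.NA, index=df.index, dtype="string")

    def flag(mask: pd.Series, code: str) -> None:
        mask = mask.fillna(False) & reason.isna()
        reason[mask] = code

    missing = df["SNP"].isna() | df["CHR"].isna() | df["POS"].isna() \
        | df["EA"].isna() | df["OA"].isna() | df["BETA"].isna() \
        | df["SE"].isna() | df["P"].isna()
    flag(missing, "missing_field")
    flag(~df["EA"].isin(VALID_ALLELES) | ~df["OA"].isin(VALID_ALLELES), "invalid_allele")
    flag(df["EA"] == df["OA"], "same_alleles")
    flag(df["POS"] < 1, "bad_pos")
    flag(df["SE"] <= 0, "nonpositive_se")
    flag((df["P"] <= 0) | (df["P"] > 1), "bad_pvalue")
    flag((df["EAF"] < 0) | (df["EAF"] > 1), "bad_eaf")
    # duplicated rsIDs among surviving rows: keep the record with the lowest p
    ok = reason.isna()
    dup_order = df.loc[ok].sort_values(["SNP", "P"], kind="stable")
    dup = dup_order.duplicated("SNP", keep="first")
    flag(dup.reindex(df.index, fill_value=False), "duplicate_snp")

    rejected = reason.notna()
    rejections = pd.DataFrame({
        "row": df.index[rejected],
        "SNP": df.loc[rejected, "SNP"],
        "reason": reason[rejected],
    }).reset_index(drop=True)
    for rec in rejections.itertuples():
        logger.warning("dropped row %s (%s): %s", rec.row, rec.SNP, rec.reason)
    clean = df.loc[~rejected].reset_index(drop=True)
    clean["POS"] = clean["POS"].astype(np.int64)
    return clean, rejections


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a tab-delimited summary-statistic file into a validated table.

    Parameters
    ----------
    path
        Path to a tab-delimited file with a header line.
    dialect
        Optional mapping from the file's column names onto the canonical
        names (e.g. ``{"rsid": "SNP", "pval": "P"}``).  Unmapped extra
        columns are ignored.

    Returns
    -------
    A validated DataFrame in canonical column order.  Rejected rows are
    logged and attached as ``result.attrs["rejections"]``.
    """
    path = Path(path)
    if not path.exists():
        raise SumStatsError(f"summary-statistic file not found: {path}")
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING_TOKEN], keep_default_na=False)
    if dialect:
        raw = raw.rename(columns=dict(dialect))
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SumStatsError(f"required columns missing from {path}: {missing}")
    clean, rejections = validate_sumstats(_coerce(raw))
    if len(clean) == 0 and len(raw) > 0:
        logger.warning("no valid records remain in %s", path)
    clean = clean[CANONICAL_COLUMNS]
    clean.attrs["rejections"] = rejections
    clean.attrs["source"] = str(path)
    return clean


def write_sumstats(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table in canonical column order, tab-delimited, NA for missing."""
    out = table.copy()
    for col in CANONICAL_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    # integer-valued sample sizes render without trailing ".0"
    for col in ("N", "N_CASE", "N_CONTROL"):
        out[col] = out[col].astype("Int64") if _all_integral(out[col]) else out[col]
    out[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def _all_integral(s: pd.Series) -> bool:
    v = pd.to_numeric(s, errors="coerce").dropna()
    return bool(len(v) == 0 or (v == v.round()).all())


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

#: canonical instrument-table columns produced by :func:`harmonize`
INSTRUMENT_COLUMNS = [
    "snp_id", "beta_exp", "se_exp", "beta_out", "se_out",
    "eaf_exp", "eaf_out", "pval_exp", "f_stat", "flags",
]


@dataclass
class HarmonizationAudit:
    """Per-SNP dispositions of a harmonization pass."""

    n_exposure: int = 0
    n_outcome: int = 0
    n_harmonized: int = 0
    dropped: dict[str, str] = field(default_factory=dict)  # snp_id -> reason

    def count(self, reason: str) -> int:
        return sum(1 for r in self.dropped.values() if r == reason)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
) -> tuple[pd.DataFrame, HarmonizationAudit]:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    For each SNP present in both tables: if the outcome's (EA, OA) equals the
    exposure's, effects are copied; if the pair is swapped, the outcome beta is
    sign-flipped and its EAF replaced by ``1 - EAF``; any other allele pair is
    dropped with flag ``allele_mismatch``.  SNPs missing from either table are
    dropped (``not_in_outcome`` / ``not_in_exposure``), as are exposure records
    without an EAF (``no_exposure_eaf`` — needed downstream for palindrome
    handling and Steiger R²).  A missing outcome EAF is tolerated and flagged
    ``no_outcome_eaf``.
    """
    audit = HarmonizationAudit(n_exposure=len(exposure), n_outcome=len(outcome))
    out_by_id = outcome.set_index("SNP")
    exp_ids = set(exposure["SNP"])
    for snp in outcome["SNP"]:
        if snp not in exp_ids:
            audit.dropped[str(snp)] = "not_in_exposure"

    rows = []
    for rec in exposure.itertuples():
        snp = rec.SNP
        if snp not in out_by_id.index:
            audit.dropped[str(snp)] = "not_in_outcome"
            continue
        if pd.isna(rec.EAF):
            audit.dropped[str(snp)] = "no_exposure_eaf"
            continue
        o = out_by_id.loc[snp]
        flags: list[str] = []
        if (o.EA, o.OA) == (rec.EA, rec.OA):
            beta_out, eaf_out = o.BETA, o.EAF
        elif (o.EA, o.OA) == (rec.OA, rec.EA):
            beta_out = -o.BETA
            eaf_out = 1.0 - o.EAF if pd.notna(o.EAF) else np.nan
            flags.append("flipped")
        else:
            audit.dropped[str(snp)] = "allele_mismatch"
            continue
        if pd.isna(eaf_out):
            flags.append("no_outcome_eaf")
        rows.append({
            "snp_id": snp,
            "beta_exp": rec.BETA, "se_exp": rec.SE,
            "beta_out": float(beta_out), "se_out": float(o.SE),
            "eaf_exp": float(rec.EAF),
            "eaf_out": float(eaf_out) if pd.notna(eaf_out) else np.nan,
            "pval_exp": rec.P,
            "f_stat": (rec.BETA / rec.SE) ** 2,
            "flags": ";".join(flags),
        })
    table = pd.DataFrame(rows, columns=INSTRUMENT_COLUMNS)
    audit.n_harmonized = len(table)
    for snp, reason in audit.dropped.items():
        logger.info("harmonize: dropped %s (%s)", snp, reason)
    return table, audit


def intersect_regions(
    region1: pd.DataFrame, region2: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict two summary-stat regions to their shared SNPs, aligned by id."""
    shared = region1[region1["SNP"].isin(set(region2["SNP"]))]["SNP"]
    r1 = region1.set_index("SNP").loc[shared].reset_index()
    r2 = region2.set_index("SNP").loc[shared].reset_index()
    return r1, r2
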