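"""Instrument selection for cis-QTL Mendelian randomization.

Candidate instruments for an exposure (a plasma protein or a transcript) are
filtered through, in order:

1. genome-wide significance (P < 5e-8, strict),
2. cis position (within 1 Mb of the gene's TSS, closed interval),
3. exclusion of the MHC region (chr6:26-34 Mb, closed),
4. greedy LD clumping (r² > 0.001 within 10 Mb pruned, best p kept),
5. instrument strength (F = (beta/se)² > 10, strict),
6. exclusion of ambiguous palindromic SNPs (A/T or C/G with MAF ≥ 0.42),

then a confounder screen (drop SNPs associated with a supplied confounder
table at P < 1e-5), and finally allele harmonization against the outcome.
Every removal is recorded in a :class:`SelectionAudit` whose stage counts
telescope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .sumstats import GeneAnnotation, HarmonizationAudit, LDMatrix, harmonize

logger = logging.getLogger("omicmr.instruments")

PALINDROMIC_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the instrument-selection pipeline (defaults as used throughout)."""

    p_threshold: float = 5e-8          # genome-wide significance, strict <
    cis_window_bp: int = 1_000_000     # TSS ± window, closed
    mhc_chrom: str = "6"
    mhc_start_bp: int = 26_000_000
    mhc_end_bp: int = 34_000_000
    clump_r2: float = 0.001            # prune r² strictly above this
    clump_window_bp: int = 10_000_000
    f_min: float = 10.0                # keep F strictly above this
    palindrome_maf_ambiguous: float = 0.42
    palindrome_exclude_all: bool = False
    confounder_p: float = 1e-5

    def __post_init__(self) -> None:
        if self.mhc_start_bp >= self.mhc_end_bp:
            raise ValueError("mhc_start_bp must be < mhc_end_bp")
        for name in ("p_threshold", "cis_window_bp", "clump_r2",
                     "clump_window_bp", "f_min", "confounder_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int
    dropped: dict[str, str] = field(default_factory=dict)  # snp_id -> reason


@dataclass
class SelectionAudit:
    """Telescoping per-stage record of the selection pipeline."""

    stages: list[StageRecord] = field(default_factory=list)
    mean_f_retained: float | None = None
    notes: list[str] = field(default_factory=list)

    def add(self, stage: str, before: pd.DataFrame, after: pd.DataFrame,
            reason: str, dropped: dict[str, str] | None = None) -> None:
        if dropped is None:
            gone = set(before["SNP"]) - set(after["SNP"])
            dropped = {str(s): reason for s in gone}
        self.stages.append(StageRecord(stage, len(before), len(after), dropped))
        if dropped:
            logger.info("%s: dropped %d SNPs", stage, len(dropped))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


# ---------------------------------------------------------------------------
# individual filter stages
# ---------------------------------------------------------------------------

def filter_significant(records: pd.DataFrame, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Keep records with P strictly below the genome-wide threshold."""
    return records[records["P"] < p_threshold].reset_index(drop=True)


def filter_cis(records: pd.DataFrame, gene: GeneAnnotation,
               window_bp: int = 1_000_000) -> pd.DataFrame:
    """Keep records on the gene's chromosome within TSS ± window (closed)."""
    keep = (records["CHR"] == gene.chrom) & \
           ((records["POS"] - gene.tss).abs() <= window_bp)
    return records[keep].reset_index(drop=True)


def filter_mhc(records: pd.DataFrame, config: SelectionConfig = SelectionConfig()) -> pd.DataFrame:
    """Drop records inside the MHC region (closed interval)."""
    in_mhc = (records["CHR"] == config.mhc_chrom) & \
             (records["POS"] >= config.mhc_start_bp) & \
             (records["POS"] <= config.mhc_end_bp)
    return records[~in_mhc].reset_index(drop=True)


def ld_clump(records: pd.DataFrame, ld: LDMatrix,
             r2_max: float = 0.001, window_bp: int = 10_000_000,
             ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Greedy LD clumping: keep the best remaining SNP by p, prune its LD friends.

    Records absent from the LD panel are dropped first (``no_ld_info``).
    Candidates are visited in ascending p (ties broken by snp_id); each
    retained index SNP removes every other SNP within ``window_bp`` whose r²
    with it exceeds ``r2_max``.  Returns (retained records, dropped map).
    """
    dropped: dict[str, str] = {}
    if len(records) == 0:
        return records.reset_index(drop=True), dropped
    in_panel = records["SNP"].apply(lambda s: s in ld).astype(bool)
    for s in records.loc[~in_panel, "SNP"]:
        dropped[str(s)] = "no_ld_info"
    pool = records[in_panel].sort_values(
        ["P", "SNP"], kind="stable").reset_index(drop=True)
    alive = dict(zip(pool["SNP"], zip(pool["CHR"], pool["POS"])))
    kept: list[str] = []
    for rec in pool.itertuples():
        if rec.SNP not in alive:
            continue
        kept.append(rec.SNP)
        del alive[rec.SNP]
        for other, (chrom, pos) in list(alive.items()):
            if chrom == rec.CHR and abs(pos - rec.POS) <= window_bp \
                    and ld.r2(rec.SNP, other) > r2_max:
                dropped[str(other)] = "ld_clumped"
                del alive[other]
    out = records[records["SNP"].isin(kept)].reset_index(drop=True)
    return out, dropped


def compute_f(beta: float, se: float) -> float:
    """Single-SNP instrument-strength F statistic, (beta/se)²."""
    return (beta / se) ** 2


def filter_f(records: pd.DataFrame, f_min: float = 10.0) -> pd.DataFrame:
    """Keep records whose F statistic strictly exceeds ``f_min``."""
    f = (records["BETA"] / records["SE"]) ** 2
    return records[f > f_min].reset_index(drop=True)


def is_palindromic(ea: str, oa: str) -> bool:
    return frozenset((ea, oa)) in PALINDROMIC_PAIRS


def filter_palindromic(records: pd.DataFrame, maf_ambiguous: float = 0.42,
                       exclude_all: bool = False,
                       ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Drop strand-ambiguous palindromic SNPs.

    A SNP is palindromic iff its allele pair is {A,T} or {C,G}.  Palindromic
    SNPs with MAF ≥ ``maf_ambiguous`` (or all of them when ``exclude_all``)
    are dropped; palindromic SNPs with a clearly skewed frequency are kept
    (frequencies disambiguate the strand).  Missing EAF on a palindromic SNP
    is a drop. Returns (kept records, dropped map).
    """
    dropped: dict[str, str] = {}
    keep_idx = []
    for rec in records.itertuples():
        if not is_palindromic(rec.EA, rec.OA):
            keep_idx.append(rec.Index)
            continue
        if pd.isna(rec.EAF):
            dropped[str(rec.SNP)] = "palindromic_no_eaf"
            continue
        maf = min(rec.EAF, 1.0 - rec.EAF)
        if exclude_all or maf >= maf_ambiguous:
            dropped[str(rec.SNP)] = "palindromic_ambiguous"
        else:
            keep_idx.append(rec.Index)
    return records.loc[keep_idx].reset_index(drop=True), dropped


def filter_confounders(records: pd.DataFrame, confounder_table: pd.DataFrame | None,
                       p_threshold: float = 1e-5) -> pd.DataFrame:
    """Drop SNPs with any confounder association below ``p_threshold``.

    ``confounder_table`` has columns SNP, TRAIT, P (one row per reported
    association); SNPs absent from the table pass.  ``None`` disables the
    screen.
    """
    if confounder_table is None or len(confounder_table) == 0:
        return records.reset_index(drop=True)
    bad = set(confounder_table.loc[confounder_table["P"] < p_threshold, "SNP"])
    return records[~records["SNP"].isin(bad)].reset_index(drop=True)


def read_confounder_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "TRAIT": str})
    df["P"] = pd.to_numeric(df["P"], errors="coerce")
    return df


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def select_instruments(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    gene: GeneAnnotation,
    ld: LDMatrix,
    confounders: pd.DataFrame | None = None,
    config: SelectionConfig = SelectionConfig(),
) -> tuple[pd.DataFrame, SelectionAudit]:
    """Run the full selection cascade and harmonize against the outcome.

    Order: significance → cis → MHC → LD clump → F → palindrome → confounder
    → harmonize.  An empty result is legal (the exposure is then skipped
    downstream); the audit records every removal with a reason.
    """
    audit = SelectionAudit()
    step = exposure.reset_index(drop=True)

    nxt = filter_significant(step, config.p_threshold)
    audit.add("significance", step, nxt, "not_significant"); step = nxt
    nxt = filter_cis(step, gene, config.cis_window_bp)
    audit.add("cis", step, nxt, "not_cis"); step = nxt
    nxt = filter_mhc(step, config)
    audit.add("mhc", step, nxt, "in_mhc"); step = nxt
    nxt, dropped = ld_clump(step, ld, config.clump_r2, config.clump_window_bp)
    audit.add("ld_clump", step, nxt, "ld_clumped", dropped); step = nxt
    nxt = filter_f(step, config.f_min)
    audit.add("f_stat", step, nxt, "weak_instrument"); step = nxt
    nxt, dropped = filter_palindromic(step, config.palindrome_maf_ambiguous,
                                      config.palindrome_exclude_all)
    audit.add("palindrome", step, nxt, "palindromic_ambiguous", dropped); step = nxt
    nxt = filter_confounders(step, confounders, config.confounder_p)
    audit.add("confounder", step, nxt, "confounder_associated"); step = nxt

    table, harm = harmonize(step, outcome)
    exposure_side = {s: r for s, r in harm.dropped.items() if r != "not_in_exposure"}
    audit.add("harmonize", step, pd.DataFrame({"SNP": table["snp_id"]}),
              "harmonization", exposure_side)
    if len(table):
        audit.mean_f_retained = float(table["f_stat"].mean())
    else:
        audit.notes.append("no instruments retained; exposure will be skipped")
        logger.info("selection left no instruments for %s", gene.symbol)
    return table, audit
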