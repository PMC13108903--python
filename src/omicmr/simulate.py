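"""Synthetic QTL + GWAS summary statistics with known truth.

The generator emulates the statistical structure of a cis-QTL study paired
with a case-control GWAS: individual-level genotypes for one LD region are
drawn from a Gaussian AR(1) copula, a molecular exposure is built from a few
causal variants, a binary outcome is generated on the log-odds (liability)
scale in an independent cohort, and per-SNP marginal summary statistics are
computed exactly as a consumer of real summary data would receive them
(linear regression for the quantitative trait, a logistic score-test
approximation for the case-control trait).  Scenarios cover the five
colocalization configurations plus directional pleiotropy, a gross outlier
instrument, and reverse causation:

``h0``    no causal variant for either trait;
``h1``    causal variant(s) for the outcome GWAS only;
``h2``    causal variant(s) for the QTL only (the exposure has no effect);
``h3``    distinct causal variants in low LD;
``h4``    shared causal variants, outcome driven by the exposure (theta_true);
``pleiotropy_directional``  h4 plus a direct outcome effect at every
          instrument, oriented with the exposure effect;
``outlier``  h4 plus one grossly pleiotropic instrument;
``reverse_cause``  the outcome's genetic liability causes the exposure.

All randomness flows from a single seed through named substreams, so every
artifact is reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .sumstats import (
    CANONICAL_COLUMNS, GeneAnnotation, LDMatrix, harmonize,
    write_ld_matrix, write_sumstats,
)

SCENARIOS = (
    "h0", "h1", "h2", "h3", "h4",
    "pleiotropy_directional", "outlier", "reverse_cause",
)

#: ordered non-palindromic allele pairs used for generated SNPs
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one simulated region.

    Defaults describe the reference conditions used throughout the test
    surface: a 200-SNP cis region with AR(1) LD (rho = 0.9), MAF uniform on
    [0.05, 0.5], 10,000 exposure samples, 20,000 outcome samples with a 10%
    case fraction, 8 causal exposure variants of effect magnitude 0.15 (SD
    units), and a causal log-odds effect of 0.5 per exposure SD.
    """

    scenario: str = "h4"
    n_snps: int = 200
    ld_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure: int = 10_000
    n_outcome: int = 20_000
    case_fraction: float = 0.1
    theta_true: float = 0.5
    n_causal: int = 8
    qtl_effect_sd: float = 0.15
    pleiotropy_intercept: float = 0.05   # direct log-odds effect per instrument
    outlier_shift: float = 10.0          # in outcome SEs
    target_z: float | None = None        # scale causal effects to this marginal z
    gwas_effect: float = 0.3             # direct log-odds effect for h1/h3
    reverse_gamma: float = 0.1           # liability -> exposure loading
    reverse_effect: float = 1.0          # log-odds per allele at reverse SNPs
    chrom: str = "1"
    pos_start: int = 10_000_000
    pos_spacing: int = 10_000

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (0 < self.n_causal <= self.n_snps):
            raise ValueError("n_causal must be in [1, n_snps]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")


@dataclass
class TruthRecord:
    """Ground truth of one simulated study."""

    scenario: str
    seed: int
    theta_true: float
    causal_exposure: list[int]      # SNP indices with a true exposure effect
    causal_outcome: list[int]       # SNP indices with a direct outcome effect
    beta_exposure: list[float]      # per-SNP true exposure effects
    direct_outcome: list[float]     # per-SNP direct log-odds effects
    snp_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass
class SimulatedStudy:
    config: ScenarioConfig
    qtl: pd.DataFrame
    gwas: pd.DataFrame
    ld: LDMatrix | None
    gene: GeneAnnotation
    truth: TruthRecord


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _haplotype_alleles(rng: np.random.Generator, n: int, maf: np.ndarray,
                       rho: float) -> np.ndarray:
    """One haplotype per row: AR(1) Gaussian copula thresholded at MAF quantiles."""
    p = len(maf)
    z = np.empty((n, p), dtype=np.float32)
    z[:, 0] = rng.standard_normal(n, dtype=np.float32)
    c = np.float32(np.sqrt(1.0 - rho ** 2))
    r = np.float32(rho)
    buf = np.empty(n, dtype=np.float32)
    for j in range(1, p):
        rng.standard_normal(out=buf, dtype=np.float32)
        np.multiply(z[:, j - 1], r, out=z[:, j])
        z[:, j] += c * buf
    thresholds = stats.norm.ppf(maf).astype(np.float32)
    return z < thresholds


def _genotypes(rng: np.random.Generator, n: int, maf: np.ndarray,
               rho: float) -> np.ndarray:
    """Diploid dosage matrix (n x p float32) from two copula haplotypes."""
    g = _haplotype_alleles(rng, n, maf, rho).astype(np.float32)
    g += _haplotype_alleles(rng, n, maf, rho)
    return g


def simulate_genotypes(config: ScenarioConfig, seed: int, n: int | None = None,
                       stream: int = 1) -> tuple[np.ndarray, LDMatrix]:
    """Genotype matrix (n x n_snps, 0/1/2) and its realized LD matrix."""
    n = config.n_exposure if n is None else n
    rng = _rng(seed, stream)
    maf = _rng(seed, 0).uniform(*config.maf_range, config.n_snps)
    g = _genotypes(rng, n, maf, config.ld_rho)
    ids = _snp_ids(config.n_snps)
    r = np.clip(np.corrcoef(g, rowvar=False), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return g, LDMatrix(ids, r)


def _snp_ids(p: int) -> list[str]:
    return [f"rs{100000 + i}" for i in range(p)]


def _causal_indices(config: ScenarioConfig) -> np.ndarray:
    if config.n_causal == 1:
        return np.array([config.n_snps // 2])
    idx = np.unique(np.round(
        np.linspace(0, config.n_snps - 1, config.n_causal)).astype(int))
    return idx


# ---------------------------------------------------------------------------
# marginal summary statistics
# ---------------------------------------------------------------------------

def _marginal_linear(g: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP simple-regression beta and SE of a quantitative trait on dosage."""
    n = len(x)
    gc = g - g.mean(axis=0, keepdims=True)
    xc = (x - x.mean()).astype(np.float64)
    sxx = np.einsum("ij,ij->j", gc, gc, dtype=np.float64)
    sxy = np.einsum("ij,i->j", gc, xc, dtype=np.float64)
    beta = sxy / sxx
    syy = float(xc @ xc)
    resid = np.maximum(syy - beta * sxy, 0.0)
    sigma2 = resid / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    return beta, se


def _marginal_logistic_score(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP log-odds effect and SE from the logistic score-test approximation."""
    v = float(y.mean())
    gc = g - g.mean(axis=0, keepdims=True)
    u = np.einsum("ij,i->j", gc, (y - v).astype(np.float64), dtype=np.float64)
    sxx = np.einsum("ij,ij->j", gc, gc, dtype=np.float64)
    info = v * (1.0 - v) * sxx
    beta = u / info
    se = info ** -0.5
    return beta, se


def _sumstats_frame(ids: list[str], config: ScenarioConfig, pos: np.ndarray,
                    ea: list[str], oa: list[str], eaf: np.ndarray,
                    beta: np.ndarray, se: np.ndarray, n: int,
                    n_case: int | None = None, n_control: int | None = None,
                    ) -> pd.DataFrame:
    z = beta / se
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR)
    df = pd.DataFrame({
        "SNP": ids, "CHR": config.chrom, "POS": pos,
        "EA": ea, "OA": oa, "EAF": eaf,
        "BETA": beta, "SE": se, "P": p, "N": n,
        "N_CASE": n_case, "N_CONTROL": n_control,
    })
    return df[CANONICAL_COLUMNS]


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

def _true_effects(config: ScenarioConfig, maf: np.ndarray, seed: int,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP exposure effects and direct outcome effects for the scenario."""
    rng = _rng(seed, 4)
    p = config.n_snps
    bx = np.zeros(p)
    d = np.zeros(p)
    idx = _causal_indices(config)
    signs = rng.choice([-1.0, 1.0], size=len(idx))
    v = config.case_fraction
    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    se_y = 1.0 / np.sqrt(v * (1.0 - v) * 2.0 * maf * (1.0 - maf) * config.n_outcome)

    def x_effects(i: np.ndarray) -> np.ndarray:
        # causal exposure effects: N(0, qtl_effect_sd²) draws, or a magnitude
        # pinned to a target marginal z-score when one is requested
        if config.target_z is not None:
            return signs * config.target_z * se_x[i]
        return rng.normal(0.0, config.qtl_effect_sd, len(i))

    def y_mag(i: np.ndarray) -> np.ndarray:
        if config.target_z is not None:
            return config.target_z * se_y[i]
        return np.full(len(i), config.gwas_effect)

    s = config.scenario
    idx_out = idx.copy()
    if s == "h0":
        idx = idx[:0]
        idx_out = idx_out[:0]
    elif s == "h1":
        idx = idx[:0]
        d[idx_out] = signs * y_mag(idx_out)
    elif s == "h2":
        bx[idx] = x_effects(idx)
        idx_out = idx_out[:0]
    elif s == "h3":
        bx[idx] = x_effects(idx)
        idx_out = (idx + 50) % p
        d[idx_out] = rng.choice([-1.0, 1.0], size=len(idx_out)) * y_mag(idx_out)
    elif s in ("h4", "pleiotropy_directional", "outlier"):
        bx[idx] = x_effects(idx)
        if config.target_z is not None and config.theta_true == 0.0:
            # shared causal variant with no mediated path: give the outcome
            # its own association of the requested strength at the same SNPs
            d[idx] = rng.choice([-1.0, 1.0], size=len(idx)) * y_mag(idx)
        if s == "pleiotropy_directional":
            d[idx] += config.pleiotropy_intercept * np.sign(bx[idx])
        if s == "outlier":
            j = idx[len(idx) // 2]
            d[j] += config.outlier_shift * se_y[j]
    elif s == "reverse_cause":
        # direct outcome effects only; the exposure inherits them via the
        # liability -> exposure loading applied in _exposure_trait
        d[idx_out] = signs * config.reverse_effect
        idx = idx[:0]
    return bx, d, idx, idx_out


_REVERSE_LIABILITY_SD = 1.8  # residual liability noise, roughly logistic scale


def _exposure_trait(config: ScenarioConfig, g: np.ndarray, bx: np.ndarray,
                    d: np.ndarray, maf: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    var_g = float(np.sum(bx ** 2 * 2.0 * maf * (1.0 - maf)))
    if config.scenario == "reverse_cause":
        liab = g @ d.astype(np.float32) + \
            rng.normal(0.0, _REVERSE_LIABILITY_SD, len(g))
        var_l = float(np.sum(d ** 2 * 2.0 * maf * (1.0 - maf))) \
            + _REVERSE_LIABILITY_SD ** 2
        resid = np.sqrt(max(0.05, 1.0 - config.reverse_gamma ** 2 * var_l))
        return config.reverse_gamma * liab + rng.normal(0.0, resid, len(g))
    resid = np.sqrt(max(0.05, 1.0 - var_g))
    return g @ bx.astype(np.float32) + rng.normal(0.0, resid, len(g))


def simulate_sumstats(config: ScenarioConfig, seed: int,
                      compute_ld: bool = True,
                      cohort_seed: int | None = None) -> SimulatedStudy:
    """Generate one study: QTL and GWAS summary tables, LD, gene, truth.

    Deterministic given (config, seed).  ``compute_ld=False`` skips the
    realized-LD computation (useful in tight simulation loops).
    ``cohort_seed`` redraws the sampled cohorts while keeping the population
    (MAFs, alleles, true effects) fixed — a replication study of the same
    region.
    """
    cohort_seed = seed if cohort_seed is None else cohort_seed
    maf = _rng(seed, 0).uniform(*config.maf_range, config.n_snps)
    ids = _snp_ids(config.n_snps)
    pos = config.pos_start + np.arange(config.n_snps) * config.pos_spacing
    pair_idx = _rng(seed, 5).integers(0, len(_ALLELE_PAIRS), config.n_snps)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    bx, d, idx_exp, idx_out = _true_effects(config, maf, seed)

    # exposure cohort
    rng_exp = _rng(cohort_seed, 1)
    g_exp = _genotypes(rng_exp, config.n_exposure, maf, config.ld_rho)
    x = _exposure_trait(config, g_exp, bx, d, maf, _rng(cohort_seed, 2))
    beta_x, se_x = _marginal_linear(g_exp, x)
    qtl = _sumstats_frame(ids, config, pos, ea, oa, g_exp.mean(0) / 2.0,
                          beta_x, se_x, config.n_exposure)

    ld = None
    if compute_ld:
        r = np.clip(np.corrcoef(g_exp, rowvar=False), -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        ld = LDMatrix(ids, r)

    # outcome cohort (independent; two-sample design by construction)
    rng_out = _rng(cohort_seed, 3)
    g_out = _genotypes(rng_out, config.n_outcome, maf, config.ld_rho)
    noise_rng = _rng(cohort_seed, 6)
    if config.scenario == "reverse_cause":
        lin = g_out @ d.astype(np.float32)
    else:
        x_out = _exposure_trait(config, g_out, bx, d * 0.0, maf, noise_rng)
        lin = config.theta_true * x_out + g_out @ d.astype(np.float32)
    v = config.case_fraction
    eta = np.log(v / (1.0 - v)) + (lin - lin.mean())
    y = (noise_rng.uniform(size=config.n_outcome) < expit(eta)).astype(np.float64)
    beta_y, se_y = _marginal_logistic_score(g_out, y)
    n_case = int(y.sum())
    gwas = _sumstats_frame(ids, config, pos, ea, oa, g_out.mean(0) / 2.0,
                           beta_y, se_y, config.n_outcome,
                           n_case=n_case, n_control=config.n_outcome - n_case)

    tss = int(pos[config.n_snps // 2])
    gene = GeneAnnotation("SIMG0001", "SIMG1", config.chrom, tss)
    truth = TruthRecord(config.scenario, seed, config.theta_true,
                        [int(i) for i in idx_exp], [int(i) for i in idx_out],
                        bx.tolist(), d.tolist(), ids)
    return SimulatedStudy(config, qtl, gwas, ld, gene, truth)


def truth_instruments(study: SimulatedStudy) -> pd.DataFrame:
    """Harmonized instrument table at the study's true causal exposure SNPs.

    For reverse-causation studies the reverse SNPs (which drive both traits)
    are used.
    """
    idx = study.truth.causal_exposure or study.truth.causal_outcome
    snps = [study.truth.snp_ids[i] for i in idx]
    exp = study.qtl[study.qtl["SNP"].isin(snps)].reset_index(drop=True)
    table, _ = harmonize(exp, study.gwas)
    return table


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, str]:
    """Write a study's artifacts to a directory; returns {name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "qtl": out / "qtl.tsv", "gwas": out / "gwas.tsv",
        "genes": out / "genes.tsv", "truth": out / "truth.json",
        "sidecar": out / "run.json",
    }
    write_sumstats(study.qtl, paths["qtl"])
    write_sumstats(study.gwas, paths["gwas"])
    g = study.gene
    pd.DataFrame([{"gene_id": g.gene_id, "symbol": g.symbol, "chr": g.chrom,
                   "tss": g.tss, "strand": g.strand}]).to_csv(
        paths["genes"], sep="\t", index=False)
    study.truth.to_json(paths["truth"])
    if study.ld is not None:
        paths["ld_matrix"] = out / "ld_matrix.txt"
        paths["ld_snps"] = out / "ld_snps.txt"
        write_ld_matrix(study.ld, paths["ld_matrix"], paths["ld_snps"])
    Path(paths["sidecar"]).write_text(json.dumps(
        {"seed": study.truth.seed, "scenario": study.config.scenario}, indent=2))
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

def selection_fixture() -> dict[str, object]:
    """A designed region where each selection stage removes exactly one SNP.

    Gene on chr6 with TSS at 25.5 Mb (cis window 24.5-26.5 Mb, MHC starts at
    26 Mb).  Victims, one per stage: ``rs_sig`` (p exactly 5e-8), ``rs_cis``
    (outside the window), ``rs_mhc`` (inside the MHC), ``rs_clump`` (r = 0.95
    with the stronger rs_keep1), ``rs_weakf`` (F = 9), ``rs_palin`` (A/T at
    EAF 0.5), ``rs_conf`` (confounder association at p = 5e-6), ``rs_noout``
    (absent from the outcome).  ``rs_keep1`` and ``rs_keep2`` survive;
    rs_keep2 arrives allele-swapped in the outcome and is sign-flipped.
    """
    gene = GeneAnnotation("FIXG0001", "FIXG1", "6", 25_500_000)

    def row(snp, pos, ea="A", og="G", eaf=0.3, beta=0.1, se=0.01, p=1e-23):
        return {"SNP": snp, "CHR": "6", "POS": pos, "EA": ea, "OA": og,
                "EAF": eaf, "BETA": beta, "SE": se, "P": p,
                "N": 10000, "N_CASE": None, "N_CONTROL": None}

    exposure = pd.DataFrame([
        row("rs_keep1", 24_600_000, p=1e-23),
        row("rs_clump", 24_601_000, p=1e-19),
        row("rs_keep2", 25_800_000, p=1e-22),
        row("rs_sig", 25_100_000, p=5e-8),
        row("rs_cis", 23_400_000),
        row("rs_mhc", 26_100_000),
        row("rs_weakf", 24_900_000, beta=0.03, p=1e-9),
        row("rs_palin", 24_800_000, ea="A", og="T", eaf=0.5),
        row("rs_conf", 24_700_000),
        row("rs_noout", 25_000_000),
    ])
    exposure["POS"] = exposure["POS"].astype(np.int64)

    ids = list(exposure["SNP"])
    r = np.eye(len(ids))
    i, j = ids.index("rs_keep1"), ids.index("rs_clump")
    r[i, j] = r[j, i] = 0.95
    ld = LDMatrix(ids, r)

    outcome = exposure[exposure["SNP"] != "rs_noout"].copy().reset_index(drop=True)
    outcome["BETA"] = 0.02
    outcome["SE"] = 0.01
    outcome["P"] = 0.1
    outcome["N"] = 20000
    outcome["N_CASE"] = 2000
    outcome["N_CONTROL"] = 18000
    k2 = outcome["SNP"] == "rs_keep2"
    outcome.loc[k2, ["EA", "OA"]] = ["G", "A"]
    outcome.loc[k2, "BETA"] = -0.02
    outcome.loc[k2, "EAF"] = 0.7

    confounders = pd.DataFrame({
        "SNP": ["rs_conf", "rs_keep1"],
        "TRAIT": ["smoking", "smoking"],
        "P": [5e-6, 2e-5],
    })
    return {"exposure": exposure, "outcome": outcome, "gene": gene,
            "ld": ld, "confounders": confounders}


def noiseless_pleiotropy_instruments(intercept: float = 0.05,
                                     slope: float = 0.3, k: int = 3,
                                     se_out: float = 0.002) -> pd.DataFrame:
    """Instrument table lying exactly on beta_out = intercept + slope * beta_exp.

    Defaults use three instruments (so the pleiotropy is judged by the Egger
    intercept, not flagged away as per-SNP outliers) with small outcome SEs:
    on noiseless data the Egger fit is exact and the nonzero intercept is
    unambiguous.
    """
    bx = np.linspace(0.1, 0.5, k)
    by = intercept + slope * bx
    return pd.DataFrame({
        "snp_id": [f"iv{i}" for i in range(k)],
        "beta_exp": bx, "se_exp": 0.01, "beta_out": by, "se_out": se_out,
        "eaf_exp": 0.3, "eaf_out": 0.3, "pval_exp": 1e-20,
        "f_stat": (bx / 0.01) ** 2, "flags": "",
    })


def outlier_instruments(shift_se: float = 10.0, k: int = 8,
                        seed: int = 11) -> tuple[pd.DataFrame, str]:
    """A homogeneous instrument set with one outcome effect shifted by ``shift_se`` SEs.

    Returns (table, outlier snp_id).
    """
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.1, 0.4, k) * rng.choice([-1, 1], k)
    se_out = np.full(k, 0.02)
    theta = 0.4
    by = theta * bx + rng.normal(0.0, se_out)
    j = k // 2
    by[j] += shift_se * se_out[j]
    table = pd.DataFrame({
        "snp_id": [f"iv{i}" for i in range(k)],
        "beta_exp": bx, "se_exp": 0.012, "beta_out": by, "se_out": se_out,
        "eaf_exp": 0.3, "eaf_out": 0.3, "pval_exp": 1e-20,
        "f_stat": (bx / 0.012) ** 2, "flags": "",
    })
    return table, f"iv{j}"


#: evidence classes as reported for the eight headline targets
REPORTED_EVIDENCE = [
    # target, outcome, mr_class, coloc_class, replication, pph4
    ("MGP", "acute_gn", "suggestive", "none", "yes", float("nan")),
    ("BRSK2", "acute_gn", "suggestive", "none", "yes", float("nan")),
    ("AFM", "chronic_gn", "strong", "moderate", "yes", 0.724),
    ("IL6R", "iga_nephropathy", "strong", "moderate", "yes", 0.782),
    ("HCK", "membranous_nephropathy", "strong", "strong", "not_available", 1.00),
    ("TIMP4", "membranous_nephropathy", "strong", "strong", "not_available", 0.873),
    ("PEAR1", "membranous_nephropathy", "strong", "strong", "not_available", 0.833),
]


def reported_evidence_table() -> pd.DataFrame:
    """Headline-target evidence classes as a DataFrame."""
    return pd.DataFrame(REPORTED_EVIDENCE, columns=[
        "target", "outcome", "mr_class", "coloc_class", "replication", "pph4"])


_TOY_GRAPHS = {
    "k4_k3.tsv": [("a1", "a2"), ("a1", "a3"), ("a1", "a4"), ("a2", "a3"),
                  ("a2", "a4"), ("a3", "a4"), ("b1", "b2"), ("b1", "b3"),
                  ("b2", "b3")],
    "k5_pendant.tsv": [(f"c{i}", f"c{j}") for i in range(1, 6)
                       for j in range(i + 1, 6)] + [("c1", "p1")],
    "two_triangles.tsv": [("t1", "t2"), ("t2", "t3"), ("t1", "t3"),
                          ("u1", "u2"), ("u2", "u3"), ("u1", "u3")],
}


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, str]:
    """Write the deterministic fixture files plus a checksum manifest.

    Contents: the single-victim selection region, a noiseless directional-
    pleiotropy instrument table, a gross-outlier instrument table, the
    headline-target evidence table, and toy PPI graphs.  Regeneration with
    the same seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = selection_fixture()
    write_sumstats(fx["exposure"], out / "selection_exposure.tsv")
    write_sumstats(fx["outcome"], out / "selection_outcome.tsv")
    write_ld_matrix(fx["ld"], out / "selection_ld.txt", out / "selection_ld_snps.txt")
    g = fx["gene"]
    pd.DataFrame([{"gene_id": g.gene_id, "symbol": g.symbol, "chr": g.chrom,
                   "tss": g.tss, "strand": g.strand}]).to_csv(
        out / "selection_genes.tsv", sep="\t", index=False)
    fx["confounders"].to_csv(out / "confounders.tsv", sep="\t", index=False)

    noiseless_pleiotropy_instruments().to_csv(
        out / "pleiotropy_instruments.tsv", sep="\t", index=False)
    table, outlier_id = outlier_instruments(seed=seed + 11)
    table.to_csv(out / "outlier_instruments.tsv", sep="\t", index=False)
    (out / "outlier_id.txt").write_text(outlier_id + "\n")
    reported_evidence_table().to_csv(out / "reported_evidence.tsv",
                                     sep="\t", index=False)
    for name, edges in _TOY_GRAPHS.items():
        (out / name).write_text("".join(f"{a}\t{b}\n" for a, b in edges))

    files = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
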