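"""Bayesian colocalization of two association signals in one cis region.

Under the single-causal-variant assumption, five hypotheses partition the
configurations of a region shared by a QTL and a GWAS: no causal variant for
either trait (H0), a causal variant for trait 1 only (H1), for trait 2 only
(H2), distinct causal variants (H3), or one shared causal variant (H4).
Per-SNP evidence is the Wakefield approximate Bayes factor computed from the
marginal beta and standard error,

    log ABF = 0.5 * (log(1 - r) + r * z**2),   r = w / (w + se**2),

with ``w`` the prior variance of a true effect (sd 0.2 for quantitative
traits, 0.15 on the log-odds scale for case-control traits).  Configuration
sums are accumulated in log space (log-sum-exp) so posteriors remain exact
for |z| far beyond 50.  Posterior PPH4 is classified as high (>= 0.80),
medium (>= 0.50) or none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import intersect_regions


class ColocError(ValueError):
    pass


@dataclass(frozen=True)
class ColocPriors:
    """Prior probabilities per SNP and per-trait effect-size prior variances."""

    p1: float = 1e-4       # causal for trait 1 only
    p2: float = 1e-4       # causal for trait 2 only
    p12: float = 1e-5      # shared causal variant
    w_quant: float = 0.2 ** 2   # prior effect variance, quantitative trait
    w_cc: float = 0.15 ** 2     # prior effect variance, case-control (log-odds)

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            import warnings
            warnings.warn("p12 exceeds min(p1, p2); the shared-variant prior "
                          "should not outweigh the single-trait priors",
                          stacklevel=2)

    def w_for(self, trait_type: str) -> float:
        if trait_type == "quantitative":
            return self.w_quant
        if trait_type == "case_control":
            return self.w_cc
        raise ValueError(f"unknown trait_type {trait_type!r}")


@dataclass(frozen=True)
class ColocResult:
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps: int

    @property
    def class_(self) -> str:
        return classify_pph4(self.pph4)

    def as_dict(self) -> dict:
        return {"pph0": self.pph0, "pph1": self.pph1, "pph2": self.pph2,
                "pph3": self.pph3, "pph4": self.pph4,
                "n_snps": self.n_snps, "class": self.class_}


def snp_labf(beta, se, w) -> np.ndarray | float:
    """Wakefield log approximate Bayes factor for one marginal association."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if w <= 0:
        raise ValueError("prior variance w must be positive")
    z = beta / se
    r = w / (w + se ** 2)
    out = 0.5 * (np.log1p(-r) + r * z ** 2)
    return out if out.ndim else float(out)


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when equal (or numerically below)."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def colocalize(region1: pd.DataFrame, region2: pd.DataFrame,
               priors: ColocPriors = ColocPriors(),
               trait_type1: str = "quantitative",
               trait_type2: str = "case_control") -> ColocResult:
    """Posterior probabilities of H0-H4 for two regions of summary statistics.

    The computation is restricted to the SNP intersection of the two regions;
    an empty intersection is an error (``no_shared_snps``).  Region tables
    are canonical summary-statistic DataFrames (columns SNP, BETA, SE, ...).
    """
    r1, r2 = intersect_regions(region1, region2)
    n = len(r1)
    if n == 0:
        raise ColocError("no_shared_snps")
    l1 = np.asarray(snp_labf(r1["BETA"].to_numpy(), r1["SE"].to_numpy(),
                             priors.w_for(trait_type1)), dtype=float)
    l2 = np.asarray(snp_labf(r2["BETA"].to_numpy(), r2["SE"].to_numpy(),
                             priors.w_for(trait_type2)), dtype=float)

    lse1 = float(logsumexp(l1))          # log sum_j B1_j
    lse2 = float(logsumexp(l2))          # log sum_j B2_j
    lse12 = float(logsumexp(l1 + l2))    # log sum_j B1_j B2_j

    ls0 = 0.0
    ls1 = np.log(priors.p1) + lse1
    ls2 = np.log(priors.p2) + lse2
    # sum over ordered pairs of distinct SNPs: sum_i B1_i * sum_j B2_j - sum_j B1_j B2_j
    cross = _logdiffexp(lse1 + lse2, lse12) if n > 1 else -np.inf
    ls3 = np.log(priors.p1) + np.log(priors.p2) + cross
    ls4 = np.log(priors.p12) + lse12

    logs = np.array([ls0, ls1, ls2, ls3, ls4])
    post = np.exp(logs - logsumexp(logs))
    post /= post.sum()
    return ColocResult(*map(float, post), n_snps=n)


def classify_pph4(pph4: float) -> str:
    """Classify a shared-causal-variant posterior: high >= 0.80, medium >= 0.50."""
    if not 0.0 <= pph4 <= 1.0:
        raise ValueError("pph4 must be in [0, 1]")
    if pph4 >= 0.80:
        return "high"
    if pph4 >= 0.50:
        return "medium"
    return "none"
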