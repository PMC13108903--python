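"""Rule-based genetic evidence scoring and ranking of candidate targets.

Each (target, outcome) pair accumulates points from three independent lines
of genetic evidence:

* 1.0 for a high-confidence MR association (adjusted p < 0.05), or 0.5 for a
  suggestive one (adjusted p < 0.10);
* 1.0 for strong colocalization (PPH4 >= 0.8), or 0.5 for moderate
  (0.5 <= PPH4 < 0.8);
* 1.0 for supportive replication/meta-analysis evidence (pooled 95% CI
  excluding OR = 1 with direction matching discovery).

The MR component uses the best class across omic layers (a target
significant in both the protein and transcript layers still receives at most
one MR point), so the attainable scores are {0, 0.5, 1, 1.5, 2, 2.5, 3} with
a maximum of 3.0.  Downstream context (network hubs, drug annotations,
knockout phenotypes) never contributes to the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

MR_CLASSES = ("strong", "suggestive", "none")
COLOC_CLASSES = ("strong", "moderate", "none")
REPLICATION_STATES = ("yes", "no", "not_available")


@dataclass(frozen=True)
class ScoreThresholds:
    fdr_strong: float = 0.05
    fdr_suggestive: float = 0.10
    pph4_strong: float = 0.80
    pph4_moderate: float = 0.50


@dataclass(frozen=True)
class EvidenceRecord:
    """Collapsed per-(target, outcome) evidence classes feeding the score."""

    target: str
    outcome: str
    mr_class: str                 # strong | suggestive | none (best across layers)
    coloc_class: str              # strong | moderate | none (best across layers)
    replication_support: str      # yes | no | not_available
    best_pph4: float = float("nan")
    best_p_adj: float = float("nan")

    def __post_init__(self) -> None:
        if self.mr_class not in MR_CLASSES:
            raise ValueError(f"bad mr_class {self.mr_class!r}")
        if self.coloc_class not in COLOC_CLASSES:
            raise ValueError(f"bad coloc_class {self.coloc_class!r}")
        if self.replication_support not in REPLICATION_STATES:
            raise ValueError(f"bad replication_support {self.replication_support!r}")


@dataclass(frozen=True)
class TargetScore:
    target: str
    outcome: str
    score: float
    components: dict[str, float] = field(hash=False, default_factory=dict)


_MR_POINTS = {"strong": 1.0, "suggestive": 0.5, "none": 0.0}
_COLOC_POINTS = {"strong": 1.0, "moderate": 0.5, "none": 0.0}


def score_target(evidence: EvidenceRecord) -> TargetScore:
    """Score one evidence record; components are itemized and sum to the score."""
    components = {
        "mr": _MR_POINTS[evidence.mr_class],
        "coloc": _COLOC_POINTS[evidence.coloc_class],
        "replication": 1.0 if evidence.replication_support == "yes" else 0.0,
    }
    return TargetScore(evidence.target, evidence.outcome,
                       sum(components.values()), components)


def enumerate_scores() -> set[float]:
    """All scores attainable over the 3 x 3 x 2 evidence-class combinations."""
    out = set()
    for mr_c, co_c, rep in product(MR_CLASSES, COLOC_CLASSES, ("yes", "no")):
        rec = EvidenceRecord("X", "Y", mr_c, co_c, rep)
        out.add(score_target(rec).score)
    return out


def mr_class_from_padj(p_adj: float, thresholds: ScoreThresholds = ScoreThresholds()) -> str:
    if np.isnan(p_adj):
        return "none"
    if p_adj < thresholds.fdr_strong:
        return "strong"
    if p_adj < thresholds.fdr_suggestive:
        return "suggestive"
    return "none"


def coloc_class_from_pph4(pph4: float, thresholds: ScoreThresholds = ScoreThresholds()) -> str:
    if np.isnan(pph4):
        return "none"
    if pph4 >= thresholds.pph4_strong:
        return "strong"
    if pph4 >= thresholds.pph4_moderate:
        return "moderate"
    return "none"


def build_evidence(
    mr_results: pd.DataFrame,
    coloc_results: pd.DataFrame | None,
    meta_results: pd.DataFrame | None,
    replicable_outcomes: set[str] | None = None,
    thresholds: ScoreThresholds = ScoreThresholds(),
) -> list[EvidenceRecord]:
    """Join MR, colocalization and meta-analysis tables into evidence records.

    ``mr_results`` needs columns target, outcome, layer, p_adj, theta;
    ``coloc_results`` target, outcome, layer, pph4; ``meta_results`` target,
    outcome, theta, ci_low, ci_high (odds-ratio-scale CI).  Replication
    support is "yes" iff a pooled estimate exists whose CI excludes OR = 1
    and whose direction matches discovery, "not_available" for outcomes
    without a replication cohort, otherwise "no".  Duplicate
    (target, outcome, layer) MR rows are an error.
    """
    if mr_results.duplicated(["target", "outcome", "layer"]).any():
        raise ValueError("ambiguous_evidence: duplicate (target, outcome, layer) rows")
    coloc_results = coloc_results if coloc_results is not None else \
        pd.DataFrame(columns=["target", "outcome", "layer", "pph4"])
    meta_results = meta_results if meta_results is not None else \
        pd.DataFrame(columns=["target", "outcome", "theta", "ci_low", "ci_high"])

    records = []
    for (target, outcome), grp in mr_results.groupby(["target", "outcome"], sort=True):
        best_p = float(grp["p_adj"].min())
        disc_theta = float(grp.loc[grp["p_adj"].idxmin(), "theta"])
        cc = coloc_results[(coloc_results["target"] == target)
                           & (coloc_results["outcome"] == outcome)]
        best_pph4 = float(cc["pph4"].max()) if len(cc) else float("nan")

        if replicable_outcomes is not None and outcome not in replicable_outcomes:
            rep = "not_available"
        else:
            mm = meta_results[(meta_results["target"] == target)
                              & (meta_results["outcome"] == outcome)]
            rep = "no"
            for row in mm.itertuples():
                excludes_null = row.ci_low > 1.0 or row.ci_high < 1.0
                same_direction = np.sign(row.theta) == np.sign(disc_theta)
                if excludes_null and same_direction:
                    rep = "yes"
                    break
            if len(mm) == 0 and replicable_outcomes is None:
                rep = "not_available"
        records.append(EvidenceRecord(
            str(target), str(outcome),
            mr_class_from_padj(best_p, thresholds),
            coloc_class_from_pph4(best_pph4, thresholds),
            rep, best_pph4=best_pph4, best_p_adj=best_p))
    return records


def rank_targets(records: list[EvidenceRecord]) -> pd.DataFrame:
    """Score and rank evidence records per outcome.

    Descending score; ties broken by best PPH4 descending, then best adjusted
    p ascending, then target symbol.  NaN tie-break keys sort last.
    """
    rows = []
    for rec in records:
        sc = score_target(rec)
        rows.append({
            "outcome": rec.outcome, "target": rec.target, "score": sc.score,
            "mr_class": rec.mr_class, "coloc_class": rec.coloc_class,
            "replication": rec.replication_support,
            "best_pph4": rec.best_pph4, "best_p_adj": rec.best_p_adj,
            "mr_points": sc.components["mr"],
            "coloc_points": sc.components["coloc"],
            "replication_points": sc.components["replication"],
        })
    df = pd.DataFrame(rows, columns=[
        "outcome", "target", "score", "mr_class", "coloc_class", "replication",
        "best_pph4", "best_p_adj", "mr_points", "coloc_points",
        "replication_points"])
    if len(df) == 0:
        return df
    df["_pph4"] = df["best_pph4"].fillna(-1.0)
    df["_padj"] = df["best_p_adj"].fillna(2.0)
    df = df.sort_values(
        ["outcome", "score", "_pph4", "_padj", "target"],
        ascending=[True, False, False, True, True], kind="stable",
    ).drop(columns=["_pph4", "_padj"]).reset_index(drop=True)
    return df
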