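"""Clinical-feature binarization and pEMT/CAF score association testing.

Seven clinical features are split into worse/better-prognosis groups by fixed
rules (samples failing a rule stay unassigned).  Signature scores -- the same
control-binned scores used for single cells, with tumours in place of cells --
are compared between groups by a two-sided Wilcoxon rank-sum test, and
discoveries are controlled by Benjamini-Hochberg FDR either per feature or
globally.  M stage is accepted as input but excluded from default runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FEATURES = ("lymph_node_metastasis", "n_stage", "lymphovascular_invasion",
            "grade", "t_stage", "reduced_survival", "therapy_resistance")

#: column each feature reads (Firehose-like names can be mapped onto these)
FEATURE_COLUMNS = {
    "lymph_node_metastasis": "lymph_node_count",
    "n_stage": "n_stage",
    "lymphovascular_invasion": "lymphovascular_invasion",
    "grade": "grade",
    "t_stage": "t_stage",
    "reduced_survival": "days_to_death",
    "therapy_resistance": "followup_outcome",
    "m_stage": "m_stage",
}

_GRADE_WORSE = {"g3", "g4", "high grade"}
_GRADE_BETTER = {"g1", "g2", "gb", "borderline", "low grade"}
_LVI_WORSE = {"yes", "present", "true", "1"}
_LVI_BETTER = {"no", "absent", "false", "0"}
_OUTCOME_WORSE = {"recurred/progressed", "recurred", "progressive disease"}
_OUTCOME_BETTER = {"complete remission/response", "complete response"}


def _norm(value) -> str | None:
    if pd.isna(value):
        return None
    return str(value).strip().lower()


def binarize_feature(table: pd.DataFrame, feature: str,
                     column_map: dict[str, str] | None = None) -> pd.Series:
    """Assign samples to worse/better prognosis groups for one feature.

    Rules: lymph-node metastasis >= 2 nodes vs none (exactly 1 unassigned);
    N stage 2-3 vs 0-1; lymphovascular invasion present vs absent; grade 3-4
    or "high grade" vs borderline/1-2/"low grade"; T stage 3-4 vs 0-2; days to
    death below the 40th percentile vs above the 60th; recurrence vs complete
    remission/response after follow-up treatment.  Unknown vocabulary values
    are left unassigned and logged.
    """
    supported = FEATURES + ("m_stage",)
    if feature not in supported:
        raise ValueError(f"unsupported feature {feature!r}")
    column = FEATURE_COLUMNS[feature]
    if column_map:
        column = column_map.get(column, column)
    values = table[column]
    groups = pd.Series(pd.NA, index=table.index, dtype="object")

    if feature == "lymph_node_metastasis":
        counts = pd.to_numeric(values, errors="coerce")
        groups[counts >= 2] = "worse"
        groups[counts == 0] = "better"
    elif feature in ("n_stage", "t_stage", "m_stage"):
        prefix = feature[0]
        if feature == "t_stage":
            worse_digits, better_digits = {"3", "4"}, {"0", "1", "2"}
        elif feature == "n_stage":
            worse_digits, better_digits = {"2", "3"}, {"0", "1"}
        else:
            worse_digits, better_digits = {"1"}, {"0"}
        for idx, v in values.items():
            s = _norm(v)
            if s is None:
                continue
            digit = s.removeprefix(prefix)[:1]
            if digit in worse_digits:
                groups[idx] = "worse"
            elif digit in better_digits:
                groups[idx] = "better"
            else:
                logger.info("unrecognised %s value %r left unassigned", feature, v)
    elif feature == "lymphovascular_invasion":
        for idx, v in values.items():
            s = _norm(v)
            if s is None:
                continue
            if s in _LVI_WORSE:
                groups[idx] = "worse"
            elif s in _LVI_BETTER:
                groups[idx] = "better"
            else:
                logger.info("unrecognised lymphovascular value %r", v)
    elif feature == "grade":
        for idx, v in values.items():
            s = _norm(v)
            if s is None:
                continue
            if s in _GRADE_WORSE:
                groups[idx] = "worse"
            elif s in _GRADE_BETTER:
                groups[idx] = "better"
            else:
                logger.info("unrecognised grade value %r", v)
    elif feature == "reduced_survival":
        days = pd.to_numeric(values, errors="coerce")
        observed = days.dropna()
        if len(observed) == 0:
            return groups
        lo = np.percentile(observed, 40)
        hi = np.percentile(observed, 60)
        groups[days < lo] = "worse"
        groups[days > hi] = "better"
    elif feature == "therapy_resistance":
        for idx, v in values.items():
            s = _norm(v)
            if s is None:
                continue
            if s in _OUTCOME_WORSE:
                groups[idx] = "worse"
            elif s in _OUTCOME_BETTER:
                groups[idx] = "better"
    return groups


# ------------------------------------------------------------------ testing

@dataclass
class AssociationResult:
    feature: str
    signature: str
    n_worse: int
    n_better: int
    effect: float | None                 # worse minus better group mean score
    p_value: float | None
    skipped: bool
    skip_reason: str | None = None
    significant: bool | None = None


def rank_sum_test(x: np.ndarray, y: np.ndarray, exact_max_n: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the exact null distribution for small tie-free samples (so the
    p-value agrees with exhaustive enumeration) and the normal approximation
    with tie and continuity correction otherwise.
    """
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if not ties and len(x) + len(y) <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method, use_continuity=True).pvalue)


def associate(scores: pd.Series, groups: pd.Series, feature: str = "",
              signature: str = "", min_n: int = 10) -> AssociationResult:
    """Rank-sum comparison of signature scores between prognosis groups.

    Skipped when fewer than ``min_n`` samples are assigned to a group overall
    or when one group is empty.  Positive effect = higher score in the
    worse-prognosis group.
    """
    aligned = pd.DataFrame({"score": scores, "group": groups}).dropna()
    n_worse = int((aligned["group"] == "worse").sum())
    n_better = int((aligned["group"] == "better").sum())
    if n_worse + n_better < min_n:
        return AssociationResult(feature, signature, n_worse, n_better, None,
                                 None, True, f"fewer than {min_n} annotated samples")
    if n_worse == 0 or n_better == 0:
        return AssociationResult(feature, signature, n_worse, n_better, None,
                                 None, True, "one group empty")
    worse = aligned.loc[aligned["group"] == "worse", "score"].to_numpy()
    better = aligned.loc[aligned["group"] == "better", "score"].to_numpy()
    p = rank_sum_test(worse, better)
    return AssociationResult(feature, signature, n_worse, n_better,
                             float(worse.mean() - better.mean()), p, False)


def fdr_control(p_values: pd.Series, alpha: float = 0.05,
                scope_labels: pd.Series | None = None):
    """Benjamini-Hochberg step-up control within the chosen scope.

    ``scope_labels`` partitions the tests (e.g. per feature); None applies BH
    globally.  Returns boolean flags and the realised threshold per scope (the
    largest accepted p-value, 0 when nothing is accepted).
    """
    p_values = p_values.dropna()
    if p_values.empty:
        raise ValueError("no p-values to adjust")
    flags = pd.Series(False, index=p_values.index)
    thresholds: dict[str, float] = {}
    if scope_labels is None:
        scope_labels = pd.Series("all", index=p_values.index)
    for scope, idx in p_values.groupby(scope_labels.reindex(p_values.index)).groups.items():
        rejected = multipletests(p_values.loc[idx], alpha=alpha, method="fdr_bh")[0]
        flags.loc[idx] = rejected
        accepted = p_values.loc[idx][rejected]
        thresholds[scope] = float(accepted.max()) if rejected.any() else 0.0
    return flags, thresholds


def run_clinical_associations(pemt_scores: pd.Series, caf_scores: pd.Series,
                              clinical: pd.DataFrame, features=FEATURES,
                              min_n: int = 10, alpha: float = 0.05,
                              fdr_scope: str = "per_feature",
                              include_m_stage: bool = False) -> pd.DataFrame:
    """Test both signatures against every feature; BH-flag the results."""
    table = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    features = list(features) + (["m_stage"] if include_m_stage else [])
    rows = []
    for feature in features:
        groups = binarize_feature(table, feature)
        for name, scores in (("pEMT", pemt_scores), ("CAF", caf_scores)):
            res = associate(scores.reindex(table.index), groups,
                            feature=feature, signature=name, min_n=min_n)
            rows.append(res)
    out = pd.DataFrame([r.__dict__ for r in rows])
    tested = out["p_value"].notna()
    if tested.any():
        scope = out.loc[tested, "feature"] if fdr_scope == "per_feature" else None
        flags, _ = fdr_control(out.loc[tested, "p_value"], alpha=alpha,
                               scope_labels=scope)
        out.loc[tested, "significant"] = flags
    return out
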