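"""Stage-wise relative expression from qPCR Ct tables.

Implements the 2^-ddCt method with housekeeping-gene normalization:
dCt = Ct_target - Ct_reference per replicate, ddCt relative to a
calibrator stage on replicate-mean dCt, fold = 2^-ddCt (amplification
efficiency fixed at 2). The fold-scale standard deviation is propagated
from the replicate dCt spread by the delta method,
sd_fold = fold * ln(2) * sd(dCt). Stage-transition reports compare each
stage with its predecessor (Myc -> Pri -> Yfb -> Mfb) with two-sample
t-tests on replicate dCt and an omnibus one-way ANOVA per gene; no
multiple-testing correction is applied (the report states the number of
tests performed).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STAGES",
    "read_ct_table",
    "validate_ct_table",
    "fold_change_ddct",
    "one_way_anova",
    "stage_transition_report",
]

#: Developmental stages in life-cycle order: mycelia, primordia, young
#: and mature fruiting body.
STAGES: Tuple[str, ...] = ("Myc", "Pri", "Yfb", "Mfb")

_REQUIRED_COLUMNS = ("gene", "stage", "replicate", "ct")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct TSV with columns gene, stage, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    validate_ct_table(df)
    return df


def validate_ct_table(df: pd.DataFrame) -> None:
    missing = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    ct = df["ct"].to_numpy(dtype=float)
    if not ((ct > 0) & (ct < 45)).all():
        raise ValueError("Ct values must lie in (0, 45)")


def _delta_ct(df: pd.DataFrame, ref_gene: str) -> pd.DataFrame:
    """Per-replicate dCt = Ct_target - Ct_ref, matched on (stage, replicate)."""
    ref = df[df["gene"] == ref_gene]
    if ref.empty:
        raise ValueError(f"reference gene {ref_gene!r} absent from Ct table")
    target_stages = set(df.loc[df["gene"] != ref_gene, "stage"])
    missing = sorted(target_stages - set(ref["stage"]))
    if missing:
        raise ValueError(
            f"reference gene {ref_gene!r} not measured at stage(s): {missing}"
        )
    ref_ct = ref.set_index(["stage", "replicate"])["ct"]
    targets = df[df["gene"] != ref_gene].copy()
    idx = pd.MultiIndex.from_frame(targets[["stage", "replicate"]])
    matched = ref_ct.reindex(idx)
    if matched.isna().any():
        bad = sorted({s for (s, _), v in zip(idx, matched) if pd.isna(v)})
        raise ValueError(
            f"reference gene {ref_gene!r} missing replicates at stage(s): {bad}"
        )
    targets["dct"] = targets["ct"].to_numpy() - matched.to_numpy()
    return targets


def fold_change_ddct(
    table: pd.DataFrame, ref_gene: str, calibrator: str = "Myc"
) -> pd.DataFrame:
    """Relative expression 2^-ddCt per (gene, stage).

    Returns a frame with gene, stage, n, mean_dct, ddct, fold, sd and
    log2_fold. By construction the calibrator-stage fold (computed on
    replicate-mean Ct) equals exactly 1. Fold changes are invariant to
    any constant offset applied to all Ct values.
    """
    validate_ct_table(table)
    targets = _delta_ct(table, ref_gene)
    rows: List[dict] = []
    for gene, sub in targets.groupby("gene", sort=True):
        per_stage = sub.groupby("stage")["dct"].agg(["mean", "std", "count"])
        if calibrator not in per_stage.index:
            raise ValueError(
                f"gene {gene!r}: calibrator stage {calibrator!r} not measured"
            )
        cal_mean = per_stage.loc[calibrator, "mean"]
        for stage, row in per_stage.iterrows():
            ddct = row["mean"] - cal_mean
            fold = 2.0 ** (-ddct)
            sd_dct = row["std"]
            sd = fold * math.log(2.0) * sd_dct if row["count"] > 1 else float("nan")
            rows.append(
                {
                    "gene": gene,
                    "stage": stage,
                    "n": int(row["count"]),
                    "mean_dct": row["mean"],
                    "ddct": ddct,
                    "fold": fold,
                    "sd": sd,
                    "log2_fold": -ddct,
                }
            )
    out = pd.DataFrame(rows)
    order = {s: i for i, s in enumerate(STAGES)}
    out["_ord"] = out["stage"].map(lambda s: order.get(s, len(order)))
    out = out.sort_values(["gene", "_ord"]).drop(columns="_ord").reset_index(drop=True)
    return out


def one_way_anova(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Requires >= 2 groups with >= 2 values each. Degenerate inputs are
    defined explicitly: identical data everywhere (zero between- and
    within-group variance) gives F = 0, p = 1; zero within-group variance
    with real group differences gives F = inf, p = 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    k = len(arrays)
    ns = np.array([len(a) for a in arrays])
    n_tot = int(ns.sum())
    grand = float(np.concatenate(arrays).mean())
    means = np.array([a.mean() for a in arrays])
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_b, df_w = k - 1, n_tot - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return f, p


def _two_sample_p(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-variance two-sample t-test p; degenerate cases made explicit."""
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def stage_transition_report(
    table: pd.DataFrame,
    ref_gene: str,
    calibrator: str = "Myc",
    stage_order: Sequence[str] = STAGES,
) -> pd.DataFrame:
    """Per-gene fold change of each stage relative to the previous one.

    For every consecutive stage pair in ``stage_order`` the report gives
    the ratio fold(stage_k) / fold(stage_{k-1}), a two-sample t-test on
    the replicate dCt values of the two stages with significance stars
    (* p<0.05, ** p<0.01, ns otherwise), and the per-gene omnibus ANOVA
    across all measured stages. A stage missing for a gene yields a row
    flagged ``missing`` with no ratio. The ``n_tests`` column records how
    many tests were performed in the whole report (no multiplicity
    correction is applied).
    """
    folds = fold_change_ddct(table, ref_gene, calibrator)
    targets = _delta_ct(table, ref_gene)
    rows: List[dict] = []
    for gene, sub in targets.groupby("gene", sort=True):
        fold_of = folds[folds["gene"] == gene].set_index("stage")["fold"]
        dct_of = {s: g["dct"].to_numpy() for s, g in sub.groupby("stage")}
        measured = [s for s in stage_order if s in dct_of]
        if len(measured) >= 2 and all(len(dct_of[s]) >= 2 for s in measured):
            _, p_omni = one_way_anova([dct_of[s] for s in measured])
        else:
            p_omni = float("nan")
        for prev, cur in zip(stage_order, stage_order[1:]):
            if prev not in dct_of or cur not in dct_of:
                rows.append(
                    {
                        "gene": gene,
                        "transition": f"{cur}/{prev}",
                        "ratio": float("nan"),
                        "p_value": float("nan"),
                        "significance": "missing",
                        "anova_p": p_omni,
                    }
                )
                continue
            ratio = float(fold_of[cur] / fold_of[prev])
            p = _two_sample_p(dct_of[prev], dct_of[cur])
            rows.append(
                {
                    "gene": gene,
                    "transition": f"{cur}/{prev}",
                    "ratio": ratio,
                    "p_value": p,
                    "significance": _stars(p),
                    "anova_p": p_omni,
                }
            )
    out = pd.DataFrame(rows)
    out["n_tests"] = int(out["p_value"].notna().sum())
    return out
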