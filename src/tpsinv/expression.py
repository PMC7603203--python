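"""Relative gene-expression analysis by the Livak 2^-ddCt method.

Input is a hierarchical Ct table (gene x condition x biological replicate x
technical replicate; a missing Ct marks a non-detection).  Technical
replicates are averaged, each target gene is normalized against a reference
(endogenous control) gene per biological replicate, and expression relative
to a basal condition is expressed as 2^-ddCt where

    dCt  = Ct_target - Ct_reference          (per condition, per replicate)
    ddCt = dCt_condition - mean(dCt_basal)
    fold = 2^-ddCt

The per-condition summary fold is the geometric mean of replicate folds
(equivalently 2 to the minus mean ddCt), so the basal condition is exactly
1 by construction and the reference gene is exactly 1 everywhere.  Fold
changes are compared across conditions per gene by one-way ANOVA on the
ddCt (log2) scale with Tukey HSD post-hoc tests, and significance stars
follow the conventional thresholds (ns at p >= 0.05; * below 0.05;
** below 0.01; *** below 0.001).  Non-detections propagate: an absent
(gene, condition) is reported absent, never imputed.

Also included is the angular-transform ANOVA used for disease-severity
percentages: x -> arcsin(sqrt(x/100)) followed by one-way ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["gene", "condition", "bio_rep", "tech_rep", "ct"]


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check Ct-table structure: unique keys, positive Ct where present."""
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    keys = table[["gene", "condition", "bio_rep", "tech_rep"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (gene, condition, bio_rep, tech_rep) keys")
    present = table["ct"].dropna()
    if (present <= 0).any():
        raise ValueError("Ct values must be > 0 when present")
    return table


def aggregate_techreps(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (gene, condition, bio_rep) with a majority-absent rule.

    A cell is flagged absent when at least half of its technical replicates
    are non-detections; otherwise the arithmetic mean of the detected Ct
    values is reported.
    """
    validate_ct_table(table)

    def agg(group: pd.DataFrame) -> pd.Series:
        n = len(group)
        n_absent = int(group["ct"].isna().sum())
        absent = n_absent * 2 >= n
        ct = float("nan") if absent else float(group["ct"].mean())
        return pd.Series({"ct": ct, "absent": absent})

    out = (
        table.groupby(["gene", "condition", "bio_rep"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    out["absent"] = out["absent"].astype(bool)
    return out


def livak_fold(
    target_ct: Sequence[float],
    reference_ct: Sequence[float],
    target_ct_basal: Sequence[float],
    reference_ct_basal: Sequence[float],
) -> np.ndarray:
    """Per-replicate 2^-ddCt for one gene in one condition.

    ddCt subtracts the mean basal dCt from each replicate's dCt.
    """
    t, r = np.asarray(target_ct, float), np.asarray(reference_ct, float)
    tb, rb = np.asarray(target_ct_basal, float), np.asarray(reference_ct_basal, float)
    if t.shape != r.shape or tb.shape != rb.shape:
        raise ValueError("target and reference Ct vectors must align")
    dct = t - r
    dct_basal = float(np.mean(tb - rb))
    return np.power(2.0, -(dct - dct_basal))


def stars_for_p(p: Optional[float]) -> str:
    """Significance code: ns for p >= 0.05 (or undefined), up to *** below 0.001."""
    if p is None or not np.isfinite(p) or p >= 0.05:
        return "ns"
    if p >= 0.01:
        return "*"
    if p >= 0.001:
        return "**"
    return "***"


@dataclass
class FoldChangeResult:
    gene: str
    condition: str
    fold_mean: float  # 2^-(mean ddCt); NaN when absent
    fold_sd: float
    folds: tuple  # per biological replicate
    p_value: Optional[float]
    stars: str
    absent: bool
    flag: str = ""


def _ddct_frame(agg: pd.DataFrame, reference_gene: str, basal_condition: str) -> pd.DataFrame:
    """Per-replicate ddCt values for every (gene, condition)."""
    genes = sorted(agg["gene"].unique())
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    conditions = sorted(agg["condition"].unique())
    if basal_condition not in conditions:
        raise ValueError(f"basal condition {basal_condition!r} not in table")
    ref = agg[agg["gene"] == reference_gene].set_index(["condition", "bio_rep"])["ct"]
    rows = []
    for gene in genes:
        sub = agg[agg["gene"] == gene].set_index(["condition", "bio_rep"])
        dct = {}
        for (cond, rep), row in sub.iterrows():
            if (cond, rep) not in ref.index or math.isnan(ref.loc[(cond, rep)]):
                continue
            dct[(cond, rep)] = row["ct"] - ref.loc[(cond, rep)]
        basal_vals = [v for (c, _), v in dct.items() if c == basal_condition and not math.isnan(v)]
        basal_mean = float(np.mean(basal_vals)) if basal_vals else float("nan")
        for (cond, rep), v in dct.items():
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "bio_rep": rep,
                    "dct": v,
                    "ddct": v - basal_mean,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "condition", "bio_rep", "dct", "ddct"])


def relative_expression(
    table: pd.DataFrame,
    reference_gene: str,
    basal_condition: str,
    run_stats: bool = True,
) -> pd.DataFrame:
    """Full Livak pipeline: aggregation, 2^-ddCt, per-gene ANOVA + Tukey.

    Returns one row per (gene, condition) with fold_mean, fold_sd, the
    per-gene ANOVA p value, a per-condition star code from the Tukey
    comparison against the basal condition, and the absent flag.  Adding a
    constant to every Ct value in the table leaves all folds unchanged.
    """
    agg = aggregate_techreps(table)
    ddct = _ddct_frame(agg, reference_gene, basal_condition)
    results: list[FoldChangeResult] = []
    for gene in sorted(agg["gene"].unique()):
        sub = ddct[ddct["gene"] == gene]
        gene_stats = _gene_stats(sub, basal_condition) if run_stats else ({}, None, "")
        tukey_p, anova_p, flag = gene_stats
        for cond in sorted(agg[agg["gene"] == gene]["condition"].unique()):
            cell = agg[(agg["gene"] == gene) & (agg["condition"] == cond)]
            vals = sub[sub["condition"] == cond]["ddct"].dropna().to_numpy()
            absent = bool(cell["absent"].all()) or vals.size == 0
            if absent:
                results.append(
                    FoldChangeResult(gene, cond, float("nan"), float("nan"), (), None, "ns", True, flag)
                )
                continue
            folds = np.power(2.0, -vals)
            fold_mean = float(np.power(2.0, -np.mean(vals)))
            fold_sd = float(np.std(folds, ddof=1)) if folds.size > 1 else 0.0
            p = None if cond == basal_condition else tukey_p.get(cond, anova_p)
            results.append(
                FoldChangeResult(
                    gene, cond, fold_mean, fold_sd, tuple(folds), p, stars_for_p(p), False, flag
                )
            )
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "condition": r.condition,
                "fold_mean": r.fold_mean,
                "fold_sd": r.fold_sd,
                "p": r.p_value,
                "stars": r.stars,
                "absent": r.absent,
                "flag": r.flag,
            }
            for r in results
        ]
    )


def _gene_stats(sub: pd.DataFrame, basal_condition: str) -> tuple[dict, Optional[float], str]:
    """Per-gene ANOVA across conditions on ddCt plus Tukey p vs basal."""
    groups = {
        cond: g["ddct"].dropna().to_numpy()
        for cond, g in sub.groupby("condition")
        if g["ddct"].dropna().size > 0
    }
    usable = {c: v for c, v in groups.items() if v.size >= 2}
    if len(usable) < 2 or basal_condition not in usable:
        return {}, None, "insufficient replication"
    anova_p, flag = fold_stats_anova(list(usable.values()))
    tukey_p: dict[str, float] = {}
    if flag in ("degenerate", "zero within-group variance"):
        # noise-free data: a condition differs from basal iff its mean does
        basal_mean = float(np.mean(usable[basal_condition]))
        for cond, vals in usable.items():
            if cond != basal_condition:
                tukey_p[cond] = 1.0 if float(np.mean(vals)) == basal_mean else 0.0
    if flag == "":  # Tukey's studentized range needs within-group variance
        try:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            values = np.concatenate(list(usable.values()))
            labels = np.concatenate([[c] * v.size for c, v in usable.items()])
            res = pairwise_tukeyhsd(values, labels, alpha=0.05)
            frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
            for _, row in frame.iterrows():
                pair = {row["group1"], row["group2"]}
                if basal_condition in pair:
                    other = (pair - {basal_condition}).pop()
                    tukey_p[other] = float(row["p-adj"])
        except Exception:  # degenerate layouts: fall back to the ANOVA p
            tukey_p = {}
    return tukey_p, anova_p, flag


def fold_stats_anova(groups: Sequence[np.ndarray]) -> tuple[Optional[float], str]:
    """One-way ANOVA p across >= 2 groups of ddCt values.

    Zero within-group variance everywhere is degenerate: equal means give an
    undefined p reported as None with a flag; distinct means give p = 0.
    """
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        return None, "insufficient replication"
    within = sum(float(np.var(a)) for a in arrays)
    means = [float(np.mean(a)) for a in arrays]
    if within == 0.0:
        if max(means) == min(means):
            return None, "degenerate"
        return 0.0, "zero within-group variance"
    stat = stats.f_oneway(*arrays)
    return float(stat.pvalue), ""


def angular_transform(percentages: Iterable[float]) -> np.ndarray:
    """arcsin(sqrt(x/100)); domain [0, 100] maps onto [0, pi/2]."""
    x = np.asarray(list(percentages), float)
    if ((x < 0) | (x > 100)).any():
        raise ValueError("percentages must lie in [0, 100]")
    return np.arcsin(np.sqrt(x / 100.0))


def angular_anova(groups: Sequence[Sequence[float]]) -> float:
    """One-way ANOVA on angular-transformed percentage groups."""
    transformed = [angular_transform(g) for g in groups]
    if len(transformed) < 2:
        raise ValueError("need at least 2 groups")
    return float(stats.f_oneway(*transformed).pvalue)


def read_ct_csv(path) -> pd.DataFrame:
    """Read a Ct CSV (header gene,condition,bio_rep,tech_rep,ct; empty ct = absent)."""
    table = pd.read_csv(path, dtype={"gene": str, "condition": str})
    table["ct"] = pd.to_numeric(table["ct"], errors="coerce")
    return validate_ct_table(table)


def write_ct_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
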