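"""Delta-delta-Ct relative quantification with dual reference genes.

The Livak formulation with amplification efficiency assumed exactly 2:
technical Ct replicates are averaged per (sample, gene); per-sample
``dCt = mean Ct(target) - mean Ct(reference)``; per-condition
``ddCt = mean dCt(condition) - mean dCt(control)``; and
``fold = 2**(-ddCt)``.  Hypothesis tests run on the per-sample dCt values
through the same normality-gated layer as the imaging metrics.  A second
reference gene is used only to validate the normalization: the result is
flagged concordant when the primary and secondary log2 fold changes agree
within a configurable threshold, never averaged into the estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = [
    "FoldChangeResult",
    "validate_ct_table",
    "delta_ct",
    "ddct_fold_change",
    "relative_expression",
    "results_to_frame",
]

log = logging.getLogger("nucleovol")

CT_COLUMNS = ["sample", "condition", "gene", "replicate", "ct"]


@dataclass
class FoldChangeResult:
    """ddCt outcome for one target gene in one condition vs control."""

    target: str
    reference: str
    condition: str
    control: str
    delta_ct_condition: list[float]
    delta_ct_control: list[float]
    ddct: float
    fold_change: float
    p_value: float | None
    test_used: str | None
    secondary_reference: str | None = None
    secondary_fold_change: float | None = None
    concordant: bool | None = None


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the replicate-level Ct table contract.

    Requires columns ``sample, condition, gene, replicate, ct``; finite Ct
    in (0, 45]; and >= 2 technical replicates per (sample, gene).
    """
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    ct = table["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)):
        raise ValueError("non-finite Ct values in table")
    if np.any((ct <= 0) | (ct > 45)):
        bad = table.loc[(ct <= 0) | (ct > 45)]
        raise ValueError(
            f"Ct values outside (0, 45] for {bad[['sample', 'gene']].values.tolist()[:5]}"
        )
    counts = table.groupby(["sample", "gene"])["ct"].size()
    low = counts[counts < 2]
    if len(low):
        raise ValueError(
            f"fewer than 2 technical replicates for {list(low.index)[:5]}"
        )
    return table


def delta_ct(table: pd.DataFrame, target: str, reference: str) -> pd.DataFrame:
    """Per-sample dCt = replicate-mean Ct(target) - replicate-mean Ct(ref).

    Returns a frame with columns ``sample, condition, delta_ct`` in the
    table's sample order; a sample missing either gene raises, naming the
    sample and gene.
    """
    validate_ct_table(table)
    means = (
        table.groupby(["sample", "condition", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    rows = []
    for (sample, condition), sub in means.groupby(["sample", "condition"], sort=False):
        by_gene = dict(zip(sub["gene"], sub["ct"]))
        for gene in (target, reference):
            if gene not in by_gene:
                raise ValueError(f"sample {sample!r} is missing gene {gene!r}")
        rows.append((sample, condition, by_gene[target] - by_gene[reference]))
    return pd.DataFrame(rows, columns=["sample", "condition", "delta_ct"])


def ddct_fold_change(
    dcts: pd.DataFrame | dict[str, list[float]],
    control: str,
    target: str = "",
    reference: str = "",
    m: int = 1,
    method: str = "pooled",
) -> list[FoldChangeResult]:
    """Fold change 2^(-ddCt) for every non-control condition vs control.

    ``dcts`` is the output of :func:`delta_ct` (or a condition -> dCt-list
    mapping).  ``method="pooled"`` (default) computes ddCt from the pooled
    condition means; ``"per_sample"`` averages per-sample folds
    ``2**-(dct_i - mean dCt(control))`` instead.  The p-value comes from
    the normality-gated comparison of the two per-sample dCt samples;
    singleton conditions return the fold with a null p-value and a logged
    warning.
    """
    if isinstance(dcts, pd.DataFrame):
        groups = {
            cond: sub["delta_ct"].to_list()
            for cond, sub in dcts.groupby("condition", sort=False)
        }
    else:
        groups = {c: list(v) for c, v in dcts.items()}
    if control not in groups:
        raise ValueError(f"control condition {control!r} not present (have {sorted(groups)})")
    if method not in ("pooled", "per_sample"):
        raise ValueError("method must be 'pooled' or 'per_sample'")
    ctrl = np.asarray(groups[control], dtype=float)
    out: list[FoldChangeResult] = []
    for cond, vals in groups.items():
        if cond == control:
            continue
        arr = np.asarray(vals, dtype=float)
        ddct = float(arr.mean() - ctrl.mean())
        if method == "pooled":
            fold = 2.0 ** (-ddct)
        else:
            fold = float(np.mean(2.0 ** (-(arr - ctrl.mean()))))
        if arr.size >= 3 and ctrl.size >= 3:
            cmp = _stats.compare(
                ctrl, arr, m=m, metric=f"dCt({target or 'target'})",
                group_names=(control, cond),
            )
            p, used = cmp.p_adjusted, cmp.test_used
        else:
            log.warning(
                "condition %s or control has < 3 samples; fold reported without p-value",
                cond,
            )
            p, used = None, None
        out.append(
            FoldChangeResult(
                target=target,
                reference=reference,
                condition=cond,
                control=control,
                delta_ct_condition=[float(v) for v in arr],
                delta_ct_control=[float(v) for v in ctrl],
                ddct=ddct,
                fold_change=float(fold),
                p_value=p,
                test_used=used,
            )
        )
    return out


def relative_expression(
    table: pd.DataFrame,
    target: str,
    reference: str,
    control: str,
    secondary_reference: str | None = None,
    m: int = 1,
    method: str = "pooled",
    concordance_log2_tol: float = 0.5,
) -> list[FoldChangeResult]:
    """Full ddCt analysis of one target gene with optional dual-reference
    validation.

    When ``secondary_reference`` is given, the fold change is recomputed
    against it and each result is flagged ``concordant`` if
    ``|log2 fold_primary - log2 fold_secondary| <= concordance_log2_tol``.
    """
    dcts = delta_ct(table, target, reference)
    results = ddct_fold_change(
        dcts, control, target=target, reference=reference, m=m, method=method
    )
    if secondary_reference is not None:
        dcts2 = delta_ct(table, target, secondary_reference)
        secondary = {
            r.condition: r
            for r in ddct_fold_change(
                dcts2, control, target=target, reference=secondary_reference,
                m=m, method=method,
            )
        }
        for r in results:
            s = secondary[r.condition]
            r.secondary_reference = secondary_reference
            r.secondary_fold_change = s.fold_change
            r.concordant = (
                abs(math.log2(r.fold_change) - math.log2(s.fold_change))
                <= concordance_log2_tol
            )
    return results


def results_to_frame(results: list[FoldChangeResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "target": r.target,
                "reference": r.reference,
                "condition": r.condition,
                "control": r.control,
                "ddct": r.ddct,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "test_used": r.test_used,
                "secondary_reference": r.secondary_reference,
                "secondary_fold_change": r.secondary_fold_change,
                "concordant": r.concordant,
            }
        )
    return pd.DataFrame(rows)
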