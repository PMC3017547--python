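"""ddCt fold-change / fold-regulation analysis for PCR arrays.

fold_change = 2^-(dCt_test - dCt_reference); fold-regulation reports
down-changes as the negative reciprocal, so a fold change of 0.25 prints
as -4.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import CtTable, FoldRegulationTable

DEFAULT_ND_CEILING = 35.0


def delta_ct(ct_table: CtTable, group: str, ceiling: float = DEFAULT_ND_CEILING) -> pd.Series:
    """Per-gene dCt = mean Ct(gene) - mean Ct(housekeeping), within one group.

    Not-detected wells are imputed to ``ceiling`` cycles before averaging.
    Raises if every housekeeping well in the group is not-detected.
    """
    sub = ct_table.data[ct_table.data["group"] == group]
    if sub.empty:
        raise ValidationError(f"no Ct rows for group {group!r}")
    hk_rows = sub[sub["gene"].isin(ct_table.housekeeping_genes)]
    if hk_rows.empty or hk_rows["ct"].isna().all():
        raise ValidationError(f"all housekeeping wells not-detected in group {group!r}")

    imputed = sub.assign(ct=sub["ct"].fillna(ceiling))
    gene_means = imputed.groupby("gene")["ct"].mean()
    hk_mean = gene_means.loc[gene_means.index.isin(ct_table.housekeeping_genes)].mean()
    return gene_means - hk_mean


def fold_regulation(dct_test, dct_reference):
    """(fold_change, fold_regulation) from test and reference dCt.

    Accepts scalars or aligned pandas Series. fold_change = 2^-ddCt;
    fold_regulation = fold_change when >= 1, else -1/fold_change.
    """
    ddct = dct_test - dct_reference
    fold_change = 2.0 ** (-ddct)
    if isinstance(fold_change, pd.Series):
        fold_reg = fold_change.where(fold_change >= 1.0, -1.0 / fold_change)
    else:
        if not np.isfinite(ddct):
            raise ValidationError("ddCt must be finite")
        fold_reg = fold_change if fold_change >= 1.0 else -1.0 / fold_change
    return fold_change, fold_reg


def classify_direction(fold_reg: float, threshold: float) -> str:
    if fold_reg >= threshold:
        return "up"
    if fold_reg <= -threshold:
        return "down"
    return "unchanged"


def fold_regulation_table(
    ct_table: CtTable,
    test_group: str,
    reference_group: str,
    threshold: float = 4.0,
    ceiling: float = DEFAULT_ND_CEILING,
) -> FoldRegulationTable:
    """Full ddCt analysis between two groups for every shared gene."""
    if threshold < 1.0:
        raise ValidationError("classification threshold must be >= 1")
    dct_test = delta_ct(ct_table, test_group, ceiling=ceiling)
    dct_ref = delta_ct(ct_table, reference_group, ceiling=ceiling)
    shared = dct_test.index.intersection(dct_ref.index)
    fold_change, fold_reg = fold_regulation(dct_test.loc[shared], dct_ref.loc[shared])
    frame = pd.DataFrame(
        {
            "fold_change": fold_change,
            "fold_regulation": fold_reg,
            "direction": [classify_direction(v, threshold) for v in fold_reg],
        },
        index=shared.rename("gene"),
    )
    return FoldRegulationTable(
        frame=frame,
        test_group=test_group,
        reference_group=reference_group,
        threshold=threshold,
    )


def classify_scatter(table: FoldRegulationTable, threshold: float | None = None) -> pd.DataFrame:
    """Re-label directions at a (possibly different) threshold.

    Returns the gene table with a ``direction`` column; summary counts are
    available via ``FoldRegulationTable.counts`` after rebuilding, or from
    the returned frame directly.
    """
    thr = table.threshold if threshold is None else threshold
    if thr < 1.0:
        raise ValidationError("classification threshold must be >= 1")
    out = table.frame.copy()
    out["direction"] = [classify_direction(v, thr) for v in out["fold_regulation"]]
    return out
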