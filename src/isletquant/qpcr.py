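"""Relative qPCR expression by the ΔCt method with PPIB as internal standard.

Relative expression of a target gene is 2^-(ΔCt) with
ΔCt = Ct(target) - Ct(reference gene), assuming doubling per cycle.
Group fold-changes divide each sample's linear-scale expression by the
mean linear-scale expression of a reference group (e.g. fresh islets),
so the reference group's mean fold is exactly 1.  Averaging is done on
the linear scale, not on Ct.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "relative_expression",
    "expression_table",
    "fold_vs_reference_group",
]


def relative_expression(ct, reference_ct):
    """2^(reference_ct - ct), i.e. 2^-ΔCt.  Accepts scalars or arrays."""
    ct = np.asarray(ct, dtype=float)
    ref = np.asarray(reference_ct, dtype=float)
    if not (np.all(np.isfinite(ct)) and np.all(np.isfinite(ref))):
        raise ValueError("Ct values must be finite")
    if np.any(ct <= 0) or np.any(ref <= 0):
        raise ValueError("Ct values must be positive")
    out = np.power(2.0, ref - ct)
    return float(out) if out.ndim == 0 else out


def expression_table(records: pd.DataFrame) -> pd.DataFrame:
    """Add a linear-scale ``expression`` column (2^-ΔCt) to a Ct table.

    Expects long-format columns sample_id, group, gene, ct, reference_ct.
    """
    required = {"sample_id", "group", "gene", "ct", "reference_ct"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if records["reference_ct"].isna().any():
        raise ValueError("every sample needs a reference-gene Ct")
    out = records.copy()
    out["expression"] = relative_expression(
        out["ct"].to_numpy(), out["reference_ct"].to_numpy()
    )
    return out


def fold_vs_reference_group(
    expressions: pd.DataFrame,
    reference_group: str,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene fold-change of each sample relative to a reference group.

    Divides every sample's expression by the reference group's mean
    expression of the same gene (the convention "taking the average of the
    reference group as 1").  Invariant under global rescaling of the
    expressions.  Returns the table with a ``fold`` column added.
    """
    if "expression" not in expressions.columns:
        expressions = expression_table(expressions)
    df = expressions if genes is None else expressions[expressions["gene"].isin(genes)]
    df = df.copy()
    ref = df[df["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")
    ref_means = ref.groupby("gene")["expression"].mean()
    if (ref_means <= 0).any():
        raise ValueError("reference-group mean expression must be positive")
    df["fold"] = df["expression"] / df["gene"].map(ref_means)
    if df["fold"].isna().any():
        raise ValueError("some genes have no reference-group measurements")
    return df
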