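"""Relative qPCR quantification: 2^-dCt profiling and 2^-ddCt fold changes.

Implements the canonical Livak procedure with amplification efficiency
fixed at 2 and replicate aggregation on the Ct (cycle) scale: technical
replicate Cts are averaged arithmetically, dCt is the mean Ct of a gene
minus the mean Ct of the reference gene in the same sample, and for paired
designs ddCt subtracts the control condition's dCt, so
log2(fold_change) = -ddCt exactly.

Input is a long-format table with columns (sample, condition, gene,
replicate, ct); ``sample`` and ``condition`` may coincide for pooled
technical-replicate designs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["CtDataError", "delta_ct", "delta_delta_ct"]

REQUIRED_COLUMNS = ("sample", "gene", "ct")


class CtDataError(ValueError):
    """The Ct table violates the layout the analysis requires."""


def _mean_ct(table: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise CtDataError(f"Ct table lacks required column {col!r}")
    if not np.isfinite(table["ct"].to_numpy(dtype=float)).all():
        raise CtDataError("Ct table contains non-finite ct values")
    keys = ["sample", "gene"]
    if "condition" in table.columns:
        keys = ["sample", "condition", "gene"]
    return table.groupby(keys, sort=False)["ct"].mean().reset_index(name="mean_ct")


def delta_ct(table: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Per (sample, gene): mean Ct, dCt versus the reference gene and
    relative expression 2^-dCt."""
    means = _mean_ct(table)
    out = []
    for sample, sub in means.groupby("sample", sort=False):
        ref = sub[sub["gene"] == reference_gene]
        if ref.empty:
            raise CtDataError(
                f"reference gene {reference_gene!r} missing from sample {sample!r}")
        ref_ct = float(ref["mean_ct"].iloc[0])
        genes = sub[sub["gene"] != reference_gene].copy()
        genes["delta_ct"] = genes["mean_ct"] - ref_ct
        genes["rel_expr"] = 2.0 ** (-genes["delta_ct"])
        out.append(genes)
    return pd.concat(out, ignore_index=True)


def delta_delta_ct(
    table: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
) -> pd.DataFrame:
    """Per (condition, gene): ddCt versus the control condition and fold
    change 2^-ddCt (control fold change is identically 1).

    With several samples per condition, per-sample dCt values are averaged
    within the condition before differencing.
    """
    if "condition" not in table.columns:
        raise CtDataError("Ct table lacks required column 'condition'")
    d = delta_ct(table, reference_gene)
    cond_of_sample = table.drop_duplicates("sample").set_index("sample")["condition"]
    d["condition"] = d["sample"].map(cond_of_sample)
    per_cond = d.groupby(["condition", "gene"], sort=False)["delta_ct"].mean().reset_index()
    ctrl = per_cond[per_cond["condition"] == control_condition]
    if ctrl.empty:
        raise CtDataError(f"control condition {control_condition!r} not present")
    ctrl_map = ctrl.set_index("gene")["delta_ct"]
    missing = set(per_cond["gene"]) - set(ctrl_map.index)
    if missing:
        raise CtDataError(
            f"control condition lacks genes required for pairing: {sorted(missing)}")
    per_cond["delta_delta_ct"] = per_cond["delta_ct"] - per_cond["gene"].map(ctrl_map)
    per_cond["fold_change"] = 2.0 ** (-per_cond["delta_delta_ct"])
    return per_cond
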