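"""Expression-presence calls, tissue specificity and RT-qPCR quantification.

Works on a gene × tissue matrix of non-negative expression values (unit
agnostic: TPM, FPKM or counts) and on Ct tables with a reference gene
(β-actin in the validation design: three biological replicates, each with
five technical replicates).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "expressed_anywhere",
    "tissue_specificity_tau",
    "delta_ct",
    "summarize_ct",
]

# smallest positive float: "max >= tiny" reads as "expressed anywhere at all"
_ANY_POSITIVE = float(np.finfo(float).tiny)


def expressed_anywhere(row: Sequence[float], threshold: float = _ANY_POSITIVE) -> bool:
    """True iff the gene reaches ``threshold`` in at least one tissue.

    The default threshold is the smallest positive float, i.e. any strictly
    positive expression value counts as "transcribed". Summary counts of
    expressed genes depend on this choice; pass an explicit threshold for
    anything stricter.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    values = np.asarray(row, dtype=float)
    if values.size == 0:
        raise ValueError("empty expression row")
    if np.any(values < 0):
        raise ValueError("expression values must be non-negative")
    return bool(values.max() >= threshold)


def tissue_specificity_tau(row: Sequence[float]) -> float:
    """Tissue-specificity index tau = sum_i (1 - x_i/x_max) / (n - 1).

    0 for perfectly uniform expression, 1 for single-tissue expression;
    invariant to positive rescaling of the row. Undefined (error) for an
    all-zero row.
    """
    values = np.asarray(row, dtype=float)
    if values.size < 2:
        raise ValueError("tau needs >= 2 tissues")
    if np.any(values < 0):
        raise ValueError("expression values must be non-negative")
    x_max = values.max()
    if x_max == 0:
        raise ValueError("tau undefined for an all-zero row")
    return float(np.sum(1.0 - values / x_max) / (values.size - 1))


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """Relative abundance by the 2^-dCt method: 2 ** -(Ct_target - Ct_ref)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** -(ct_target - ct_reference))


def summarize_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(gene, tissue) 2^-dCt summary over replicates.

    ``table`` needs columns gene, tissue, ct_target, ct_reference and
    optionally biological_replicate. Each measurement is converted to
    2^-dCt; the mean is taken over technical replicates within each
    biological replicate, then over biological replicates; the SD is over
    all individual measurements.
    """
    required = {"gene", "tissue", "ct_target", "ct_reference"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    df = table.copy()
    df["abundance"] = 2.0 ** -(df["ct_target"] - df["ct_reference"])
    if "biological_replicate" in df.columns:
        biorep_means = (
            df.groupby(["gene", "tissue", "biological_replicate"])["abundance"]
            .mean()
            .groupby(["gene", "tissue"])
            .mean()
        )
    else:
        biorep_means = df.groupby(["gene", "tissue"])["abundance"].mean()
    sd = df.groupby(["gene", "tissue"])["abundance"].std(ddof=1)
    n = df.groupby(["gene", "tissue"])["abundance"].size()
    out = pd.DataFrame({"mean": biorep_means, "sd": sd, "n": n}).reset_index()
    return out
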