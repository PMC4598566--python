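"""Shared statistical utilities and the interaction-screen hit filter.

The luminescence-based interactome (LUMIER) screen scores each bait-prey
pair with a luminescence intensity ratio (LIR) in two biological replicates;
an interaction is called a hit when the LIR reaches the threshold (default
3) in *both* replicates, boundary inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .imgio import ParameterError, warn

__all__ = ["LumierTable", "filter_lumier_hits", "sem", "welch_t_test"]


@dataclass
class LumierTable:
    """Rows of (prey, lir_rep1, lir_rep2); LIR values finite and >= 0."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"prey", "lir_rep1", "lir_rep2"}
        missing = required - set(self.data.columns)
        if missing:
            raise ParameterError(f"LumierTable missing columns {sorted(missing)}")
        vals = self.data[["lir_rep1", "lir_rep2"]].to_numpy(float)
        finite = np.isfinite(vals)
        if (vals[finite] < 0).any():
            raise ParameterError("LIR values must be >= 0")

    def __len__(self) -> int:
        return len(self.data)


def filter_lumier_hits(table: LumierTable, threshold: float = 3.0) -> list[str]:
    """Preys whose LIR reaches ``threshold`` in both replicates (inclusive).

    Row order is preserved; rows with a NaN LIR are rejected with a warning.
    """
    hits: list[str] = []
    for _, row in table.data.iterrows():
        a, b = float(row["lir_rep1"]), float(row["lir_rep2"])
        if np.isnan(a) or np.isnan(b):
            warn(f"prey {row['prey']!r} has NaN LIR; rejected")
            continue
        if a >= threshold and b >= threshold:
            hits.append(str(row["prey"]))
    return hits


def sem(values) -> float:
    """Standard error of the mean, sample sd / sqrt(n); NaN (with a warning)
    for fewer than two values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        warn("s.e.m. undefined for fewer than two values")
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def welch_t_test(a, b) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test.

    Returns ``(t, p)`` with Welch-Satterthwaite degrees of freedom; NaNs with
    a warning when either group has fewer than two values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        warn("Welch t-test needs >= 2 values per group")
        return float("nan"), float("nan")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
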