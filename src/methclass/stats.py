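"""Outcome-association statistics.

The clinical question is whether postsurgical seizure freedom differs
between tumor groups; that is a 2x2 chi-square test (optionally with
Yates continuity correction) on group membership versus seizure-free
status.  Samples with missing outcome are excluded from the table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Chi-square test of independence on a 2x2 contingency table.

    ``statistic = n * (|ad - bc| - correction)^2 /
    ((a+b)(c+d)(a+c)(b+d))`` with ``correction = n/2`` under Yates
    (clamped at zero), and the p-value from chi-square with 1 df.
    All four marginals must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    a, b, c, d = t.ravel()
    n = a + b + c + d
    margins = np.array([a + b, c + d, a + c, b + d])
    if (margins == 0).any():
        raise ValueError("all row and column marginals must be positive")
    correction = n / 2.0 if yates else 0.0
    num = max(abs(a * d - b * c) - correction, 0.0)
    stat = n * num**2 / margins.prod()
    return float(stat), float(chi2.sf(stat, df=1))


def outcome_table(
    sheet: pd.DataFrame, in_group: pd.Series | np.ndarray
) -> np.ndarray:
    """Build the 2x2 (group x seizure-free) table from a sample sheet.

    Rows: in-group / out-group; columns: seizure-free yes / no.
    Reference samples and samples with missing outcome are excluded.
    """
    mask = np.asarray(in_group, dtype=bool)
    if mask.shape[0] != len(sheet):
        raise ValueError("in_group mask length does not match the sample sheet")
    usable = (~sheet["is_reference"].astype(bool)) & sheet["seizure_free"].notna()
    sf = sheet["seizure_free"].astype("boolean").fillna(False).to_numpy(dtype=bool)
    u = usable.to_numpy()
    a = int((u & mask & sf).sum())
    b = int((u & mask & ~sf).sum())
    c = int((u & ~mask & sf).sum())
    d = int((u & ~mask & ~sf).sum())
    return np.array([[a, b], [c, d]])
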