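"""Feature reproducibility across repeated segmentations: ICC filtering.

The reliability index is ICC(2,1) — two-way random effects, absolute
agreement, single measurement — the usual choice for radiomics test-retest
work. A feature survives only if BOTH its intra-observer ICC (one reader's
two sessions) and inter-observer ICC (both readers' first sessions) exceed
the threshold (strictly), 0.75 by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def icc(measurements: np.ndarray) -> float:
    """ICC(2,1) from the two-way ANOVA mean-squares decomposition.

    ``measurements`` is patients (rows) x occasions (columns), at least 3x2.
    A matrix with zero total variance (all cells equal) has ICC 1 by
    convention: perfect agreement on a constant.
    """
    m = np.asarray(measurements, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("need at least 3 patients x 2 occasions")
    if not np.all(np.isfinite(m)):
        raise ValueError("measurements must be finite")

    n, k = m.shape
    if np.allclose(m, m.flat[0], rtol=0.0, atol=0.0):
        return 1.0

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)

    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return 1.0
    return float((msr - mse) / denom)


def build_reliability_stacks(
    tables: dict[tuple[int, int], pd.DataFrame],
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Assemble intra- and inter-observer stacks from per-(reader, session)
    feature tables (rows = patients, identical columns).

    Intra: reader 0, sessions 0 and 1. Inter: readers 0 and 1, session 0.
    Returns two dicts feature name -> patients x 2 matrix.
    """
    required = [(0, 0), (0, 1), (1, 0)]
    for key in required:
        if key not in tables:
            raise KeyError(f"missing (reader, session) table {key}")
    t00, t01, t10 = (tables[k] for k in required)
    intra = {c: np.column_stack([t00[c], t01[c]]) for c in t00.columns if c != "label"}
    inter = {c: np.column_stack([t00[c], t10[c]]) for c in t00.columns if c != "label"}
    return intra, inter


def filter_by_icc(
    intra_stacks: dict[str, np.ndarray],
    inter_stacks: dict[str, np.ndarray],
    threshold: float = 0.75,
) -> list[str]:
    """Names of features whose intra- AND inter-observer ICC both exceed
    ``threshold`` (strict inequality), in input order."""
    kept = []
    for name, intra in intra_stacks.items():
        if name not in inter_stacks:
            warnings.warn(f"feature {name!r} lacks an inter-observer stack; excluded")
            continue
        if icc(intra) > threshold and icc(inter_stacks[name]) > threshold:
            kept.append(name)
    return kept


def icc_report(
    intra_stacks: dict[str, np.ndarray],
    inter_stacks: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-feature intra/inter ICC values (for reporting)."""
    rows = {
        name: {"icc_intra": icc(intra_stacks[name]), "icc_inter": icc(inter_stacks[name])}
        for name in intra_stacks
        if name in inter_stacks
    }
    return pd.DataFrame(rows).T
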