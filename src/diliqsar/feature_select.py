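"""Unsupervised descriptor filtering: near-constant and correlation passes.

Two filters only, applied in order:

* a feature whose modal value occurs in strictly more than 95% of compounds
  carries essentially no information and is removed;
* for every remaining pair with |Pearson r| strictly above 0.95, the
  later feature in the canonical column order is dropped (a greedy scan, so
  the earliest member of a correlated clique is the one kept).

Both passes are deterministic and idempotent; anti-correlated features are
treated as redundant too (|r|).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .descriptors import DescriptorMatrix


@dataclass
class FeatureSelectionReport:
    removed_near_constant: list[str] = field(default_factory=list)
    removed_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def remove_near_constant(
    matrix: DescriptorMatrix, threshold: float = 0.95
) -> tuple[DescriptorMatrix, FeatureSelectionReport]:
    """Drop features whose modal-value frequency exceeds ``threshold``.

    The boundary is strict: modal frequency exactly at the threshold is
    retained.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    df = matrix.values
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("empty descriptor matrix")
    n = df.shape[0]
    removed, retained = [], []
    for col in df.columns:
        modal_freq = df[col].value_counts().iloc[0] / n
        (removed if modal_freq > threshold else retained).append(col)
    report = FeatureSelectionReport(
        removed_near_constant=removed, retained=retained
    )
    return matrix.subset_features(retained), report


def remove_correlated(
    matrix: DescriptorMatrix, cutoff: float = 0.95
) -> tuple[DescriptorMatrix, FeatureSelectionReport]:
    """Greedy correlation filter in canonical column order.

    Scans pairs (i, j), i < j, in column order; whenever |Pearson r| of a
    surviving pair exceeds ``cutoff`` (strictly), the later column j is
    dropped and attributed to its earliest kept partner.  Zero-variance
    columns are an error here — the near-constant pass must run first.
    """
    df = matrix.values
    if df.shape[1] < 2:
        raise ValueError("correlation filter needs at least 2 features")
    values = df.to_numpy(dtype=float)
    stds = values.std(axis=0)
    zero_var = [c for c, s in zip(df.columns, stds) if s == 0.0]
    if zero_var:
        raise ValueError(
            f"zero-variance features reached the correlation filter: {zero_var}"
        )
    corr = np.corrcoef(values, rowvar=False)
    cols = list(df.columns)
    dropped: dict[int, tuple[int, float]] = {}
    for i in range(len(cols)):
        if i in dropped:
            continue
        for j in range(i + 1, len(cols)):
            if j in dropped:
                continue
            r = corr[i, j]
            if abs(r) > cutoff:
                dropped[j] = (i, float(r))
    retained = [c for k, c in enumerate(cols) if k not in dropped]
    report = FeatureSelectionReport(
        removed_correlated=[
            (cols[j], cols[i], r) for j, (i, r) in sorted(dropped.items())
        ],
        retained=retained,
    )
    return matrix.subset_features(retained), report


def select_features(
    matrix: DescriptorMatrix,
    near_constant_threshold: float = 0.95,
    correlation_cutoff: float = 0.95,
) -> tuple[DescriptorMatrix, FeatureSelectionReport]:
    """Run both filters in order and merge their reports."""
    m1, rep1 = remove_near_constant(matrix, near_constant_threshold)
    m2, rep2 = remove_correlated(m1, correlation_cutoff)
    report = FeatureSelectionReport(
        removed_near_constant=rep1.removed_near_constant,
        removed_correlated=rep2.removed_correlated,
        retained=rep2.retained,
    )
    return m2, report
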