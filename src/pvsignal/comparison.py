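"""Overlap analysis between two binary signal matrices.

Compares significant-signal sets derived from two report sources (e.g. a
clinical-trial-derived table vs a spontaneous-reporting one) on their
common drug x SOC grid: Jaccard similarity over significant cells, and a
four-way per-cell categorisation (shared / only-A / only-B / neither).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signals import SignalLabelMatrix

__all__ = ["OverlapSummary", "jaccard", "overlap_categories"]


def _common_grid(a: SignalLabelMatrix, b: SignalLabelMatrix):
    drugs = sorted(set(a.drug_ids) & set(b.drug_ids))
    socs = sorted(set(a.socs) & set(b.socs))
    if not drugs or not socs:
        raise ValueError("signal matrices share no common drug x SOC grid")
    dropped = {
        "drugs_only_a": sorted(set(a.drug_ids) - set(drugs)),
        "drugs_only_b": sorted(set(b.drug_ids) - set(drugs)),
        "socs_only_a": sorted(set(a.socs) - set(socs)),
        "socs_only_b": sorted(set(b.socs) - set(socs)),
    }
    return a.submatrix(drugs, socs), b.submatrix(drugs, socs), dropped


def jaccard(a: SignalLabelMatrix, b: SignalLabelMatrix) -> float:
    """|A n B| / |A u B| over significant cells of the common grid.

    Both-empty significant sets are defined as 0 with a warning.
    """
    sub_a, sub_b, _ = _common_grid(a, b)
    set_a, set_b = sub_a.significant_set(), sub_b.significant_set()
    union = len(set_a | set_b)
    if union == 0:
        warnings.warn("both signal sets are empty; Jaccard defined as 0")
        return 0.0
    return len(set_a & set_b) / union


@dataclass
class OverlapSummary:
    """Four-way cell categorisation and Jaccard over a common grid."""

    n_shared: int
    n_only_a: int
    n_only_b: int
    n_neither: int
    jaccard: float
    frame: pd.DataFrame = field(repr=False)
    dropped: dict = field(default_factory=dict, repr=False)

    @property
    def grid_size(self) -> int:
        return self.n_shared + self.n_only_a + self.n_only_b + self.n_neither

    @property
    def percentages(self) -> dict[str, float]:
        n = self.grid_size
        return {
            "shared": 100.0 * self.n_shared / n,
            "only_a": 100.0 * self.n_only_a / n,
            "only_b": 100.0 * self.n_only_b / n,
            "neither": 100.0 * self.n_neither / n,
        }

    def to_dict(self) -> dict:
        return {
            "n_shared": self.n_shared,
            "n_only_a": self.n_only_a,
            "n_only_b": self.n_only_b,
            "n_neither": self.n_neither,
            "grid_size": self.grid_size,
            "percentages": self.percentages,
            "jaccard": self.jaccard,
            "dropped": self.dropped,
        }


def overlap_categories(a: SignalLabelMatrix, b: SignalLabelMatrix) -> OverlapSummary:
    """Assign every common cell to shared / only_a / only_b / neither.

    Percentages use the full common grid as denominator (most cells are
    insignificant in both sources); the Jaccard index uses significant
    cells only, consistent with :func:`jaccard`.
    """
    sub_a, sub_b, dropped = _common_grid(a, b)
    la, lb = sub_a.labels.astype(bool), sub_b.labels.astype(bool)
    shared = la & lb
    only_a = la & ~lb
    only_b = ~la & lb
    neither = ~la & ~lb
    category = np.where(
        shared, "shared", np.where(only_a, "only_a", np.where(only_b, "only_b", "neither"))
    )
    frame = pd.DataFrame(
        {
            "drug_id": np.repeat(sub_a.drug_ids, len(sub_a.socs)),
            "soc": np.tile(sub_a.socs, len(sub_a.drug_ids)),
            "label_a": la.ravel().astype(int),
            "label_b": lb.ravel().astype(int),
            "category": category.ravel(),
        }
    )
    n_shared, n_only_a, n_only_b = int(shared.sum()), int(only_a.sum()), int(only_b.sum())
    denom = n_shared + n_only_a + n_only_b
    if denom == 0:
        warnings.warn("both signal sets are empty; Jaccard defined as 0")
    jac = n_shared / denom if denom else 0.0
    return OverlapSummary(
        n_shared=n_shared,
        n_only_a=n_only_a,
        n_only_b=n_only_b,
        n_neither=int(neither.sum()),
        jaccard=jac,
        frame=frame,
        dropped=dropped,
    )
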