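"""Drug-target interaction matrices: the model feature space.

Interaction evidence arrives as a long-format TSV of ``(drug_id, target_id,
score)`` rows with confidence scores in [0, 1] (STITCH-style). Pairs absent
from the file, or present with an empty score field, carry no supporting
evidence and are conservatively treated as score 0. Scores below a
confidence threshold (default 0.4, the boundary between low and medium
confidence) are zeroed before modelling.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "InteractionMatrix",
    "load_interactions",
    "write_interactions",
    "filter_confidence",
    "align_drugs",
    "normalize_drug_id",
]

_WS = re.compile(r"\s+")


def normalize_drug_id(drug_id: str) -> str:
    """Case-fold, trim, and collapse internal whitespace of a drug identifier."""
    return _WS.sub(" ", str(drug_id).strip()).casefold()


@dataclass
class InteractionMatrix:
    """Dense drugs x targets matrix of interaction confidence scores in [0, 1].

    Rows are drugs, columns are targets; a stored 0 means "no evidence".
    """

    drug_ids: list[str]
    target_ids: list[str]
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.drug_ids = [str(d) for d in self.drug_ids]
        self.target_ids = [str(t) for t in self.target_ids]
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug ids in InteractionMatrix")
        if len(set(self.target_ids)) != len(self.target_ids):
            raise ValueError("duplicate target ids in InteractionMatrix")
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ValueError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.target_ids)} targets"
            )
        if self.scores.size and not np.all(np.isfinite(self.scores)):
            raise ValueError("interaction scores must be finite")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("interaction scores must lie in [0, 1]")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    def score(self, drug_id: str, target_id: str) -> float:
        """Score of one (drug, target) pair; raises KeyError on unknown ids."""
        i = self.drug_ids.index(drug_id) if drug_id in self.drug_ids else -1
        j = self.target_ids.index(target_id) if target_id in self.target_ids else -1
        if i < 0:
            raise KeyError(f"unknown drug id: {drug_id!r}")
        if j < 0:
            raise KeyError(f"unknown target id: {target_id!r}")
        return float(self.scores[i, j])

    def to_frame(self, include_zeros: bool = True) -> pd.DataFrame:
        """Long-format view with columns drug_id, target_id, score."""
        frame = pd.DataFrame(
            {
                "drug_id": np.repeat(self.drug_ids, self.n_targets),
                "target_id": np.tile(self.target_ids, self.n_drugs),
                "score": self.scores.ravel(),
            }
        )
        if not include_zeros:
            frame = frame[frame["score"] > 0].reset_index(drop=True)
        return frame

    def nonzero_count(self) -> int:
        return int(np.count_nonzero(self.scores))


def load_interactions(path: str | Path) -> InteractionMatrix:
    """Read a drug-target interaction TSV into an :class:`InteractionMatrix`.

    The file must be tab-delimited with a header row containing at least
    ``drug_id``, ``target_id`` and ``score``. Empty score fields become 0
    (no supporting evidence). Duplicate (drug, target) rows are resolved by
    keeping the maximum score. Scores outside [0, 1] or unparseable values
    raise ``ValueError`` naming the offending data row (1-based).
    """
    frame = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "target_id": str})
    required = {"drug_id", "target_id", "score"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    raw = frame["score"]
    parsed = pd.to_numeric(raw, errors="coerce")
    bad_parse = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad_parse.any():
        row = int(bad_parse.idxmax()) + 1
        raise ValueError(f"{path}: unparseable score at data row {row}")
    parsed = parsed.fillna(0.0)  # missing evidence -> 0
    out_of_range = (parsed < 0) | (parsed > 1)
    if out_of_range.any():
        row = int(out_of_range.idxmax()) + 1
        raise ValueError(
            f"{path}: score {parsed[out_of_range.idxmax()]} outside [0, 1] "
            f"at data row {row}"
        )
    frame = frame.assign(score=parsed)
    # duplicate rows: keep the maximum score
    agg = frame.groupby(["drug_id", "target_id"], sort=True)["score"].max()
    wide = agg.unstack(fill_value=0.0)
    return InteractionMatrix(
        drug_ids=list(wide.index),
        target_ids=list(wide.columns),
        scores=wide.to_numpy(dtype=float),
    )


def write_interactions(matrix: InteractionMatrix, path: str | Path) -> Path:
    """Write the full grid (zeros included, so dimensions round-trip) as TSV."""
    path = Path(path)
    matrix.to_frame(include_zeros=True).to_csv(path, sep="\t", index=False)
    return path


def filter_confidence(
    matrix: InteractionMatrix, threshold: float = 0.4
) -> InteractionMatrix:
    """Zero out scores below the confidence threshold.

    Scores >= ``threshold`` are retained unchanged; scores < ``threshold``
    become 0 (low confidence treated as no evidence). Dimensions are
    unchanged. Idempotent, and never increases any score.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    scores = np.where(matrix.scores >= threshold, matrix.scores, 0.0)
    return InteractionMatrix(
        drug_ids=list(matrix.drug_ids),
        target_ids=list(matrix.target_ids),
        scores=scores,
    )


def align_drugs(matrix: InteractionMatrix, reports, normalizer=normalize_drug_id):
    """Restrict interactions and report counts to their shared drugs.

    Drug identifiers are matched exactly after normalization (case-fold,
    trim, collapse internal whitespace); fuzzy merging is deliberately not
    attempted. Returns ``(matrix, reports, report_dict)`` where the first two
    are restricted to the intersection (with normalized ids) and the report
    lists kept ids and the ids dropped from each side.

    Raises ``ValueError`` if the intersection is empty — there is nothing to
    model.
    """
    from .signals import ReportCountTable  # local import to avoid a cycle

    int_map: dict[str, list[str]] = {}
    for d in matrix.drug_ids:
        int_map.setdefault(normalizer(d), []).append(d)
    rep_map: dict[str, list[str]] = {}
    for d in reports.drugs:
        rep_map.setdefault(normalizer(d), []).append(d)

    kept = sorted(set(int_map) & set(rep_map))
    if not kept:
        raise ValueError("no drugs shared between interactions and reports")
    dropped_int = sorted(
        orig for key, origs in int_map.items() if key not in rep_map for orig in origs
    )
    dropped_rep = sorted(
        orig for key, origs in rep_map.items() if key not in int_map for orig in origs
    )

    # interactions: collapse same-normalization rows by elementwise max
    rows = np.zeros((len(kept), matrix.n_targets))
    index = {d: i for i, d in enumerate(matrix.drug_ids)}
    for i, key in enumerate(kept):
        members = [index[d] for d in int_map[key]]
        rows[i] = matrix.scores[members].max(axis=0)
    aligned_matrix = InteractionMatrix(
        drug_ids=kept, target_ids=list(matrix.target_ids), scores=rows
    )

    frame = reports.frame.copy()
    frame["drug_id"] = frame["drug_id"].map(normalizer)
    frame = frame[frame["drug_id"].isin(kept)]
    aligned_reports = ReportCountTable(frame, excluded_socs=reports.excluded_socs)

    report = {
        "kept": kept,
        "dropped_interactions": dropped_int,
        "dropped_reports": dropped_rep,
    }
    return aligned_matrix, aligned_reports, report
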