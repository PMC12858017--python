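"""Model interpretation and external validation of influential targets.

The interpretability loop: rank targets by their contribution to a fitted
per-SOC classifier, cross-reference the top-ranked targets against a
target-disease association table (DisGeNET-style), map free-text disease
terms onto the SOC vocabulary with fuzzy string matching, and finally
relate the influential targets back to the drugs that engage them and to
the drugs' ATC classification.

Two importance modes are offered. ``global`` is the standard normalized
mean-decrease-in-impurity. ``positive`` restricts the impurity-decrease
accumulation to the decision paths actually traversed by rows the model
predicts positive, isolating the targets that drive significant-signal
predictions specifically.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactions import InteractionMatrix

__all__ = [
    "ImportanceTable",
    "SocMatchSummary",
    "AlignmentReport",
    "feature_importance",
    "top_k",
    "similarity_ratio",
    "match_associations",
    "soc_alignment",
    "drug_target_relations",
    "atc_enrichment",
]


# ---------------------------------------------------------------------------
# feature importance


@dataclass
class ImportanceTable:
    """Ranked target importances; rows ordered rank 1..n."""

    frame: pd.DataFrame = field(repr=False)  # target_id, importance, rank
    mode: str = "global"

    def __post_init__(self):
        required = {"target_id", "importance", "rank"}
        if required - set(self.frame.columns):
            raise ValueError("importance frame needs target_id, importance, rank")

    @property
    def targets(self) -> list[str]:
        return list(self.frame["target_id"])

    def __len__(self) -> int:
        return len(self.frame)


def _rank_frame(target_ids, importances) -> pd.DataFrame:
    frame = pd.DataFrame({"target_id": target_ids, "importance": importances})
    # ties broken deterministically: higher importance first, then id
    frame = frame.sort_values(
        ["importance", "target_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame


def _tree_positive_contrib(estimator, X_rows: np.ndarray, n_features: int) -> np.ndarray:
    """Impurity-decrease accumulated along paths of the given rows."""
    t = estimator.tree_
    internal = t.children_left != -1
    w = t.weighted_n_node_samples / t.weighted_n_node_samples[0]
    node_gain = np.zeros(t.node_count)
    left, right = t.children_left[internal], t.children_right[internal]
    node_gain[internal] = (
        w[internal] * t.impurity[internal]
        - w[left] * t.impurity[left]
        - w[right] * t.impurity[right]
    )
    visits = np.asarray(
        estimator.decision_path(X_rows).sum(axis=0)
    ).ravel()
    contrib = np.zeros(n_features)
    np.add.at(
        contrib,
        t.feature[internal],
        node_gain[internal] * visits[internal],
    )
    return contrib


def feature_importance(
    model,
    target_ids,
    mode: str = "global",
    X=None,
    y_pred=None,
) -> ImportanceTable:
    """Rank targets by their contribution to a fitted tree-based model.

    ``global`` mode returns the model's normalized mean impurity decrease.
    ``positive`` mode accumulates per-node impurity decreases only along
    the decision paths traversed by positively-predicted rows of ``X``
    (weighted by traversal count) and renormalizes; if no row is predicted
    positive it falls back to global mode with a warning. Both modes are
    deterministic given the fitted model.
    """
    target_ids = list(target_ids)
    n_features = len(target_ids)
    if getattr(model, "n_features_in_", n_features) != n_features:
        raise ValueError("target_ids length does not match the fitted model")

    if mode == "global":
        imp = np.asarray(model.feature_importances_, dtype=float)
        total = imp.sum()
        if total > 0:
            imp = imp / total
        return ImportanceTable(_rank_frame(target_ids, imp), mode="global")

    if mode != "positive":
        raise ValueError(f"unknown importance mode: {mode!r}")
    if X is None:
        raise ValueError("positive mode requires feature rows X")
    X = np.asarray(X, dtype=float)
    if y_pred is None:
        y_pred = model.predict(X)
    y_pred = np.asarray(y_pred).astype(int)
    pos_rows = X[y_pred == 1]
    if len(pos_rows) == 0:
        warnings.warn(
            "no positively-predicted rows; falling back to global importance"
        )
        return feature_importance(model, target_ids, mode="global")

    estimators = getattr(model, "estimators_", [model])
    contrib = np.zeros(n_features)
    for est in estimators:
        contrib += _tree_positive_contrib(est, pos_rows, n_features)
    total = contrib.sum()
    if total > 0:
        contrib = contrib / total
    return ImportanceTable(_rank_frame(target_ids, contrib), mode="positive")


def top_k(importance: ImportanceTable, k: int = 10) -> ImportanceTable:
    """First k rows by rank (fewer if the table is shorter)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return ImportanceTable(
        importance.frame.head(k).reset_index(drop=True), mode=importance.mode
    )


# ---------------------------------------------------------------------------
# fuzzy disease-term -> SOC matching


_NON_ALNUM = re.compile(r"[^0-9a-z]+")


def _token_sort(text: str) -> str:
    tokens = _NON_ALNUM.sub(" ", str(text).casefold()).split()
    return " ".join(sorted(tokens))


def _levenshtein(a: str, b: str) -> int:
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def similarity_ratio(a: str, b: str) -> float:
    """Token-sorted normalized edit-distance similarity on a 0-100 scale.

    Case, surrounding whitespace and punctuation are ignored; tokens are
    sorted so word order does not matter.
    """
    na, nb = _token_sort(a), _token_sort(b)
    if not na and not nb:
        return 100.0
    longest = max(len(na), len(nb))
    return 100.0 * (1.0 - _levenshtein(na, nb) / longest)


@dataclass
class SocMatchSummary:
    """Per-target SOC association counts from fuzzy disease-term mapping."""

    per_target: dict[str, dict[str, int]]
    unmatched: dict[str, int]
    no_data: set[str]
    mappings: pd.DataFrame = field(repr=False)
    min_similarity: float = 80.0

    def total_rows(self, target: str) -> int:
        return sum(self.per_target.get(target, {}).values()) + self.unmatched.get(
            target, 0
        )


def match_associations(
    targets,
    associations: pd.DataFrame,
    soc_vocabulary,
    min_similarity: float = 80.0,
) -> SocMatchSummary:
    """Map each target's disease terms to their most similar SOC.

    Every association row for a requested target is matched against the
    vocabulary; the best-scoring SOC wins (ties broken by lexicographic
    SOC order). Matches below ``min_similarity`` count as unmatched.
    Targets with no rows at all are flagged ``no_data``.
    """
    vocab = [str(s) for s in soc_vocabulary]
    if not vocab:
        raise ValueError("SOC vocabulary is empty")
    targets = [str(t) for t in targets]
    required = {"target_id", "disease_term"}
    if required - set(associations.columns):
        raise ValueError("association table needs target_id, disease_term columns")

    rows = associations[associations["target_id"].astype(str).isin(targets)]
    per_target: dict[str, dict[str, int]] = {t: {} for t in targets}
    unmatched: dict[str, int] = {t: 0 for t in targets}
    mapping_rows = []
    term_cache: dict[str, tuple[str, float]] = {}
    sorted_vocab = sorted(vocab)
    for _, row in rows.iterrows():
        target = str(row["target_id"])
        term = str(row["disease_term"])
        if term not in term_cache:
            scores = [(similarity_ratio(term, soc), soc) for soc in sorted_vocab]
            best_score = max(s for s, _ in scores)
            best_soc = min(soc for s, soc in scores if s == best_score)
            term_cache[term] = (best_soc, best_score)
        best_soc, best_score = term_cache[term]
        matched = best_score >= min_similarity
        if matched:
            per_target[target][best_soc] = per_target[target].get(best_soc, 0) + 1
        else:
            unmatched[target] += 1
        mapping_rows.append(
            {
                "target_id": target,
                "disease_term": term,
                "best_soc": best_soc,
                "similarity": best_score,
                "matched": matched,
            }
        )
    with_rows = set(rows["target_id"].astype(str))
    no_data = {t for t in targets if t not in with_rows}
    mappings = pd.DataFrame(
        mapping_rows,
        columns=["target_id", "disease_term", "best_soc", "similarity", "matched"],
    )
    return SocMatchSummary(
        per_target=per_target,
        unmatched=unmatched,
        no_data=no_data,
        mappings=mappings,
        min_similarity=min_similarity,
    )


@dataclass
class AlignmentReport:
    """Per-target alignment with a focal SOC plus figure-ready totals."""

    focal_soc: str
    aligned: dict[str, bool]
    aligned_count: int
    n_targets: int
    no_data: list[str]
    soc_totals: dict[str, int]
    groups: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "focal_soc": self.focal_soc,
            "aligned": self.aligned,
            "aligned_count": self.aligned_count,
            "n_targets": self.n_targets,
            "no_data": self.no_data,
            "soc_totals": self.soc_totals,
            "groups": self.groups,
        }


def soc_alignment(summary: SocMatchSummary, focal_soc: str) -> AlignmentReport:
    """Check which targets carry at least one association in the focal SOC.

    Also aggregates association counts per SOC across all targets and
    groups them as focal / next-two-most-common / other for summary plots.
    """
    aligned = {
        t: summary.per_target.get(t, {}).get(focal_soc, 0) > 0
        for t in summary.per_target
    }
    totals: Counter = Counter()
    for counts in summary.per_target.values():
        totals.update(counts)
    others = [
        (soc, n) for soc, n in sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
        if soc != focal_soc
    ]
    groups = {"focal": totals.get(focal_soc, 0)}
    for i, (soc, n) in enumerate(others[:2]):
        groups[soc] = n
    groups["other"] = sum(n for _, n in others[2:])
    return AlignmentReport(
        focal_soc=focal_soc,
        aligned=aligned,
        aligned_count=int(sum(aligned.values())),
        n_targets=len(aligned),
        no_data=sorted(summary.no_data),
        soc_totals=dict(totals),
        groups=groups,
    )


# ---------------------------------------------------------------------------
# drug / ATC cross-referencing


def drug_target_relations(
    targets, interactions: InteractionMatrix
) -> pd.DataFrame:
    """Bipartite (drug, target, score) edges for the selected targets.

    One edge per nonzero post-filter score. Raises ``KeyError`` for
    targets absent from the matrix.
    """
    targets = [str(t) for t in targets]
    unknown = [t for t in targets if t not in interactions.target_ids]
    if unknown:
        raise KeyError(f"unknown target ids: {unknown}")
    cols = [interactions.target_ids.index(t) for t in targets]
    sub = interactions.scores[:, cols]
    ii, jj = np.nonzero(sub)
    frame = pd.DataFrame(
        {
            "drug_id": [interactions.drug_ids[i] for i in ii],
            "target_id": [targets[j] for j in jj],
            "score": sub[ii, jj],
        }
    ).sort_values(["drug_id", "target_id"]).reset_index(drop=True)
    return frame


def atc_enrichment(relations: pd.DataFrame, atc: pd.DataFrame) -> dict:
    """Level-1 ATC prefix breakdown of the drugs in a relation table.

    Fractions are over classified drugs only; drugs without an ATC code
    are reported separately and excluded from the denominator. A drug with
    codes under several prefixes counts once per prefix.
    """
    if {"drug_id", "atc_code"} - set(atc.columns):
        raise ValueError("ATC table needs drug_id, atc_code columns")
    drugs = sorted(set(relations["drug_id"].astype(str))) if len(relations) else []
    if not drugs:
        return {"prefixes": pd.DataFrame(columns=["prefix", "n_drugs", "fraction"]),
                "n_classified": 0, "unclassified": []}
    codes = atc.copy()
    codes["drug_id"] = codes["drug_id"].astype(str)
    codes = codes[codes["drug_id"].isin(drugs)]
    codes["prefix"] = codes["atc_code"].astype(str).str.strip().str[:1].str.upper()
    pairs = codes[["drug_id", "prefix"]].drop_duplicates()
    classified = sorted(set(pairs["drug_id"]))
    unclassified = sorted(set(drugs) - set(classified))
    counts = (
        pairs.groupby("prefix")["drug_id"].nunique().sort_values(ascending=False)
    )
    frame = pd.DataFrame(
        {
            "prefix": counts.index,
            "n_drugs": counts.values,
            "fraction": counts.values / len(classified) if classified else np.nan,
        }
    ).reset_index(drop=True)
    return {
        "prefixes": frame,
        "n_classified": len(classified),
        "unclassified": unclassified,
    }
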