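"""Disproportionality analysis of spontaneous ADR report counts.

Spontaneous-report tables give, for each (drug, System Organ Class) pair,
the number of suspected adverse-reaction reports. A pair is reported
*disproportionately* when the focal drug's share of reports in the focal
SOC exceeds what the rest of the table would predict under independence.
Two classical pharmacovigilance statistics quantify this on the 2x2
contingency table

    a = reports of the focal drug in the focal SOC
    b = reports of the focal drug in all other SOCs
    c = reports of all other drugs in the focal SOC
    d = reports of all other drugs in all other SOCs

    ROR = (a/b) / (c/d)             reporting odds ratio
    PRR = [a/(a+b)] / [c/(c+d)]     proportional reporting ratio

A (drug, SOC) pair is labelled a *significant signal* when both statistics
strictly exceed a threshold (default 2). Missing pairs and undefined
statistics are non-significant. Six SOC categories without pharmacological
relevance (administration-site conditions, injuries, investigations,
product issues, social circumstances, surgical procedures) are excluded
before analysis, leaving 21 of the 27 SOCs.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SOC_VOCABULARY",
    "DEFAULT_EXCLUDED_SOCS",
    "normalize_soc",
    "ReportCountTable",
    "load_reports",
    "ContingencyTable",
    "exclude_socs",
    "build_contingency",
    "ror",
    "prr",
    "score_signals",
    "label_signals",
    "SignalLabelMatrix",
    "percentages_to_pseudocounts",
]


def _load_vocabulary() -> tuple[str, ...]:
    text = resources.files(__package__).joinpath("data/soc_vocabulary.txt").read_text()
    return tuple(line.strip() for line in text.splitlines() if line.strip())


#: Bundled 27-term System Organ Class vocabulary stand-in (names only).
SOC_VOCABULARY: tuple[str, ...] = _load_vocabulary()

#: SOC categories excluded by default for lack of pharmacological relevance.
DEFAULT_EXCLUDED_SOCS: tuple[str, ...] = (
    "General disorders and administration site conditions",
    "Injury, poisoning and procedural complications",
    "Investigations",
    "Product issues",
    "Social circumstances",
    "Surgical and medical procedures",
)

_NON_ALNUM = re.compile(r"[^0-9a-z]+")


def normalize_soc(name: str) -> str:
    """Normalize a SOC name for comparison: case-fold, strip punctuation."""
    return _NON_ALNUM.sub(" ", str(name).casefold()).strip()


class ReportCountTable:
    """Long-format (drug_id, soc, count) table with cached marginals.

    Counts must be non-negative integers; duplicate (drug, soc) rows are
    aggregated by summation. Pairs absent from the table are semantically
    zero.
    """

    def __init__(self, frame: pd.DataFrame, excluded_socs: tuple[str, ...] = ()):
        required = {"drug_id", "soc", "count"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"report table missing columns {sorted(missing)}")
        frame = frame[["drug_id", "soc", "count"]].copy()
        frame["drug_id"] = frame["drug_id"].astype(str)
        frame["soc"] = frame["soc"].astype(str)
        counts = pd.to_numeric(frame["count"], errors="coerce")
        if counts.isna().any():
            row = int(counts.isna().idxmax()) + 1
            raise ValueError(f"unparseable report count at data row {row}")
        if (counts < 0).any():
            row = int((counts < 0).idxmax()) + 1
            raise ValueError(f"negative report count at data row {row}")
        if not np.allclose(counts, np.round(counts)):
            bad = ~np.isclose(counts, np.round(counts))
            row = int(bad.idxmax()) + 1
            raise ValueError(f"non-integer report count at data row {row}")
        frame["count"] = counts.round().astype(np.int64)
        frame = (
            frame.groupby(["drug_id", "soc"], sort=True, as_index=False)["count"]
            .sum()
            .reset_index(drop=True)
        )
        self.frame = frame
        self.excluded_socs = tuple(excluded_socs)

    @property
    def drugs(self) -> list[str]:
        return sorted(self.frame["drug_id"].unique())

    @property
    def socs(self) -> list[str]:
        return sorted(self.frame["soc"].unique())

    @property
    def drug_totals(self) -> pd.Series:
        return self.frame.groupby("drug_id")["count"].sum()

    @property
    def soc_totals(self) -> pd.Series:
        return self.frame.groupby("soc")["count"].sum()

    @property
    def grand_total(self) -> int:
        return int(self.frame["count"].sum())

    def count_matrix(self, drugs=None, socs=None):
        """Dense count matrix over ``drugs`` x ``socs`` (defaults: observed)."""
        drugs = list(drugs) if drugs is not None else self.drugs
        socs = list(socs) if socs is not None else self.socs
        pivot = self.frame.pivot_table(
            index="drug_id", columns="soc", values="count", aggfunc="sum", fill_value=0
        )
        pivot = pivot.reindex(index=drugs, columns=socs, fill_value=0)
        return drugs, socs, pivot.fillna(0).to_numpy(dtype=np.int64)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, sep="\t", index=False)
        return path

    def __len__(self) -> int:
        return len(self.frame)


def load_reports(path: str | Path) -> ReportCountTable:
    """Read a reports.tsv dialect file (drug_id, soc, count)."""
    frame = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "soc": str})
    return ReportCountTable(frame)


def exclude_socs(
    reports: ReportCountTable,
    exclusion: tuple[str, ...] = DEFAULT_EXCLUDED_SOCS,
) -> ReportCountTable:
    """Drop rows whose SOC is in the exclusion list (case-insensitive).

    Marginals of the returned table are recomputed over the retained SOC
    universe, so the 2x2 construction downstream never counts excluded
    categories.
    """
    norm = {normalize_soc(s) for s in exclusion}
    keep = ~reports.frame["soc"].map(normalize_soc).isin(norm)
    return ReportCountTable(
        reports.frame[keep], excluded_socs=tuple(exclusion)
    )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report contingency table for one (drug, SOC) pair."""

    a: int  # focal drug, focal SOC
    b: int  # focal drug, other SOCs
    c: int  # other drugs, focal SOC
    d: int  # other drugs, other SOCs

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def build_contingency(
    reports: ReportCountTable, drug: str, soc: str
) -> ContingencyTable:
    """Build the 2x2 table for a focal (drug, SOC) over the table's universe."""
    if drug not in set(reports.frame["drug_id"]):
        raise KeyError(f"unknown drug id: {drug!r}")
    if soc not in set(reports.frame["soc"]):
        raise KeyError(f"unknown SOC: {soc!r}")
    cell = reports.frame.query("drug_id == @drug and soc == @soc")["count"].sum()
    a = int(cell)
    b = int(reports.drug_totals[drug]) - a
    c = int(reports.soc_totals[soc]) - a
    d = reports.grand_total - a - b - c
    return ContingencyTable(a, b, c, d)


def ror(t: ContingencyTable, continuity: bool = False) -> float:
    """Reporting odds ratio (a/b)/(c/d) = a*d/(b*c).

    Conventions: ``a = 0`` maps to 0; a zero ``b*c`` with ``a > 0`` is
    undefined and returned as ``nan`` (treated as non-significant
    downstream). ``continuity=True`` applies the Haldane-Anscombe +0.5
    correction to all four cells first (off by default).
    """
    a, b, c, d = (t.a, t.b, t.c, t.d)
    if continuity:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if a == 0:
        return 0.0
    if b * c == 0:
        return math.nan
    return (a * d) / (b * c)


def prr(t: ContingencyTable, continuity: bool = False) -> float:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)].

    Conventions mirror :func:`ror`: ``a = 0`` maps to 0; an undefined
    denominator (``c = 0`` or ``a+b = 0`` with ``a > 0``) returns ``nan``.
    """
    a, b, c, d = (t.a, t.b, t.c, t.d)
    if continuity:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if a == 0:
        return 0.0
    if (a + b) == 0 or c == 0 or (c + d) == 0:
        return math.nan
    return (a / (a + b)) / (c / (c + d))


@dataclass
class SignalLabelMatrix:
    """Binary drugs x SOCs significance labels with provenance."""

    drug_ids: list[str]
    socs: list[str]
    labels: np.ndarray = field(repr=False)
    threshold: float = 2.0
    excluded_socs: tuple[str, ...] = ()

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (len(self.drug_ids), len(self.socs)):
            raise ValueError("label matrix shape mismatch")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        norm_excluded = {normalize_soc(s) for s in self.excluded_socs}
        if any(normalize_soc(s) in norm_excluded for s in self.socs):
            raise ValueError("label matrix contains an excluded SOC column")

    def column(self, soc: str) -> np.ndarray:
        return self.labels[:, self.socs.index(soc)]

    def significant_set(self) -> set[tuple[str, str]]:
        ii, jj = np.nonzero(self.labels)
        return {(self.drug_ids[i], self.socs[j]) for i, j in zip(ii, jj)}

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_id": np.repeat(self.drug_ids, len(self.socs)),
                "soc": np.tile(self.socs, len(self.drug_ids)),
                "label": self.labels.ravel(),
            }
        )

    def submatrix(self, drugs, socs) -> "SignalLabelMatrix":
        di = [self.drug_ids.index(d) for d in drugs]
        sj = [self.socs.index(s) for s in socs]
        return SignalLabelMatrix(
            drug_ids=list(drugs),
            socs=list(socs),
            labels=self.labels[np.ix_(di, sj)] if di and sj else
            np.zeros((len(di), len(sj)), dtype=np.int8),
            threshold=self.threshold,
            excluded_socs=self.excluded_socs,
        )


def score_signals(
    reports: ReportCountTable,
    drugs=None,
    socs=None,
    continuity: bool = False,
) -> pd.DataFrame:
    """Vectorized ROR/PRR over the full drug x SOC grid.

    ``drugs``/``socs`` may extend the observed universe (extra ids behave
    as all-zero rows/columns, i.e. missing data). Returns a long DataFrame
    with columns drug_id, soc, a, ror, prr; undefined statistics are NaN.
    """
    if reports.grand_total == 0:
        raise ValueError("empty report table: nothing to score")
    drug_ids, soc_ids, counts = reports.count_matrix(drugs=drugs, socs=socs)
    a = counts.astype(float)
    row = a.sum(axis=1, keepdims=True)
    col = a.sum(axis=0, keepdims=True)
    n = a.sum()
    b = row - a
    c = col - a
    d = n - row - col + a
    if continuity:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        ror_v = np.where(b * c > 0, a * d / (b * c), np.nan)
        num = np.where(a + b > 0, a / (a + b), np.nan)
        den = np.where((c > 0) & (c + d > 0), c / (c + d), np.nan)
        prr_v = num / den
    zero = a == 0
    ror_v = np.where(zero, 0.0, ror_v)
    prr_v = np.where(zero, 0.0, prr_v)
    return pd.DataFrame(
        {
            "drug_id": np.repeat(drug_ids, len(soc_ids)),
            "soc": np.tile(soc_ids, len(drug_ids)),
            "a": counts.ravel(),
            "ror": ror_v.ravel(),
            "prr": prr_v.ravel(),
        }
    )


def label_signals(
    reports: ReportCountTable,
    threshold: float = 2.0,
    drugs=None,
    socs=None,
    continuity: bool = False,
) -> tuple[pd.DataFrame, SignalLabelMatrix]:
    """Compute signal scores and joint binary labels.

    A cell is significant (1) iff *both* ROR and PRR strictly exceed
    ``threshold``; undefined statistics, zero counts, and (drug, SOC)
    pairs absent from the reports all yield 0. The reports are expected to
    have SOC exclusion already applied.
    """
    scores = score_signals(reports, drugs=drugs, socs=socs, continuity=continuity)
    with np.errstate(invalid="ignore"):
        sig = (scores["ror"].to_numpy() > threshold) & (
            scores["prr"].to_numpy() > threshold
        )
    scores = scores.assign(label=sig.astype(np.int8))
    drug_ids = list(dict.fromkeys(scores["drug_id"]))
    soc_ids = list(dict.fromkeys(scores["soc"]))
    labels = scores["label"].to_numpy().reshape(len(drug_ids), len(soc_ids))
    matrix = SignalLabelMatrix(
        drug_ids=drug_ids,
        socs=soc_ids,
        labels=labels,
        threshold=threshold,
        excluded_socs=reports.excluded_socs,
    )
    return scores, matrix


def percentages_to_pseudocounts(
    pct: pd.DataFrame, pseudo_total: int = 10_000
) -> ReportCountTable:
    """Convert a percentage-based drug x ADR table to pseudo report counts.

    ``count = round(pct / 100 * pseudo_total)`` per cell, so a
    percentage-valued source (SIDER-style) can flow through the same
    disproportionality path as raw counts. The default ``pseudo_total`` of
    10,000 preserves two-decimal percentage resolution.
    """
    if pseudo_total < 1 or not float(pseudo_total).is_integer():
        raise ValueError("pseudo_total must be a positive integer")
    required = {"drug_id", "soc", "pct"}
    missing = required - set(pct.columns)
    if missing:
        raise ValueError(f"percentage table missing columns {sorted(missing)}")
    values = pd.to_numeric(pct["pct"], errors="coerce")
    if values.isna().any():
        row = int(values.isna().idxmax()) + 1
        raise ValueError(f"unparseable percentage at data row {row}")
    bad = (values < 0) | (values > 100)
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ValueError(f"percentage outside [0, 100] at data row {row}")
    counts = np.rint(values.to_numpy() / 100.0 * pseudo_total).astype(np.int64)
    frame = pd.DataFrame(
        {"drug_id": pct["drug_id"], "soc": pct["soc"], "count": counts}
    )
    return ReportCountTable(frame)
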