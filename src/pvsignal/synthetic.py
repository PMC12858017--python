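"""Synthetic worlds with planted target -> SOC adverse-reaction mechanisms.

The generator emulates the five data sources the pipeline consumes: a
sparse drug-target interaction matrix with Beta-distributed confidence
scores, a spontaneous-report count table whose disproportionality
structure is driven by planted causal target sets, a clinical-trial-style
percentage table (an independent noisy re-draw in which a fraction of the
planted signals is missed), a noisy target-disease association table, and
a drug -> ATC code table whose focal-SOC engagers share a designated
level-1 prefix.

Mechanism: each planted SOC owns a disjoint set of causal targets. A drug
"engages" a planted SOC when its interaction score with at least one of
that SOC's causal targets exceeds the confidence threshold 0.4 (the same
cut the feature filter applies, so the planted mechanism is exactly what
the features can see). Report counts per (drug, SOC) cell are Poisson
with rate ``baseline_report_rate``, multiplied by ``relative_risk`` where
the drug engages the SOC. Null SOCs have no causal targets, so their only
significant labels are Poisson noise.
"""

from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .interactions import InteractionMatrix, load_interactions, write_interactions
from .signals import ReportCountTable, load_reports

__all__ = [
    "ENGAGEMENT_THRESHOLD",
    "DEFAULT_SOC_NAMES",
    "SyntheticConfig",
    "SyntheticWorld",
    "generate_world",
    "write_world",
    "load_world",
]

#: Post-filter confidence score above which a drug engages a causal target.
ENGAGEMENT_THRESHOLD = 0.4

#: Default world: four planted SOCs followed by two null SOCs.
DEFAULT_SOC_NAMES: tuple[str, ...] = (
    "Psychiatric disorders",
    "Nervous system disorders",
    "Cardiac disorders",
    "Gastrointestinal disorders",
    "Eye disorders",
    "Renal and urinary disorders",
)

_ATC_LETTERS = "ABCDGHJLMPRSV"


def _require(condition: bool, name: str, message: str) -> None:
    if not condition:
        raise ValueError(f"invalid {name}: {message}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world for the generator; every default is the package's
    documented desk-scale condition (see docs/methods.md)."""

    n_drugs: int = 300
    n_targets: int = 120
    soc_names: tuple[str, ...] = DEFAULT_SOC_NAMES
    causal_targets_per_soc: int = 5
    interaction_density: float = 0.05
    interaction_score_shape: tuple[float, float] = (2.0, 2.0)
    baseline_report_rate: float = 8.0
    relative_risk: float = 4.0
    null_soc_fraction: float = 1 / 3
    association_recall: float = 1.0
    name_noise_rate: float = 0.1
    ct_miss_rate: float = 0.3
    atc_focal_prefix: str = "N"
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "soc_names", tuple(self.soc_names))
        object.__setattr__(
            self, "interaction_score_shape", tuple(self.interaction_score_shape)
        )
        _require(int(self.n_drugs) == self.n_drugs and self.n_drugs >= 1,
                 "n_drugs", "must be a positive integer")
        _require(int(self.n_targets) == self.n_targets and self.n_targets >= 1,
                 "n_targets", "must be a positive integer")
        _require(len(self.soc_names) >= 1, "soc_names", "must be non-empty")
        _require(len(set(self.soc_names)) == len(self.soc_names),
                 "soc_names", "must be unique")
        _require(self.causal_targets_per_soc >= 1,
                 "causal_targets_per_soc", "must be a positive integer")
        _require(0 < self.interaction_density <= 1,
                 "interaction_density", "must lie in (0, 1]")
        shape = self.interaction_score_shape
        _require(len(shape) == 2 and all(s > 0 for s in shape),
                 "interaction_score_shape", "needs two positive shape parameters")
        _require(self.baseline_report_rate > 0,
                 "baseline_report_rate", "must be positive")
        _require(self.relative_risk >= 1, "relative_risk", "must be >= 1")
        _require(0 <= self.null_soc_fraction < 1,
                 "null_soc_fraction", "must lie in [0, 1)")
        _require(0 <= self.association_recall <= 1,
                 "association_recall", "must lie in [0, 1]")
        _require(0 <= self.name_noise_rate <= 1,
                 "name_noise_rate", "must lie in [0, 1]")
        _require(0 <= self.ct_miss_rate <= 1, "ct_miss_rate", "must lie in [0, 1]")
        _require(
            len(self.atc_focal_prefix) == 1 and self.atc_focal_prefix.isupper(),
            "atc_focal_prefix", "must be a single uppercase letter",
        )
        _require(int(self.seed) == self.seed and self.seed >= 0,
                 "seed", "must be a non-negative integer")
        _require(len(self.planted_socs) >= 1,
                 "null_soc_fraction", "leaves no planted SOC")
        _require(
            self.causal_targets_per_soc * len(self.planted_socs) <= self.n_targets,
            "causal_targets_per_soc",
            "total causal targets exceed n_targets",
        )

    @property
    def n_socs(self) -> int:
        return len(self.soc_names)

    @property
    def n_null_socs(self) -> int:
        return int(round(self.null_soc_fraction * self.n_socs))

    @property
    def planted_socs(self) -> tuple[str, ...]:
        return self.soc_names[: self.n_socs - self.n_null_socs]

    @property
    def null_socs(self) -> tuple[str, ...]:
        return self.soc_names[self.n_socs - self.n_null_socs:]


@dataclass
class SyntheticWorld:
    """A complete generated data set plus its ground truth."""

    interactions: InteractionMatrix
    reports: ReportCountTable
    truth: dict[str, list[str]]
    associations: pd.DataFrame = field(repr=False)
    atc: pd.DataFrame = field(repr=False)
    percentages: pd.DataFrame = field(repr=False)
    config: SyntheticConfig = None

    def __post_init__(self):
        if self.config is not None:
            if not set(self.truth) <= set(self.config.soc_names):
                raise ValueError("truth keys must be a subset of soc_names")
        targets = set(self.interactions.target_ids)
        for soc, causal in self.truth.items():
            if not set(causal) <= targets:
                raise ValueError(f"causal targets of {soc!r} missing from matrix")

    @property
    def no_data_target(self) -> str | None:
        """The designated causal target absent from the association table.

        Deterministic rule: the lexicographically last causal target of the
        first planted SOC (no extra file is needed to recover it).
        """
        if self.config is None or not self.config.planted_socs:
            return None
        focal = self.config.planted_socs[0]
        causal = self.truth.get(focal)
        return sorted(causal)[-1] if causal else None


def _noisy_term(soc: str, rng: np.random.Generator, rate: float) -> str:
    """SOC name as a disease term, optionally perturbed (typo or plural)."""
    term = soc.lower()
    if rate > 0 and rng.random() < rate:
        if rng.random() < 0.5:
            term = term[:-1] if term.endswith("s") else term + "s"
        else:
            pos = int(rng.integers(len(term)))
            repl = string.ascii_lowercase[int(rng.integers(26))]
            term = term[:pos] + repl + term[pos + 1:]
    return term


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Generate a complete synthetic world; deterministic given the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    width_d = max(4, len(str(cfg.n_drugs)))
    width_t = max(4, len(str(cfg.n_targets)))
    drugs = [f"D{i:0{width_d}d}" for i in range(1, cfg.n_drugs + 1)]
    targets = [f"T{i:0{width_t}d}" for i in range(1, cfg.n_targets + 1)]

    # sparse interaction matrix with Beta-distributed present scores
    present = rng.random((cfg.n_drugs, cfg.n_targets)) < cfg.interaction_density
    a, b = cfg.interaction_score_shape
    raw = rng.beta(a, b, size=(cfg.n_drugs, cfg.n_targets))
    scores = np.where(present, raw, 0.0)
    interactions = InteractionMatrix(drugs, targets, scores)

    # disjoint causal target sets for the planted SOCs
    perm = rng.permutation(cfg.n_targets)
    k = cfg.causal_targets_per_soc
    truth: dict[str, list[str]] = {}
    for i, soc in enumerate(cfg.planted_socs):
        cols = perm[i * k: (i + 1) * k]
        truth[soc] = sorted(targets[j] for j in cols)

    # engagement: max causal-target score above the confidence threshold
    engaged = np.zeros((cfg.n_drugs, cfg.n_socs), dtype=bool)
    target_index = {t: j for j, t in enumerate(targets)}
    for s, soc in enumerate(cfg.soc_names):
        if soc in truth:
            cols = [target_index[t] for t in truth[soc]]
            engaged[:, s] = (scores[:, cols] > ENGAGEMENT_THRESHOLD).any(axis=1)

    rates = cfg.baseline_report_rate * np.where(engaged, cfg.relative_risk, 1.0)
    counts = rng.poisson(rates)
    reports = ReportCountTable(
        pd.DataFrame(
            {
                "drug_id": np.repeat(drugs, cfg.n_socs),
                "soc": np.tile(cfg.soc_names, cfg.n_drugs),
                "count": counts.ravel(),
            }
        )
    )

    # clinical-trial-style source: fresh draw, some engaged cells missed
    missed = rng.random(engaged.shape) < cfg.ct_miss_rate
    ct_rates = cfg.baseline_report_rate * np.where(
        engaged & ~missed, cfg.relative_risk, 1.0
    )
    ct_counts = rng.poisson(ct_rates).astype(float)
    row_totals = ct_counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_totals > 0, 100.0 * ct_counts / row_totals, 0.0)
    percentages = pd.DataFrame(
        {
            "drug_id": np.repeat(drugs, cfg.n_socs),
            "soc": np.tile(cfg.soc_names, cfg.n_drugs),
            "pct": pct.ravel(),
        }
    )

    # association table: causal targets under their true SOC (with recall),
    # decoy rows for non-causal targets, one designated no-data target
    focal = cfg.planted_socs[0]
    no_data = sorted(truth[focal])[-1]
    causal_all = {t for causal in truth.values() for t in causal}
    nonfocal_socs = [s for s in cfg.soc_names if s != focal]
    rows = []
    for soc in cfg.planted_socs:
        for t in truth[soc]:
            if t == no_data:
                continue
            if rng.random() < cfg.association_recall:
                rows.append((t, _noisy_term(soc, rng, cfg.name_noise_rate)))
    for t in targets:
        if t in causal_all:
            continue
        for _ in range(int(rng.integers(0, 3))):
            soc = nonfocal_socs[int(rng.integers(len(nonfocal_socs)))] if nonfocal_socs else focal
            rows.append((t, _noisy_term(soc, rng, cfg.name_noise_rate)))
    associations = pd.DataFrame(rows, columns=["target_id", "disease_term"])

    # ATC codes: focal-SOC engagers share the designated level-1 prefix
    focal_idx = list(cfg.soc_names).index(focal)
    other_letters = [c for c in _ATC_LETTERS if c != cfg.atc_focal_prefix]
    atc_rows = []
    for i, drug in enumerate(drugs):
        if engaged[i, focal_idx]:
            prefix = cfg.atc_focal_prefix
        else:
            prefix = other_letters[int(rng.integers(len(other_letters)))]
        code = (
            f"{prefix}{int(rng.integers(1, 100)):02d}"
            f"{string.ascii_uppercase[int(rng.integers(26))]}"
            f"{string.ascii_uppercase[int(rng.integers(26))]}"
            f"{int(rng.integers(1, 100)):02d}"
        )
        atc_rows.append((drug, code))
    atc = pd.DataFrame(atc_rows, columns=["drug_id", "atc_code"])

    return SyntheticWorld(
        interactions=interactions,
        reports=reports,
        truth=truth,
        associations=associations,
        atc=atc,
        percentages=percentages,
        config=cfg,
    )


def write_world(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Write a world to a directory as UTF-8 TSV/JSON files.

    Emits interactions.tsv, reports.tsv, associations.tsv, atc.tsv,
    truth.json and config.json (plus percentages.tsv for the
    clinical-trial-style source). Round-trips losslessly through
    :func:`load_world`. Empty tables yield valid headers-only files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": directory / "interactions.tsv",
        "reports": directory / "reports.tsv",
        "associations": directory / "associations.tsv",
        "atc": directory / "atc.tsv",
        "percentages": directory / "percentages.tsv",
        "truth": directory / "truth.json",
        "config": directory / "config.json",
    }
    write_interactions(world.interactions, paths["interactions"])
    world.reports.frame.to_csv(paths["reports"], sep="\t", index=False)
    world.associations.to_csv(paths["associations"], sep="\t", index=False)
    world.atc.to_csv(paths["atc"], sep="\t", index=False)
    world.percentages.to_csv(paths["percentages"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump({soc: sorted(ts) for soc, ts in world.truth.items()}, fh, indent=2)
        fh.write("\n")
    config_dict = dataclasses.asdict(world.config) if world.config else None
    with open(paths["config"], "w") as fh:
        json.dump(config_dict, fh, indent=2)
        fh.write("\n")
    return paths


def load_world(directory: str | Path) -> SyntheticWorld:
    """Read back a directory written by :func:`write_world`."""
    directory = Path(directory)
    with open(directory / "config.json") as fh:
        config_dict = json.load(fh)
    config = SyntheticConfig(**config_dict) if config_dict is not None else None
    with open(directory / "truth.json") as fh:
        truth = {soc: list(ts) for soc, ts in json.load(fh).items()}
    interactions = load_interactions(directory / "interactions.tsv")
    reports = load_reports(directory / "reports.tsv")
    associations = pd.read_csv(
        directory / "associations.tsv", sep="\t", dtype=str
    )
    if associations.empty:
        associations = pd.DataFrame(columns=["target_id", "disease_term"])
    atc = pd.read_csv(directory / "atc.tsv", sep="\t", dtype=str)
    if atc.empty:
        atc = pd.DataFrame(columns=["drug_id", "atc_code"])
    percentages = pd.read_csv(
        directory / "percentages.tsv", sep="\t",
        dtype={"drug_id": str, "soc": str, "pct": float},
    )
    if percentages.empty:
        percentages = pd.DataFrame(columns=["drug_id", "soc", "pct"])
    return SyntheticWorld(
        interactions=interactions,
        reports=reports,
        truth=truth,
        associations=associations,
        atc=atc,
        percentages=percentages,
        config=config,
    )
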