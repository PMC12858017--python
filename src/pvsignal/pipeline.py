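"""End-to-end orchestration: simulate, run, report.

The three entry points mirror how the workflow is used in practice:
``simulate`` writes a synthetic world to disk, ``run`` executes the full
analysis (confidence filtering -> drug alignment -> SOC exclusion ->
disproportionality labelling -> optional second-source comparison ->
per-SOC modelling -> interpretation and external validation) and writes
all artefacts plus a reproducibility manifest, ``report`` summarises a
completed results directory. Everything is a plain Python function; the
examples/ scripts show one capability each.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import overlap_categories
from .interactions import (
    align_drugs,
    filter_confidence,
    load_interactions,
    normalize_drug_id,
)
from .interpretation import (
    atc_enrichment,
    drug_target_relations,
    feature_importance,
    match_associations,
    soc_alignment,
    top_k,
)
from .modeling import RunSettings, SearchSpace, SplitSpec, run_all_socs
from .signals import (
    DEFAULT_EXCLUDED_SOCS,
    SOC_VOCABULARY,
    exclude_socs,
    label_signals,
    load_reports,
    percentages_to_pseudocounts,
)
from .synthetic import SyntheticConfig, generate_world, write_world

__all__ = ["RunConfig", "RunResult", "simulate", "run", "report"]

log = logging.getLogger("pvsignal")


@dataclass
class RunConfig:
    """Paths and tunables for one full pipeline run."""

    interactions_path: str
    reports_path: str
    associations_path: str
    atc_path: str
    compare_path: str | None = None
    out_dir: str = "results/run"
    confidence_threshold: float = 0.4
    signal_threshold: float = 2.0
    excluded_socs: tuple[str, ...] = DEFAULT_EXCLUDED_SOCS
    soc_vocabulary: tuple[str, ...] = SOC_VOCABULARY
    test_fraction: float = 0.2
    stratified: bool = True
    n_trials: int = 20
    cv_folds: int = 3
    search_space: SearchSpace = field(default_factory=SearchSpace)
    kinds: tuple[str, ...] = ("forest", "tree")
    k_neighbors: int = 5
    top_k: int = 10
    min_similarity: float = 80.0
    pseudo_total: int = 10_000
    seed: int = 0
    save_models: bool = True

    @classmethod
    def from_world_dir(cls, directory: str | Path, **overrides) -> "RunConfig":
        """Point a config at a directory written by :func:`write_world`."""
        d = Path(directory)
        defaults = dict(
            interactions_path=str(d / "interactions.tsv"),
            reports_path=str(d / "reports.tsv"),
            associations_path=str(d / "associations.tsv"),
            atc_path=str(d / "atc.tsv"),
        )
        pct = d / "percentages.tsv"
        if pct.exists():
            defaults["compare_path"] = str(pct)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("excluded_socs", "soc_vocabulary", "kinds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if isinstance(raw.get("search_space"), dict):
            space = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["search_space"].items()
            }
            raw["search_space"] = SearchSpace(**space)
        return cls(**raw)

    def validate(self) -> None:
        for name in ("interactions_path", "reports_path",
                     "associations_path", "atc_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.compare_path is not None and not Path(self.compare_path).exists():
            raise FileNotFoundError(f"compare_path: {self.compare_path} does not exist")


@dataclass
class RunResult:
    """In-memory handles to everything ``run`` produced."""

    out_dir: Path
    labels: object
    soc_result: object
    focal_soc: str | None
    alignment: object = None
    overlap: object = None
    manifest: dict = field(default_factory=dict)


def simulate(config: SyntheticConfig, out_dir: str | Path) -> Path:
    """Generate a synthetic world and write it to ``out_dir``."""
    world = generate_world(config)
    write_world(world, out_dir)
    log.info(
        "simulated world: %d drugs x %d targets, %d SOCs (%d planted), seed=%d",
        config.n_drugs, config.n_targets, config.n_socs,
        len(config.planted_socs), config.seed,
    )
    return Path(out_dir)


def _stage(name: str, t0: float, **counts) -> None:
    extras = ", ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage %-12s %6.2fs  %s", name, time.perf_counter() - t0, extras)


def run(config: RunConfig) -> RunResult:
    """Execute the full workflow and write all artefacts to ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    t0 = time.perf_counter()
    matrix = load_interactions(config.interactions_path)
    counts["drugs_interactions"] = matrix.n_drugs
    counts["targets"] = matrix.n_targets
    _stage("load", t0, drugs=matrix.n_drugs, targets=matrix.n_targets)

    t0 = time.perf_counter()
    matrix = filter_confidence(matrix, config.confidence_threshold)
    counts["nonzero_after_filter"] = matrix.nonzero_count()
    _stage("filter", t0, nonzero=matrix.nonzero_count())

    t0 = time.perf_counter()
    reports = load_reports(config.reports_path)
    n_before = len(set(reports.frame["soc"]))
    reports = exclude_socs(reports, config.excluded_socs)
    counts["socs_retained"] = len(reports.socs)
    _stage("exclude", t0, socs_before=n_before, socs_after=len(reports.socs))
    if len(reports) == 0:
        raise ValueError("no report rows remain after SOC exclusion")

    t0 = time.perf_counter()
    n_int, n_rep = matrix.n_drugs, len(reports.drugs)
    matrix, reports, align_report = align_drugs(matrix, reports)
    counts["drugs_aligned"] = matrix.n_drugs
    with open(out / "alignment_report.json", "w") as fh:
        json.dump(align_report, fh, indent=2)
    _stage("align", t0, before=f"{n_int}/{n_rep}", after=matrix.n_drugs)

    t0 = time.perf_counter()
    scores, labels = label_signals(
        reports, threshold=config.signal_threshold, drugs=matrix.drug_ids
    )
    scores.to_csv(out / "signals.tsv", sep="\t", index=False)
    counts["significant_cells"] = int(labels.labels.sum())
    _stage("label", t0, cells=labels.labels.size, significant=int(labels.labels.sum()))

    overlap = None
    if config.compare_path is not None:
        t0 = time.perf_counter()
        pct = pd.read_csv(
            config.compare_path, sep="\t", dtype={"drug_id": str, "soc": str}
        )
        # same id normalization as align_drugs, so the grids intersect
        pct["drug_id"] = pct["drug_id"].map(normalize_drug_id)
        cmp_reports = exclude_socs(
            percentages_to_pseudocounts(pct, config.pseudo_total),
            config.excluded_socs,
        )
        _, cmp_labels = label_signals(cmp_reports, threshold=config.signal_threshold)
        overlap = overlap_categories(labels, cmp_labels)
        overlap.frame.to_csv(out / "overlap.tsv", sep="\t", index=False)
        with open(out / "overlap_summary.json", "w") as fh:
            json.dump(overlap.to_dict(), fh, indent=2)
        _stage("compare", t0, jaccard=round(overlap.jaccard, 4))

    t0 = time.perf_counter()
    settings = RunSettings(
        split=SplitSpec(config.test_fraction, config.stratified, config.seed),
        space=config.search_space,
        n_trials=config.n_trials,
        cv_folds=config.cv_folds,
        kinds=tuple(config.kinds),
        seed=config.seed,
        k_neighbors=config.k_neighbors,
    )
    soc_result = run_all_socs(matrix, labels, settings)
    soc_result.metrics_frame().to_csv(out / "metrics.tsv", sep="\t", index=False)
    best_params = {}
    with open(out / "trials.jsonl", "w") as fh:
        for b in soc_result.bundles:
            if b.trainable:
                best_params.setdefault(b.soc, {})[b.kind] = b.params
                for rec in b.trials:
                    fh.write(json.dumps({"soc": b.soc, "kind": b.kind, **rec}) + "\n")
    with open(out / "best_params.json", "w") as fh:
        json.dump(best_params, fh, indent=2)
    with open(out / "run_summary.json", "w") as fh:
        json.dump(
            {"pooled": soc_result.pooled, "comparison": soc_result.comparison}, fh,
            indent=2, default=float,
        )
    if config.save_models:
        for b in soc_result.bundles:
            if b.trainable:
                mdir = out / "models" / b.soc.replace(" ", "_")
                mdir.mkdir(parents=True, exist_ok=True)
                joblib.dump(b.model, mdir / f"{b.kind}.joblib")
    _stage("train", t0, bundles=len(soc_result.bundles))

    # interpretation on the best-performing forest model (the case study),
    # global importances for every trainable forest
    t0 = time.perf_counter()
    forests = [
        b for b in soc_result.bundles
        if b.kind == "forest" and b.trainable and not np.isnan(b.metrics.roc_auc)
    ]
    focal_soc = None
    alignment = None
    importance_rows = []
    if forests:
        best = max(forests, key=lambda b: (b.metrics.roc_auc, b.soc))
        focal_soc = best.soc
        for b in forests:
            table = feature_importance(b.model, matrix.target_ids, mode="global")
            frame = table.frame.assign(soc=b.soc, mode="global")
            importance_rows.append(frame)
        pos_table = feature_importance(
            best.model, matrix.target_ids, mode="positive",
            X=matrix.scores[best.test_idx],
        )
        importance_rows.append(pos_table.frame.assign(soc=focal_soc, mode="positive"))
        top = top_k(pos_table, config.top_k)

        associations = pd.read_csv(config.associations_path, sep="\t", dtype=str)
        if associations.empty:
            associations = pd.DataFrame(columns=["target_id", "disease_term"])
        summary = match_associations(
            top.targets, associations, config.soc_vocabulary, config.min_similarity
        )
        alignment = soc_alignment(summary, focal_soc)
        with open(out / "alignment.json", "w") as fh:
            json.dump(alignment.to_dict(), fh, indent=2)

        relations = drug_target_relations(top.targets, matrix)
        relations.to_csv(out / "relations.tsv", sep="\t", index=False)
        atc = pd.read_csv(config.atc_path, sep="\t", dtype=str)
        enrichment = atc_enrichment(relations, atc)
        enrichment["prefixes"].to_csv(out / "atc_summary.tsv", sep="\t", index=False)
    if importance_rows:
        pd.concat(importance_rows, ignore_index=True)[
            ["soc", "target_id", "importance", "rank", "mode"]
        ].to_csv(out / "importance.tsv", sep="\t", index=False)
    _stage("interpret", t0, focal=focal_soc or "none")

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "library_versions": _library_versions(),
        "stage_counts": counts,
        "focal_soc": focal_soc,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return RunResult(
        out_dir=out,
        labels=labels,
        soc_result=soc_result,
        focal_soc=focal_soc,
        alignment=alignment,
        overlap=overlap,
        manifest=manifest,
    )


def _library_versions() -> dict[str, str]:
    import sklearn
    import scipy

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }


def report(out_dir: str | Path, save_plots: bool = False) -> dict:
    """Summarise a completed results directory.

    Returns the pooled confusion breakdown, per-SOC metric ranges, top-k
    importance bar data, the SOC-alignment summary and the ATC prefix
    summary. Raises ``FileNotFoundError`` listing whichever artefacts are
    missing.
    """
    out = Path(out_dir)
    needed = ["metrics.tsv", "run_summary.json", "manifest.json"]
    missing = [name for name in needed if not (out / name).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run in {out}: missing {missing}")

    metrics = pd.read_csv(out / "metrics.tsv", sep="\t")
    with open(out / "run_summary.json") as fh:
        run_summary = json.load(fh)

    ranges: dict[str, dict] = {}
    trainable = metrics[metrics["trainable"] == True]  # noqa: E712
    for kind, group in trainable.groupby("model_kind"):
        ranges[kind] = {
            metric: {
                "min": float(np.nanmin(group[metric])),
                "max": float(np.nanmax(group[metric])),
            }
            for metric in ("roc_auc", "accuracy", "precision", "recall", "f1", "mcc")
            if metric in group
        }

    summary = {
        "pooled": run_summary["pooled"],
        "comparison": run_summary.get("comparison", {}),
        "metric_ranges": ranges,
        "n_soc_models": int(trainable["soc"].nunique()) if len(trainable) else 0,
    }
    if (out / "importance.tsv").exists():
        imp = pd.read_csv(out / "importance.tsv", sep="\t")
        pos = imp[imp["mode"] == "positive"].nsmallest(10, "rank")
        summary["top_targets"] = pos[["target_id", "importance"]].to_dict("records")
    if (out / "alignment.json").exists():
        with open(out / "alignment.json") as fh:
            summary["alignment"] = json.load(fh)
    if (out / "atc_summary.tsv").exists():
        atc = pd.read_csv(out / "atc_summary.tsv", sep="\t")
        summary["atc_prefixes"] = atc.to_dict("records")
    if (out / "overlap_summary.json").exists():
        with open(out / "overlap_summary.json") as fh:
            overlap = json.load(fh)
        overlap.pop("dropped", None)
        summary["overlap"] = overlap

    if save_plots and "top_targets" in summary and summary["top_targets"]:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        data = pd.DataFrame(summary["top_targets"])
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.barh(data["target_id"][::-1], data["importance"][::-1])
        ax.set_xlabel("positive-prediction importance")
        ax.set_title("Top targets of the focal SOC model")
        fig.tight_layout()
        fig.savefig(out / "top_targets.png", dpi=150)
        plt.close(fig)

    return summary
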