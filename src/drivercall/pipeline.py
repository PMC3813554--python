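"""End-to-end orchestration: simulate/curate -> impute -> select -> train
-> predict -> evaluate, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import SiteBlacklist, write_calls, write_catalog
from .classifier import ModelSpec, predict, save_model, train
from .curation import CurationConfig, curate_expanded, curate_stringent
from .evaluation import roc_auc_and_recall
from .features import ImputationConfig, impute, write_feature_table
from .selection import CVConfig, select_features
from .simulate import FixtureSpec, make_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a full pipeline run, with one master seed."""

    out_dir: str
    fixture: FixtureSpec = field(default_factory=FixtureSpec)
    curation: CurationConfig = field(default_factory=CurationConfig)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    alpha: float = 0.05
    auc_margin: float = 0.05
    exclude_features: tuple[str, ...] = ()
    cv: CVConfig = field(default_factory=CVConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        # one master seed propagated to every stochastic stage
        self.fixture = FixtureSpec(**{**asdict(self.fixture), "seed": self.seed})
        self.cv = CVConfig(folds=self.cv.folds, repeats=self.cv.repeats, seed=self.seed)
        self.model = ModelSpec(
            kernel=self.model.kernel,
            C=self.model.C,
            gamma=self.model.gamma,
            class_weights=self.model.class_weights,
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on simulated inputs and write artifacts to out_dir.

    Returns a summary dict (also written as ``manifest.json``) with stage
    outputs, input hashes, and the evaluation numbers.  Re-running with
    the same config reproduces byte-identical call tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: generating catalog and feature table")
    data = make_dataset(config.fixture)
    write_catalog(data.catalog, out / "catalog.tsv")
    write_feature_table(data.table, out / "features.tsv")

    logger.info("stage curate: building expanded training set")
    stringent = curate_stringent(
        data.catalog,
        SiteBlacklist(),
        data.cancer_genes,
        config.curation,
        cancer_type=config.fixture.cancer_type,
    )
    expanded = curate_expanded(
        data.catalog,
        config.fixture.cancer_type,
        data.cancer_genes,
        config.curation,
        stringent,
    )
    if not expanded.drivers or not expanded.passengers:
        raise RuntimeError("stage curate: expanded set has an empty class")
    labels = pd.Series(
        {m: 1 for m in expanded.drivers} | {m: 0 for m in expanded.passengers}
    ).sort_index()
    labels.rename("label").to_csv(out / "labels.tsv", sep="\t", index_label="mutation_id")

    logger.info("stage impute: filling %d-cell table", data.table.values.size)
    imputed = impute(data.table, data.catalog, config.imputation)

    logger.info("stage select: screening + combinatorial search")
    train_table = type(imputed)(
        imputed.values.loc[labels.index], dict(imputed.kinds)
    )
    screen, trace = select_features(
        train_table,
        labels,
        alpha=config.alpha,
        auc_margin=config.auc_margin,
        exclude=config.exclude_features,
        cv=config.cv,
        model_spec=config.model,
    )
    pd.DataFrame([vars(r) for r in screen]).to_csv(
        out / "screen.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"step": i + 1, "feature_added": f, "cv_auc": a}
            for i, (f, a) in enumerate(trace.path)
        ]
    ).to_csv(out / "selection_trace.tsv", sep="\t", index=False)

    logger.info("stage train: weighted SVM on %d features", len(trace.optimal_set))
    model = train(train_table, labels, trace.optimal_set, config.model)
    save_model(model, out / "model.joblib")

    logger.info("stage predict: scoring %d mutations", len(imputed.mutation_ids))
    calls = predict(model, imputed)
    write_calls(calls, out / "calls.tsv")

    logger.info("stage evaluate: against simulation truth")
    truth = {m: 1 for m in data.truth.expanded_drivers} | {
        m: 0 for m in data.truth.expanded_passengers
    }
    ev = roc_auc_and_recall(calls, truth)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            p.name: _sha256(p)
            for p in (out / "catalog.tsv", out / "features.tsv", out / "labels.tsv")
        },
        "n_expanded_drivers": len(expanded.drivers),
        "n_expanded_passengers": len(expanded.passengers),
        "core_set": list(trace.core_set),
        "optimal_set": list(trace.optimal_set),
        "optimal_cv_auc": trace.optimal_cv_auc,
        "truth_auc": ev.auc,
        "truth_recall": f"{ev.n_driver_calls_in_truth}/{ev.n_true_drivers}",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
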