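"""One-command orchestration: generate/ingest -> build -> balance -> split ->
train -> evaluate -> report, with a manifest that makes every run
reproducible from its output directory alone.

A single global seed fans out into stage seeds (generation, split, weight
init, projection) so stages can be re-run independently.  Two profiles are
provided: ``quick`` (a ~1,222-gene cohort, 200 epochs at a larger step size)
and ``full`` (the full-scale cohort and the 5,000-epoch regimen).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .balancing import balance_and_split, save_split_manifest
from .experiments import (GENE_DIALECT, INTERACTION_DIALECT, derive_seeds,
                          load_cohort_graph)
from .io import build_graph, filter_human_interactions, read_gene_table, \
    read_interaction_table
from .model import GeneNodeClassifier, TrainConfig
from .synthetic import SyntheticCohortConfig, generate_cohort

logger = logging.getLogger(__name__)

PROFILES = {
    "quick": {"scale": 10.0, "train": {"learning_rate": 0.01, "epochs": 200},
              "hidden_dim": 32},
    "full": {"scale": 1.0, "train": {"learning_rate": 0.001, "epochs": 5000},
             "hidden_dim": 64},
}


@dataclass
class RunConfig:
    task: str = "binary"
    family: str = "sage"
    featureless: bool = False
    profile: str = "quick"
    seed: int = 0
    outdir: str = "runs/run0"
    # data source: explicit table paths, or None -> synthetic generation
    gene_table: Optional[str] = None
    interaction_table: Optional[str] = None
    gene_dialect: dict = field(default_factory=lambda: dict(GENE_DIALECT))
    interaction_dialect: dict = field(
        default_factory=lambda: dict(INTERACTION_DIALECT))
    # synthetic knobs (used when no table paths are given)
    homophily: float = 5.0
    band_signal: float = 0.8
    # balancing
    balance_mode: str = "duplicate"
    protocol: str = "after_upsample"
    test_fraction: float = 0.25
    # training overrides on top of the profile
    epochs: Optional[int] = None
    learning_rate: Optional[float] = None
    hidden_dim: Optional[int] = None
    tsne: bool = False
    top_k: int = 10

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def resolved_train_config(self, seed: int) -> TrainConfig:
        base = dict(PROFILES[self.profile]["train"])
        if self.epochs is not None:
            base["epochs"] = self.epochs
        if self.learning_rate is not None:
            base["learning_rate"] = self.learning_rate
        return TrainConfig(seed=seed, **base)

    def resolved_hidden_dim(self) -> int:
        return (self.hidden_dim if self.hidden_dim is not None
                else PROFILES[self.profile]["hidden_dim"])


def _prepare_graph(config: RunConfig, outdir: Path, gen_seed: int):
    if config.gene_table and config.interaction_table:
        genes = read_gene_table(config.gene_table, dialect=config.gene_dialect)
        inter = read_interaction_table(config.interaction_table,
                                       dialect=config.interaction_dialect)
        return build_graph(genes, filter_human_interactions(inter),
                           config.task)
    scale = PROFILES[config.profile]["scale"]
    cohort_cfg = SyntheticCohortConfig.scaled(
        scale, homophily=config.homophily, band_signal=config.band_signal,
        seed=gen_seed)
    cohort = generate_cohort(cohort_cfg, outdir / "data")
    return load_cohort_graph(cohort, config.task)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Writes ``manifest.json`` (resolved config + stage seeds), the balanced
    graph and split manifest, a weight checkpoint, ``metrics.json`` (balanced
    test set and originals-only), per-class ROC points, ranked gene lists and
    the loss trace.  Any stage failure leaves a ``FAILED_<stage>`` marker.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    gen_seed, split_seed, init_seed, proj_seed = map(int, derive_seeds(
        config.seed, 4))
    manifest = {"config": config.to_dict(),
                "stage_seeds": {"generate": gen_seed, "split": split_seed,
                                "init": init_seed, "projection": proj_seed}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    stage = "generate"
    try:
        graph = _prepare_graph(config, out, gen_seed)
        stage = "balance"
        bal, train_idx, test_idx = balance_and_split(
            graph, protocol=config.protocol, mode=config.balance_mode,
            test_fraction=config.test_fraction, seed=split_seed)
        bal.graph.save(out / "balanced_graph")
        save_split_manifest(out / "split.json", config.protocol, split_seed,
                            train_idx, test_idx)
        stage = "train"
        clf = GeneNodeClassifier(bal, family=config.family,
                                 featureless=config.featureless,
                                 hidden_dim=config.resolved_hidden_dim())
        res = clf.fit(train_idx, config.resolved_train_config(init_seed))
        res.save(out / "checkpoint.npz")
        pd.DataFrame({"epoch": np.arange(res.loss_trace.size),
                      "loss": res.loss_trace}).to_csv(
            out / "loss_trace.csv", index=False)
        stage = "evaluate"
        report = res.evaluate(test_idx)
        report_orig = res.evaluate(test_idx, original_only=True)
        (out / "metrics.json").write_text(json.dumps({
            "balanced_test": report.to_dict(),
            "original_test_nodes_only": report_orig.to_dict(),
        }, indent=2) + "\n")
        (out / "report.txt").write_text(
            res.summary(test_idx) + "\n\nOriginal test nodes only\n"
            + "-" * 42 + "\n" + report_orig.summary() + "\n")
        for cname, (fpr, tpr, thr) in report.roc.items():
            safe = cname.replace(" ", "_").lower()
            pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(
                out / f"roc_{safe}.csv", index=False)
        ranked = []
        for cname in graph.classes:
            for gene, conf in res.top_genes(cname, k=config.top_k):
                ranked.append({"class": cname, "gene": gene,
                               "confidence": conf})
        pd.DataFrame(ranked).to_csv(out / "top_genes.tsv", sep="\t",
                                    index=False)
        if config.tsne:
            orig = np.arange(clf.n_original)
            coords = res.project_embeddings(
                idx=orig, seed=proj_seed,
                perplexity=min(30.0, max(2.0, orig.size / 4)))
            pd.DataFrame({
                "gene": [graph.nodes[i] for i in orig],
                "x": coords[:, 0], "y": coords[:, 1],
                "label": [graph.classes[l] for l in graph.labels[orig]],
            }).to_csv(out / "tsne.csv", index=False)
    except Exception:
        (out / f"FAILED_{stage}").write_text("")
        raise
    return out


def compare_models(configs: Sequence[RunConfig]) -> pd.DataFrame:
    """Run several model variants on identical data/split seeds and tabulate.

    Refuses configurations whose data or split seeds differ, since their
    metrics would not be comparable.
    """
    seeds = {(c.seed, c.task, c.protocol, c.test_fraction) for c in configs}
    if len(seeds) != 1:
        raise ValueError("configs must share seed, task, protocol and "
                         "test fraction to be comparable")
    rows = []
    for c in configs:
        out = run_pipeline(c)
        metrics = json.loads((out / "metrics.json").read_text())["balanced_test"]
        rows.append({
            "model": c.family + (" featureless" if c.featureless else ""),
            "f1_positive": metrics["f1_positive"],
            "f1_macro": metrics["f1_macro"],
            "accuracy": metrics["accuracy"],
            "specificity": metrics["specificity"],
            "sensitivity": metrics["sensitivity"],
            "outdir": str(out),
        })
    return pd.DataFrame(rows)
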