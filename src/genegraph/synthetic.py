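"""Synthetic risk-catalogue and interaction-network generator.

Emulates the statistical shape of a curated autism-risk gene catalogue joined
to a protein-interaction network, with planted structure the pipeline can be
validated against:

* exact per-class gene counts (default 214 high / 530 moderate / 69 low
  confidence against 11,403 unassociated genes, 169 syndromic);
* a chromosome-band vocabulary in which risk classes draw from small
  class-specific enriched band subsets with probability ``band_signal``;
* a degree-corrected planted-partition interaction graph in which pairs in
  the same risk class connect with ``homophily`` times the background rate
  (pairs in two different risk classes get the intermediate factor
  ``(1 + homophily) / 2``), over heavy-tailed node propensities so hub
  structure resembles a real interaction network;
* a small fraction of decoy non-human interaction rows to exercise the
  species filter.

Everything is deterministic for a fixed seed; the written files re-parse into
exactly the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .io import (TASK_CLASSES, filter_human_interactions, read_gene_table,
                 read_interaction_table)

RISK_CLASSES = ("low", "moderate", "high")
CLASS_ORDER = ("none", "low", "moderate", "high")     # label-index order
CLASS_TO_SCORE = {"high": 1, "moderate": 2, "low": 3, "none": None}

#: class counts of the emulated catalogue (high:moderate:low:none)
DEFAULT_CLASS_COUNTS = {"high": 214, "moderate": 530, "low": 69, "none": 11403}
DEFAULT_SYNDROMIC = 169
DEFAULT_N_BANDS = 471

NONHUMAN_SPECIES = ("Mus musculus", "Rattus norvegicus",
                    "Saccharomyces cerevisiae")

#: fraction of the band vocabulary reserved as risk-enriched loci
ENRICHED_FRACTION = 0.10


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_genes: int = 12216
    class_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    syndromic_count: int = DEFAULT_SYNDROMIC
    n_bands: int = DEFAULT_N_BANDS
    band_signal: float = 0.8
    homophily: float = 5.0
    mean_degree: float = 8.0
    nonhuman_fraction: float = 0.05
    degree_sigma: float = 0.75        # log-normal spread of node propensities
    seed: int = 0

    def __post_init__(self):
        if sum(self.class_counts.values()) != self.n_genes:
            raise ValueError("class_counts must sum to n_genes")
        if not 0.0 <= self.band_signal <= 1.0:
            raise ValueError("band_signal must be in [0, 1]")
        if self.homophily < 1.0:
            raise ValueError("homophily multiplier must be >= 1")
        if not 0.0 < self.mean_degree < self.n_genes:
            raise ValueError("mean_degree must be in (0, n_genes)")
        if self.syndromic_count > self.n_genes:
            raise ValueError("syndromic_count exceeds n_genes")

    @classmethod
    def scaled(cls, factor: float, **overrides) -> "SyntheticCohortConfig":
        """Shrink the default cohort by ``factor``, preserving class ratios."""
        counts = {c: max(1, round(n / factor))
                  for c, n in DEFAULT_CLASS_COUNTS.items() if c != "none"}
        n_genes = round(12216 / factor)
        counts["none"] = n_genes - sum(counts.values())
        base = cls(n_genes=n_genes, class_counts=counts,
                   syndromic_count=max(1, round(DEFAULT_SYNDROMIC / factor)),
                   n_bands=max(10, round(DEFAULT_N_BANDS / factor)))
        return replace(base, **overrides) if overrides else base


@dataclass
class SyntheticCohort:
    gene_table_path: Path
    interaction_table_path: Path
    truth_path: Path
    truth: pd.DataFrame           # symbol, class, syndromic, band
    config: SyntheticCohortConfig


def _band_names(n: int) -> list:
    """Cytoband-style names (1p11, 1q11, ... 22q.., Xp..)."""
    chroms = [str(c) for c in range(1, 23)] + ["X"]
    names = []
    num = 11
    while len(names) < n:
        for c in chroms:
            for arm in ("p", "q"):
                names.append(f"{c}{arm}{num}")
                if len(names) == n:
                    return names
        num += 1
    return names


def _assign_genes(config: SyntheticCohortConfig, rng: np.random.Generator
                  ) -> pd.DataFrame:
    """Symbols, classes, syndromic flags and bands with the planted signal."""
    n = config.n_genes
    symbols = [f"G{i:05d}" for i in range(n)]
    classes = np.concatenate([
        np.full(config.class_counts.get(c, 0), i)
        for i, c in enumerate(CLASS_ORDER)])
    rng.shuffle(classes)

    # syndromic genes are drawn preferentially from the risk classes
    risk_idx = np.flatnonzero(classes > 0)
    none_idx = np.flatnonzero(classes == 0)
    synd = np.zeros(n, dtype=bool)
    k = config.syndromic_count
    take_risk = min(k, risk_idx.size)
    synd[rng.choice(risk_idx, size=take_risk, replace=False)] = True
    if k > take_risk:
        synd[rng.choice(none_idx, size=k - take_risk, replace=False)] = True

    vocab = _band_names(config.n_bands)
    n_enriched = max(len(RISK_CLASSES), int(round(ENRICHED_FRACTION * len(vocab))))
    enriched_pool = rng.choice(len(vocab), size=n_enriched, replace=False)
    per_class = {c: enriched_pool[i::len(RISK_CLASSES)]
                 for i, c in enumerate(RISK_CLASSES)}

    band_idx = rng.integers(0, len(vocab), size=n)
    for ci, cname in enumerate(CLASS_ORDER):
        if cname == "none":
            continue
        members = np.flatnonzero(classes == ci)
        use_signal = rng.random(members.size) < config.band_signal
        subset = per_class[cname]
        band_idx[members[use_signal]] = rng.choice(
            subset, size=int(use_signal.sum()), replace=True)

    return pd.DataFrame({
        "symbol": symbols,
        "class": [CLASS_ORDER[c] for c in classes],
        "syndromic": synd.astype(int),
        "band": [vocab[j] for j in band_idx],
    })


def _pair_multiplier(ci: np.ndarray, cj: np.ndarray, h: float) -> np.ndarray:
    """Planted-partition block factor for class indices ci (column) vs cj (row)."""
    both_risk = (ci > 0) & (cj > 0)
    same = ci == cj
    out = np.ones(np.broadcast_shapes(ci.shape, cj.shape))
    out[both_risk & ~same] = (1.0 + h) / 2.0
    out[both_risk & same] = h
    return out


def _sample_edges(classes: np.ndarray, config: SyntheticCohortConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Upper-triangle Bernoulli edges of the degree-corrected planted partition."""
    n = classes.size
    h = config.homophily
    theta = rng.lognormal(mean=0.0, sigma=config.degree_sigma, size=n)
    theta /= theta.mean()

    # calibrate the base rate so the expected mean degree matches, using the
    # closed-form block sums  sum_{i<j} theta_i theta_j m_ij
    total = 0.0
    cls_ids = np.arange(len(CLASS_ORDER))
    s = np.array([theta[classes == c].sum() for c in cls_ids])
    q = np.array([(theta[classes == c] ** 2).sum() for c in cls_ids])
    for a in cls_ids:
        for b in cls_ids[a:]:
            m = float(_pair_multiplier(np.array([a]), np.array([b]), h)[0])
            if a == b:
                total += m * (s[a] ** 2 - q[a]) / 2.0
            else:
                total += m * s[a] * s[b]
    p0 = config.mean_degree * n / 2.0 / total

    edges = []
    chunk = max(1, int(2e6 // max(n, 1)))
    for start in range(0, n - 1, chunk):
        stop = min(start + chunk, n - 1)
        rows = np.arange(start, stop)
        p = (p0 * theta[rows, None] * theta[None, :]
             * _pair_multiplier(classes[None, :], classes[rows, None], h))
        np.clip(p, 0.0, 1.0, out=p)
        mask = rng.random(p.shape) < p
        # keep only the strict upper triangle
        cols = np.arange(n)[None, :]
        mask &= cols > rows[:, None]
        r, c = np.nonzero(mask)
        edges.append(np.column_stack([rows[r], c]))
    return np.vstack(edges) if edges else np.empty((0, 2), dtype=int)


def generate_gene_assignments(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Gene/class/syndromic/band assignments only, without an interaction
    graph — cheap even at full catalogue scale."""
    return _assign_genes(config, np.random.default_rng(config.seed))


def gene_table_from_assignments(assignments: pd.DataFrame):
    """Parse an assignment frame into a :class:`~genegraph.io.GeneTable`."""
    from .io import GeneRecord, GeneTable
    return GeneTable(
        GeneRecord(row.symbol, row.band, CLASS_TO_SCORE[row.cls],
                   bool(row.syndromic))
        for row in assignments.rename(columns={"class": "cls"}).itertuples())


def generate_cohort(config: SyntheticCohortConfig, directory) -> SyntheticCohort:
    """Write the synthetic gene table, interaction table and truth files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genes = _assign_genes(config, rng)
    class_codes = np.array([CLASS_ORDER.index(c) for c in genes["class"]])
    edges = _sample_edges(class_codes, config, rng)

    symbols = genes["symbol"].to_numpy()
    human = pd.DataFrame({
        "interactor_a": symbols[edges[:, 0]],
        "interactor_b": symbols[edges[:, 1]],
        "species": "Homo sapiens",
    })
    n_decoy = int(round(config.nonhuman_fraction * len(human)))
    decoy_pairs = rng.integers(0, config.n_genes, size=(n_decoy, 2))
    decoy_pairs = decoy_pairs[decoy_pairs[:, 0] != decoy_pairs[:, 1]]
    decoys = pd.DataFrame({
        "interactor_a": symbols[decoy_pairs[:, 0]],
        "interactor_b": symbols[decoy_pairs[:, 1]],
        "species": rng.choice(NONHUMAN_SPECIES, size=len(decoy_pairs)),
    })
    interactions = pd.concat([human, decoys], ignore_index=True)
    interactions = interactions.iloc[rng.permutation(len(interactions))]

    gene_table = pd.DataFrame({
        "symbol": genes["symbol"],
        "chromosome_band": genes["band"],
        "gene_score": [
            "" if CLASS_TO_SCORE[c] is None else str(CLASS_TO_SCORE[c])
            for c in genes["class"]],
        "syndromic": genes["syndromic"],
    })

    gene_path = d / "genes.csv"
    inter_path = d / "interactions.tsv"
    truth_path = d / "truth.tsv"
    gene_table.to_csv(gene_path, index=False)
    interactions.to_csv(inter_path, sep="\t", index=False)
    genes.to_csv(truth_path, sep="\t", index=False)
    return SyntheticCohort(gene_path, inter_path, truth_path, genes, config)


def summarize_cohort(cohort: SyntheticCohort) -> dict:
    """Class counts, degree statistics, homophily estimate and band vocabulary."""
    table = read_gene_table(cohort.gene_table_path,
                            dialect={"band": "chromosome_band",
                                     "score": "gene_score"})
    records = read_interaction_table(
        cohort.interaction_table_path,
        dialect={"a": "interactor_a", "b": "interactor_b"})
    human = filter_human_interactions(records)

    truth = cohort.truth.set_index("symbol")
    classes = truth["class"]
    counts = classes.value_counts().to_dict()
    degree = pd.Series(0, index=truth.index)
    seen = set()
    for r in human:
        key = (min(r.a, r.b), max(r.a, r.b))
        if r.a == r.b or key in seen:
            continue
        seen.add(key)
        degree[r.a] += 1
        degree[r.b] += 1

    # empirical same-risk-class density vs background (pairs involving 'none')
    risk_n = {c: counts.get(c, 0) for c in RISK_CLASSES}
    within_pairs = sum(n * (n - 1) / 2 for n in risk_n.values())
    within_edges = sum(1 for a, b in seen
                       if classes[a] == classes[b] and classes[a] != "none")
    none_n = counts.get("none", 0)
    risk_total = sum(risk_n.values())
    bg_pairs = none_n * (none_n - 1) / 2 + none_n * risk_total
    bg_edges = sum(1 for a, b in seen
                   if classes[a] == "none" or classes[b] == "none")
    within_rate = within_edges / within_pairs if within_pairs else np.nan
    bg_rate = bg_edges / bg_pairs if bg_pairs else np.nan

    return {
        "n_genes": len(table),
        "class_counts": counts,
        "syndromic_count": int(truth["syndromic"].sum()),
        "n_interactions_total": len(records),
        "n_interactions_human": len(seen),
        "mean_degree": float(degree.mean()),
        "median_degree": float(degree.median()),
        "max_degree": int(degree.max()),
        "within_risk_class_rate": within_rate,
        "background_rate": bg_rate,
        "homophily_estimate": (within_rate / bg_rate
                               if bg_rate and not np.isnan(bg_rate) else np.nan),
        "band_vocabulary_size": len({b for r in table for b in r.bands}),
    }


def cohort_tasks_check(cohort: SyntheticCohort) -> dict:
    """Label counts per task as the classes the graph builder will assign."""
    truth = cohort.truth
    risk = (truth["class"] != "none").sum()
    return {
        "binary": {"No Risk": int(len(truth) - risk), "Risk": int(risk)},
        "multiclass": {
            TASK_CLASSES["multiclass"][0]: int((truth["class"] == "none").sum()),
            TASK_CLASSES["multiclass"][1]: int((truth["class"] == "low").sum()),
            TASK_CLASSES["multiclass"][2]: int((truth["class"] == "moderate").sum()),
            TASK_CLASSES["multiclass"][3]: int((truth["class"] == "high").sum()),
        },
        "syndromic": {
            "Non-Syndromic": int((truth["syndromic"] == 0).sum()),
            "Syndromic": int((truth["syndromic"] == 1).sum()),
        },
    }
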