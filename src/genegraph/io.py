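"""Parsing of gene-catalogue and interaction tables and assembly of the gene graph.

The analysis operates on a graph G = (V, E, C): nodes are genes appearing in a
protein-interaction network (PIN), edges are reported physical interactions,
node features are one-hot chromosome-band locations taken from a curated risk
catalogue (SFARI-style: gene symbol, band, confidence score 1-3, syndromic
flag), and C is a per-task label set.  Three labelling tasks are supported:

* ``binary``     — risk (gene present in the catalogue with a score) vs no risk
* ``multiclass`` — no / low / moderate / high association (score 3/2/1)
* ``syndromic``  — syndromic flag vs not
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

TASKS = ("binary", "multiclass", "syndromic")

#: class names per task, in label-index order (index 0 is the "background" class)
TASK_CLASSES = {
    "binary": ("No Risk", "Risk"),
    "multiclass": ("No Association", "Low Association",
                   "Moderate Association", "High Association"),
    "syndromic": ("Non-Syndromic", "Syndromic"),
}

#: catalogue confidence score -> multiclass label index (1 = most confident)
SCORE_TO_CLASS = {1: 3, 2: 2, 3: 1}

UNKNOWN_BAND = "<unknown>"

#: species annotations accepted as human by default (matched case-insensitively)
DEFAULT_HUMAN_TAGS = frozenset({"human", "homo sapiens", "9606"})

_BAND_SEPARATORS = str.maketrans({c: " " for c in ",;|/"})


class ConfigurationError(ValueError):
    """Raised when inputs or options cannot be interpreted."""


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    band: str = ""
    score: Optional[int] = None       # 1 (most confident) .. 3, or None
    syndromic: Optional[bool] = None

    def __post_init__(self):
        if not self.symbol:
            raise ValueError("gene symbol must be nonempty")
        if self.score is not None and self.score not in (1, 2, 3):
            raise ValueError(f"score must be in {{1,2,3}}, got {self.score!r}")

    @property
    def bands(self) -> tuple:
        """Normalised band tokens (genes can span several bands)."""
        return tuple(sorted({b for b in self.band.translate(_BAND_SEPARATORS)
                             .lower().split() if b}))


@dataclass(frozen=True)
class InteractionRecord:
    a: str
    b: str
    species: str = ""

    def __post_init__(self):
        if not self.a or not self.b:
            raise ValueError("both interactors must be nonempty")


class GeneTable:
    """Catalogue of :class:`GeneRecord`, unique by symbol."""

    def __init__(self, records: Iterable[GeneRecord]):
        self._records = {}
        for r in records:
            if r.symbol in self._records:
                raise ValueError(f"duplicate symbol {r.symbol!r}")
            self._records[r.symbol] = r

    def __len__(self):
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, symbol):
        return symbol in self._records

    def get(self, symbol: str) -> Optional[GeneRecord]:
        return self._records.get(symbol)

    @property
    def symbols(self) -> list:
        return list(self._records)


@dataclass(frozen=True)
class LabelScheme:
    task: str
    classes: tuple
    counts: Mapping[str, int]

    def __post_init__(self):
        if self.task not in TASKS:
            raise ConfigurationError(f"unknown task {self.task!r}")


@dataclass
class GeneGraph:
    """Node-indexed undirected gene-interaction graph with features and labels."""

    nodes: list                       # ordered gene symbols (0-based indexing)
    adjacency: sp.csr_array           # symmetric binary, zero diagonal
    features: sp.csr_array            # n_nodes x d band one-hot/multi-hot
    labels: np.ndarray                # int label per node for `task`
    task: str
    band_vocab: list = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def classes(self) -> tuple:
        return TASK_CLASSES[self.task]

    def label_scheme(self) -> LabelScheme:
        counts = {c: int((self.labels == i).sum())
                  for i, c in enumerate(self.classes)}
        return LabelScheme(self.task, self.classes, counts)

    def validate(self):
        a = self.adjacency
        if a.shape[0] != a.shape[1] or a.shape[0] != self.n_nodes:
            raise ValueError("adjacency shape does not match node count")
        if a.diagonal().sum() != 0:
            raise ValueError("adjacency has nonzero diagonal")
        if (a != a.T).nnz != 0:
            raise ValueError("adjacency is not symmetric")
        if self.features.shape[0] != self.n_nodes:
            raise ValueError("feature rows do not match node count")
        if self.labels.shape != (self.n_nodes,):
            raise ValueError("labels do not match node count")

    # -- serialisation --------------------------------------------------
    def save(self, directory) -> None:
        """Dump to edge-list TSV, node-table TSV and sparse-triplet features."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        coo = sp.triu(sp.coo_array(self.adjacency))
        pd.DataFrame({
            "a": [self.nodes[i] for i in coo.row],
            "b": [self.nodes[j] for j in coo.col],
        }).to_csv(d / "edges.tsv", sep="\t", index=False)
        pd.DataFrame({
            "symbol": self.nodes,
            "label": [self.classes[i] for i in self.labels],
        }).to_csv(d / "nodes.tsv", sep="\t", index=False)
        fc = sp.coo_array(self.features)
        pd.DataFrame({"row": fc.row, "col": fc.col, "value": fc.data}).to_csv(
            d / "features.tsv", sep="\t", index=False)
        pd.Series(self.band_vocab, name="band").to_csv(
            d / "band_vocab.tsv", sep="\t", index=False)
        (d / "task.txt").write_text(self.task + "\n")

    @classmethod
    def load(cls, directory) -> "GeneGraph":
        d = Path(directory)
        task = (d / "task.txt").read_text().strip()
        nodes_df = pd.read_csv(d / "nodes.tsv", sep="\t", dtype=str)
        nodes = nodes_df["symbol"].tolist()
        index = {s: i for i, s in enumerate(nodes)}
        classes = TASK_CLASSES[task]
        labels = np.array([classes.index(c) for c in nodes_df["label"]])
        edges = pd.read_csv(d / "edges.tsv", sep="\t", dtype=str)
        rows = edges["a"].map(index).to_numpy()
        cols = edges["b"].map(index).to_numpy()
        n = len(nodes)
        adj = sp.coo_array((np.ones(len(rows) * 2),
                            (np.r_[rows, cols], np.r_[cols, rows])),
                           shape=(n, n)).tocsr()
        adj.data[:] = 1.0
        vocab = pd.read_csv(d / "band_vocab.tsv", sep="\t", dtype=str)[
            "band"].fillna("").tolist()
        ft = pd.read_csv(d / "features.tsv", sep="\t")
        feats = sp.coo_array((ft["value"].to_numpy(float),
                              (ft["row"].to_numpy(int), ft["col"].to_numpy(int))),
                             shape=(n, len(vocab))).tocsr()
        return cls(nodes, adj, feats, labels, task, vocab)


# ---------------------------------------------------------------------------
# table readers
# ---------------------------------------------------------------------------

_GENE_COLUMNS = {"symbol": "symbol", "band": "band",
                 "score": "score", "syndromic": "syndromic"}
_INTERACTION_COLUMNS = {"a": "a", "b": "b", "species": "species"}


def _read_delimited(path) -> pd.DataFrame:
    """Read a CSV/TSV, autodetecting the delimiter."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str,
                       keep_default_na=False)


def _resolve(df: pd.DataFrame, defaults: Mapping[str, str],
             dialect: Optional[Mapping[str, str]], required: Sequence[str]):
    mapping = dict(defaults)
    if dialect:
        mapping.update(dialect)
    for canon in required:
        if mapping[canon] not in df.columns:
            raise ConfigurationError(
                f"required column {mapping[canon]!r} (for {canon!r}) not found; "
                f"available: {list(df.columns)}")
    return mapping


def _parse_score(raw: str, row: int, errors: list) -> Optional[int]:
    raw = raw.strip()
    if raw in ("", "na", "nan", "none", "NA", "None"):
        return None
    try:
        val = int(float(raw))
    except ValueError:
        errors.append(row)
        return None
    if val not in (1, 2, 3):
        errors.append(row)
        return None
    return val


_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f", ""}


def read_gene_table(path, dialect: Optional[Mapping[str, str]] = None) -> GeneTable:
    """Parse a risk-catalogue table into a :class:`GeneTable`.

    Duplicate symbols collapse to the record with the best (lowest) confidence
    score, with a logged warning; a present score beats an absent one.

    ``dialect`` maps the canonical names ``symbol``, ``band``, ``score`` and
    ``syndromic`` to the file's column headers.
    """
    df = _read_delimited(path)
    cols = _resolve(df, _GENE_COLUMNS, dialect, ["symbol", "band"])
    score_col = cols["score"] if cols["score"] in df.columns else None
    synd_col = cols["syndromic"] if cols["syndromic"] in df.columns else None

    bad_scores: list = []
    best: dict = {}
    for i, row in enumerate(df.itertuples(index=False, name=None)):
        row = dict(zip(df.columns, row))
        symbol = str(row[cols["symbol"]]).strip()
        if not symbol:
            continue
        score = _parse_score(str(row[score_col]), i, bad_scores) if score_col else None
        synd = None
        if synd_col is not None:
            sraw = str(row[synd_col]).strip().lower()
            if sraw in _TRUE:
                synd = True
            elif sraw in _FALSE:
                synd = False
        rec = GeneRecord(symbol, str(row[cols["band"]]).strip(), score, synd)
        prev = best.get(symbol)
        if prev is None:
            best[symbol] = rec
        else:
            logger.warning("duplicate symbol %s: keeping highest-confidence record",
                           symbol)
            prev_key = prev.score if prev.score is not None else 99
            new_key = rec.score if rec.score is not None else 99
            if new_key < prev_key:
                best[symbol] = rec
    if bad_scores:
        raise ValueError(
            f"unparseable confidence score in rows (0-based): {bad_scores}")
    return GeneTable(best.values())


def read_interaction_table(path, dialect: Optional[Mapping[str, str]] = None
                           ) -> list:
    """Parse an interaction table into ``InteractionRecord`` rows."""
    df = _read_delimited(path)
    cols = _resolve(df, _INTERACTION_COLUMNS, dialect, ["a", "b"])
    species_col = cols["species"] if cols["species"] in df.columns else None
    out = []
    for row in df.itertuples(index=False, name=None):
        row = dict(zip(df.columns, row))
        a, b = str(row[cols["a"]]).strip(), str(row[cols["b"]]).strip()
        if not a or not b:
            continue
        species = str(row[species_col]).strip() if species_col else ""
        out.append(InteractionRecord(a, b, species))
    return out


def filter_human_interactions(records: Sequence[InteractionRecord],
                              human_tags: Iterable[str] = DEFAULT_HUMAN_TAGS
                              ) -> list:
    """Keep only interactions annotated with a human species tag.

    Matching is case-insensitive on the trimmed annotation; order is preserved.
    """
    tags = {t.strip().lower() for t in human_tags}
    if not tags:
        raise ConfigurationError("human_tags must be nonempty")
    kept = [r for r in records if r.species.strip().lower() in tags]
    if not kept:
        warnings.warn("no interactions matched the human species tags")
    return kept


# ---------------------------------------------------------------------------
# featurisation and labelling
# ---------------------------------------------------------------------------

def band_vocabulary(genes: GeneTable) -> list:
    """Sorted distinct band tokens plus a reserved unknown category (last)."""
    vocab = sorted({b for rec in genes for b in rec.bands})
    return vocab + [UNKNOWN_BAND]


def encode_bands(genes: GeneTable, vocab: Optional[list] = None):
    """One-/multi-hot encode chromosome bands.

    Returns ``(features, vocab)`` where features is a sparse ``len(genes) x d``
    matrix.  Genes with no recorded band get the reserved unknown indicator.
    """
    if len(genes) == 0:
        raise ValueError("gene table is empty")
    if vocab is None:
        vocab = band_vocabulary(genes)
    index = {b: j for j, b in enumerate(vocab)}
    unknown = index[UNKNOWN_BAND]
    rows, cols = [], []
    for i, rec in enumerate(genes):
        bands = [index[b] for b in rec.bands if b in index]
        if not bands:
            bands = [unknown]
        rows.extend([i] * len(bands))
        cols.extend(bands)
    feats = sp.coo_array((np.ones(len(rows)), (rows, cols)),
                         shape=(len(genes), len(vocab))).tocsr()
    return feats, vocab


def label_for(record: Optional[GeneRecord], task: str) -> int:
    """Label index of a gene (``None`` = gene absent from the catalogue)."""
    if task == "binary":
        return int(record is not None and record.score is not None)
    if task == "multiclass":
        if record is None or record.score is None:
            return 0
        return SCORE_TO_CLASS[record.score]
    if task == "syndromic":
        return int(record is not None and bool(record.syndromic))
    raise ConfigurationError(f"unknown task {task!r}")


def make_labels(genes: GeneTable, task: str) -> LabelScheme:
    """Class counts over a gene table for one task."""
    classes = TASK_CLASSES.get(task)
    if classes is None:
        raise ConfigurationError(f"unknown task {task!r}")
    counts = dict.fromkeys(classes, 0)
    for rec in genes:
        counts[classes[label_for(rec, task)]] += 1
    nonzero = [c for c, n in counts.items() if n > 0]
    if len(nonzero) < 2:
        warnings.warn(f"task {task!r}: only one class present ({nonzero})")
    return LabelScheme(task, classes, counts)


def build_graph(genes: GeneTable, interactions: Sequence[InteractionRecord],
                task: str, include_isolated_catalogue_genes: bool = False
                ) -> GeneGraph:
    """Assemble the labelled, featurised gene graph.

    Nodes are the genes appearing in the (already human-filtered) interaction
    list; edges are deduplicated, self-interactions dropped, and the adjacency
    made symmetric.  Genes absent from the catalogue receive the background
    class and the unknown band.
    """
    if task not in TASKS:
        raise ConfigurationError(f"unknown task {task!r}")
    if not interactions:
        raise ValueError("empty interaction list: graph tasks are undefined")
    symbols = {s for r in interactions for s in (r.a, r.b)}
    if include_isolated_catalogue_genes:
        symbols |= set(genes.symbols)
    nodes = sorted(symbols)
    index = {s: i for i, s in enumerate(nodes)}
    n = len(nodes)

    pairs = {(min(index[r.a], index[r.b]), max(index[r.a], index[r.b]))
             for r in interactions if r.a != r.b}
    if pairs:
        rows, cols = map(np.array, zip(*pairs))
    else:
        rows = cols = np.array([], dtype=int)
    adj = sp.coo_array((np.ones(2 * len(rows)),
                        (np.r_[rows, cols], np.r_[cols, rows])),
                       shape=(n, n)).tocsr()
    adj.data[:] = 1.0

    vocab = band_vocabulary(genes)
    bidx = {b: j for j, b in enumerate(vocab)}
    unknown = bidx[UNKNOWN_BAND]
    frows, fcols = [], []
    labels = np.zeros(n, dtype=int)
    for i, s in enumerate(nodes):
        rec = genes.get(s)
        labels[i] = label_for(rec, task)
        bands = [bidx[b] for b in rec.bands] if rec is not None and rec.bands else []
        if not bands:
            bands = [unknown]
        frows.extend([i] * len(bands))
        fcols.extend(bands)
    feats = sp.coo_array((np.ones(len(frows)), (frows, fcols)),
                         shape=(n, len(vocab))).tocsr()
    return GeneGraph(nodes, adj, feats, labels, task, vocab)
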