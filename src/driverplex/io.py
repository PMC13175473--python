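"""File I/O and input alignment.

Readers for the package's plain-text interchange formats:

* edge lists — two whitespace- or tab-delimited columns, one edge per line,
  ``#`` comment lines skipped, optional header tolerated;
* a network manifest (YAML) listing per layer a path and a directed flag;
* feature tables — TSV with a header, first column the gene symbol;
* gene lists — one symbol per line.

Also the multi-omics feature construction: per cancer type three columns
(mutation frequency, mean tumor-normal methylation difference, mean log2
expression fold change), concatenated across cancer types and z-scored per
column over genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .graph import MultiplexGraph
from .universe import GeneUniverse

logger = logging.getLogger(__name__)


@dataclass
class EdgeList:
    """Cleaned edge set: no self-loops, no duplicate (source, target) pairs."""

    pairs: list[tuple[str, str]]
    directed: bool
    n_duplicates_dropped: int = 0
    n_self_loops_dropped: int = 0

    @property
    def symbols(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b in self.pairs:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)


def clean_edges(raw_pairs, directed: bool) -> EdgeList:
    """Drop self-loops and duplicates; for undirected input a pair is stored
    once in canonical (sorted) order and symmetrized when the adjacency is
    built."""
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[str, str]] = []
    dups = loops = 0
    for a, b in raw_pairs:
        if a == b:
            loops += 1
            continue
        key = (a, b) if directed else (min(a, b), max(a, b))
        if key in seen:
            dups += 1
            continue
        seen.add(key)
        pairs.append(key)
    if loops or dups:
        logger.info("edge cleaning: dropped %d self-loops, %d duplicates",
                    loops, dups)
    return EdgeList(pairs, directed, dups, loops)


def read_edge_list(path: str | Path, directed: bool) -> EdgeList:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = []
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            if first_data_line:
                first_data_line = False
                if cols[0].lower() in {"source", "from", "gene1"}:
                    continue
            raw.append((cols[0], cols[1]))
    return clean_edges(raw, directed)


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in edges.pairs:
            fh.write(f"{a}\t{b}\n")


def read_manifest(path: str | Path) -> list[tuple[Path, bool, str]]:
    """YAML manifest: list of {path, directed, name?} entries."""
    path = Path(path)
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    out = []
    for e in entries:
        p = Path(e["path"])
        if not p.is_absolute():
            p = path.parent / p
        out.append((p, bool(e["directed"]), str(e.get("name", p.stem))))
    return out


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """TSV with header; first column gene symbol, the rest numeric."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: feature table has no feature columns")
    return df.astype(float)


def read_gene_list(path: str | Path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


# -- alignment ----------------------------------------------------------

@dataclass
class AlignmentReport:
    dropped_edges: list[int] = field(default_factory=list)
    dropped_positives: list[str] = field(default_factory=list)


def align_to_universe(
    edge_lists: list[EdgeList],
    features: pd.DataFrame,
    positives: list[str] | None = None,
    layer_names: list[str] | None = None,
) -> tuple[MultiplexGraph, list[int], AlignmentReport]:
    """Align networks, features and labels to one shared gene universe.

    The universe is the feature-table gene set (features are mandatory for
    every node).  Edges touching genes outside the universe are dropped and
    counted; genes absent from a layer become isolated nodes there.  Known
    positives outside the universe are dropped with a warning.
    """
    universe = GeneUniverse(list(features.index.astype(str)))
    n = len(universe)
    report = AlignmentReport()

    network_genes = set()
    for el in edge_lists:
        network_genes.update(el.symbols)
    if not network_genes & set(universe.symbols):
        raise ValueError("no overlap between feature-table genes and any network")

    layers = []
    directed_flags = []
    for el in edge_lists:
        rows, cols = [], []
        dropped = 0
        for a, b in el.pairs:
            if a not in universe or b not in universe:
                dropped += 1
                continue
            i, j = universe.index[a], universe.index[b]
            rows.append(i)
            cols.append(j)
            if not el.directed:
                rows.append(j)
                cols.append(i)
        adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        adj.data[:] = 1.0  # undirected double entries collapse to 1
        adj.sum_duplicates()
        adj.data[:] = 1.0
        layers.append(adj)
        directed_flags.append(el.directed)
        report.dropped_edges.append(dropped)
        if dropped:
            logger.warning("dropped %d edges outside universe", dropped)

    pos_idx: list[int] = []
    for g in positives or []:
        if g in universe:
            pos_idx.append(universe.index[g])
        else:
            report.dropped_positives.append(g)
            logger.warning("positive gene %r not in universe; dropped", g)

    graph = MultiplexGraph(universe, layers, directed_flags,
                           features.to_numpy(dtype=np.float64),
                           layer_names or [])
    return graph, pos_idx, report


# -- omics feature construction ------------------------------------------

@dataclass
class OmicsTables:
    """Per-cancer-type omics inputs keyed by cancer type.

    mutation[ct]:    DataFrame indexed by gene with columns
                     ``snv_count`` (non-silent SNVs) and ``exon_length``.
    methylation[ct]: DataFrame indexed by gene, per-sample column pairs
                     ``tumor_<s>`` / ``normal_<s>``.
    expression[ct]:  same layout as methylation.
    """

    mutation: dict[str, pd.DataFrame]
    methylation: dict[str, pd.DataFrame]
    expression: dict[str, pd.DataFrame]


def zscore_columns(x: np.ndarray) -> np.ndarray:
    """Population z-score per column; constant columns become all-zero."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population (ddof=0)
    out = np.zeros_like(x, dtype=np.float64)
    nz = sd > 0
    out[:, nz] = (x[:, nz] - mu[nz]) / sd[nz]
    return out


def _paired(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    tcols = sorted(c for c in df.columns if c.startswith("tumor_"))
    ncols = ["normal_" + c[len("tumor_"):] for c in tcols]
    missing = [c for c in ncols if c not in df.columns]
    if missing:
        raise ValueError(f"unmatched tumor/normal sample columns: {missing}")
    return df[tcols].to_numpy(float), df[ncols].to_numpy(float)


def build_omics_features(tables: OmicsTables,
                         cancer_types: list[str]) -> pd.DataFrame:
    """Three feature columns per cancer type, z-scored over genes.

    mutation frequency  = non-silent SNV count / exonic length
    methylation feature = mean over samples of (tumor - normal)
    expression feature  = mean over samples of log2(tumor / normal)
    """
    if not cancer_types:
        raise ValueError("need at least one cancer type")
    genes = list(tables.mutation[cancer_types[0]].index)
    blocks, names = [], []
    for ct in cancer_types:
        mut = tables.mutation[ct].loc[genes]
        if (mut["exon_length"] <= 0).any():
            bad = mut.index[mut["exon_length"] <= 0][0]
            raise ValueError(f"gene {bad!r}: non-positive exonic length")
        freq = (mut["snv_count"] / mut["exon_length"]).to_numpy(float)

        tum, nrm = _paired(tables.methylation[ct].loc[genes])
        meth = (tum - nrm).mean(axis=1)

        tum, nrm = _paired(tables.expression[ct].loc[genes])
        if (tum <= 0).any() or (nrm <= 0).any():
            bad_row = np.argwhere((tum <= 0) | (nrm <= 0))[0, 0]
            raise ValueError(
                f"gene {genes[bad_row]!r}: non-positive expression value "
                "where a log2 ratio is required")
        expr = np.log2(tum / nrm).mean(axis=1)

        blocks.append(np.column_stack([freq, meth, expr]))
        names += [f"{ct}_mutfreq", f"{ct}_methdiff", f"{ct}_log2fc"]
    X = zscore_columns(np.hstack(blocks))
    return pd.DataFrame(X, index=genes, columns=names)
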