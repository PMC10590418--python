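"""Validated in-memory data model and on-disk formats.

Every other stage of the pipeline consumes the types defined here:

* :class:`CountTable` — an ASV × sample matrix of non-negative integer
  read counts (pandas DataFrame, ASVs as rows).
* :class:`SampleMetadata` — one row per sample: conditioning type
  (aquarium/reef), conditioning time in months, tank, tetrapod and
  tetrapod compartment (surface/crevice/bottom, or "pooled").
* :class:`TaxonomyTable` — a seven-rank lineage per ASV
  (domain..species), with missing ranks normalised to ``"unassigned"``.

The canonical on-disk format for tables is plain TSV; BIOM 1.0 (the JSON
dialect) is supported for count tables. Networks are written as GraphML
or as a source/target/weight/sign edge-list TSV.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNASSIGNED = "unassigned"
COMPARTMENTS = ("surface", "crevice", "bottom", "pooled")
CONDITIONINGS = ("aquarium", "reef")

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


class DataError(ValueError):
    """An in-memory table violates a domain invariant."""


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """ASV × sample matrix of non-negative integer read counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate ASV ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        try:
            mat = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric count cell: {exc}") from exc
        if not np.isfinite(mat).all():
            raise FormatError("non-finite count cell")
        if (mat < 0).any():
            r, c = np.argwhere(mat < 0)[0]
            raise FormatError(
                f"negative count for ASV {df.index[r]!r} in sample {df.columns[c]!r}"
            )
        if not np.allclose(mat, np.round(mat)):
            r, c = np.argwhere(~np.isclose(mat, np.round(mat)))[0]
            raise FormatError(
                f"non-integer count for ASV {df.index[r]!r} in sample {df.columns[c]!r}"
            )
        self.counts = df.astype(np.int64)
        if self.counts.shape[1]:
            zero = self.counts.sum(axis=0) == 0
            if zero.any():
                raise DataError(
                    f"all-zero sample column(s): {list(self.counts.columns[zero])}"
                )

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def restrict(self, asv_ids=None, sample_ids=None) -> "CountTable":
        """Sub-table on the given ids (order preserved as given)."""
        df = self.counts
        if asv_ids is not None:
            missing = [a for a in asv_ids if a not in df.index]
            if missing:
                raise DataError(f"unknown ASV ids: {missing[:5]}")
            df = df.loc[list(asv_ids)]
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in df.columns]
            if missing:
                raise DataError(f"unknown sample ids: {missing[:5]}")
            df = df[list(sample_ids)]
        return CountTable(df.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.counts.equals(other.counts)


def read_count_table(path, format: str | None = None) -> CountTable:
    """Read a count table from TSV (ASV rows, sample columns) or BIOM 1.0 JSON."""
    path = Path(path)
    if format is None:
        format = "biom" if path.suffix == ".biom" else "tsv"
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # malformed TSV
            raise FormatError(f"cannot parse count table {path}: {exc}") from exc
        return CountTable(df)
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown count-table format: {format!r}")


def write_count_table(table: CountTable, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "biom" if path.suffix == ".biom" else "tsv"
    if format == "tsv":
        table.counts.rename_axis("asv_id").to_csv(path, sep="\t")
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise ValueError(f"unknown count-table format: {format!r}")


def _read_biom(path: Path) -> CountTable:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"not a BIOM 1.0 JSON file: {path}") from exc
    try:
        n_rows, n_cols = doc["shape"]
        rows = [r["id"] for r in doc["rows"]]
        cols = [c["id"] for c in doc["columns"]]
        mat = np.zeros((n_rows, n_cols))
        if doc.get("matrix_type", "sparse") == "dense":
            mat[:] = np.asarray(doc["data"], dtype=float)
        else:
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
    except (KeyError, TypeError, ValueError, IndexError) as exc:
        raise FormatError(f"malformed BIOM file {path}: {exc}") from exc
    return CountTable(pd.DataFrame(mat, index=rows, columns=cols))


def _write_biom(table: CountTable, path: Path) -> None:
    mat = table.matrix
    nz = np.argwhere(mat != 0)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "settlenet",
        "date": datetime.now(timezone.utc).isoformat(),
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": list(mat.shape),
        "rows": [{"id": str(a), "metadata": None} for a in table.asv_ids],
        "columns": [{"id": str(s), "metadata": None} for s in table.sample_ids],
        "data": [[int(i), int(j), int(mat[i, j])] for i, j in nz],
    }
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------

_META_COLS = ("sample_id", "conditioning", "time_months", "tank_id", "tetrapod_id", "compartment")


@dataclass
class SampleMetadata:
    """Per-sample experimental design: conditioning, time, tank, tetrapod, compartment."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _META_COLS if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing column(s): {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate metadata rows for sample(s): {dups}")
        bad = set(df["conditioning"]) - set(CONDITIONINGS)
        if bad:
            raise FormatError(f"unknown conditioning value(s): {sorted(bad)}")
        bad = set(df["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise FormatError(f"unknown compartment value(s): {sorted(bad)}")
        times = set(int(t) for t in df["time_months"])
        if not times <= {0, 1, 2, 3}:
            raise FormatError(f"time_months outside 0..3: {sorted(times - {0, 1, 2, 3})}")
        self.table = df.reset_index(drop=True)

    def for_samples(self, sample_ids) -> pd.DataFrame:
        """Metadata rows for the given samples, in that order; all must be present."""
        idx = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in idx.index]
        if missing:
            raise DataError(f"sample(s) without metadata: {missing[:5]}")
        return idx.loc[list(sample_ids)].reset_index()

    def validate_against(self, table: CountTable) -> None:
        self.for_samples(table.sample_ids)


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                                             "tank_id": str,
                                                             "tetrapod_id": str}))


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TaxonomyTable
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyTable:
    """ASV → seven-rank lineage (domain..species); empty ranks are "unassigned"."""

    table: pd.DataFrame  # index asv_id, columns RANKS

    def __post_init__(self) -> None:
        df = self.table
        if list(df.columns) != list(RANKS):
            raise FormatError(f"taxonomy columns must be {RANKS}, got {list(df.columns)}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxonomy rows for ASV(s): {dups}")
        self.table = df.fillna(UNASSIGNED)

    def lineage(self, asv_id: str) -> tuple[str, ...]:
        if asv_id not in self.table.index:
            raise DataError(f"no taxonomy entry for ASV {asv_id!r}")
        return tuple(self.table.loc[asv_id])

    def rank_of(self, asv_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.lineage(asv_id)[RANKS.index(rank)]


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a semicolon lineage into 7 ranks; both ``f__Foo`` and bare ``Foo`` accepted."""
    fields = [f.strip() for f in lineage.split(";")] if lineage.strip() else []
    if len(fields) > len(RANKS):
        raise FormatError(f"lineage has {len(fields)} fields (max {len(RANKS)}): {lineage!r}")
    out = []
    for f in fields:
        f = _RANK_PREFIX.sub("", f).strip()
        out.append(f if f else UNASSIGNED)
    out.extend([UNASSIGNED] * (len(RANKS) - len(out)))
    return tuple(out)


def read_taxonomy(path) -> TaxonomyTable:
    """Read a two-column TSV: asv_id, semicolon-delimited lineage (QIIME2-style)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["asv_id", "lineage"],
                     dtype=str, skiprows=_taxonomy_skiprows(path))
    rows = {r.asv_id: parse_lineage(r.lineage if isinstance(r.lineage, str) else "")
            for r in df.itertuples()}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    return TaxonomyTable(out)


def _taxonomy_skiprows(path) -> int:
    first = Path(path).read_text().splitlines()[:1]
    if first and first[0].lower().startswith(("feature id", "asv_id", "#otu")):
        return 1
    return 0


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    lines = []
    for asv_id, row in tax.table.iterrows():
        ranks = [f"{r[0]}__{v}" if v != UNASSIGNED else "" for r, v in zip(RANKS, row)]
        while ranks and ranks[-1] == "":
            ranks.pop()
        lines.append(f"{asv_id}\t{';'.join(ranks)}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def write_network(network: nx.Graph, path, format: str | None = None) -> None:
    """Write a network as GraphML (all attributes) or edge-list TSV.

    The TSV has columns source, target, weight, sign; GraphML preserves every
    scalar node/edge attribute.
    """
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix == ".graphml" else "edge_tsv"
    if format == "graphml":
        for _, _, d in network.edges(data=True):
            for k, v in d.items():
                if not isinstance(v, (str, int, float, bool, np.integer, np.floating)):
                    raise FormatError(f"unserialisable edge attribute {k}={v!r}")
        nx.write_graphml(network, path)
    elif format == "edge_tsv":
        rows = []
        for u, v, d in network.edges(data=True):
            w = float(d.get("weight", 1.0))
            rows.append((u, v, w, int(np.sign(w)) or 1))
        pd.DataFrame(rows, columns=["source", "target", "weight", "sign"]).to_csv(
            path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path, format: str | None = None) -> nx.Graph:
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix == ".graphml" else "edge_tsv"
    if format == "graphml":
        g = nx.read_graphml(path)
        return nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        g = nx.Graph()
        for r in df.itertuples():
            g.add_edge(r.source, r.target, weight=float(r.weight), sign=int(r.sign))
        return g
    raise ValueError(f"unknown network format: {format!r}")


# ---------------------------------------------------------------------------
# Settlement counts
# ---------------------------------------------------------------------------


def read_settlement_counts(path) -> pd.DataFrame:
    """TSV with columns tetrapod_id, tank_id, settled (integer larvae counts)."""
    df = pd.read_csv(path, sep="\t", dtype={"tetrapod_id": str, "tank_id": str})
    for col in ("tetrapod_id", "tank_id", "settled"):
        if col not in df.columns:
            raise FormatError(f"settlement table missing column {col!r}")
    if (df["settled"] < 0).any():
        bad = df.loc[df["settled"] < 0, "tetrapod_id"].tolist()
        raise FormatError(f"negative settled count for tetrapod(s): {bad}")
    return df


def write_settlement_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
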