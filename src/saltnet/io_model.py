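"""Domain types and tabular I/O shared by every analysis stage.

The package works on four aligned tables:

* a gene x sample integer count matrix (RNA-seq quantification),
* a gene x sample TPM matrix on the same samples,
* a metabolite x sample matrix of log-transformed intensities,
* a sample sheet assigning ecotype, treatment (``control``/``salt``),
  time point and batch/replicate to every sample.

All matrices are feature x sample.  Sample order of a matrix must match its
sample sheet; :func:`align_check` is called by every cross-table computation.
Time is treated as an unordered factor with a declared level ordering (the
first declared level is the baseline, "time 0"); a numeric annotation can be
carried separately for plotting but plays no role in modelling.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("saltnet")

SAMPLE_SHEET_COLUMNS = ("sample_id", "ecotype", "treatment", "time", "batch")

MatrixKind = Literal["counts", "tpm", "metabolite"]


class SaltnetError(ValueError):
    """Base class for input-contract violations."""


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample factor assignment with declared level orderings.

    Levels are ordered by first appearance unless an explicit ordering is
    given.  The baseline time is the first time level (by default the
    minimum in declaration order), playing the role of "time 0".
    """

    table: pd.DataFrame = field(repr=False)
    baseline_time: str = ""

    def __post_init__(self) -> None:
        tbl = self.table
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in tbl.columns]
        if missing:
            raise SaltnetError(f"sample sheet missing column(s): {missing}")
        dup = tbl["sample_id"][tbl["sample_id"].duplicated()].tolist()
        if dup:
            raise SaltnetError(f"duplicate sample_id(s): {dup}")
        if tbl["treatment"].nunique() < 2:
            raise SaltnetError("sample sheet must declare at least 2 treatment levels")
        tbl = tbl.copy()
        for col in ("ecotype", "treatment", "time", "batch"):
            if not isinstance(tbl[col].dtype, pd.CategoricalDtype):
                levels = list(pd.unique(tbl[col].astype(str)))
                tbl[col] = pd.Categorical(tbl[col].astype(str), categories=levels)
        object.__setattr__(self, "table", tbl.reset_index(drop=True))
        if not self.baseline_time:
            object.__setattr__(self, "baseline_time", str(self.time_levels[0]))
        elif self.baseline_time not in self.time_levels:
            raise SaltnetError(
                f"baseline time {self.baseline_time!r} not a declared time level"
            )

    # -- convenience accessors ------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].astype(str).tolist()

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def ecotype_levels(self) -> list[str]:
        return list(self.table["ecotype"].cat.categories)

    @property
    def treatment_levels(self) -> list[str]:
        return list(self.table["treatment"].cat.categories)

    @property
    def time_levels(self) -> list[str]:
        return list(self.table["time"].cat.categories)

    @property
    def batch_levels(self) -> list[str]:
        return list(self.table["batch"].cat.categories)

    def subset(self, mask: Sequence[bool] | np.ndarray) -> "SampleSheet":
        """Row subset; unused levels are dropped so designs stay full rank."""
        sub = self.table.loc[np.asarray(mask, dtype=bool)].copy()
        for col in ("ecotype", "treatment", "time", "batch"):
            sub[col] = sub[col].cat.remove_unused_categories()
        baseline = self.baseline_time
        if baseline not in list(sub["time"].cat.categories):
            baseline = ""
        return SampleSheet(sub.reset_index(drop=True), baseline_time=baseline)

    def subset_ecotype(self, ecotype: str) -> "SampleSheet":
        if ecotype not in self.ecotype_levels:
            raise SaltnetError(f"unknown ecotype {ecotype!r}")
        return self.subset((self.table["ecotype"] == ecotype).to_numpy())


def read_sample_sheet(path: str | Path, baseline_time: str = "") -> SampleSheet:
    """Read a TSV/CSV sample sheet (columns sample_id, ecotype, treatment,
    time, batch).  Baseline time defaults to the first declared time level."""
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    return SampleSheet(df, baseline_time=baseline_time)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureMatrix:
    """A feature x sample numeric matrix with ordered string indices."""

    data: pd.DataFrame = field(repr=False)
    kind: str = "generic"

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].tolist()
            raise SaltnetError(f"duplicate feature id(s): {dup}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()].tolist()
            raise SaltnetError(f"duplicate sample id(s): {dup}")
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = _first_non_numeric(df)
            raise SaltnetError(f"non-numeric value at {bad}")
        if not np.isfinite(vals).all():
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise SaltnetError(
                f"non-finite value at row {df.index[r]!r}, column {df.columns[c]!r}"
            )

    @property
    def features(self) -> list[str]:
        return self.data.index.astype(str).tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.astype(str).tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_features(self, ids: Iterable[str]) -> "FeatureMatrix":
        ids = list(ids)
        missing = set(ids) - set(self.features)
        if missing:
            raise SaltnetError(f"unknown feature id(s): {sorted(missing)[:5]}")
        return dataclasses.replace(self, data=self.data.loc[ids])

    def subset_samples(self, mask: Sequence[bool] | np.ndarray) -> "FeatureMatrix":
        return dataclasses.replace(
            self, data=self.data.loc[:, np.asarray(mask, dtype=bool)]
        )


@dataclass(frozen=True)
class CountMatrix(FeatureMatrix):
    kind: str = "counts"

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.data.to_numpy()
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise SaltnetError(
                f"negative count at row {self.data.index[r]!r}, "
                f"column {self.data.columns[c]!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            r, c = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
            raise SaltnetError(
                f"non-integer count at row {self.data.index[r]!r}, "
                f"column {self.data.columns[c]!r}"
            )
        object.__setattr__(self, "data", self.data.astype(np.int64))

    @property
    def genes(self) -> list[str]:
        return self.features


@dataclass(frozen=True)
class TpmMatrix(FeatureMatrix):
    kind: str = "tpm"

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.data.to_numpy()
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise SaltnetError(
                f"negative TPM at row {self.data.index[r]!r}, "
                f"column {self.data.columns[c]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return self.features


@dataclass(frozen=True)
class MetaboliteMatrix(FeatureMatrix):
    kind: str = "metabolite"

    @property
    def metabolites(self) -> list[str]:
        return self.features


_KIND_MAP = {"counts": CountMatrix, "tpm": TpmMatrix, "metabolite": MetaboliteMatrix}


def read_matrix(path: str | Path, kind: MatrixKind, sep: str | None = None):
    """Read a feature x sample TSV/CSV matrix (header row = sample ids,
    first column = feature ids) into the typed container for ``kind``."""
    if kind not in _KIND_MAP:
        raise SaltnetError(f"unknown matrix kind {kind!r}")
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise SaltnetError(
                f"non-numeric value in column {col!r}, row {bad_rows[0]!r}"
            )
    if df.isna().any().any():
        col = df.columns[df.isna().any().to_numpy()][0]
        row = df.index[df[col].isna()][0]
        raise SaltnetError(f"missing value at row {row!r}, column {col!r}")
    return _KIND_MAP[kind](df)


def write_matrix(
    mat: FeatureMatrix, path: str | Path, float_format: str | None = None
) -> None:
    """TSV export; default float formatting is the shortest round-trippable
    representation, so write-then-read is bitwise identity."""
    mat.data.to_csv(path, sep="\t", float_format=float_format)


def align_check(mat: FeatureMatrix, sheet: SampleSheet) -> None:
    """Require matrix sample order to equal the sheet order exactly."""
    if mat.samples != sheet.sample_ids:
        raise SaltnetError(
            "sample ids/order of matrix do not match the sample sheet "
            f"(matrix starts {mat.samples[:3]}, sheet starts {sheet.sample_ids[:3]})"
        )


# ---------------------------------------------------------------------------
# regulatory network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkEdge:
    gene: str
    metabolite: str
    frequency: float
    mean_r: float


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Bipartite gene-metabolite network with hub annotation.

    Edges carry the selection frequency over resampled LASSO models
    (must exceed 1/2) and the metabolite's mean test-set correlation.
    Hubs are genes linked to at least ``hub_degree`` metabolites.
    """

    edges: tuple[NetworkEdge, ...]
    hub_degree: int = 5

    def __post_init__(self) -> None:
        for e in self.edges:
            if not (0.5 < e.frequency <= 1.0):
                raise SaltnetError(
                    f"edge {e.gene}-{e.metabolite} frequency {e.frequency} "
                    "outside (0.5, 1]"
                )

    @property
    def gene_nodes(self) -> list[str]:
        return sorted({e.gene for e in self.edges})

    @property
    def metabolite_nodes(self) -> list[str]:
        return sorted({e.metabolite for e in self.edges})

    @property
    def hubs(self) -> list[str]:
        deg: dict[str, int] = {}
        for e in self.edges:
            deg[e.gene] = deg.get(e.gene, 0) + 1
        return sorted(g for g, d in deg.items() if d >= self.hub_degree)

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.gene, e.metabolite) for e in self.edges}

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        hubs = set(self.hubs)
        for m in self.metabolite_nodes:
            g.add_node(m, type="metabolite")
        for gene in self.gene_nodes:
            g.add_node(gene, type="gene", hub=gene in hubs)
        for e in self.edges:
            g.add_edge(e.gene, e.metabolite, frequency=e.frequency, mean_r=e.mean_r)
        return g


def write_network(
    net: RegulatoryNetwork,
    path: str | Path,
    fmt: Literal["tsv", "graphml"] = "tsv",
) -> None:
    """Export the network as an edge-list TSV or GraphML; an empty network
    yields a valid header-only file."""
    path = Path(path)
    if fmt == "tsv":
        rows = [
            {
                "gene": e.gene,
                "metabolite": e.metabolite,
                "frequency": e.frequency,
                "mean_r": e.mean_r,
            }
            for e in sorted(net.edges, key=lambda e: (e.metabolite, e.gene))
        ]
        df = pd.DataFrame(rows, columns=["gene", "metabolite", "frequency", "mean_r"])
        write_results_table(df, path)
    elif fmt == "graphml":
        nx.write_graphml(net.to_graph(), path)
    else:
        raise SaltnetError(f"unknown network format {fmt!r}")


def read_network(
    path: str | Path,
    fmt: Literal["tsv", "graphml"] = "tsv",
    hub_degree: int = 5,
) -> RegulatoryNetwork:
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "metabolite": str})
        edges = tuple(
            NetworkEdge(r.gene, r.metabolite, float(r.frequency), float(r.mean_r))
            for r in df.itertuples()
        )
    elif fmt == "graphml":
        g = nx.read_graphml(path)
        edges = []
        for u, v, attrs in g.edges(data=True):
            if g.nodes[u].get("type") == "gene":
                gene, met = u, v
            else:
                gene, met = v, u
            edges.append(
                NetworkEdge(gene, met, float(attrs["frequency"]), float(attrs["mean_r"]))
            )
        edges = tuple(sorted(edges, key=lambda e: (e.metabolite, e.gene)))
    else:
        raise SaltnetError(f"unknown network format {fmt!r}")
    return RegulatoryNetwork(edges, hub_degree=hub_degree)


# ---------------------------------------------------------------------------
# result tables & run metadata
# ---------------------------------------------------------------------------


def write_results_table(
    df: pd.DataFrame, path: str | Path, sig_digits: int = 6
) -> None:
    """Deterministic TSV export: fixed column order (as given), floats in
    %.{sig}g format so extreme p-values survive the round trip."""
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{sig_digits}g")


def write_run_metadata(path: str | Path, **fields) -> None:
    """JSON run manifest (seed, thresholds, versions...)."""
    meta = dict(fields)
    meta.setdefault("package", "saltnet")
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _sniff_sep(path: str | Path) -> str:
    """Delimiter auto-detection: tab wins if present in the header line."""
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _first_non_numeric(df: pd.DataFrame) -> str:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            return f"row {bad[0]!r}, column {col!r}"
    return "unknown cell"


def configure_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.WARNING if quiet else (logging.DEBUG if verbose else logging.INFO)
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )
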