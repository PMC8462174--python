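"""Tabular data model and validated I/O.

All pipeline inputs are delimited text (comma separated, UTF-8, header row,
``.`` decimal separator): a fuzzy-coded trait table (species rows x
trait-modality columns), an abundance table, an environment table and a
function table (sample rows x variable columns).  Missing cells are hard
errors, never imputed: the sampling designs this pipeline targets are
complete, and silent imputation would corrupt cooccurrence counts.

Networks (trait networks and the final multifunctionality network) are
exported as GraphML, GEXF (both Gephi-compatible) or a plain edge CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mfnet")

SAMPLE_KINDS = ("abundance", "environment", "function")
NETWORK_FORMATS = ("graphml", "gexf", "edge_csv")


class ValidationError(ValueError):
    """Raised when an input table violates the data model."""


@dataclass
class FuzzyTraitTable:
    """Species x trait-modality affinity matrix, fuzzy coded.

    Fuzzy coding assigns each species proportional affinity scores over the
    modalities of each trait category (e.g. the levels of "feeding mode").
    Scores are non-negative; after :meth:`normalize`, scores within each
    (species, category) block sum to 1 or are all zero.  A species may
    appear as several size-class rows (e.g. ``Austrovenus_10mm``).
    """

    species_ids: list[str]
    modality_ids: list[str]
    category_of_modality: dict[str, str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.species_ids), len(self.modality_ids)):
            raise ValidationError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.modality_ids)} modalities"
            )
        dupes = _duplicates(self.species_ids)
        if dupes:
            raise ValidationError(f"duplicate species ids: {sorted(dupes)}")
        dupes = _duplicates(self.modality_ids)
        if dupes:
            raise ValidationError(f"duplicate modality ids: {sorted(dupes)}")
        missing = [m for m in self.modality_ids if m not in self.category_of_modality]
        if missing:
            raise ValidationError(f"modalities missing from category map: {missing}")
        if np.any(self.scores < 0):
            i, j = np.argwhere(self.scores < 0)[0]
            raise ValidationError(
                f"negative trait score at species {self.species_ids[i]!r}, "
                f"modality {self.modality_ids[j]!r}"
            )
        if np.any(~np.isfinite(self.scores)):
            raise ValidationError("non-finite trait score")

    @property
    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.modality_ids:
            seen.setdefault(self.category_of_modality[m], None)
        return list(seen)

    def category_columns(self, category: str) -> list[int]:
        return [
            j for j, m in enumerate(self.modality_ids)
            if self.category_of_modality[m] == category
        ]

    def normalize(self) -> "FuzzyTraitTable":
        """Divide each (species, category) block by its sum.

        Blocks summing to zero are left at zero and logged; the operation is
        idempotent.
        """
        scores = self.scores.copy()
        for cat in self.categories:
            cols = self.category_columns(cat)
            block = scores[:, cols]
            sums = block.sum(axis=1)
            zero = sums == 0
            if np.any(zero):
                for i in np.flatnonzero(zero):
                    logger.warning(
                        "species %s has all-zero scores in category %s",
                        self.species_ids[i], cat,
                    )
            safe = np.where(zero, 1.0, sums)
            scores[:, cols] = block / safe[:, None]
        return FuzzyTraitTable(
            list(self.species_ids), list(self.modality_ids),
            dict(self.category_of_modality), scores,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.species_ids, columns=self.modality_ids)


@dataclass
class SampleMatrix:
    """Sample x variable matrix of one of three kinds.

    ``abundance`` holds non-negative species counts, ``environment`` holds
    sediment/habitat characteristics (e.g. %mud, %SOM), ``function`` holds
    ecosystem-function indicators (fluxes, chlorophyll a, degradation rates).
    """

    sample_ids: list[str]
    variable_ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in SAMPLE_KINDS:
            raise ValidationError(f"kind must be one of {SAMPLE_KINDS}, got {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.variable_ids)):
            raise ValidationError("value matrix shape does not match ids")
        if len(self.sample_ids) == 0:
            raise ValidationError("no samples")
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise ValidationError(f"duplicate sample ids: {sorted(dupes)}")
        dupes = _duplicates(self.variable_ids)
        if dupes:
            raise ValidationError(f"duplicate variable ids: {sorted(dupes)}")
        if np.any(~np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"missing or non-finite value at sample {self.sample_ids[i]!r}, "
                f"variable {self.variable_ids[j]!r}"
            )
        if self.kind == "abundance" and np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"species {self.variable_ids[j]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.variable_ids)

    def column(self, variable: str) -> np.ndarray:
        try:
            j = self.variable_ids.index(variable)
        except ValueError:
            raise KeyError(f"unknown variable {variable!r}") from None
        return self.values[:, j]


@dataclass
class RunConfig:
    """Every tunable knob of the pipeline, serialized to the run log.

    alpha
        One-sided significance level for positive trait cooccurrence and for
        permutation tests in the selection stages.
    min_expected
        Pairs whose expected shared-modality count falls below this are not
        tested (conventional filter of the probabilistic cooccurrence model);
        0 disables it.
    binarize_threshold
        Fuzzy affinity strictly above this counts as trait possession.
    resolution, louvain_restarts, seed
        Modularity clustering controls; the best-modularity partition over
        ``louvain_restarts`` seeded runs is kept.
    n_permutations
        Permutations for sequential pseudo-F tests.
    transform_family
        Second predictor transform alongside raw and log10(x+1): ``square``
        (x^2, approximating a two-degree polynomial together with raw) or
        ``sqrt``.
    transform_constraint
        ``strict``: a log column may be selected only while no raw/square
        column of the same base variable is in the model, and vice versa;
        ``lenient``: no admissibility restriction.
    min_cluster_size
        Trait clusters with fewer members are excluded before aggregation
        (drops singleton isolates such as species sharing no traits).
    significance_rule
        ``selected_and_p``: a predictor counts as significant if selected by
        adjusted R^2 AND its sequential permutation p <= alpha;
        ``selected``: selection alone suffices.
    """

    alpha: float = 0.05
    min_expected: float = 1.0
    binarize_threshold: float = 0.0
    resolution: float = 1.0
    louvain_restarts: int = 20
    seed: int = 0
    n_permutations: int = 9999
    transform_family: str = "square"
    transform_constraint: str = "strict"
    min_cluster_size: int = 2
    significance_rule: str = "selected_and_p"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.louvain_restarts < 1:
            raise ValidationError("louvain_restarts must be >= 1")
        if self.transform_family not in ("square", "sqrt"):
            raise ValidationError("transform_family must be 'square' or 'sqrt'")
        if self.transform_constraint not in ("strict", "lenient"):
            raise ValidationError("transform_constraint must be 'strict' or 'lenient'")
        if self.significance_rule not in ("selected", "selected_and_p"):
            raise ValidationError("significance_rule must be 'selected' or 'selected_and_p'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(load_config_mapping(path))


def load_config_mapping(path: str | Path) -> dict:
    """Load a YAML or JSON mapping from *path*."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} does not contain a mapping")
    return data


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _read_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_fuzzy_traits(
    path: str | Path,
    category_map: Mapping[str, str],
    normalize: bool = True,
) -> FuzzyTraitTable:
    """Read a fuzzy-coded trait table from CSV.

    First column species id, remaining columns numeric modality scores.
    Per-(species, category) normalization is applied unless disabled.
    """
    df = _read_csv(path)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValidationError(
                f"non-numeric trait score in column {col!r}, species {bad.index[0]!r}"
            )
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValidationError(
            f"missing trait score at species {df.index[i]!r}, modality {df.columns[j]!r}"
        )
    missing = [m for m in df.columns if m not in category_map]
    if missing:
        raise ValidationError(f"modalities missing from category map: {missing}")
    table = FuzzyTraitTable(
        species_ids=list(df.index),
        modality_ids=list(df.columns),
        category_of_modality={m: category_map[m] for m in df.columns},
        scores=df.to_numpy(dtype=float),
    )
    return table.normalize() if normalize else table


def read_category_map(path: str | Path) -> dict[str, str]:
    """Read a two-column CSV ``modality,category``."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError("category map needs columns: modality, category")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_sample_matrix(path: str | Path, kind: str) -> SampleMatrix:
    """Read a sample x variable CSV of the declared *kind*."""
    df = _read_csv(path)
    if df.shape[0] == 0:
        raise ValidationError("no samples")
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.any(np.isnan(arr)):
        i, j = np.argwhere(np.isnan(arr))[0]
        raise ValidationError(
            f"empty or non-numeric cell at sample {df.index[i]!r}, "
            f"variable {df.columns[j]!r}"
        )
    return SampleMatrix(list(df.index), list(df.columns), arr, kind)


def write_sample_matrix(mat: SampleMatrix, path: str | Path) -> None:
    mat.to_frame().to_csv(path, index_label="sample")


# ---------------------------------------------------------------------------
# network I/O


def write_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a trait or multifunctionality network for external viewers.

    GraphML and GEXF are loadable by Gephi (edge attribute ``weight`` as
    double, node attributes ``size`` double and ``role`` string where
    present).  ``edge_csv`` writes ``source,target,weight,directed`` rows;
    isolated nodes get a row with empty target so the node set round-trips.
    """
    if format not in NETWORK_FORMATS:
        raise ValidationError(
            f"unknown network format {format!r}; supported: {NETWORK_FORMATS}"
        )
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "gexf":
        nx.write_gexf(net, path)
    else:
        directed = int(net.is_directed())
        rows = []
        for u, v, data in net.edges(data=True):
            w = float(data.get("weight", 1.0))
            rows.append(f"{u},{v},{w!r},{directed}")
        for node in net.nodes:
            if net.degree(node) == 0:
                rows.append(f"{node},,,{directed}")
        path.write_text("source,target,weight,directed\n" + "\n".join(rows) + "\n",
                        encoding="utf-8")


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a network previously written by :func:`write_network`."""
    if format not in NETWORK_FORMATS:
        raise ValidationError(
            f"unknown network format {format!r}; supported: {NETWORK_FORMATS}"
        )
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "gexf":
        return nx.read_gexf(path)
    lines = Path(path).read_text(encoding="utf-8").strip().splitlines()
    header, *rows = lines
    if header.strip() != "source,target,weight,directed":
        raise ValidationError("edge_csv header must be source,target,weight,directed")
    directed = any(r.rsplit(",", 1)[1] == "1" for r in rows) if rows else False
    net: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    for r in rows:
        source, target, weight, _ = r.split(",")
        if target == "":
            net.add_node(source)
        else:
            net.add_edge(source, target, weight=float(weight))
    return net
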