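"""Shared containers: entity indexes, labelled matrices, the disease DAG,
run configuration, and the heterogeneous network bundle.

All matrices are stored dense (numpy) with explicit name indexes; files on
disk always use names, never integer positions, so artifacts are
order-independent.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger("lncdis")

ENTITY_KINDS = ("lncRNA", "gene", "disease", "miRNA", "protein", "sample")


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


@dataclass(frozen=True)
class EntityIndex:
    """Ordered, unique identifiers for one entity kind.

    Names are sorted lexicographically on construction unless
    ``keep_order=True`` (an explicit order was supplied).
    """

    kind: str
    names: tuple[str, ...]
    _lookup: Mapping[str, int] = field(repr=False, compare=False, default=None)

    def __init__(self, kind: str, names: Iterable[str], keep_order: bool = False):
        if kind not in ENTITY_KINDS:
            raise ValidationError(f"unknown entity kind {kind!r}")
        names = list(names)
        if len(set(names)) != len(names):
            seen, dup = set(), None
            for nm in names:
                if nm in seen:
                    dup = nm
                    break
                seen.add(nm)
            raise ValidationError(f"duplicate identifier {dup!r} in {kind} index")
        if not keep_order:
            names = sorted(names)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "names", tuple(names))
        object.__setattr__(self, "_lookup", {n: i for i, n in enumerate(names)})

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._lookup

    def position(self, name: str) -> int:
        try:
            return self._lookup[name]
        except KeyError:
            raise KeyError(f"{name!r} not in {self.kind} index") from None


@dataclass
class LabeledMatrix:
    """Real-valued matrix with row/column entity indexes."""

    row_index: EntityIndex
    col_index: EntityIndex
    values: np.ndarray

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_index), len(self.col_index)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match indexes "
                f"({len(self.row_index)}, {len(self.col_index)})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "LabeledMatrix":
        return dataclasses.replace(self, values=self.values.copy())


class BinaryMatrix(LabeledMatrix):
    """0/1 matrix (interaction profiles and association matrices)."""

    def __post_init__(self):
        super().__post_init__()
        bad = ~np.isin(self.values, (0.0, 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"binary matrix contains non-0/1 value {self.values[i, j]!r} at "
                f"row {self.row_index.names[i]!r}, column {self.col_index.names[j]!r}"
            )


# Aliases matching their roles in the method.
BinaryProfileMatrix = BinaryMatrix
AssociationMatrix = BinaryMatrix


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over one entity index."""

    index: EntityIndex
    values: np.ndarray
    value_range: tuple[float, float] = (0.0, 1.0)
    kernel: bool = False  # kernel-type: diagonal must equal the range maximum

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=float)
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValidationError(f"similarity matrix must be {n}x{n}, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("similarity matrix is not symmetric (tol 1e-10)")
        if self.kernel and not np.allclose(np.diag(self.values), self.value_range[1], atol=1e-12):
            raise ValidationError("kernel similarity diagonal must equal the range maximum")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class DiseaseDAG:
    """Disease ontology as a child -> parent DAG.

    ``relation_weight`` maps a relation label (e.g. ``is_a``) to its
    semantic contribution factor in (0, 1).
    """

    graph: nx.DiGraph  # edges point child -> parent
    relation_weight: dict[str, float] = field(default_factory=lambda: {"is_a": 0.5})

    def __post_init__(self):
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValidationError(f"disease DAG contains a cycle: {cycle}")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def parents(self, term: str) -> list[tuple[str, float]]:
        out = []
        for _, parent, data in self.graph.out_edges(term, data=True):
            rel = data.get("relation", "is_a")
            out.append((parent, self.relation_weight.get(rel, 0.5)))
        return out

    def ancestors_closure(self, term: str) -> set[str]:
        return {term} | nx.descendants(self.graph, term)


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with the defaults used
    throughout the package."""

    # kernel bandwidth factors
    alpha_lnc_mirna: float = 0.5
    alpha_lnc_protein: float = 0.5
    alpha_dis_mirna: float = 0.5
    bandwidth_convention: str = "divide"  # {"divide", "multiply"}
    # diffusion
    restart_probability: float = 0.7
    rwr_tol: float = 1e-8
    rwr_max_iter: int = 10_000
    fusion: str = "cosine-concat"  # {"cosine-concat", "mean"}
    # embedding
    embed_dim: int = 64        # d: initial node representation size
    embed_dim_low: int = 32    # d_low: projected embedding size
    neighbor_norm: str = "row"  # {"row", "none"}
    # bilinear decoders
    mapping_rank: int | None = None  # q; defaults to embed_dim_low
    # optimisation
    learning_rate: float = 0.01
    max_iterations: int = 2000
    convergence_tol: float = 1e-6
    backtracking: bool = True
    negative_sampling_ratio: float = 1.0
    loss_mask: str = "sampled"  # {"sampled", "full"}
    # misc
    random_seed: int = 0

    def __post_init__(self):
        if not (0 < self.restart_probability <= 1):
            raise ValidationError("restart probability must lie in (0, 1]")
        for name in ("alpha_lnc_mirna", "alpha_lnc_protein", "alpha_dis_mirna"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must lie in (0, 1]")
        if self.bandwidth_convention not in ("divide", "multiply"):
            raise ValidationError("bandwidth_convention must be 'divide' or 'multiply'")
        if self.learning_rate <= 0 or self.max_iterations <= 0 or self.convergence_tol <= 0:
            raise ValidationError("learning_rate, max_iterations, convergence_tol must be positive")
        if self.embed_dim <= 0 or self.embed_dim_low <= 0:
            raise ValidationError("embedding dimensions must be positive")

    @property
    def q(self) -> int:
        return self.mapping_rank if self.mapping_rank is not None else self.embed_dim_low

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in d.items()})


@dataclass
class HeteroNetwork:
    """Everything the model consumes: the observed association matrices and
    the per-entity topological similarity matrices."""

    A: AssociationMatrix                  # lncRNA x disease
    LTS: SimilarityMatrix                 # lncRNA topological similarity
    DTS: SimilarityMatrix                 # disease topological similarity
    A_lg: AssociationMatrix | None = None  # lncRNA x gene
    A_gd: AssociationMatrix | None = None  # gene x disease

    def __post_init__(self):
        if self.A.row_index != self.LTS.index:
            raise ValidationError("A rows and LTS index disagree")
        if self.A.col_index != self.DTS.index:
            raise ValidationError("A columns and DTS index disagree")
        if (self.A_lg is None) != (self.A_gd is None):
            raise ValidationError("gene block requires both A_lg and A_gd (or neither)")
        if self.A_lg is not None:
            if self.A_lg.row_index != self.A.row_index:
                raise ValidationError("A_lg rows must match the lncRNA index")
            if self.A_gd.col_index != self.A.col_index:
                raise ValidationError("A_gd columns must match the disease index")
            if self.A_lg.col_index != self.A_gd.row_index:
                raise ValidationError("A_lg columns and A_gd rows disagree on the gene index")

    @property
    def lnc_index(self) -> EntityIndex:
        return self.A.row_index

    @property
    def dis_index(self) -> EntityIndex:
        return self.A.col_index

    @property
    def gene_index(self) -> EntityIndex | None:
        return None if self.A_lg is None else self.A_lg.col_index

    @property
    def has_genes(self) -> bool:
        return self.A_lg is not None

    def copy(self) -> "HeteroNetwork":
        return HeteroNetwork(
            A=self.A.copy(),
            LTS=dataclasses.replace(self.LTS, values=self.LTS.values.copy()),
            DTS=dataclasses.replace(self.DTS, values=self.DTS.values.copy()),
            A_lg=None if self.A_lg is None else self.A_lg.copy(),
            A_gd=None if self.A_gd is None else self.A_gd.copy(),
        )


def row_normalize(M: np.ndarray) -> np.ndarray:
    """Divide each row by its sum; zero rows stay zero."""
    M = np.asarray(M, dtype=float)
    s = M.sum(axis=1, keepdims=True)
    out = np.divide(M, s, out=np.zeros_like(M), where=s != 0)
    return out
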