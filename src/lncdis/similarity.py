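"""Base similarity networks.

Five networks feed the diffusion stage:

* ``LncSm1`` — biweight midcorrelation (bicor) of lncRNA expression profiles,
  a median/MAD-weighted correlation robust to outliers;
* ``LncSm2`` / ``LncSm3`` — Gaussian interaction profile (GIP) kernels on the
  binary lncRNA-miRNA and lncRNA-protein interaction profiles;
* ``DisSm1`` — Wang-measure semantic similarity over the disease ontology DAG;
* ``DisSm2`` — GIP kernel on the binary disease-miRNA profiles.

The GIP kernel between interaction profiles p_i, p_j is
``exp(-alpha * ||p_i - p_j||^2)`` with effective bandwidth
``alpha = alpha' / mean_i ||p_i||^2`` (bandwidth factor alpha' = 0.5 by
default). Normalising by the mean squared profile norm keeps the kernel
stable in the typical number of interaction partners; the literal
multiplicative form is available via ``convention="multiply"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    BinaryProfileMatrix,
    DiseaseDAG,
    EntityIndex,
    LabeledMatrix,
    SimilarityMatrix,
    ValidationError,
)

logger = logging.getLogger("lncdis")

BICOR_C = 9.0  # standard biweight tuning constant


@dataclass
class KernelBandwidth:
    """Effective GIP bandwidth derived from a profile matrix."""

    alpha: float
    alpha_prime: float
    mean_sq_norm: float


@dataclass
class SimilarityNetworkSet:
    """Named similarity matrices over one shared entity index."""

    kind: str
    members: dict[str, SimilarityMatrix] = field(default_factory=dict)

    def __post_init__(self):
        idx = None
        for name, sim in self.members.items():
            if idx is None:
                idx = sim.index
            elif sim.index != idx:
                raise ValidationError(f"member {name!r} has a different entity index")

    @property
    def index(self) -> EntityIndex:
        return next(iter(self.members.values())).index

    def __len__(self) -> int:
        return len(self.members)


def _biweights(x: np.ndarray) -> np.ndarray | None:
    """Langfelder-Horvath biweights; None signals MAD == 0 (Pearson fallback)."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    u = (x - med) / (BICOR_C * mad)
    w = np.zeros_like(u)
    inside = np.abs(u) < 1
    w[inside] = (1 - u[inside] ** 2) ** 2
    return (x - med) * w


def biweight_midcorrelation(x, y) -> float:
    """Biweight midcorrelation of two equal-length vectors, in [-1, 1].

    Falls back to the Pearson correlation (logged) for a vector whose median
    absolute deviation is zero, where the biweights are undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("bicor requires two equal-length vectors")
    if x.size < 3:
        raise ValidationError("bicor requires length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("bicor undefined for a constant vector")
    xt, yt = _biweights(x), _biweights(y)
    if xt is None or yt is None:
        logger.info("bicor: MAD=0, falling back to Pearson for this pair")
        xt = x - x.mean()
        yt = y - y.mean()
    denom = np.linalg.norm(xt) * np.linalg.norm(yt)
    if denom == 0:  # all weights vanished; degenerate, fall back to Pearson
        logger.info("bicor: degenerate biweights, falling back to Pearson")
        xt, yt = x - x.mean(), y - y.mean()
        denom = np.linalg.norm(xt) * np.linalg.norm(yt)
    return float(np.clip(xt @ yt / denom, -1.0, 1.0))


def bicor_network(expr: LabeledMatrix) -> SimilarityMatrix:
    """Pairwise bicor of expression rows -> the LncSm1 similarity network."""
    X = expr.values
    m, s = X.shape
    if s < 3:
        raise ValidationError("expression profiles need at least 3 samples")
    transformed = []
    for i in range(m):
        row = X[i]
        if np.ptp(row) == 0:
            raise ValidationError(
                f"constant expression profile for {expr.row_index.names[i]!r}"
            )
        t = _biweights(row)
        if t is None:
            logger.info(
                "bicor_network: MAD=0 for %s, Pearson fallback", expr.row_index.names[i]
            )
            t = row - row.mean()
        norm = np.linalg.norm(t)
        if norm == 0:
            t = row - row.mean()
            norm = np.linalg.norm(t)
        transformed.append(t / norm)
    T = np.vstack(transformed)
    S = np.clip(T @ T.T, -1.0, 1.0)
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(expr.row_index, S, value_range=(-1.0, 1.0))


def gip_bandwidth(
    profiles: BinaryProfileMatrix, alpha_prime: float = 0.5, convention: str = "divide"
) -> KernelBandwidth:
    """Effective bandwidth for the GIP kernel on a profile matrix."""
    P = profiles.values
    mean_sq_norm = float((P**2).sum(axis=1).mean())
    if mean_sq_norm == 0:
        raise ValidationError("kernel undefined: all interaction profiles are zero")
    if convention == "divide":
        alpha = alpha_prime / mean_sq_norm
    elif convention == "multiply":
        alpha = alpha_prime * mean_sq_norm
    else:
        raise ValidationError("convention must be 'divide' or 'multiply'")
    return KernelBandwidth(alpha=alpha, alpha_prime=alpha_prime, mean_sq_norm=mean_sq_norm)


def gip_kernel(profiles: BinaryProfileMatrix, bandwidth: KernelBandwidth) -> SimilarityMatrix:
    """GIP kernel similarity exp(-alpha * ||p_i - p_j||^2)."""
    P = profiles.values
    sq = (P**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * (P @ P.T)
    np.maximum(d2, 0.0, out=d2)
    S = np.exp(-bandwidth.alpha * d2)
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(profiles.row_index, S, value_range=(0.0, 1.0), kernel=True)


def _svalues(dag: DiseaseDAG, term: str) -> dict[str, float]:
    """Wang S-values of ``term`` over its ancestor closure.

    S(term) = 1; S(t) = max over children t' of t inside the closure of
    w(t'->t) * S(t'). Computed by a best-first relaxation (weights <= 1, so
    this is a shortest-path-style fixed point).
    """
    import heapq

    sval = {term: 1.0}
    heap = [(-1.0, term)]
    while heap:
        negv, t = heapq.heappop(heap)
        v = -negv
        if v < sval.get(t, 0.0):
            continue
        for parent, w in dag.parents(t):
            cand = v * w
            if cand > sval.get(parent, 0.0):
                sval[parent] = cand
                heapq.heappush(heap, (-cand, parent))
    return sval


def semantic_similarity(dag: DiseaseDAG, diseases: EntityIndex) -> SimilarityMatrix:
    """Wang DAG-based semantic similarity (DisSm1).

    sim(a, b) = sum over shared ancestors t of (S_a(t) + S_b(t)) divided by
    (SV(a) + SV(b)); self-similarity is exactly 1.
    """
    missing = [d for d in diseases.names if d not in dag.graph]
    if missing:
        raise ValidationError(f"diseases absent from the DAG: {missing}")
    svals = {d: _svalues(dag, d) for d in diseases.names}
    totals = {d: sum(sv.values()) for d, sv in svals.items()}
    n = len(diseases)
    S = np.eye(n)
    for i in range(n):
        a = diseases.names[i]
        for j in range(i + 1, n):
            b = diseases.names[j]
            shared = svals[a].keys() & svals[b].keys()
            num = sum(svals[a][t] + svals[b][t] for t in shared)
            S[i, j] = S[j, i] = num / (totals[a] + totals[b])
    return SimilarityMatrix(diseases, S, value_range=(0.0, 1.0))


def build_similarity_sets(
    expression: LabeledMatrix | None = None,
    lnc_mirna: BinaryProfileMatrix | None = None,
    lnc_protein: BinaryProfileMatrix | None = None,
    dis_mirna: BinaryProfileMatrix | None = None,
    dag: DiseaseDAG | None = None,
    dis_semantic: SimilarityMatrix | None = None,
    lnc_index: EntityIndex | None = None,
    dis_index: EntityIndex | None = None,
    alpha_lnc_mirna: float = 0.5,
    alpha_lnc_protein: float = 0.5,
    alpha_dis_mirna: float = 0.5,
    convention: str = "divide",
) -> tuple[SimilarityNetworkSet, SimilarityNetworkSet]:
    """Assemble the lncRNA {LncSm1,2,3} and disease {DisSm1,2} network sets.

    Any input layer may be omitted (the corresponding member is skipped with
    a warning), supporting missing-omics ablation runs; at least one member
    per entity type is required. A precomputed semantic-similarity matrix can
    stand in for the DAG.
    """
    lnc_members: dict[str, SimilarityMatrix] = {}
    dis_members: dict[str, SimilarityMatrix] = {}

    if expression is not None:
        lnc_members["LncSm1"] = bicor_network(expression)
    else:
        logger.warning("no expression input: LncSm1 omitted")
    if lnc_mirna is not None:
        bw = gip_bandwidth(lnc_mirna, alpha_lnc_mirna, convention)
        lnc_members["LncSm2"] = gip_kernel(lnc_mirna, bw)
    else:
        logger.warning("no lncRNA-miRNA input: LncSm2 omitted")
    if lnc_protein is not None:
        bw = gip_bandwidth(lnc_protein, alpha_lnc_protein, convention)
        lnc_members["LncSm3"] = gip_kernel(lnc_protein, bw)
    else:
        logger.warning("no lncRNA-protein input: LncSm3 omitted")

    if dis_semantic is not None:
        dis_members["DisSm1"] = dis_semantic
    elif dag is not None:
        if dis_index is None:
            raise ValidationError("semantic similarity needs the disease index")
        dis_members["DisSm1"] = semantic_similarity(dag, dis_index)
    else:
        logger.warning("no ontology input: DisSm1 omitted")
    if dis_mirna is not None:
        bw = gip_bandwidth(dis_mirna, alpha_dis_mirna, convention)
        dis_members["DisSm2"] = gip_kernel(dis_mirna, bw)
    else:
        logger.warning("no disease-miRNA input: DisSm2 omitted")

    if not lnc_members:
        raise ValidationError("no lncRNA similarity source available")
    if not dis_members:
        raise ValidationError("no disease similarity source available")

    for name, sim in list(lnc_members.items()):
        if lnc_index is not None and sim.index != lnc_index:
            raise ValidationError(f"{name} index mismatch against the lncRNA universe")
    for name, sim in list(dis_members.items()):
        if dis_index is not None and sim.index != dis_index:
            raise ValidationError(f"{name} index mismatch against the disease universe")

    return (
        SimilarityNetworkSet("lncRNA", lnc_members),
        SimilarityNetworkSet("disease", dis_members),
    )
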