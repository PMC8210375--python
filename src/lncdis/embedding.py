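"""Neighborhood-aggregation node embedding.

Every node carries a random initial representation of size ``d``. One
aggregation layer collects, for each node, a nonlinearly transformed
(ReLU) sum of its neighbors' representations across every relation it
participates in, weighted by the row-normalised relation matrices:

* lncRNA i:  concat(x_i, sum_j LTS'[i,j] relu(x_j W_ll + b_ll)
                       + sum_j A'[i,j]  relu(y_j W_ld + b_ld)
                       + sum_j Alg'[i,j] relu(g_j W_lg + b_lg))
* disease i: concat(y_i, DTS' / A^T' / Agd^T' analogously)
* gene i:    concat(g_i, Alg^T' lncRNA side + Agd' disease side)

The lg and gd transforms are shared between the two directions of their
relation; ld and dl are distinct. The 2d-dimensional concatenation is then
projected through one shared ReLU layer (W0, b0) and L2-normalised to a
unit vector of size ``d_low``.

This module also houses the exact backward pass through aggregation,
projection and normalisation, used by the trainer; ``backward_embeddings``
consumes the gradients of the loss w.r.t. the final unit embeddings and
returns gradients for every embedding-side parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import HeteroNetwork, RunConfig, ValidationError, row_normalize

logger = logging.getLogger("lncdis")

NORM_EPS = 1e-12  # floor added to ||u|| so degenerate all-negative rows stay finite


@dataclass
class NormalizedRelations:
    """Row-normalised relation matrices used inside the aggregation sums."""

    LTSp: np.ndarray   # m x m
    Ap: np.ndarray     # m x n
    DTSp: np.ndarray   # n x n
    ATp: np.ndarray    # n x m
    Algp: np.ndarray | None = None   # m x k
    AgdTp: np.ndarray | None = None  # n x k
    AlgTp: np.ndarray | None = None  # k x m
    Agdp: np.ndarray | None = None   # k x n

    @property
    def has_genes(self) -> bool:
        return self.Algp is not None


@dataclass
class EmbeddingState:
    """Final unit-norm embeddings plus the full parameter dictionary."""

    params: dict[str, np.ndarray]
    lnc_embedding: np.ndarray   # m x d_low, rows unit norm
    dis_embedding: np.ndarray   # n x d_low
    gene_embedding: np.ndarray | None  # k x d_low
    seed: int | None = None


def build_normalized_relations(network: HeteroNetwork, mode: str = "row") -> NormalizedRelations:
    """Row-normalise each relation matrix (zero rows stay zero); ``mode='none'``
    keeps the raw matrices."""
    if mode not in ("row", "none"):
        raise ValidationError("neighbor_norm must be 'row' or 'none'")
    norm = row_normalize if mode == "row" else (lambda M: np.asarray(M, dtype=float).copy())
    A = network.A.values
    rel = NormalizedRelations(
        LTSp=norm(network.LTS.values),
        Ap=norm(A),
        DTSp=norm(network.DTS.values),
        ATp=norm(A.T),
    )
    if network.has_genes:
        Alg, Agd = network.A_lg.values, network.A_gd.values
        rel.Algp = norm(Alg)
        rel.AgdTp = norm(Agd.T)
        rel.AlgTp = norm(Alg.T)
        rel.Agdp = norm(Agd)
    return rel


def relation_transform(e: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """ReLU(e @ W + b) for a single neighbor representation or a stack."""
    e = np.asarray(e, dtype=float)
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    if e.shape[-1] != W.shape[0] or W.shape[1] != b.shape[-1]:
        raise ValidationError("relation_transform: shape mismatch")
    return np.maximum(e @ W + b, 0.0)


def init_embedding_params(
    m: int, n: int, k: int | None, d: int, d_low: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Seeded initial parameters: node representations i.i.d.
    uniform(-0.5/d, 0.5/d); transform weights uniform(-1/sqrt(d), 1/sqrt(d));
    biases small positive so ReLU units start active."""
    lim = 0.5 / d
    wlim = 1.0 / np.sqrt(d)
    params: dict[str, np.ndarray] = {
        "Xl": rng.uniform(-lim, lim, size=(m, d)),
        "Xd": rng.uniform(-lim, lim, size=(n, d)),
    }
    relations = ["ll", "ld", "dd", "dl"]
    if k is not None:
        params["Xg"] = rng.uniform(-lim, lim, size=(k, d))
        relations += ["lg", "gd"]
    for r in relations:
        params[f"W_{r}"] = rng.uniform(-wlim, wlim, size=(d, d))
        params[f"b_{r}"] = np.full(d, 0.01)
    params["W0"] = rng.uniform(-1.0 / np.sqrt(2 * d), 1.0 / np.sqrt(2 * d), size=(2 * d, d_low))
    params["b0"] = np.full(d_low, 0.01)
    return params


def _relu_layer(X, W, b):
    Z = X @ W + b
    return np.maximum(Z, 0.0), Z > 0


def _project(Eprime, W0, b0):
    U, mask = _relu_layer(Eprime, W0, b0)
    norms = np.linalg.norm(U, axis=1)
    degenerate = norms == 0
    if degenerate.any():
        logger.info("projection: %d node(s) with all-negative pre-activations", degenerate.sum())
    E2 = U / (norms + NORM_EPS)[:, None]
    return E2, U, mask, norms


def forward_embeddings(params: dict[str, np.ndarray], rel: NormalizedRelations) -> dict:
    """Full forward pass; returns a cache consumed by ``backward_embeddings``."""
    cache: dict = {"params": params, "rel": rel}
    Xl, Xd = params["Xl"], params["Xd"]
    has_genes = rel.has_genes

    cache["S_ll"], cache["m_ll"] = _relu_layer(Xl, params["W_ll"], params["b_ll"])
    cache["S_ld"], cache["m_ld"] = _relu_layer(Xd, params["W_ld"], params["b_ld"])
    cache["S_dd"], cache["m_dd"] = _relu_layer(Xd, params["W_dd"], params["b_dd"])
    cache["S_dl"], cache["m_dl"] = _relu_layer(Xl, params["W_dl"], params["b_dl"])
    agg_l = rel.LTSp @ cache["S_ll"] + rel.Ap @ cache["S_ld"]
    agg_d = rel.DTSp @ cache["S_dd"] + rel.ATp @ cache["S_dl"]
    if has_genes:
        Xg = params["Xg"]
        # lg transform applied to genes (lncRNA side) and to lncRNAs (gene side)
        cache["S_lg_g"], cache["m_lg_g"] = _relu_layer(Xg, params["W_lg"], params["b_lg"])
        cache["S_lg_l"], cache["m_lg_l"] = _relu_layer(Xl, params["W_lg"], params["b_lg"])
        # gd transform applied to genes (disease side) and to diseases (gene side)
        cache["S_gd_g"], cache["m_gd_g"] = _relu_layer(Xg, params["W_gd"], params["b_gd"])
        cache["S_gd_d"], cache["m_gd_d"] = _relu_layer(Xd, params["W_gd"], params["b_gd"])
        agg_l = agg_l + rel.Algp @ cache["S_lg_g"]
        agg_d = agg_d + rel.AgdTp @ cache["S_gd_g"]
        agg_g = rel.AlgTp @ cache["S_lg_l"] + rel.Agdp @ cache["S_gd_d"]
        cache["Eg_prime"] = np.concatenate([Xg, agg_g], axis=1)
    cache["El_prime"] = np.concatenate([Xl, agg_l], axis=1)
    cache["Ed_prime"] = np.concatenate([Xd, agg_d], axis=1)

    W0, b0 = params["W0"], params["b0"]
    cache["Lp"], cache["Ul"], cache["mask_l"], cache["norm_l"] = _project(cache["El_prime"], W0, b0)
    cache["Dp"], cache["Ud"], cache["mask_d"], cache["norm_d"] = _project(cache["Ed_prime"], W0, b0)
    if has_genes:
        cache["Gp"], cache["Ug"], cache["mask_g"], cache["norm_g"] = _project(
            cache["Eg_prime"], W0, b0
        )
    return cache


def _backward_normalize(dE2, U, norms):
    """Backward through u -> u / (||u|| + eps), rowwise."""
    denom = norms + NORM_EPS
    dU = dE2 / denom[:, None]
    dot = (U * dE2).sum(axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    corr = np.where(norms > 0, dot / (safe * denom**2), 0.0)
    dU -= U * corr[:, None]
    return dU


def backward_embeddings(
    cache: dict, dLp: np.ndarray, dDp: np.ndarray, dGp: np.ndarray | None
) -> dict[str, np.ndarray]:
    """Exact gradients of the loss w.r.t. every embedding-side parameter,
    given gradients w.r.t. the final unit embeddings."""
    params, rel = cache["params"], cache["rel"]
    has_genes = rel.has_genes
    grads: dict[str, np.ndarray] = {}
    W0 = params["W0"]
    d = params["Xl"].shape[1]

    dUl = _backward_normalize(dLp, cache["Ul"], cache["norm_l"]) * cache["mask_l"]
    dUd = _backward_normalize(dDp, cache["Ud"], cache["norm_d"]) * cache["mask_d"]
    grads["W0"] = cache["El_prime"].T @ dUl + cache["Ed_prime"].T @ dUd
    grads["b0"] = dUl.sum(axis=0) + dUd.sum(axis=0)
    dEl = dUl @ W0.T
    dEd = dUd @ W0.T
    if has_genes:
        dUg = _backward_normalize(dGp, cache["Ug"], cache["norm_g"]) * cache["mask_g"]
        grads["W0"] += cache["Eg_prime"].T @ dUg
        grads["b0"] += dUg.sum(axis=0)
        dEg = dUg @ W0.T

    dXl = dEl[:, :d].copy()
    dAgg_l = dEl[:, d:]
    dXd = dEd[:, :d].copy()
    dAgg_d = dEd[:, d:]

    def relu_back(dS, mask, X, W, wkey, bkey):
        dZ = dS * mask
        grads[wkey] = grads.get(wkey, 0) + X.T @ dZ
        grads[bkey] = grads.get(bkey, 0) + dZ.sum(axis=0)
        return dZ @ W.T

    dXl += relu_back(rel.LTSp.T @ dAgg_l, cache["m_ll"], params["Xl"], params["W_ll"], "W_ll", "b_ll")
    dXd += relu_back(rel.Ap.T @ dAgg_l, cache["m_ld"], params["Xd"], params["W_ld"], "W_ld", "b_ld")
    dXd += relu_back(rel.DTSp.T @ dAgg_d, cache["m_dd"], params["Xd"], params["W_dd"], "W_dd", "b_dd")
    dXl += relu_back(rel.ATp.T @ dAgg_d, cache["m_dl"], params["Xl"], params["W_dl"], "W_dl", "b_dl")

    if has_genes:
        dXg = dEg[:, :d].copy()
        dAgg_g = dEg[:, d:]
        dXg += relu_back(
            rel.Algp.T @ dAgg_l, cache["m_lg_g"], params["Xg"], params["W_lg"], "W_lg", "b_lg"
        )
        dXg += relu_back(
            rel.AgdTp.T @ dAgg_d, cache["m_gd_g"], params["Xg"], params["W_gd"], "W_gd", "b_gd"
        )
        dXl += relu_back(
            rel.AlgTp.T @ dAgg_g, cache["m_lg_l"], params["Xl"], params["W_lg"], "W_lg", "b_lg"
        )
        dXd += relu_back(
            rel.Agdp.T @ dAgg_g, cache["m_gd_d"], params["Xd"], params["W_gd"], "W_gd", "b_gd"
        )
        grads["Xg"] = dXg
    grads["Xl"] = dXl
    grads["Xd"] = dXd
    return grads


def aggregate_node(
    node: int, kind: str, rel: NormalizedRelations, params: dict[str, np.ndarray]
) -> np.ndarray:
    """The 2d concatenated representation of one node (reference path used by
    the vectorised forward pass; exposed for inspection and testing)."""
    cache = forward_embeddings(params, rel)
    key = {"lncRNA": "El_prime", "disease": "Ed_prime", "gene": "Eg_prime"}.get(kind)
    if key is None or (key == "Eg_prime" and not rel.has_genes):
        raise ValidationError(f"unknown or unavailable node kind {kind!r}")
    return cache[key][node]


def project_and_normalize(e_prime: np.ndarray, W0: np.ndarray, b0: np.ndarray) -> np.ndarray:
    """Unit-norm low-dimensional embedding of one 2d-vector (or a stack)."""
    arr = np.atleast_2d(np.asarray(e_prime, dtype=float))
    E2, _, _, _ = _project(arr, W0, b0)
    return E2[0] if np.asarray(e_prime).ndim == 1 else E2


def embed_all(
    network: HeteroNetwork, config: RunConfig, seed: int | None = None
) -> EmbeddingState:
    """Deterministic seeded initialisation + one forward pass."""
    seed = config.random_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    m, n = network.A.shape
    k = len(network.gene_index) if network.has_genes else None
    params = init_embedding_params(m, n, k, config.embed_dim, config.embed_dim_low, rng)
    rel = build_normalized_relations(network, config.neighbor_norm)
    cache = forward_embeddings(params, rel)
    return EmbeddingState(
        params=params,
        lnc_embedding=cache["Lp"],
        dis_embedding=cache["Dp"],
        gene_embedding=cache.get("Gp"),
        seed=seed,
    )
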