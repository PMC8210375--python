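"""Bilinear matrix-reconstruction model over embedded nodes.

``AssociationModel`` is built from a :class:`~lncdis.core.HeteroNetwork`
(observed association matrices plus fused topological similarities) and a
:class:`~lncdis.core.RunConfig`; ``fit`` trains, by full-batch gradient
descent, the joint objective

    sum_(i,j) in mask (A[i,j]   - l_i C_ld d_j^T)^2
  + sum_(i,j)        (LTS[i,j]  - l_i E_ll E_ll^T l_j^T)^2
  + sum_(i,j)        (DTS[i,j]  - d_i E_dd E_dd^T d_j^T)^2
  + sum_(i,j)        (Alg[i,j]  - l_i C_lg g_j^T)^2
  + sum_(i,j)        (Agd[i,j]  - g_i C_gd d_j^T)^2

where l, d, g are the unit-norm node embeddings (recomputed from the
current parameters every iteration, so embedding and decoder parameters
are trained end-to-end), C_xy = E_xy1 E_xy2^T are shared per-relation
mapping products, and the symmetric within-type decoders use E E^T so the
reconstruction is symmetric for any parameters. Gradients are exact
(ReLU subgradient 0 at kinks).

``fit`` returns an :class:`AssociationResults` carrying the trained
parameters, the loss trace, recovered scores and ranking helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import HeteroNetwork, RunConfig, ValidationError
from .embedding import (
    EmbeddingState,
    NormalizedRelations,
    backward_embeddings,
    build_normalized_relations,
    forward_embeddings,
    init_embedding_params,
)

logger = logging.getLogger("lncdis")

DIVERGENCE_LIMIT = 1e12


@dataclass
class TrainTrace:
    """Loss per iteration, overall and per reconstruction term."""

    total: list[float] = field(default_factory=list)
    terms: list[dict[str, float]] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0
    seed: int | None = None
    config: dict | None = None


def init_mapping_params(
    d_low: int, q: int, rng: np.random.Generator, has_genes: bool
) -> dict[str, np.ndarray]:
    lim = 1.0 / np.sqrt(d_low)
    keys = ["E_ld1", "E_ld2", "E_ll", "E_dd"]
    if has_genes:
        keys += ["E_lg1", "E_lg2", "E_gd1", "E_gd2"]
    return {k: rng.uniform(-lim, lim, size=(d_low, q)) for k in keys}


def build_training_mask(
    A: np.ndarray,
    ratio: float,
    rng: np.random.Generator,
    forbidden: np.ndarray | None = None,
) -> np.ndarray:
    """Observed positives plus ``ratio`` times as many sampled zero entries.

    ``forbidden`` marks entries that must not be used at all (e.g. held-out
    pairs during evaluation).
    """
    pos = A == 1
    if forbidden is not None:
        pos = pos & ~forbidden
    neg_pool = np.argwhere((A == 0) & ~(forbidden if forbidden is not None else False))
    n_neg = min(int(round(ratio * pos.sum())), len(neg_pool))
    mask = pos.copy()
    if n_neg > 0:
        chosen = neg_pool[rng.choice(len(neg_pool), size=n_neg, replace=False)]
        mask[chosen[:, 0], chosen[:, 1]] = True
    return mask


def _loss_terms(
    params: dict[str, np.ndarray],
    network: HeteroNetwork,
    rel: NormalizedRelations,
    mask: np.ndarray,
    want_grads: bool = True,
    mask_lg: np.ndarray | None = None,
    mask_gd: np.ndarray | None = None,
):
    """Forward (and optionally backward) pass through the full objective."""
    cache = forward_embeddings(params, rel)
    Lp, Dp = cache["Lp"], cache["Dp"]
    has_genes = rel.has_genes
    Gp = cache.get("Gp")
    A = network.A.values
    LTS, DTS = network.LTS.values, network.DTS.values

    terms: dict[str, float] = {}
    grads: dict[str, np.ndarray] = {}
    dLp = np.zeros_like(Lp)
    dDp = np.zeros_like(Dp)
    dGp = np.zeros_like(Gp) if has_genes else None

    def bilinear_term(name, target, Xi, Xj, k1, k2, dXi, dXj, msk=None):
        E1, E2 = params[k1], params[k2]
        R = Xi @ E1 @ E2.T @ Xj.T
        resid = target - R
        if msk is not None:
            resid = resid * msk
        terms[name] = float((resid**2).sum())
        if want_grads:
            dR = -2.0 * resid
            grads[k1] = grads.get(k1, 0) + Xi.T @ dR @ Xj @ E2
            grads[k2] = grads.get(k2, 0) + Xj.T @ dR.T @ Xi @ E1
            dXi += dR @ Xj @ E2 @ E1.T
            dXj += dR.T @ Xi @ E1 @ E2.T
        return R

    def symmetric_term(name, target, X, key, dX):
        E = params[key]
        B = E @ E.T
        R = X @ B @ X.T
        resid = target - R
        terms[name] = float((resid**2).sum())
        if want_grads:
            dR = -2.0 * resid
            dX += (dR + dR.T) @ X @ B
            dB = X.T @ dR @ X
            grads[key] = (dB + dB.T) @ E

    R_A = bilinear_term("A", A, Lp, Dp, "E_ld1", "E_ld2", dLp, dDp, msk=mask)
    symmetric_term("LTS", LTS, Lp, "E_ll", dLp)
    symmetric_term("DTS", DTS, Dp, "E_dd", dDp)
    if has_genes:
        bilinear_term(
            "A_lg", network.A_lg.values, Lp, Gp, "E_lg1", "E_lg2", dLp, dGp, msk=mask_lg
        )
        bilinear_term(
            "A_gd", network.A_gd.values, Gp, Dp, "E_gd1", "E_gd2", dGp, dDp, msk=mask_gd
        )

    total = float(sum(terms.values()))
    if not np.isfinite(total):
        raise ValidationError("non-finite loss encountered")
    if not want_grads:
        return total, terms, None, R_A, cache
    grads.update(backward_embeddings(cache, dLp, dDp, dGp))
    return total, terms, grads, R_A, cache


def loss(
    params: dict[str, np.ndarray],
    network: HeteroNetwork,
    rel: NormalizedRelations | None = None,
    mask: np.ndarray | None = None,
    neighbor_norm: str = "row",
) -> float:
    """Objective value at ``params`` (mask defaults to all entries)."""
    if rel is None:
        rel = build_normalized_relations(network, neighbor_norm)
    if mask is None:
        mask = np.ones(network.A.shape, dtype=bool)
    total, _, _, _, _ = _loss_terms(params, network, rel, mask, want_grads=False)
    return total


def loss_gradients(
    params: dict[str, np.ndarray],
    network: HeteroNetwork,
    rel: NormalizedRelations | None = None,
    mask: np.ndarray | None = None,
    neighbor_norm: str = "row",
) -> tuple[float, dict[str, np.ndarray]]:
    """Objective and exact gradients for every parameter family."""
    if rel is None:
        rel = build_normalized_relations(network, neighbor_norm)
    if mask is None:
        mask = np.ones(network.A.shape, dtype=bool)
    total, _, grads, _, _ = _loss_terms(params, network, rel, mask, want_grads=True)
    return total, grads


def gradient_step(
    params: dict[str, np.ndarray],
    network: HeteroNetwork,
    learning_rate: float,
    rel: NormalizedRelations | None = None,
    mask: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], float]:
    """One plain gradient-descent step; returns updated params and the loss
    at the *starting* point."""
    if learning_rate < 0:
        raise ValidationError("learning rate must be nonnegative")
    total, grads = loss_gradients(params, network, rel, mask)
    if total > DIVERGENCE_LIMIT:
        raise ValidationError("training diverged; reduce the learning rate")
    new = {k: v - learning_rate * grads.get(k, 0) for k, v in params.items()}
    return new, total


class AssociationModel:
    """lncRNA-disease association model over a heterogeneous network.

    Parameters
    ----------
    network : HeteroNetwork
        Observed associations (A, and optionally A_lg / A_gd) with the fused
        topological similarity matrices LTS and DTS.
    config : RunConfig, optional
        Hyperparameters; defaults are used when omitted.
    """

    def __init__(self, network: HeteroNetwork, config: RunConfig | None = None):
        self.network = network
        self.config = config or RunConfig()
        self.rel = build_normalized_relations(network, self.config.neighbor_norm)

    @classmethod
    def from_bundle(cls, bundle, config: RunConfig | None = None) -> "AssociationModel":
        """Build the model from a raw input bundle by running the similarity
        and diffusion stages (see :func:`lncdis.pipeline.build_network`)."""
        from .pipeline import build_network

        return cls(build_network(bundle, config or RunConfig()), config)

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg = self.config
        m, n = self.network.A.shape
        k = len(self.network.gene_index) if self.network.has_genes else None
        params = init_embedding_params(m, n, k, cfg.embed_dim, cfg.embed_dim_low, rng)
        params.update(init_mapping_params(cfg.embed_dim_low, cfg.q, rng, k is not None))
        return params

    def fit(
        self,
        seed: int | None = None,
        start_params: dict[str, np.ndarray] | None = None,
        max_iterations: int | None = None,
        forbidden: np.ndarray | None = None,
    ) -> "AssociationResults":
        """Train by full-batch gradient descent.

        With ``backtracking`` enabled (default) the configured learning rate
        is the initial trial step of each iteration and is halved until the
        loss decreases, so the trace is non-increasing.
        """
        cfg = self.config
        seed = cfg.random_seed if seed is None else seed
        rng = np.random.default_rng(seed)
        params = (
            {k: v.copy() for k, v in start_params.items()}
            if start_params is not None
            else self.init_params(rng)
        )
        mask_lg = mask_gd = None
        if cfg.loss_mask == "full":
            mask = np.ones(self.network.A.shape, dtype=bool)
        else:
            # balanced sampled masks for every sparse binary relation
            mask = build_training_mask(
                self.network.A.values, cfg.negative_sampling_ratio, rng, forbidden
            )
            if self.network.has_genes:
                mask_lg = build_training_mask(
                    self.network.A_lg.values, cfg.negative_sampling_ratio, rng
                )
                mask_gd = build_training_mask(
                    self.network.A_gd.values, cfg.negative_sampling_ratio, rng
                )
        max_iter = cfg.max_iterations if max_iterations is None else max_iterations

        trace = TrainTrace(seed=seed, config=cfg.to_dict())

        def evaluate(p, with_grads):
            return _loss_terms(
                p, self.network, self.rel, mask,
                want_grads=with_grads, mask_lg=mask_lg, mask_gd=mask_gd,
            )

        total, terms, grads, _, _ = evaluate(params, True)
        step = cfg.learning_rate
        for it in range(max_iter):
            if total > DIVERGENCE_LIMIT:
                raise ValidationError(
                    f"training diverged at iteration {it}; reduce the learning rate"
                )
            trace.total.append(total)
            trace.terms.append(terms)
            # line search: trial step warm-started from the last accepted one,
            # halved until the loss decreases (loss-only evaluations)
            step = min(cfg.learning_rate, 2 * step) if cfg.backtracking else cfg.learning_rate
            while True:
                cand = {k: v - step * grads.get(k, 0) for k, v in params.items()}
                cand_total, cand_terms, _, _, _ = evaluate(cand, False)
                if cand_total <= total or not cfg.backtracking:
                    break
                step /= 2
                if step < 1e-15:
                    break
            if cfg.backtracking and cand_total > total:
                trace.converged = True  # no descent step helps
                break
            params, prev = cand, total
            total, terms = cand_total, cand_terms
            if abs(prev - total) < cfg.convergence_tol * max(abs(prev), 1.0):
                trace.total.append(total)
                trace.terms.append(terms)
                trace.converged = True
                break
            _, _, grads, _, _ = evaluate(params, True)
        else:
            trace.total.append(total)
            trace.terms.append(terms)
        if trace.total[-1] != total:
            trace.total.append(total)
            trace.terms.append(terms)
        trace.iterations = len(trace.total) - 1

        cache = forward_embeddings(params, self.rel)
        state = EmbeddingState(
            params=params,
            lnc_embedding=cache["Lp"],
            dis_embedding=cache["Dp"],
            gene_embedding=cache.get("Gp"),
            seed=seed,
        )
        return AssociationResults(self, params, trace, mask, state)


class AssociationResults:
    """Fitted model: trained parameters, loss trace and recovered scores."""

    def __init__(
        self,
        model: AssociationModel,
        params: dict[str, np.ndarray],
        trace: TrainTrace,
        mask: np.ndarray,
        embeddings: EmbeddingState,
    ):
        self.model = model
        self.params = params
        self.trace = trace
        self.mask = mask
        self.embeddings = embeddings
        self._scores: np.ndarray | None = None

    def scores(self) -> np.ndarray:
        """Recovered association matrix: l_i E_ld1 E_ld2^T d_j^T for every
        pair (the same decoder used in training); higher = more likely."""
        if self._scores is None:
            Lp, Dp = self.embeddings.lnc_embedding, self.embeddings.dis_embedding
            self._scores = Lp @ self.params["E_ld1"] @ self.params["E_ld2"].T @ Dp.T
        return self._scores

    def scores_frame(self) -> pd.DataFrame:
        net = self.model.network
        return pd.DataFrame(
            self.scores(), index=list(net.lnc_index.names), columns=list(net.dis_index.names)
        )

    def top_k(self, disease: str | int, k: int = 15, exclude_known: bool = True) -> pd.DataFrame:
        """Top-k candidate lncRNAs for one disease, ties broken by name.

        Returns a frame with columns (rank, lncRNA, score, known).
        """
        net = self.model.network
        j = disease if isinstance(disease, int) else net.dis_index.position(disease)
        col = self.scores()[:, j]
        known = net.A.values[:, j] == 1
        order = sorted(range(len(col)), key=lambda i: (-col[i], net.lnc_index.names[i]))
        if exclude_known:
            order = [i for i in order if not known[i]]
        if k > len(order):
            logger.warning("top_k: only %d candidates available (k=%d)", len(order), k)
        order = order[:k]
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(order) + 1),
                "lncRNA": [net.lnc_index.names[i] for i in order],
                "score": [col[i] for i in order],
                "known": [bool(known[i]) for i in order],
            }
        )

    @property
    def final_loss(self) -> float:
        return self.trace.total[-1]

    def summary(self) -> str:
        net = self.model.network
        cfg = self.model.config
        m, n = net.A.shape
        k = len(net.gene_index) if net.has_genes else 0
        lines = [
            "Association model (bilinear reconstruction over node embeddings)",
            "=" * 64,
            f"lncRNAs: {m}    diseases: {n}    genes: {k}",
            f"known associations: {int(net.A.values.sum())}"
            f"    training mask entries: {int(self.mask.sum())}",
            f"embedding dim d={cfg.embed_dim}, d_low={cfg.embed_dim_low}, q={cfg.q}",
            f"seed: {self.trace.seed}    iterations: {self.trace.iterations}"
            f"    converged: {self.trace.converged}",
            f"initial loss: {self.trace.total[0]:.6g}    final loss: {self.final_loss:.6g}",
            "per-term final loss: "
            + ", ".join(f"{k2}={v:.4g}" for k2, v in self.trace.terms[-1].items()),
        ]
        return "\n".join(lines)
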