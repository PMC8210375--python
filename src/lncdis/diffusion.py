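"""Random walk with restart (RWR) diffusion and profile fusion.

Each base similarity network is converted into a matrix of RWR stationary
distributions (one column per seed node). Within an entity type, the
stationary profiles of all member networks are fused into a single
topological similarity matrix: the lncRNA network ``LTS`` and the disease
network ``DTS``. The default fusion concatenates every node's stationary
columns across networks and takes cosine similarity between the
concatenated profiles.

Signed edge weights (bicor can be negative) enter diffusion through their
absolute value; the raw signed matrix is left untouched on the similarity
side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import SimilarityMatrix, ValidationError
from .similarity import SimilarityNetworkSet

logger = logging.getLogger("lncdis")


@dataclass
class DiffusionProfile:
    """Stationary RWR matrix for one network: column j is the stationary
    distribution of a walk restarting at node j."""

    name: str
    P: np.ndarray
    restart: float
    iterations: int

    def __post_init__(self):
        col_sums = self.P.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-8):
            raise ValidationError("stationary columns must sum to 1")
        if (self.P < -1e-12).any():
            raise ValidationError("stationary distributions must be nonnegative")


@dataclass
class TopoSimilarity:
    """Fused topological similarity matrices."""

    LTS: SimilarityMatrix
    DTS: SimilarityMatrix
    fusion: str
    restart: float


def _transition_matrix(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-normalised transition matrix plus the mask of dangling
    (all-zero) columns, whose mass teleports back to the seed."""
    W = np.abs(np.asarray(W, dtype=float))
    col = W.sum(axis=0)
    dangling = col == 0
    if dangling.any():
        logger.info("RWR: %d isolated node(s); restart mass stays at seed", dangling.sum())
    M = np.divide(W, col[None, :], out=np.zeros_like(W), where=col[None, :] != 0)
    return M, dangling


def _rwr_all(
    W: np.ndarray, restart: float, tol: float = 1e-8, max_iter: int = 10_000
) -> tuple[np.ndarray, int]:
    """Stationary matrix for every seed simultaneously by power iteration.

    Solves P = (1-r) M P + r I columnwise; dangling-column mass is returned
    to the seed (teleport), preserving total probability mass.
    """
    if not (0 < restart <= 1):
        raise ValidationError("restart probability must lie in (0, 1]")
    n = W.shape[0]
    M, dangling = _transition_matrix(W)
    P = np.eye(n)
    if restart == 1.0:
        return P, 0
    for it in range(1, max_iter + 1):
        dead = P[dangling, :].sum(axis=0) if dangling.any() else 0.0
        P_new = (1 - restart) * (M @ P)
        if dangling.any():
            P_new[np.arange(n), np.arange(n)] += (1 - restart) * dead
        P_new[np.arange(n), np.arange(n)] += restart
        delta = np.abs(P_new - P).sum(axis=0).max()
        P = P_new
        if delta < tol:
            return P, it
    logger.warning("RWR did not reach tol=%g in %d iterations", tol, max_iter)
    return P, max_iter


def rwr(
    W: SimilarityMatrix | np.ndarray,
    restart: float,
    seed_node: int,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Stationary RWR distribution seeded at one node."""
    values = W.values if isinstance(W, SimilarityMatrix) else np.asarray(W, dtype=float)
    P, _ = _rwr_all(values, restart, tol, max_iter)
    return P[:, seed_node]


def diffuse_set(
    networks: SimilarityNetworkSet,
    restart: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> list[DiffusionProfile]:
    """One diffusion profile per member network, in member-name order."""
    if len(networks) == 0:
        raise ValidationError("empty similarity network set")
    profiles = []
    for name in sorted(networks.members):
        P, its = _rwr_all(networks.members[name].values, restart, tol, max_iter)
        profiles.append(DiffusionProfile(name=name, P=P, restart=restart, iterations=its))
    return profiles


def fuse_profiles(profiles: list[DiffusionProfile], method: str = "cosine-concat") -> np.ndarray:
    """Fuse member diffusion profiles into one similarity matrix.

    ``cosine-concat``: node feature = its stationary columns concatenated
    across networks; similarity = cosine between features. ``mean``: plain
    average of the stationary matrices, symmetrised.
    """
    if not profiles:
        raise ValidationError("no diffusion profiles to fuse")
    n = profiles[0].P.shape[0]
    for p in profiles:
        if p.P.shape[0] != n:
            raise ValidationError("diffusion profiles disagree on node count")
    if method == "cosine-concat":
        F = np.vstack([p.P for p in sorted(profiles, key=lambda p: p.name)])  # features in columns
        norms = np.linalg.norm(F, axis=0)
        norms[norms == 0] = 1.0
        Fn = F / norms[None, :]
        S = Fn.T @ Fn
    elif method == "mean":
        S = np.mean([p.P for p in profiles], axis=0)
    else:
        raise ValidationError(f"unknown fusion method {method!r}")
    S = (S + S.T) / 2
    np.clip(S, 0.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return S


def build_topological_similarity(
    lnc_networks: SimilarityNetworkSet,
    dis_networks: SimilarityNetworkSet,
    restart: float = 0.7,
    fusion: str = "cosine-concat",
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> TopoSimilarity:
    """Diffuse and fuse both entity types into LTS and DTS."""
    lnc_profiles = diffuse_set(lnc_networks, restart, tol, max_iter)
    dis_profiles = diffuse_set(dis_networks, restart, tol, max_iter)
    LTS = SimilarityMatrix(lnc_networks.index, fuse_profiles(lnc_profiles, fusion))
    DTS = SimilarityMatrix(dis_networks.index, fuse_profiles(dis_profiles, fusion))
    return TopoSimilarity(LTS=LTS, DTS=DTS, fusion=fusion, restart=restart)
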