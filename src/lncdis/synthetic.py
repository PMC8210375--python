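"""Synthetic heterogeneous-network generator with planted low-rank structure.

The generator draws latent factors U (lncRNA), V (disease) and G (gene) of a
chosen rank and derives every pipeline input from them, so the whole method
can be exercised — and its ability to recover planted signal quantified —
without any external database:

* associations A, A_lg, A_gd: top-scoring entries of the corresponding factor
  products (exact planted counts), plus optional label flips;
* expression: U times a random loading matrix plus Gaussian noise;
* binary interaction profiles (lncRNA-miRNA, lncRNA-protein, disease-miRNA):
  Bernoulli draws with a logistic link on latent-factor affinity, the
  intercept solved numerically so the expected density hits its target;
* disease ontology: a binary tree from hierarchical clustering of V, so
  ontologically close diseases are latent-similar.

Measured omics views (expression, interaction profiles, the ontology) are
generated from only the leading ``observed_rank`` latent components,
emulating that such measurements are partial proxies of function; the
relational matrices A, A_lg, A_gd use the full factors, so gene
associations carry complementary signal the similarity networks cannot
see — the property the missing-omics ablation experiments probe.

The ``paper-small`` preset mirrors the scale of the small benchmark network
used in this literature (356 lncRNAs, 354 diseases, 132 genes with
2169 / 736 / 462 planted associations); ``tiny`` (8/6/5) serves unit tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.optimize import brentq

from .core import (
    AssociationMatrix,
    BinaryProfileMatrix,
    DiseaseDAG,
    EntityIndex,
    LabeledMatrix,
    ValidationError,
)

LAYERS = ("expression", "lnc_mirna", "lnc_protein", "dis_mirna", "gene_block")


@dataclass
class SynthSpec:
    """Generator settings. Counts are planted exactly (before label flips)."""

    m: int = 356            # lncRNAs
    n: int = 354            # diseases
    k: int = 132            # genes
    n_mirna: int = 128
    n_protein: int = 96
    n_sample: int = 48
    latent_rank: int = 4
    observed_rank: int | None = None  # components visible to omics views; default rank//2
    n_assoc: int = 2169     # lncRNA-disease positives
    n_lnc_gene: int = 736
    n_gene_dis: int = 462
    profile_density: float = 0.08   # target density of binary profiles
    noise_sd: float = 0.1           # Gaussian noise on expression
    flip_rate: float = 0.0          # label noise on A
    seed: int = 0

    def __post_init__(self):
        if min(self.m, self.n, self.k) < 2:
            raise ValidationError("entity counts must be >= 2")
        if self.latent_rank > min(self.m, self.n, self.k):
            raise ValidationError("latent rank exceeds the smallest entity count")
        if self.observed_rank is not None and not (
            1 <= self.observed_rank <= self.latent_rank
        ):
            raise ValidationError("observed_rank must lie in [1, latent_rank]")
        for cnt, shape in (
            (self.n_assoc, self.m * self.n),
            (self.n_lnc_gene, self.m * self.k),
            (self.n_gene_dis, self.k * self.n),
        ):
            if not (0 < cnt < shape):
                raise ValidationError(
                    "association count unreachable; reduce the count or grow the matrix"
                )


TINY = SynthSpec(
    m=8, n=6, k=5, n_mirna=6, n_protein=5, n_sample=12,
    latent_rank=2, n_assoc=14, n_lnc_gene=10, n_gene_dis=8,
    profile_density=0.3,
)

PRESETS = {"paper-small": SynthSpec(), "tiny": TINY}


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes plus the planted ground truth."""

    spec: SynthSpec
    lnc_index: EntityIndex
    dis_index: EntityIndex
    gene_index: EntityIndex | None
    A: AssociationMatrix
    expression: LabeledMatrix | None
    lnc_mirna: BinaryProfileMatrix | None
    lnc_protein: BinaryProfileMatrix | None
    dis_mirna: BinaryProfileMatrix | None
    dag: DiseaseDAG | None
    A_lg: AssociationMatrix | None
    A_gd: AssociationMatrix | None
    # planted ground truth
    U: np.ndarray = field(repr=False, default=None)
    V: np.ndarray = field(repr=False, default=None)
    G: np.ndarray = field(repr=False, default=None)

    def copy(self) -> "SyntheticBundle":
        return dataclasses.replace(
            self,
            A=self.A.copy(),
            A_lg=None if self.A_lg is None else self.A_lg.copy(),
            A_gd=None if self.A_gd is None else self.A_gd.copy(),
        )


def _names(prefix: str, count: int) -> list[str]:
    width = len(str(count - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(count)]


def _plant_topk(scores: np.ndarray, count: int) -> np.ndarray:
    """0/1 matrix with exactly ``count`` ones at the largest scores."""
    flat = scores.ravel()
    idx = np.argpartition(flat, -count)[-count:]
    out = np.zeros_like(flat)
    out[idx] = 1.0
    return out.reshape(scores.shape)


def _logistic_profiles(
    left: np.ndarray, right: np.ndarray, density: float, rng: np.random.Generator,
    slope: float = 2.0,
) -> np.ndarray:
    """Bernoulli 0/1 profiles with P = sigmoid(slope * affinity + intercept),
    the intercept solved so the mean probability equals ``density``."""
    affinity = left @ right.T
    affinity = (affinity - affinity.mean()) / (affinity.std() + 1e-12)

    def mean_prob(b):
        return 1.0 / (1.0 + np.exp(-(slope * affinity + b))) .mean() - density

    intercept = brentq(mean_prob, -50, 50)
    P = 1.0 / (1.0 + np.exp(-(slope * affinity + intercept)))
    return (rng.random(P.shape) < P).astype(float)


def _cluster_dag(dis_names: list[str], V: np.ndarray) -> DiseaseDAG:
    """Binary ontology tree from average-linkage clustering of V: leaves are
    diseases, internal terms T<i>, all edges is_a toward the root."""
    n = len(dis_names)
    g = nx.DiGraph()
    if n == 1:
        g.add_node(dis_names[0])
        return DiseaseDAG(g)
    Z = linkage(V, method="average")
    labels = {i: dis_names[i] for i in range(n)}
    for step, (a, b, _, _) in enumerate(Z):
        parent = f"T{step:04d}"
        g.add_edge(labels[int(a)], parent, relation="is_a")
        g.add_edge(labels[int(b)], parent, relation="is_a")
        labels[n + step] = parent
    return DiseaseDAG(g)


def generate(spec: SynthSpec | None = None, seed: int | None = None) -> SyntheticBundle:
    """Draw a complete input bundle from the planted low-rank model."""
    spec = spec or SynthSpec()
    if seed is not None:
        spec = dataclasses.replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    r = spec.latent_rank
    U = rng.normal(size=(spec.m, r))
    V = rng.normal(size=(spec.n, r))
    G = rng.normal(size=(spec.k, r))

    lnc_index = EntityIndex("lncRNA", _names("L", spec.m))
    dis_index = EntityIndex("disease", _names("D", spec.n))
    gene_index = EntityIndex("gene", _names("G", spec.k))

    A_vals = _plant_topk(U @ V.T, spec.n_assoc)
    if spec.flip_rate > 0:
        n_flip = int(round(spec.flip_rate * A_vals.size))
        flat = rng.choice(A_vals.size, size=n_flip, replace=False)
        A_vals.ravel()[flat] = 1.0 - A_vals.ravel()[flat]
    Alg_vals = _plant_topk(U @ G.T, spec.n_lnc_gene)
    Agd_vals = _plant_topk(G @ V.T, spec.n_gene_dis)

    r_obs = spec.observed_rank if spec.observed_rank is not None else max(1, r // 2)
    U_obs, V_obs = U[:, :r_obs], V[:, :r_obs]

    loading = rng.normal(size=(r_obs, spec.n_sample))
    expr_vals = U_obs @ loading + spec.noise_sd * rng.normal(size=(spec.m, spec.n_sample))

    mirna_f = rng.normal(size=(spec.n_mirna, r_obs))
    protein_f = rng.normal(size=(spec.n_protein, r_obs))
    mirna_index = EntityIndex("miRNA", _names("M", spec.n_mirna))
    protein_index = EntityIndex("protein", _names("P", spec.n_protein))
    sample_index = EntityIndex("sample", _names("S", spec.n_sample))

    lm = _logistic_profiles(U_obs, mirna_f, spec.profile_density, rng)
    lp = _logistic_profiles(U_obs, protein_f, spec.profile_density, rng)
    dm = _logistic_profiles(V_obs, mirna_f, spec.profile_density, rng)

    return SyntheticBundle(
        spec=spec,
        lnc_index=lnc_index,
        dis_index=dis_index,
        gene_index=gene_index,
        A=AssociationMatrix(lnc_index, dis_index, A_vals),
        expression=LabeledMatrix(lnc_index, sample_index, expr_vals),
        lnc_mirna=BinaryProfileMatrix(lnc_index, mirna_index, lm),
        lnc_protein=BinaryProfileMatrix(lnc_index, protein_index, lp),
        dis_mirna=BinaryProfileMatrix(dis_index, mirna_index, dm),
        dag=_cluster_dag(list(dis_index.names), V_obs),
        A_lg=AssociationMatrix(lnc_index, gene_index, Alg_vals),
        A_gd=AssociationMatrix(gene_index, dis_index, Agd_vals),
        U=U, V=V, G=G,
    )


def holdout_mask(
    bundle: SyntheticBundle, fraction: float, seed: int = 0
) -> tuple[SyntheticBundle, list[tuple[int, int]], list[tuple[int, int]]]:
    """Remove ``floor(fraction * n_pos)`` positives from A for testing.

    Returns (train bundle with those entries zeroed, held-out positive pairs,
    an equal number of held-out negative pairs). Train and test are disjoint.
    """
    if not (0 < fraction < 1):
        raise ValidationError("holdout fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    A = bundle.A.values
    pos = np.argwhere(A == 1)
    n_out = int(np.floor(fraction * len(pos)))
    if n_out == 0 or n_out == len(pos):
        raise ValidationError("holdout fraction leaves no train or no test positives")
    out_pos = pos[rng.choice(len(pos), size=n_out, replace=False)]
    neg = np.argwhere(A == 0)
    out_neg = neg[rng.choice(len(neg), size=n_out, replace=False)]
    train = bundle.copy()
    train.A.values[out_pos[:, 0], out_pos[:, 1]] = 0.0
    return train, [tuple(p) for p in out_pos], [tuple(p) for p in out_neg]


def ablate_layer(bundle: SyntheticBundle, layer: str) -> SyntheticBundle:
    """Copy of the bundle with one input layer removed; ``gene_block`` drops
    A_lg, A_gd and the gene entities together."""
    if layer not in LAYERS:
        raise ValidationError(f"unknown layer {layer!r}; choose from {LAYERS}")
    out = bundle.copy()
    if layer == "gene_block":
        out.A_lg = out.A_gd = None
        out.gene_index = None
        return out
    if (
        layer in ("expression", "lnc_mirna", "lnc_protein")
        and sum(getattr(bundle, ly) is not None for ly in ("expression", "lnc_mirna", "lnc_protein"))
        <= 1
    ):
        raise ValidationError("cannot remove the last lncRNA similarity source")
    if layer == "dis_mirna" and bundle.dag is None:
        raise ValidationError("cannot remove the last disease similarity source")
    setattr(out, layer, None)
    return out
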