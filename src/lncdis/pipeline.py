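"""Stage chaining: inputs -> similarity networks -> diffusion -> model input.

`build_network` is the library entry used by `AssociationModel.from_bundle`;
the CLI subcommands call the same functions stage by stage, writing TSV
artifacts and a manifest between stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from .core import HeteroNetwork, RunConfig
from .diffusion import build_topological_similarity
from .similarity import build_similarity_sets

logger = logging.getLogger("lncdis")


def build_network(bundle, config: RunConfig | None = None) -> HeteroNetwork:
    """Run the similarity and diffusion stages on an input bundle.

    The bundle may be a :class:`~lncdis.synthetic.SyntheticBundle` or any
    object with the same attributes (A, expression, lnc_mirna, lnc_protein,
    dis_mirna, dag, A_lg, A_gd and the entity indexes).
    """
    config = config or RunConfig()
    lnc_set, dis_set = build_similarity_sets(
        expression=bundle.expression,
        lnc_mirna=bundle.lnc_mirna,
        lnc_protein=bundle.lnc_protein,
        dis_mirna=bundle.dis_mirna,
        dag=bundle.dag,
        lnc_index=bundle.lnc_index,
        dis_index=bundle.dis_index,
        alpha_lnc_mirna=config.alpha_lnc_mirna,
        alpha_lnc_protein=config.alpha_lnc_protein,
        alpha_dis_mirna=config.alpha_dis_mirna,
        convention=config.bandwidth_convention,
    )
    topo = build_topological_similarity(
        lnc_set,
        dis_set,
        restart=config.restart_probability,
        fusion=config.fusion,
        tol=config.rwr_tol,
        max_iter=config.rwr_max_iter,
    )
    return HeteroNetwork(
        A=bundle.A, LTS=topo.LTS, DTS=topo.DTS, A_lg=bundle.A_lg, A_gd=bundle.A_gd
    )


def file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class ManifestWriter:
    """Accumulates stage provenance (files, hashes, wall-clock) and writes a
    JSON manifest next to the outputs."""

    def __init__(self, out_dir, config: RunConfig, seed: int):
        self.out_dir = Path(out_dir)
        self.entries: list[dict] = []
        self.config = config
        self.seed = seed
        self._t0 = time.time()

    def add_stage(self, name: str, outputs: list) -> None:
        self.entries.append(
            {
                "stage": name,
                "outputs": {str(p): file_hash(p) for p in outputs},
                "elapsed_s": round(time.time() - self._t0, 3),
            }
        )
        self._t0 = time.time()

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(
            json.dumps(
                {"seed": self.seed, "config": self.config.to_dict(), "stages": self.entries},
                indent=2,
            )
        )
        return path
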