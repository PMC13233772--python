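"""Run configuration with presets mirroring the published parameter sets."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "PRESETS", "substream_seed"]


def substream_seed(master_seed: int, name: str) -> int:
    """Deterministic named substream seed derived from one master seed."""
    mix = np.random.SeedSequence(
        [int(master_seed), zlib.crc32(name.encode())]
    )
    return int(mix.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All pipeline parameters; defaults match the adult-mouse-atlas run.

    Factorization: either a fixed ``K`` or a ``candidate_ks`` scan selected by
    the top-``m`` coverage rule (coverage 0.70). Graph: k=15 Jensen-Shannon
    kNN pruned at the 85th-percentile information radius, Leiden resolution
    1.5, clusters < 20 cells dropped. Refinement: purity rule (<10% or <15
    cells), states < 250 cells merged. One master seed feeds named substreams
    per stage.
    """

    # inputs
    counts_path: str | None = None
    panel_path: str | None = None
    output_dir: str = "castate_run"
    # factorization
    K: int | None = None
    candidate_ks: list[int] = field(
        default_factory=lambda: list(range(4, 17, 2))
    )
    m: int = 4
    coverage: float = 0.70
    restarts: int = 3
    max_iter: int = 500
    tol: float = 1e-5
    # cell-cycle factor flagging
    flag_cycle_factors: bool = False
    cycle_markers: tuple[str, ...] = ("TOP2A", "MKI67", "BIRC5")
    cycle_r_threshold: float = 0.3
    # graph + clustering
    k_neighbors: int = 15
    metric: str = "jsd"
    radius_percentile: float = 0.85
    radius_mode: str = "global"
    resolution: float = 1.5
    min_cluster_size: int = 20
    # refinement
    min_type_fraction: float = 0.10
    min_type_cells: int = 15
    min_state_size: int = 250
    embed_dims: int = 10
    # visualization
    viz_neighbors: int = 50
    # scoring
    top_n_genes: int = 50
    # seeding
    seed: int = 0

    def seed_for(self, stage: str) -> int:
        return substream_seed(self.seed, stage)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        data = asdict(self)
        data["cycle_markers"] = list(self.cycle_markers)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        preset = data.pop("preset", None)
        base = PRESETS[preset] if preset else {}
        merged = {**base, **data}
        if "cycle_markers" in merged:
            merged["cycle_markers"] = tuple(merged["cycle_markers"])
        return cls(**merged)


#: Named parameter sets for the published analyses.
PRESETS: dict[str, dict] = {
    # adult mouse nervous system: k=15, 85th-percentile radius, Leiden 1.5
    "mouse_atlas": {},
    # developing human forebrain: same graph, Leiden 2.5, cell-cycle factors
    # flagged against TOP2A/MKI67/BIRC5 and removed
    "human_dev": {
        "resolution": 2.5,
        "flag_cycle_factors": True,
    },
    # developmental subset re-iteration: coverage rule with m=3, k=100,
    # Leiden 0.6
    "dev_subset": {
        "m": 3,
        "k_neighbors": 100,
        "resolution": 0.6,
    },
    # human EMX1+ re-clustering: correlation distance, Leiden 0.6
    "emx1_correlation": {
        "metric": "correlation",
        "resolution": 0.6,
    },
}
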