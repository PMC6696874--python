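"""Pipeline configuration and deterministic per-stage seeding.

Defaults follow the published protocol: QC at 500 genes / 1,500 UMI /
10% mitochondrial UMIs, 50 principal components as meta-genes, t-SNE
with seed 0 and perplexity 30, 50-nearest-neighbor Jaccard graph, and
top-100 gf-icf cluster signatures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .io_qc import DEFAULT_MITO_PREFIXES

__all__ = ["PipelineConfig", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed from the global seed.

    Stage-name CRC offsets keep stages independent while allowing any
    stage to be rerun in isolation with the same seed it saw in a full
    run.
    """
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    # QC
    min_genes: int = 500
    min_umi: int = 1500
    max_mito_fraction: float = 0.10
    mito_prefixes: tuple = DEFAULT_MITO_PREFIXES
    # gf-icf
    icf_smoothing: str = "add_one_denominator"
    allow_negative_icf: bool = False
    # dimensionality reduction / embedding
    n_components: int = 50
    embed_method: str = "tsne"
    perplexity: float = 30.0
    # graph clustering
    k_neighbors: int = 50
    cluster_space: str = "embedding"   # or "meta_genes"
    # annotation
    signature_size: int = 100
    n_permutations: int = 1000
    weight_exponent: float = 1.0
    # metrics
    distance_weighting: str = "unweighted"   # or "cell_weighted"
    # reproducibility
    seed: int = 0

    _BOOL = {"allow_negative_icf"}
    _INT = {"min_genes", "min_umi", "n_components", "k_neighbors",
            "signature_size", "n_permutations", "seed"}
    _FLOAT = {"max_mito_fraction", "perplexity", "weight_exponent"}

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read ``key = value`` lines; '#' starts a comment."""
        kwargs = {}
        known = {f.name for f in fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"unknown config key: {key!r}")
            kwargs[key] = value
        return cls().updated(**kwargs)

    def updated(self, **overrides) -> "PipelineConfig":
        """Copy with string-or-typed overrides (CLI > file > defaults)."""
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        for key, value in overrides.items():
            if value is None:
                continue
            if isinstance(value, str):
                if key in self._BOOL:
                    value = value.lower() in ("1", "true", "yes")
                elif key in self._INT:
                    value = int(value)
                elif key in self._FLOAT:
                    value = float(value)
                elif key == "mito_prefixes":
                    value = tuple(s.strip() for s in value.split(",") if s.strip())
            values[key] = value
        return PipelineConfig(**values)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["mito_prefixes"] = ",".join(d["mito_prefixes"])
        return d
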