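"""End-to-end orchestration: simulate -> combine -> rank -> ifs -> filters -> compare.

A run is a pure function of (config, seed): one global seed deterministically
derives a seed per stage (by hashing the stage name), so stages can be rerun
independently and a repeated run is byte-identical.  All artifacts are
tab-delimited text plus a JSON manifest recording the config, the seed and
the library versions used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .errors import PipelineError
from .ifs import ClassifierSpec, ifs_scan, select_key_set, summarize_key_features
from .io import combine_tissues, write_annotation, write_combined, write_expression
from .mcfs import MCFSConfig, run_mcfs
from .filters import rank_all
from .overlap import compare_ranks, hypergeom_overlap
from .synthetic import SyntheticSpec, generate_cohort, write_truth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything a full pipeline run needs."""

    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    mcfs: MCFSConfig = field(default_factory=MCFSConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    k_max: int = 500
    delta: float = 0.02
    universe: int | None = None  # None -> combined feature count
    overlap_top: int | None = None  # list size for enrichment; None -> k_final
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        kwargs = dict(cfg)
        if "synthetic" in kwargs:
            kwargs["synthetic"] = SyntheticSpec(**kwargs["synthetic"])
        if "mcfs" in kwargs:
            kwargs["mcfs"] = MCFSConfig(**kwargs["mcfs"])
        if "classifier" in kwargs:
            kwargs["classifier"] = ClassifierSpec(**kwargs["classifier"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _ctx()


def run_all(config: RunConfig, outdir) -> Path:
    """Execute the full pipeline into ``outdir`` and return that path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    with _stage("simulate"):
        spec = replace(config.synthetic, seed=stage_seed(seed, "simulate"))
        tumor, adjacent, ann, truth = generate_cohort(spec)
        write_expression(tumor, out / "tumor.tsv")
        write_expression(adjacent, out / "adjacent.tsv")
        write_annotation(ann, out / "annotation.tsv")
        write_truth(truth, out / "truth.txt")

    with _stage("combine"):
        data = combine_tissues(tumor, adjacent, ann)
        write_combined(data, out / "combined.tsv")

    with _stage("rank"):
        mcfs_cfg = replace(config.mcfs, seed=stage_seed(seed, "rank"))
        ranking = run_mcfs(data, mcfs_cfg)
        ranking.to_tsv(out / "ranking.tsv")

    with _stage("ifs"):
        K = min(config.k_max, data.n_features)
        curve = ifs_scan(data, ranking, config.classifier, K=K)
        curve.to_tsv(out / "curve.tsv")
        k_peak, k_final = select_key_set(curve, config.delta)
        report = summarize_key_features(data, ranking, k_final)
        report.to_tsv(out / "key_features.tsv")

    with _stage("filters"):
        fdir = out / "filters"
        fdir.mkdir(exist_ok=True)
        others = rank_all(data)
        for method, r in others.items():
            r.to_tsv(fdir / f"{method}.tsv")

    with _stage("compare"):
        comparison = compare_ranks(ranking, others, k=k_final)
        comparison.to_tsv(out / "comparison.tsv")
        universe = config.universe or data.n_features
        top = config.overlap_top or k_final
        key_set = set(ranking.top(top))
        with open(out / "enrichment.tsv", "wt", encoding="utf-8") as fh:
            fh.write("method\tuniverse\ta\tb\toverlap\tp\tfold\n")
            for method in sorted(others):
                other_set = set(others[method].top(top))
                res = hypergeom_overlap(universe, top, top, len(key_set & other_set))
                fh.write(
                    f"{method}\t{res.universe}\t{res.a}\t{res.b}\t{res.overlap}"
                    f"\t{res.p!r}\t{res.fold!r}\n"
                )

    with _stage("manifest"):
        manifest = {
            "config": config.to_dict(),
            "seed": seed,
            "stage_seeds": {
                name: stage_seed(seed, name) for name in ("simulate", "rank")
            },
            "k_peak": k_peak,
            "k_final": k_final,
            "tissue_counts": report.tissue_counts,
            "versions": _versions(),
        }
        with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return out


def _versions() -> dict[str, str]:
    import pandas
    import scipy
    import sklearn

    return {
        "mcifs": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "sklearn": sklearn.__version__,
    }
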