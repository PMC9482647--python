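"""Run configuration and end-to-end orchestration.

A run is described by a YAML file::

    k: 3
    seed: 11
    alpha: 0.1
    # any other RISynG parameter (eig_mode, scale_factor, ...) may appear
    preprocess:
      max_missing_frac: 0.05
      top_n: 2000
    views:
      - path: mrna.tsv
        name: mRNA
        modality: sequence_expression
      - path: meth.tsv
        name: metDNA
        modality: methylation_beta

Every effective parameter, including defaults, is echoed into the run log
so a result can be traced back to its exact configuration.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cluster import risyng_run
from .integration import ClusteringResult
from .io import align_samples, preprocess_view, read_view

__all__ = ["RISynGConfig", "load_config", "run_from_config", "write_results"]

logger = logging.getLogger("risyng")

_ESTIMATOR_KEYS = (
    "alpha",
    "eig_mode",
    "scale_factor",
    "gramian_squared",
    "zero_diagonal",
    "use_shifted_laplacian",
    "literal_power",
    "row_normalize",
    "reorthonormalize",
    "kmeans_restarts",
    "t_max",
)


@dataclass
class ViewConfig:
    path: str
    name: str | None = None
    modality: str = "other"
    log: bool | None = None
    delimiter: str | None = None


@dataclass
class RISynGConfig:
    """Validated run configuration with every tunable parameter."""

    k: int
    views: list[ViewConfig]
    seed: int = 0
    alpha: float = 0.1
    eig_mode: str = "smallest"
    scale_factor: float = 1.0
    gramian_squared: bool = False
    zero_diagonal: bool = False
    use_shifted_laplacian: bool = True
    literal_power: bool = False
    row_normalize: bool = False
    reorthonormalize: bool = False
    kmeans_restarts: int = 50
    t_max: int = 300
    max_missing_frac: float = 0.05
    top_n: int = 2000

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if not self.views:
            raise ValueError("configuration lists no views")

    def estimator_params(self) -> dict:
        d = asdict(self)
        return {key: d[key] for key in _ESTIMATOR_KEYS}


def load_config(path: str | Path) -> RISynGConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    pre = raw.pop("preprocess", {}) or {}
    views = [ViewConfig(**v) for v in raw.pop("views", [])]
    known = {f for f in RISynGConfig.__dataclass_fields__} - {"views"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    return RISynGConfig(views=views, **raw, **pre)


def run_from_config(
    config: RISynGConfig | str | Path,
    base_dir: str | Path | None = None,
) -> ClusteringResult:
    """Preprocess the configured views, run the estimator, return the result."""
    if not isinstance(config, RISynGConfig):
        base_dir = base_dir or Path(config).parent
        config = load_config(config)
    base = Path(base_dir) if base_dir is not None else Path(".")

    views = []
    for vc in config.views:
        path = Path(vc.path)
        if not path.is_absolute():
            path = base / path
        view = read_view(path, name=vc.name, modality=vc.modality,
                         delimiter=vc.delimiter)
        views.append(
            preprocess_view(
                view,
                max_missing_frac=config.max_missing_frac,
                top_n=config.top_n,
                log=vc.log,
            )
        )
    data = align_samples(views)
    for key, value in sorted(asdict(config).items()):
        if key != "views":
            logger.info("config %s = %r", key, value)
    logger.info("dataset: %d views, %d shared samples", data.n_views, data.n_samples)
    params = config.estimator_params()
    params["seed"] = config.seed
    return risyng_run(data, k=config.k, config=params)


def write_results(result: ClusteringResult, out_dir: str | Path,
                  sample_ids: list[str] | None = None) -> dict[str, Path]:
    """Write labels, per-view diagnostics and the final basis as TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = result.labels.size
    ids = sample_ids or [f"S{i:04d}" for i in range(n)]
    paths = {
        "labels": out / "labels.tsv",
        "diagnostics": out / "view_diagnostics.tsv",
        "basis": out / "accretive_basis.tsv",
    }
    pd.DataFrame({"sample_id": ids, "cluster": result.labels}).to_csv(
        paths["labels"], sep="\t", index=False
    )
    pd.DataFrame(result.per_view).to_csv(paths["diagnostics"], sep="\t", index=False)
    pd.DataFrame(
        result.b_final,
        index=ids,
        columns=[f"dim{j}" for j in range(result.b_final.shape[1])],
    ).to_csv(paths["basis"], sep="\t", index_label="sample_id")
    return paths
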