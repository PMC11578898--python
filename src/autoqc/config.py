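"""Run configuration for the automated QC pipeline, with YAML loading."""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import yaml

from .errors import ConfigError
from .gmm import DEFAULT_GUIDANCE, MetricGuidance
from .qc_metrics import GeneSetConfig

#: The four metrics the per-cell classification defaults to.
DEFAULT_DECISION_METRICS = (
    "log1p_n_counts",
    "log1p_n_genes",
    "percent_mito",
    "percent_spliced",
)


@dataclass
class QCConfig:
    """Every tunable of the QC pipeline, with the package defaults.

    ``metrics`` is the subset of QC metrics used for the per-cell pass/fail
    conjunction; ``guidance`` maps metric name -> anchor interval.  Clustering
    uses ``k_neighbors`` and a low Leiden ``resolution``; the mixtures scan
    1..``k_max`` components unless ``fixed_k`` pins the count.
    """

    metrics: tuple[str, ...] = DEFAULT_DECISION_METRICS
    guidance: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GUIDANCE)
    )
    k_neighbors: int = 15
    resolution: float = 0.2
    k_max: int = 10
    fixed_k: int | None = None
    pass_fraction_threshold: float = 0.5
    doublet_threshold: float = 0.25
    min_frac: float = 0.10
    min_cells: int = 100
    layout: str = "pca"
    genesets: GeneSetConfig = field(default_factory=GeneSetConfig)

    def __post_init__(self) -> None:
        if not self.metrics:
            raise ConfigError("empty decision-metric subset")
        if self.k_max < 1 or (self.fixed_k is not None and self.fixed_k < 1):
            raise ConfigError("component counts must be >= 1")

    def guidance_for(self, metric: str) -> MetricGuidance:
        if metric in self.guidance:
            low, high = self.guidance[metric]
            return MetricGuidance(metric, float(low), float(high))
        return MetricGuidance.default(metric)

    def with_guidance(self, metric: str, low: float, high: float) -> "QCConfig":
        gd = dict(self.guidance)
        gd[metric] = (low, high)
        return replace(self, guidance=gd)

    def snapshot(self) -> dict:
        """JSON-serializable snapshot recorded in the run report."""
        d = asdict(self)
        d["guidance"] = {
            m: [None if math.isinf(lo) else lo, None if math.isinf(hi) else hi]
            for m, (lo, hi) in self.guidance.items()
        }
        d["metrics"] = list(self.metrics)
        d["genesets"] = {
            "mito_prefixes": list(self.genesets.mito_prefixes),
            "ribo_prefixes": list(self.genesets.ribo_prefixes),
            "hb_regex": self.genesets.hb_regex,
            "top_n": self.genesets.top_n,
        }
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "QCConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "QCConfig":
        kwargs: dict = {}
        simple = {
            "k_neighbors", "resolution", "k_max", "fixed_k",
            "pass_fraction_threshold", "doublet_threshold",
            "min_frac", "min_cells", "layout",
        }
        for key, val in raw.items():
            if key in simple:
                kwargs[key] = val
            elif key == "metrics":
                kwargs["metrics"] = tuple(val)
            elif key == "guidance":
                kwargs["guidance"] = {
                    m: (
                        -math.inf if lo is None else float(lo),
                        math.inf if hi is None else float(hi),
                    )
                    for m, (lo, hi) in val.items()
                }
            elif key == "genesets":
                kwargs["genesets"] = GeneSetConfig(
                    mito_prefixes=tuple(val.get("mito_prefixes", ("MT-",))),
                    ribo_prefixes=tuple(val.get("ribo_prefixes", ("RPS", "RPL"))),
                    hb_regex=val.get("hb_regex", r"^HB[ABDEGMQZ]"),
                    top_n=int(val.get("top_n", 50)),
                )
            else:
                raise ConfigError(f"unknown config key {key!r}")
        merged = dict(DEFAULT_GUIDANCE)
        merged.update(kwargs.get("guidance", {}))
        kwargs["guidance"] = merged
        return cls(**kwargs)
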