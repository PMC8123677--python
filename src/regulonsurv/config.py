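"""Pipeline configuration: every tunable in one validated structure."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


def _check_unknown(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {section}: {sorted(unknown)}")


@dataclass
class SimulateConfig:
    n_regulators: int = 5
    targets_per_regulator: int = 20
    frac_negative: float = 0.2
    overlap_frac: float = 0.0
    beta: float = 1.0
    n_train_samples: int = 60
    train_sigma: float = 0.5
    n_decoys: int = 200
    n_low_expression: int = 0
    n_tumour: int = 40
    n_benign: int = 12
    delta: float = 3.0
    cohort_sigma: float = 0.5
    active_fraction: float = 0.5
    n_active_regulators: int = 1
    true_hr: float = 6.0
    baseline_rate: float = 0.028881  # ln2 / 24 events per month
    censor_time: float = 60.0


@dataclass
class InferenceConfig:
    expression_threshold: float = 1.0
    n_perm: int = 1000
    fdr: float = 0.05
    dpi_tolerance: float = 0.0


@dataclass
class GraphConfig:
    min_jaccard: float = 0.1
    shadow: bool = True
    overlap_alpha: float = 0.01
    shadow_n_perm: int = 500


@dataclass
class DEGConfig:
    pseudocount: float = 1.0
    lfc_threshold: float = 1.0
    fdr: float = 0.05


@dataclass
class GGEAConfig:
    cap: float = 3.0
    fdr: float = 0.05
    n_perm: int = 1000


@dataclass
class SurvivalConfig:
    alpha: float = 0.05
    covariates: tuple = ("gleason", "stage")


@dataclass
class PipelineConfig:
    """All stage parameters plus the single top-level seed."""

    seed: int = 0
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    deg: DEGConfig = field(default_factory=DEGConfig)
    ggea: GGEAConfig = field(default_factory=GGEAConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)

    _SECTIONS = {
        "simulate": SimulateConfig,
        "inference": InferenceConfig,
        "graph": GraphConfig,
        "deg": DEGConfig,
        "ggea": GGEAConfig,
        "survival": SurvivalConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        _check_unknown("top level", data, {"seed", "log_level", *cls._SECTIONS})
        kwargs = {}
        for key in ("seed", "log_level"):
            if key in data:
                kwargs[key] = data[key]
        for name, section_cls in cls._SECTIONS.items():
            section = dict(data.get(name) or {})
            allowed = {f.name for f in fields(section_cls)}
            _check_unknown(name, section, allowed)
            if name == "survival" and "covariates" in section:
                section["covariates"] = tuple(section["covariates"])
            kwargs[name] = section_cls(**section)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["survival"]["covariates"] = list(d["survival"]["covariates"])
        return d
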