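"""Schema-validated pipeline configuration (YAML file + CLI overrides).

Defaults are the published operating point of the procedure: threshold
modulation 0.6 / 0.82 / 0.86, geometric filters 3 / 130,000 / 900 px,
linking k = 2. Unknown keys are rejected so typos cannot silently revert a
parameter to its default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .contrast import ThresholdParams
from .linking import LinkParams
from .phantom import PhantomSpec
from .segments import FilterParams


@dataclass(frozen=True)
class EvalParams:
    min_overlap: float = 0.5
    roi_margin_nm: float = 500.0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_overlap <= 1.0:
            raise ValueError(f"min_overlap must be in (0, 1], got {self.min_overlap}")
        if self.roi_margin_nm < 0:
            raise ValueError(f"roi_margin_nm must be >= 0, got {self.roi_margin_nm}")


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, grouped by stage."""

    threshold: ThresholdParams = field(default_factory=ThresholdParams)
    filter: FilterParams = field(default_factory=FilterParams)
    link: LinkParams = field(default_factory=LinkParams)
    eval: EvalParams = field(default_factory=EvalParams)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    equalize: bool = True
    prune: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


_GROUPS = {
    "threshold": ThresholdParams,
    "filter": FilterParams,
    "link": LinkParams,
    "eval": EvalParams,
    "phantom": PhantomSpec,
}
_SCALARS = {"equalize", "prune", "seed"}

# config-file key -> dataclass field, where they differ
_KEY_ALIASES = {
    "filter": {"min_area": "min_area_px", "max_area": "max_area_px", "max_major_axis": "max_major_axis_px"},
    "link": {"max_distance_nm": "max_link_distance_nm"},
}


def _build_group(name: str, cls, raw: dict):
    aliases = _KEY_ALIASES.get(name, {})
    known = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        fname = aliases.get(key, key)
        if fname not in known:
            raise ValueError(f"unknown config key: {name}.{key}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[fname] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config; apply dotted-key overrides (e.g. link.k=3).

    Raises ``ValueError`` on unknown keys or invalid parameter values, before
    any computation runs.
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = loaded
    for dotted, value in (overrides or {}).items():
        group, _, key = dotted.partition(".")
        if key:
            raw.setdefault(group, {})[key] = value
        else:
            raw[group] = value

    cfg_kwargs: dict = {}
    for key, value in raw.items():
        if key in _GROUPS:
            if not isinstance(value, dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            cfg_kwargs[key] = _build_group(key, _GROUPS[key], value)
        elif key in _SCALARS:
            cfg_kwargs[key] = value
        else:
            raise ValueError(f"unknown config key: {key}")
    return PipelineConfig(**cfg_kwargs)
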