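"""Study configuration: schema, validation, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .equating import METHODS
from .population import GeneratorConfig
from .simulation import CRITERIA, SAMPLE_SIZES, SIM_METHODS, TEST_LENGTHS

__all__ = ["StudyConfig", "ConfigError"]


class ConfigError(ValueError):
    """Configuration schema violation; the message names the field path."""


@dataclass
class StudyConfig:
    """Everything needed to reproduce a run bit-identically.

    Defaults reproduce the full 240-cell study grid for one design.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    design: str = "eg"
    methods: tuple = METHODS
    sample_sizes: tuple = SAMPLE_SIZES
    test_lengths: tuple = TEST_LENGTHS
    sim_methods: tuple = SIM_METHODS
    criteria: tuple = CRITERIA
    replications: int = 500
    seed: int = 0
    dtm_threshold: float = 0.5
    presmooth_degree: int = 3
    margin_degrees: tuple = (3, 3)
    cross_terms: int = 1
    linking: str = "stocking-lord"
    mixture_weight: float = 0.5
    anchor_fraction: float = 0.30
    output: str = "results"

    def __post_init__(self):
        def check(cond, path, msg):
            if not cond:
                raise ConfigError(f"{path}: {msg}")

        check(self.design in ("eg", "neat"), "design", "must be 'eg' or 'neat'")
        for m in self.methods:
            check(m in METHODS, f"methods[{m}]", f"must be one of {METHODS}")
        for c in self.criteria:
            check(c in CRITERIA, f"criteria[{c}]", f"must be one of {CRITERIA}")
        for s in self.sim_methods:
            check(s in SIM_METHODS, f"sim_methods[{s}]", f"must be one of {SIM_METHODS}")
        for n in self.sample_sizes:
            check(int(n) >= 2, f"sample_sizes[{n}]", "must be >= 2")
        for L in self.test_lengths:
            check(2 <= int(L) <= 80, f"test_lengths[{L}]", "must be in [2, 80]")
        check(self.replications >= 2, "replications", "must be >= 2")
        check(self.dtm_threshold > 0, "dtm_threshold", "must be positive")
        check(0 < self.mixture_weight < 1, "mixture_weight", "must be in (0, 1)")
        check(0 < self.anchor_fraction < 1, "anchor_fraction", "must be in (0, 1)")

    # ------------------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d or {})
        gen = d.pop("generator", {})
        try:
            gcfg = GeneratorConfig(**gen)
        except TypeError as exc:
            raise ConfigError(f"generator: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__ if f != "generator"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown fields: {sorted(unknown)}")
        for key in ("methods", "sample_sizes", "test_lengths", "sim_methods",
                    "criteria", "margin_degrees"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(generator=gcfg, **d)

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def method_options(self) -> dict:
        return {
            "EE": {},
            "KE": {
                "presmooth_degree": self.presmooth_degree,
                "margin_degrees": self.margin_degrees,
                "cross_terms": self.cross_terms,
            },
            "IRT": {"linking": self.linking, "mixture_weight": self.mixture_weight},
            "IRTKE": {"linking": self.linking, "mixture_weight": self.mixture_weight},
        }
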