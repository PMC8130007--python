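"""Run configuration: one YAML document describing a reproducible AL run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .al_engine import ALVariant, InitialSizes, SplitRatios
from .classifier import ClassifierSpec, Family
from .sampling import SamplingConfig


@dataclass
class RunConfig:
    variant: ALVariant = ALVariant.DUAL_MODEL_VAL_UPDATE
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    ratios: SplitRatios = field(default_factory=SplitRatios)
    sizes: InitialSizes = field(default_factory=InitialSizes)
    rounds: int = 2
    seed: int = 0
    sd_threshold: float = 0.03
    eval_threshold: float = 0.5
    recall_target: float = 0.99
    acquisition_preference: str = "union"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variant"] = self.variant.value
        d["classifier"]["family"] = self.classifier.family.value
        d["classifier"]["calibration"] = self.classifier.calibration.value
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs: dict = {}
        if "variant" in d:
            try:
                kwargs["variant"] = ALVariant(d.pop("variant"))
            except ValueError as exc:
                raise ValueError(f"unknown variant: {exc}") from None
        for key, typ in (
            ("classifier", ClassifierSpec),
            ("sampling", SamplingConfig),
            ("ratios", SplitRatios),
            ("sizes", InitialSizes),
        ):
            if key in d:
                try:
                    kwargs[key] = typ(**d.pop(key))
                except (TypeError, ValueError) as exc:
                    raise ValueError(f"invalid {key} config: {exc}") from None
        for key in (
            "rounds",
            "seed",
            "sd_threshold",
            "eval_threshold",
            "recall_target",
            "acquisition_preference",
        ):
            if key in d:
                kwargs[key] = d.pop(key)
        if d:
            raise ValueError(f"unknown config fields: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
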