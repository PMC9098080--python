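"""Pipeline-wide configuration bundle with YAML round-trip and validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from usvpipe.errors import ConfigError
from usvpipe.frontend import FilterBankParams, SpectrogramParams
from usvpipe.model import ClassifierConfig
from usvpipe.segment import SegmenterParams

_RESAMPLING_MODES = ("none", "bootstrap", "undersample", "oversample")
_POOLING_SCHEMES = ("12", "11", "6", "5", "3", "2", "EV6")


@dataclass
class PipelineConfig:
    """All module parameter blocks plus run-level seeds and modes.

    Construction validates every block (each block's own ``__post_init__``
    runs), so an invalid YAML fails fast with a named error.
    """

    spectrogram: SpectrogramParams = field(default_factory=SpectrogramParams)
    filterbank: FilterBankParams = field(default_factory=FilterBankParams)
    segmenter: SegmenterParams = field(default_factory=SegmenterParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    resampling: str = "bootstrap"
    n_bootstraps: int = 10
    pooling: str = "12"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resampling not in _RESAMPLING_MODES:
            raise ConfigError(f"resampling must be one of {_RESAMPLING_MODES}")
        if self.pooling not in _POOLING_SCHEMES:
            raise ConfigError(f"pooling must be one of {_POOLING_SCHEMES}")
        if self.n_bootstraps < 1:
            raise ConfigError("n_bootstraps must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        blocks = {
            "spectrogram": SpectrogramParams,
            "filterbank": FilterBankParams,
            "segmenter": SegmenterParams,
            "classifier": ClassifierConfig,
        }
        kwargs = {}
        for key, value in data.items():
            if key in blocks:
                if isinstance(value, dict):
                    value = {k: tuple(v) if isinstance(v, list) else v
                             for k, v in value.items()}
                    value = blocks[key](**value)
                kwargs[key] = value
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
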