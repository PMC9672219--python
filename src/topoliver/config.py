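"""Run configuration: one serializable object controlling every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .lbp import LBPConfig
from .modeling import TreeHyperparams

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of an end-to-end run.

    ``patch_size`` defaults to 16 for the 128-px synthetic phantoms
    (the patching module itself defaults to 32, sized for 256-512 px
    clinical matrices).  ``superlevel`` negates intensities so bright
    features enter the filtration first; ``use_dims`` selects which
    homology dimensions feed the feature vector.
    """

    patch_size: int = 16
    stride: int | None = None
    superlevel: bool = False
    cap_policy: str = "cap_to_max"
    resolution: tuple[int, int] = (20, 20)
    sigma_scale: float = 0.05
    use_dims: tuple[int, ...] = (0, 1)
    lbp_method: str = "u2"
    lbp_normalize: bool = True
    k: int = 5
    cv_seed: int = 0
    tree: TreeHyperparams = field(default_factory=TreeHyperparams)

    @property
    def lbp(self) -> LBPConfig:
        return LBPConfig(method=self.lbp_method, normalize=self.lbp_normalize)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["resolution"] = list(self.resolution)
        d["use_dims"] = list(self.use_dims)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "tree" in data and isinstance(data["tree"], dict):
            data["tree"] = TreeHyperparams(**data["tree"])
        for key in ("resolution", "use_dims"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
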