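"""Run configuration: the thresholds and cross-validation settings shared
by the CLI subcommands, serializable to a flat YAML file."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    threshold: float = 0.5  # positive-call probability
    forced_threshold: float = 0.1  # forced-mode floor on the max probability
    rho_threshold: float = 0.1  # SSP minimal Spearman rho
    n_folds: int = 7  # split-sample CV folds
    vdv_alpha: float = 0.10  # van der Voet significance level
    n_randomizations: int = 2000
    kappa_scheme: str = "linear"
    center_only: bool = False
    seed: int | None = None  # required for stochastic operations

    def __post_init__(self) -> None:
        for name in ("threshold", "forced_threshold", "rho_threshold",
                     "vdv_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
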