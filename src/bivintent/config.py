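"""Run configuration: one YAML file drives a full pipeline run."""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclasses.dataclass
class RunConfig:
    """Everything a pipeline run needs; the seed is echoed in every output."""

    input: str | None = None            # None -> simulate
    output_dir: str = "runs/latest"
    seed: int = 0
    mcmc_iterations: int = 10_000
    mcmc_burnin: int = 1_000
    run_selection: bool = False         # DIC forward selection (slow)
    bbg_covariates: list[str] = dataclasses.field(
        default_factory=lambda: ["doubts_cat", "flu_vaccine_2019",
                                 "risk_cat", "trust_cat", "s(age)"]
    )
    motivation_covariates: list[str] = dataclasses.field(
        default_factory=lambda: ["measure_type", "motivation_target",
                                 "gender", "age"]
    )
    conspiracy_covariates: list[str] = dataclasses.field(
        default_factory=lambda: ["gender", "trust_cat", "doubts_cat"]
    )
    tercile_bounds: dict[str, list[float]] = dataclasses.field(default_factory=dict)
    schema: dict[str, str] = dataclasses.field(default_factory=dict)
    synthetic_n: int = 448

    def __post_init__(self):
        if not self.mcmc_iterations > self.mcmc_burnin >= 0:
            raise ValueError("require mcmc_iterations > mcmc_burnin >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: Mapping[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def write_manifest(self, out_dir: str | Path) -> Path:
        """Machine-readable run manifest: seed, versions, config echo."""
        import numpy, pandas, scipy  # noqa: PLC0415

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "seed": self.seed,
            "config": dataclasses.asdict(self),
            "versions": {
                "python": platform.python_version(),
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pandas.__version__,
            },
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
        return path
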