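"""Pipeline configuration: schema, defaults, validation, run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "STAGES"]

STAGES = ("simulate", "faers", "signals", "meta", "mr", "network", "report")


@dataclass
class Thresholds:
    gwas_p: float = 5e-8
    ld_r2: float = 0.1
    f_stat: float = 10.0
    fdr: float = 0.05
    score: float = 400.0
    signal_min_cases: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ebgm_z: float = 1.645

    def violations(self) -> list[str]:
        out = []
        if not (0 < self.gwas_p < 1):
            out.append(f"gwas_p must lie in (0, 1), got {self.gwas_p}")
        if not (0 < self.ld_r2 < 1):
            out.append(f"ld_r2 must lie in (0, 1), got {self.ld_r2}")
        if self.f_stat <= 0:
            out.append(f"f_stat must be positive, got {self.f_stat}")
        if not (0 < self.fdr <= 1):
            out.append(f"fdr must lie in (0, 1], got {self.fdr}")
        if not (0 <= self.score <= 1000):
            out.append(f"score must lie in [0, 1000], got {self.score}")
        if self.signal_min_cases < 1:
            out.append(f"signal_min_cases must be >= 1, got {self.signal_min_cases}")
        return out


@dataclass
class SimulateSection:
    n_reports: int = 20_000
    duplicate_rate: float = 0.05
    planted_signals: list = field(
        default_factory=lambda: [["DrugA", "Guillain-Barre syndrome", 10.0]]
    )
    n_snps: int = 5_000
    n_proteins: int = 8
    n_causal_proteins: int = 3
    causal_beta: float = 0.5
    instruments_per_protein: int = 12


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "gbsig_out"
    log_level: str = "INFO"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    event_terms: list[str] = field(default_factory=lambda: ["Guillain-Barre syndrome"])
    top_signals: int = 30
    roles: list[str] = field(default_factory=lambda: ["PS", "SS", "C", "I"])
    inputs: dict[str, str] = field(default_factory=dict)
    simulate: SimulateSection = field(default_factory=SimulateSection)
    thresholds: Thresholds = field(default_factory=Thresholds)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31 derived from the run seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)

    def canonical(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _build(data: dict) -> tuple[PipelineConfig, list[str]]:
    violations: list[str] = []
    known = {
        "seed", "out_dir", "log_level", "stages", "event_terms", "top_signals",
        "roles", "inputs", "simulate", "thresholds",
    }
    for key in data:
        if key not in known:
            violations.append(f"unknown configuration key: {key!r}")

    cfg = PipelineConfig()
    for key in ("seed", "out_dir", "log_level", "top_signals"):
        if key in data:
            setattr(cfg, key, data[key])
    for key in ("stages", "event_terms", "roles"):
        if key in data:
            setattr(cfg, key, list(data[key]))
    cfg.inputs = dict(data.get("inputs", {}))

    sim = data.get("simulate", {})
    if isinstance(sim, dict):
        for k, v in sim.items():
            if hasattr(cfg.simulate, k):
                setattr(cfg.simulate, k, v)
            else:
                violations.append(f"unknown simulate key: {k!r}")
    th = data.get("thresholds", {})
    if isinstance(th, dict):
        for k, v in th.items():
            if hasattr(cfg.thresholds, k):
                setattr(cfg.thresholds, k, v)
            else:
                violations.append(f"unknown threshold key: {k!r}")

    for stage in cfg.stages:
        if stage not in STAGES:
            violations.append(f"unknown stage: {stage!r}")
    violations.extend(cfg.thresholds.violations())
    if not cfg.event_terms:
        violations.append("event_terms must not be empty")
    if cfg.simulate.n_reports < 1:
        violations.append("simulate.n_reports must be >= 1")
    if not (0 <= cfg.simulate.duplicate_rate < 1):
        violations.append("simulate.duplicate_rate must lie in [0, 1)")
    for name, path in cfg.inputs.items():
        if not Path(path).exists():
            violations.append(f"input {name!r} does not exist: {path}")
    return cfg, violations


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML config, reporting every violation at once."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data).__name__}")
    cfg, violations = _build(data)
    if violations:
        raise ConfigurationError("invalid configuration:\n  - " + "\n  - ".join(violations))
    return cfg


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict] = field(default_factory=dict)  # stage -> {duration_s, counts}
    input_checksums: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, duration_s: float, counts: dict) -> None:
        if stage in self.stages:
            raise ConfigurationError(f"stage {stage!r} recorded twice in the manifest")
        self.stages[stage] = {"duration_s": round(duration_s, 3), "counts": counts}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
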