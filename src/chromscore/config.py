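"""Structured pipeline configuration and run manifests.

One YAML file drives every stage; each stage's manifest records the digest
of the config sections it depends on, the seeds used, and checksums of its
outputs, so reruns with an unchanged config skip up-to-date stages and any
artifact is traceable to the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .synthetic_fixtures import ASSAY_SCHEMES


class ConfigError(ValueError):
    pass


@dataclass
class FixtureSection:
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_cell_types: int = 3
    n_elements: int = 40
    n_repressive: int = 15
    n_genes: int = 10
    effect: float = 3.0
    noise_sd: float = 0.25
    schemes: tuple[str, ...] = ASSAY_SCHEMES


@dataclass
class LabelsSection:
    sharpr_act_thresh: float = 1.0
    sharpr_rep_thresh: float = -1.0
    pvalue_alpha: float = 0.05
    peak_top_fraction: float = 0.10
    neutral_ratio: int = 3


@dataclass
class FeaturesSection:
    window: int = 2000
    step: int = 25
    n_pcs: int = 3
    n_states: int = 25


@dataclass
class ExpertsSection:
    n_members: int = 100
    C: float = 1.0


@dataclass
class TracksSection:
    n_quantile_bins: int = 1000
    n_normalization_sample: int = 100_000
    n_correlation_sample: int = 50_000


@dataclass
class HMMSection:
    K: int = 15
    top_fraction: float = 0.02
    n_restarts: int = 5
    max_iter: int = 200
    tol: float = 1e-4


@dataclass
class EvaluationSection:
    n_reps: int = 20
    chunk: int = 5_000
    p_train: float = 0.75


@dataclass
class PipelineConfig:
    seed: int = 0
    bin_size: int = 25
    fixture: FixtureSection = field(default_factory=FixtureSection)
    labels: LabelsSection = field(default_factory=LabelsSection)
    features: FeaturesSection = field(default_factory=FeaturesSection)
    experts: ExpertsSection = field(default_factory=ExpertsSection)
    tracks: TracksSection = field(default_factory=TracksSection)
    hmm: HMMSection = field(default_factory=HMMSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)

    def section_digest(self, *sections: str) -> str:
        """Stable digest of the named config sections plus the global seed."""
        payload = {"seed": self.seed, "bin_size": self.bin_size}
        for s in sections:
            payload[s] = asdict(getattr(self, s))
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=list).encode()
        ).hexdigest()


_SECTION_TYPES = {
    "fixture": FixtureSection,
    "labels": LabelsSection,
    "features": FeaturesSection,
    "experts": ExpertsSection,
    "tracks": TracksSection,
    "hmm": HMMSection,
    "evaluation": EvaluationSection,
}


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys raise with their path."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    cfg = PipelineConfig()
    for key, val in raw.items():
        if key in ("seed", "bin_size"):
            setattr(cfg, key, int(val))
        elif key in _SECTION_TYPES:
            section_cls = _SECTION_TYPES[key]
            known = {f.name for f in fields(section_cls)}
            unknown = set(val) - known
            if unknown:
                raise ConfigError(f"{key}.{sorted(unknown)[0]}: unknown config field")
            kwargs = dict(val)
            if "schemes" in kwargs:
                kwargs["schemes"] = tuple(kwargs["schemes"])
            setattr(cfg, key, section_cls(**kwargs))
        else:
            raise ConfigError(f"{key}: unknown config section")
    return cfg


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    stage: str
    config_digest: str
    seed: int
    outputs: dict[str, str]
    timestamp: float

    def write(self, path: Path) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def read(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def stage_up_to_date(manifest_path: Path, digest: str, base: Path) -> bool:
    """A stage is current if its manifest digest and output checksums match."""
    if not manifest_path.exists():
        return False
    try:
        m = RunManifest.read(manifest_path)
    except (json.JSONDecodeError, TypeError):
        return False
    if m.config_digest != digest:
        return False
    for rel, checksum in m.outputs.items():
        p = base / rel
        if not p.exists() or file_sha256(p) != checksum:
            return False
    return True


def write_stage_manifest(
    manifest_path: Path, stage: str, digest: str, seed: int, outputs: list[Path], base: Path
) -> RunManifest:
    m = RunManifest(
        stage=stage,
        config_digest=digest,
        seed=seed,
        outputs={str(p.relative_to(base)): file_sha256(p) for p in outputs},
        timestamp=time.time(),
    )
    m.write(manifest_path)
    return m
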