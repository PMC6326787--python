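"""Run configuration: a flat YAML file drives every pipeline stage.

One config file describes a sample (technique, read structure, paths,
analysis parameters) and is passed unchanged to each stage, so a run is
reproducible from the config plus the per-stage manifests the pipeline
writes next to its outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .coordinate import Technique
from .genome import ConfigurationError

__all__ = ["SimulateConfig", "RunConfig", "parse_config", "write_manifest"]

KNOWN_KEYS = {
    "technique",
    "sample",
    "output_dir",
    "reference",
    "organelles",
    "fastq",
    "alignments",
    "barcode",
    "umi_length",
    "min_mapq",
    "windows",
    "per_chromosome_normalization",
    "unique_site_weighting",
    "seed",
    "simulate",
}

REQUIRED_KEYS = ("technique", "sample", "output_dir")

SIMULATE_KEYS = {"chromosomes", "n_sites", "read_length", "duplication_rate"}


@dataclass(frozen=True)
class SimulateConfig:
    """Parameters of the ``simulate`` stage."""

    chromosomes: tuple[tuple[str, int, str, float], ...]
    n_sites: int = 1000
    read_length: int = 50
    duplication_rate: float = 0.0


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one sample."""

    technique: Technique
    sample: str
    output_dir: Path
    reference: Path | None = None
    organelles: Mapping[str, str] = field(default_factory=dict)
    fastq: Path | None = None
    alignments: Path | None = None
    barcode: str = ""
    umi_length: int = 0
    min_mapq: int = 0
    windows: tuple[int, ...] = (100, 15)
    per_chromosome_normalization: bool = False
    unique_site_weighting: bool = False
    seed: int = 0
    simulate: SimulateConfig | None = None

    # --- resolved output locations -------------------------------------
    def path_reference(self) -> Path:
        return self.reference or self.output_dir / "reference.fa"

    def path_fastq(self) -> Path:
        return self.fastq or self.output_dir / f"{self.sample}.reads.fastq"

    def path_alignments(self) -> Path:
        return self.alignments or self.output_dir / f"{self.sample}.alignments.bed"

    def path_trimmed_fastq(self) -> Path:
        return self.output_dir / f"{self.sample}.trimmed.fastq"

    def path_dedup_bed(self) -> Path:
        return self.output_dir / f"{self.sample}.dedup.bed"

    def path_truth_bed(self) -> Path:
        return self.output_dir / f"{self.sample}.truth.bed"

    def path_site_bed(self) -> Path:
        return self.output_dir / f"{self.sample}.sites.bed"

    def path_counts_tsv(self) -> Path:
        return self.output_dir / f"{self.sample}.counts.tsv"

    def path_rejects_tsv(self) -> Path:
        return self.output_dir / f"{self.sample}.rejected.tsv"

    def manifest_dict(self) -> dict[str, Any]:
        """All effective settings, defaults included, JSON-serializable."""
        return {
            "technique": self.technique.value,
            "sample": self.sample,
            "output_dir": str(self.output_dir),
            "reference": str(self.path_reference()),
            "organelles": dict(self.organelles),
            "fastq": str(self.path_fastq()),
            "alignments": str(self.path_alignments()),
            "barcode": self.barcode,
            "umi_length": self.umi_length,
            "min_mapq": self.min_mapq,
            "windows": list(self.windows),
            "per_chromosome_normalization": self.per_chromosome_normalization,
            "unique_site_weighting": self.unique_site_weighting,
            "seed": self.seed,
            "simulate": None
            if self.simulate is None
            else {
                "chromosomes": [list(c) for c in self.simulate.chromosomes],
                "n_sites": self.simulate.n_sites,
                "read_length": self.simulate.read_length,
                "duplication_rate": self.simulate.duplication_rate,
            },
        }


def parse_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config.

    Unknown keys are rejected by name (typos surface immediately); missing
    required keys are reported by name; the technique parse is
    case-insensitive. Input paths that are named in the config must exist,
    except that ``reference`` may be absent when a ``simulate`` block will
    generate it.
    """
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a key: value mapping")
    unknown = sorted(set(data) - KNOWN_KEYS)
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown config key(s): {', '.join(unknown)}"
        )
    missing = [k for k in REQUIRED_KEYS if k not in data]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required key(s): {', '.join(missing)}"
        )
    technique = Technique.parse(data["technique"])

    sim = None
    if "simulate" in data and data["simulate"] is not None:
        block = data["simulate"]
        unknown = sorted(set(block) - SIMULATE_KEYS)
        if unknown:
            raise ConfigurationError(
                f"{path}: unknown simulate key(s): {', '.join(unknown)}"
            )
        chroms = []
        for item in block.get("chromosomes", []):
            chroms.append(
                (
                    str(item["name"]),
                    int(item["length"]),
                    str(item["organelle"]),
                    float(item.get("gc", 0.5)),
                )
            )
        if not chroms:
            raise ConfigurationError(
                f"{path}: simulate block needs at least one chromosome"
            )
        sim = SimulateConfig(
            chromosomes=tuple(chroms),
            n_sites=int(block.get("n_sites", 1000)),
            read_length=int(block.get("read_length", 50)),
            duplication_rate=float(block.get("duplication_rate", 0.0)),
        )

    def opt_path(key: str) -> Path | None:
        return Path(data[key]) if data.get(key) else None

    config = RunConfig(
        technique=technique,
        sample=str(data["sample"]),
        output_dir=Path(data["output_dir"]),
        reference=opt_path("reference"),
        organelles={
            str(k): str(v) for k, v in (data.get("organelles") or {}).items()
        },
        fastq=opt_path("fastq"),
        alignments=opt_path("alignments"),
        barcode=str(data.get("barcode") or ""),
        umi_length=int(data.get("umi_length") or 0),
        min_mapq=int(data.get("min_mapq") or 0),
        windows=tuple(int(w) for w in data.get("windows", (100, 15))),
        per_chromosome_normalization=bool(
            data.get("per_chromosome_normalization", False)
        ),
        unique_site_weighting=bool(data.get("unique_site_weighting", False)),
        seed=int(data.get("seed") or 0),
        simulate=sim,
    )

    if config.reference is None and sim is None:
        raise ConfigurationError(
            f"{path}: missing required key(s): reference "
            "(or a simulate block that generates it)"
        )
    for key, p in (("reference", config.reference),):
        if p is not None and sim is None and not p.exists():
            raise ConfigurationError(f"{path}: {key} path does not exist: {p}")
    for key, p in (("fastq", config.fastq), ("alignments", config.alignments)):
        if p is not None and sim is None and not p.exists():
            raise ConfigurationError(f"{path}: {key} path does not exist: {p}")
    return config


def write_manifest(
    config: RunConfig, stage: str, extra: Mapping[str, Any]
) -> Path:
    """Write the stage manifest (inputs, effective parameters, counts)."""
    from . import __version__

    manifest = {
        "stage": stage,
        "version": __version__,
        "config": config.manifest_dict(),
        **extra,
    }
    path = config.output_dir / f"{config.sample}.{stage}.manifest.json"
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return path
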