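"""End-to-end pipeline driver with YAML configuration and provenance.

Stages: build-ref -> map (built-in) or import (SAM/BAM) -> dedup -> classify ->
call -> quantify. Every output file starts with a provenance comment (config
hash, seeds, package version) so runs are traceable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

import circkit
from circkit import calling, mapping, quantify, reference

logger = logging.getLogger(__name__)

EXIT_CONFIG = 2
EXIT_INPUT = 3
EXIT_STAGE = 4


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(slots=True)
class PipelineConfig:
    genome: str
    annotation: str
    out_dir: str
    samples: dict[str, dict] = field(default_factory=dict)  # sample_id -> {fastq1, fastq2} or {sam}
    min_overlap: int = 10
    min_junctional: int = 3
    min_supported: int = 10
    policy: str = "A"
    k: int = 15
    max_mismatch: int = 2
    max_fragment_span: int = 1000
    max_exons_per_gene: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        for key in ("genome", "annotation", "out_dir"):
            if key not in raw:
                raise ConfigError(f"config missing required key: {key!r}")
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("min_overlap", "min_junctional", "min_supported", "k"):
            if getattr(cfg, name) <= 0:
                raise ConfigError(f"config key {name!r} must be a positive integer")
        if cfg.policy not in ("A", "B"):
            raise ConfigError("config key 'policy' must be 'A' or 'B'")
        return cfg

    def config_hash(self) -> str:
        # fingerprint the analytic settings; output location doesn't change results
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> str:
        return (
            f"circkit v{circkit.__version__} config={self.config_hash()} seed={self.seed} "
            f"thresholds=overlap:{self.min_overlap},junctional:{self.min_junctional},"
            f"supported:{self.min_supported},policy:{self.policy}"
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full detection pipeline; returns a summary dict of artifacts."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()

    try:
        genes, pairs, entries = reference.build_reference_from_files(
            config.annotation, config.genome, config.max_exons_per_gene
        )
        reference.write_reference(
            entries, out_dir / "junctions.fa", out_dir / "junctions.manifest.tsv", seed=config.seed
        )
    except (OSError, ValueError) as exc:
        raise StageError(f"build-ref: {exc}") from exc

    index = None
    all_alignments = []
    try:
        for sample_id in sorted(config.samples):
            spec = config.samples[sample_id]
            if "sam" in spec:
                alns = mapping.import_alignments(
                    spec["sam"], known_entries={e.junction_id for e in entries}, sample_id=sample_id
                )
            elif "fastq1" in spec and "fastq2" in spec:
                if index is None:
                    index = mapping.KmerIndex(entries, k=config.k)
                alns = mapping.map_fastq(
                    spec["fastq1"], spec["fastq2"], index, sample_id=sample_id,
                    max_mismatch=config.max_mismatch, max_fragment_span=config.max_fragment_span,
                )
            else:
                raise ConfigError(
                    f"sample {sample_id!r} needs either 'sam' or 'fastq1'+'fastq2'"
                )
            all_alignments.extend(alns)
    except ConfigError:
        raise
    except (OSError, ValueError) as exc:
        raise StageError(f"map: {exc}") from exc

    try:
        deduped = mapping.remove_duplicates(all_alignments)
        evidence = calling.classify_alignments(deduped, entries, config.min_overlap)
        candidates = calling.call_candidates(
            evidence, entries, config.min_junctional, config.min_supported, config.policy
        )
        calling.write_candidates(candidates, out_dir / "candidates.tsv", provenance=prov)
    except (OSError, ValueError) as exc:
        raise StageError(f"call: {exc}") from exc

    try:
        counts = quantify.circ_counts(evidence, samples=sorted(config.samples) or None)
        with open(out_dir / "circ_counts.tsv", "w") as fh:
            fh.write(f"# {prov}\n")
            counts.to_csv(fh, sep="\t")
    except (OSError, ValueError) as exc:
        raise StageError(f"quantify: {exc}") from exc

    n_passed = sum(c.passed for c in candidates)
    summary = {
        "n_genes": len(genes),
        "n_junction_entries": len(entries),
        "n_alignments": len(all_alignments),
        "n_fragments_after_dedup": len(deduped),
        "n_candidates": len(candidates),
        "n_passed": n_passed,
        "out_dir": str(out_dir),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump({"provenance": prov, **summary}, fh, indent=2, sort_keys=True)
    return summary
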