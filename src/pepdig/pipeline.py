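"""One-shot job orchestration: digest -> match -> report -> GFF.

Mirrors the original web tool's job flow as a synchronous run with
deterministic outputs: identical inputs and configuration produce
byte-identical CSV/GFF files (the log, which carries timings, is the only
run-dependent artifact).  Any stage failure aborts the job, removes partial
outputs and raises a :class:`StageError` naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import annotate as _annotate
from . import gff as _gff
from .bpdb import load_db
from .digestion import digest_collection, read_fasta
from .rules import load_builtin_rules

__all__ = ["JobConfig", "StageError", "run_job", "load_config"]


@dataclass
class JobConfig:
    """Job parameters; the defaults encode the tool's default job
    (trypsin, no miscleavage, either-coverage matching)."""

    input_fasta: str
    db_path: str
    out_dir: str
    enzyme_ids: list = field(default_factory=lambda: ["trypsin"])
    max_level: int = 0
    min_len: int = 2
    mode: str = "either"
    gff_scope: str = "matched_only"  # or "all"
    split_gff: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.enzyme_ids:
            raise ValueError("enzyme list must be non-empty")
        if not 0 <= self.max_level <= 3:
            raise ValueError(f"max_level must be in 0..3, got {self.max_level}")
        if self.mode not in _annotate.MATCH_MODES:
            raise ValueError(f"unknown match mode {self.mode!r}")
        if self.gff_scope not in ("matched_only", "all"):
            raise ValueError(f"unknown gff scope {self.gff_scope!r}")


def load_config(path, **overrides) -> JobConfig:
    """Read a YAML key:value config file; keyword overrides win."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return JobConfig(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_job(config: JobConfig) -> dict:
    """Run the full job; returns a manifest dict (also written as JSON).

    Outputs in ``out_dir``: list_all.csv, summary.csv, counts.csv, job.gff3
    (or per-protein GFFs with split_gff), job.tracks.txt, job.log and
    manifest.json.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list = []

    log_path = out_dir / "job.log"
    logger = logging.getLogger(f"pepdig.job.{id(config)}")
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    logger.handlers.clear()
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    written.append(log_path)

    timings = {}

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                logger.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    logger.error("stage %s: failed: %s", name, exc)
                    handler.close()
                    for path in written:
                        if path != log_path:
                            Path(path).unlink(missing_ok=True)
                    raise StageError(name, exc) from exc
                dt = time.perf_counter() - self_inner.t0
                timings[name] = round(dt, 3)
                logger.info("stage %s: done in %.3fs", name, dt)

        return _Stage()

    logger.info("job config: %s", asdict(config))

    with stage("load_inputs"):
        proteins = read_fasta(config.input_fasta)
        if not proteins:
            raise ValueError(f"no protein records in {config.input_fasta}")
        db = load_db(config.db_path)
        ruleset = load_builtin_rules()
        logger.info("loaded %d proteins, %d db entries", len(proteins), len(db))

    with stage("digest"):
        result = digest_collection(
            proteins, config.enzyme_ids, config.max_level, config.min_len, ruleset
        )
        total = sum(result.peptide_count(e, m) for e, m in result.cells())
        logger.info("digestion: %d non-redundant peptides over %d cells",
                    total, sum(1 for _ in result.cells()))

    with stage("match"):
        index = _annotate.build_match_index(db)
        matches = _annotate.match_peptides(result.all_peptides(), index, config.mode)
        logger.info("matching: %d bioactive peptides (%s mode)", len(matches), config.mode)

    with stage("report"):
        list_all = _annotate.backtrack(matches)
        summary = _annotate.summarize(matches, proteins, result.all_peptides())
        la_path, su_path, co_path = (
            out_dir / "list_all.csv",
            out_dir / "summary.csv",
            out_dir / "counts.csv",
        )
        _annotate.export_list_all(list_all, la_path)
        _annotate.export_summary(summary, su_path)
        _annotate.export_counts(result, matches, co_path)
        written += [la_path, su_path, co_path]

    with stage("gff"):
        frags_by_protein: dict = {p.protein_id: [] for p in proteins}
        for cell in result.cells():
            for frag in result.fragments[cell]:
                frags_by_protein[frag.protein_id].append(frag)
        matches_by_protein: dict = {p.protein_id: [] for p in proteins}
        for rec in matches:
            for pid in rec.peptide.origin_proteins():
                matches_by_protein[pid].append(rec)
        all_features = []
        per_protein_features = {}
        for protein in proteins:
            feats = _gff.features_for_protein(
                protein,
                frags_by_protein[protein.protein_id],
                matches_by_protein[protein.protein_id],
                which=config.gff_scope,
            )
            per_protein_features[protein.protein_id] = feats
            all_features.extend(feats)
        if config.split_gff:
            for pid, feats in per_protein_features.items():
                path = out_dir / f"{pid}.gff3"
                _gff.write_gff(feats, path)
                written.append(path)
        else:
            path = out_dir / "job.gff3"
            _gff.write_gff(all_features, path)
            written.append(path)
        tracks_path = out_dir / "job.tracks.txt"
        _gff.write_track_hints(all_features, tracks_path)
        written.append(tracks_path)

    with stage("manifest"):
        manifest = {
            "config": asdict(config),
            "n_proteins": len(proteins),
            "n_db_entries": len(db),
            "n_bioactive_peptides": len(matches),
            "outputs": {
                p.name: _sha256(p) for p in sorted(written) if p != log_path
            },
        }
        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(manifest_path)
        logger.info("timings: %s", timings)

    handler.close()
    logger.handlers.clear()
    manifest["timings"] = timings
    return manifest
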