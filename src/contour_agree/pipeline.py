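"""Full-study orchestration: manifest in, report tables out.

``run_study`` loads every mask referenced by the manifest, computes the
all-pairs agreement records, and writes the report bundle:

    pair_metrics.csv      one row per (patient, sequence, reader pair)
    summary_table.csv     per-sequence/pair means, medians and 95% CIs
    spearman_table.csv    rank correlations between reader pairs
    cross_comparison.csv  Friedman + Bonferroni-Wilcoxon across sequences
    volumes.csv           per (patient, sequence, reader) volume in cc
    icc_table.csv         per-sequence ICC(2,1) on the volumes
    bland_altman.csv      volume agreement between sequences
    run_metadata.json     config echo, seed, package version

Every number in the summary tables is a pure aggregation of
pair_metrics.csv and volumes.csv, and reruns with identical inputs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .agreement import all_pairs, records_to_frame, summarize
from .io_masks import (
    BinaryMask,
    StudyManifest,
    mask_volume_cc,
    read_manifest,
    read_volume,
    SEQUENCES,
)
from .stats import (
    bland_altman_table,
    cross_comparison_table,
    icc_table,
    spearman_table,
)

logger = logging.getLogger("contour_agree")


@dataclass
class PipelineConfig:
    """Configuration of one analysis run."""

    manifest: str
    out_dir: str
    sequences: Sequence[str] = SEQUENCES
    ci_level: float = 0.95
    alpha: float = 0.001
    bland_altman_sequences: Sequence[str] = ("FET-PET", "T1-GD", "T2-FLAIR")
    bland_altman_source: str = "patient_mean"
    cross_comparison_sequences: Sequence[str] = ("T1-GD", "T2-FLAIR", "FET-PET")
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


@dataclass
class ValidationReport:
    duplicates: list[tuple[str, str, str]] = field(default_factory=list)
    unknown_sequences: list[str] = field(default_factory=list)
    unreadable: list[str] = field(default_factory=list)
    missing_per_sequence: dict[str, int] = field(default_factory=dict)

    @property
    def is_clean(self) -> bool:
        return not (self.duplicates or self.unknown_sequences or self.unreadable)


def validate_manifest(manifest: StudyManifest, base_dir: str | Path = ".") -> ValidationReport:
    """Report-only sanity check of a manifest.

    Lists duplicated (patient, sequence, reader) triplets, unknown sequence
    labels, unreadable mask paths, and per-sequence counts of missing mask
    slots. Duplicates and unknown labels can only appear in hand-edited
    manifests (the constructor rejects them), but files may vanish between
    manifest creation and the run.
    """
    base = Path(base_dir)
    report = ValidationReport()
    seen: set[tuple[str, str, str]] = set()
    for e in manifest.entries:
        key = (e.patient_id, e.sequence, e.reader)
        if key in seen:
            report.duplicates.append(key)
        seen.add(key)
        if e.sequence not in SEQUENCES:
            report.unknown_sequences.append(e.sequence)
        if e.path:
            if not (base / e.path).exists():
                report.unreadable.append(e.path)
        else:
            report.missing_per_sequence[e.sequence] = (
                report.missing_per_sequence.get(e.sequence, 0) + 1
            )
    return report


def load_masks(
    manifest: StudyManifest, base_dir: str | Path
) -> dict[tuple[str, str, str], BinaryMask | None]:
    """Load every referenced mask; each (patient, sequence) shares a grid.

    The first available mask of a (patient, sequence) defines the grid the
    others are validated against (inputs are assumed co-registered).
    """
    from .io_masks import read_mask

    base = Path(base_dir)
    masks: dict[tuple[str, str, str], BinaryMask | None] = {}
    grids: dict[tuple[str, str], object] = {}
    for e in manifest.entries:
        key = (e.patient_id, e.sequence, e.reader)
        if not e.path:
            masks[key] = None
            continue
        gkey = (e.patient_id, e.sequence)
        if gkey not in grids:
            grids[gkey] = read_volume(base / e.path, modality_label=e.sequence)
        masks[key] = read_mask(base / e.path, grids[gkey], label=key)
    return masks


def volumes_frame(
    masks: Mapping[tuple[str, str, str], BinaryMask | None],
    manifest: StudyManifest,
) -> pd.DataFrame:
    """Long-form per-(patient, sequence, reader) delineated volumes in cc."""
    rows = []
    for e in manifest.entries:
        mask = masks.get((e.patient_id, e.sequence, e.reader))
        rows.append(
            {
                "patient_id": e.patient_id,
                "sequence": e.sequence,
                "reader": e.reader,
                "volume_cc": mask_volume_cc(mask) if mask is not None else float("nan"),
            }
        )
    return pd.DataFrame(rows)


_FLOAT_FORMAT = "%.10g"


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def run_tables(
    masks: Mapping[tuple[str, str, str], BinaryMask | None],
    manifest: StudyManifest,
    config: PipelineConfig,
) -> dict[str, pd.DataFrame]:
    """Compute every report table from loaded masks (no file I/O)."""
    records = all_pairs(manifest, masks)
    pair_frame = records_to_frame(records)
    vol_frame = volumes_frame(masks, manifest)

    tables = {
        "pair_metrics": pair_frame,
        "summary_table": summarize(records, ci_level=config.ci_level),
        "spearman_table": spearman_table(pair_frame),
        "cross_comparison": cross_comparison_table(
            pair_frame,
            sequences=config.cross_comparison_sequences,
            alpha=config.alpha,
        ),
        "volumes": vol_frame,
        "icc_table": icc_table(vol_frame, ci_level=config.ci_level),
        "bland_altman": bland_altman_table(
            vol_frame,
            sequences=config.bland_altman_sequences,
            source_rule=config.bland_altman_source,
        ),
    }
    return tables


def run_study(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis described by ``config`` and write the bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest_path = Path(config.manifest)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = read_manifest(manifest_path)
    base_dir = manifest_path.parent

    report = validate_manifest(manifest, base_dir)
    if not report.is_clean:
        raise ValueError(
            "manifest validation failed: "
            f"duplicates={report.duplicates} unknown={report.unknown_sequences} "
            f"unreadable={report.unreadable}"
        )
    for seq, n_missing in sorted(report.missing_per_sequence.items()):
        logger.info("sequence %s: %d missing mask slot(s)", seq, n_missing)

    masks = load_masks(manifest, base_dir)
    tables = run_tables(masks, manifest, config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in tables.items():
        _write(frame, out / f"{name}.csv")
    metadata = {
        "config": {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "seed": config.seed,
        "version": __version__,
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
    return tables
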