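"""End-to-end orchestration: scan -> annotate -> density -> report.

The pipeline reads a genome FASTA (and optionally an exon BED/GFF3),
scans every configured PAM class on both strands, writes one BED per
class, intersects sites with exons, and emits density and availability
tables plus a checksummed manifest.  Outputs are written atomically
(temp file + rename) so a failed stage never leaves truncated files,
and each stage's outputs survive a later stage's failure — the manifest
records which stage failed.
"""

from __future__ import annotations

import hashlib
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from . import density_stats, exon_annotation, pam_scanner
from .density_stats import BaseComposition
from .pam_scanner import PAM_CLASSES, PamSpec
from .sequence_core import FastaParseError, read_fasta

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "MissingInputError",
    "InputParseError",
    "StageError",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger("pamscape")


class PipelineError(Exception):
    """Base class for pipeline failures."""


class MissingInputError(PipelineError):
    """A configured input path does not exist (CLI exit 2)."""


class InputParseError(PipelineError):
    """An input file failed to parse (CLI exit 3)."""


class StageError(PipelineError):
    """A stage failed internally (CLI exit 4); carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    genome: str = ""
    exons: str = ""  # optional
    pam_classes: tuple[str, ...] = PAM_CLASSES
    spacer_length: int = 20
    bed_span: str = "union"  # union | pam
    overlap_mode: str = "any_overlap"
    composition: str = "uniform"  # uniform | empirical
    outdir: str = "pamscape_out"
    seed: int = 0
    log_level: str = "INFO"


def load_config(path) -> PipelineConfig:
    """Parse a ``key = value`` config file (# comments allowed)."""
    cfg = PipelineConfig()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InputParseError(f"{path}:{lineno}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key == "pam_classes":
                cfg.pam_classes = tuple(v.strip() for v in value.split(",") if v.strip())
            elif key in ("spacer_length", "seed"):
                setattr(cfg, key, int(value))
            elif key in (
                "genome",
                "exons",
                "bed_span",
                "overlap_mode",
                "composition",
                "outdir",
                "log_level",
            ):
                setattr(cfg, key, value)
            else:
                raise InputParseError(f"{path}:{lineno}: unknown key {key!r}")
    if not cfg.pam_classes:
        raise InputParseError(f"{path}: pam_classes must be non-empty")
    return cfg


def _atomic_write(path: Path, writer: Callable) -> None:
    """Write via temp file + rename so readers never see partial output."""
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class _Manifest:
    rows: list[dict] = field(default_factory=list)

    def add(self, path: Path, stage: str) -> None:
        self.rows.append(
            {
                "file": path.name,
                "stage": stage,
                "status": "ok",
                "bytes": path.stat().st_size,
                "sha256": _sha256(path),
            }
        )

    def fail(self, stage: str, message: str) -> None:
        self.rows.append(
            {
                "file": ".",
                "stage": stage,
                "status": f"failed: {message}",
                "bytes": 0,
                "sha256": "-",
            }
        )

    def write(self, path: Path) -> None:
        def _w(fh):
            fh.write("file\tstage\tstatus\tbytes\tsha256\n")
            for r in self.rows:
                fh.write(
                    f"{r['file']}\t{r['stage']}\t{r['status']}\t{r['bytes']}\t{r['sha256']}\n"
                )

        _atomic_write(path, _w)


def run_pipeline(config: PipelineConfig) -> list[dict]:
    """Run scan -> annotate -> density on the configured inputs.

    Returns the manifest rows; also writes ``manifest.tsv`` in the
    output directory.  Raises :class:`MissingInputError`,
    :class:`InputParseError` or :class:`StageError`; inputs are checked
    before any output is created, so a missing input leaves no partial
    results behind.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
    genome_path = Path(config.genome)
    if not config.genome or not genome_path.exists():
        raise MissingInputError(f"genome FASTA not found: {config.genome!r}")
    exon_path = Path(config.exons) if config.exons else None
    if exon_path is not None and not exon_path.exists():
        raise MissingInputError(f"exon file not found: {config.exons!r}")
    if config.bed_span not in ("union", "pam"):
        raise InputParseError(f"bed_span must be union|pam, got {config.bed_span!r}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest()
    manifest_path = outdir / "manifest.tsv"

    # ---- ingest ----
    t0 = time.monotonic()
    try:
        records = read_fasta(genome_path)
    except FastaParseError as exc:
        raise InputParseError(f"genome FASTA: {exc}") from exc
    exons = None
    if exon_path is not None:
        try:
            exons = exon_annotation.read_intervals(exon_path)
        except ValueError as exc:
            raise InputParseError(f"exon file: {exc}") from exc
    log.info(
        "ingest: %d records, %d bp (%.2fs)",
        len(records),
        sum(len(r) for r in records),
        time.monotonic() - t0,
    )

    # ---- scan ----
    stage = "scan"
    try:
        t0 = time.monotonic()
        specs = [PamSpec.from_name(c, config.spacer_length) for c in config.pam_classes]
        tables = pam_scanner.scan_genome(records, specs)
        for cls in config.pam_classes:
            path = outdir / f"sites_{cls}.bed"
            _atomic_write(
                path, lambda fh, t=tables[cls]: pam_scanner.write_bed(
                    t, fh, span=config.bed_span
                )
            )
            manifest.add(path, stage)
            log.info("scan %s: %d sites", cls, len(tables[cls].sites))
        log.info("scan: done (%.2fs)", time.monotonic() - t0)
    except Exception as exc:
        manifest.fail(stage, str(exc))
        manifest.write(manifest_path)
        raise StageError(stage, exc) from exc

    # ---- annotate ----
    if exons is not None:
        stage = "annotate"
        try:
            t0 = time.monotonic()
            summaries = []
            for cls in config.pam_classes:
                annotated = exon_annotation.intersect_sites(
                    tables[cls], exons, mode=config.overlap_mode
                )
                path = outdir / f"annotated_{cls}.bed"
                _atomic_write(
                    path,
                    lambda fh, a=annotated: exon_annotation.write_annotated_bed(a, fh),
                )
                manifest.add(path, stage)
                summaries.append(exon_annotation.summarize_availability(annotated))
            import pandas as pd

            summary = pd.concat(summaries, ignore_index=True)
            path = outdir / "summary.tsv"
            _atomic_write(
                path, lambda fh: summary.to_csv(fh, sep="\t", index=False)
            )
            manifest.add(path, stage)
            log.info("annotate: done (%.2fs)", time.monotonic() - t0)
        except Exception as exc:
            manifest.fail(stage, str(exc))
            manifest.write(manifest_path)
            raise StageError(stage, exc) from exc

    # ---- density ----
    stage = "density"
    try:
        t0 = time.monotonic()
        comp = (
            BaseComposition.from_records(records)
            if config.composition == "empirical"
            else BaseComposition.uniform()
        )

        def _write_density(fh):
            fh.write(
                "pam_class\tp_match_per_strand\texpected_rate_both_strands\t"
                "expected_spacing\tobserved_count\tscanned_bp\tobserved_spacing\t"
                "z\tverdict\n"
            )
            for cls in config.pam_classes:
                spec = PamSpec.from_name(cls, config.spacer_length)
                exp = density_stats.expected_density(spec.pattern, comp, pam_class=cls)
                obs = density_stats.empirical_density(tables[cls], pam_class=cls)
                z, ok = density_stats.compare_densities(exp, obs)
                fh.write(
                    f"{cls}\t{exp.p_match_per_strand:.8g}\t"
                    f"{exp.expected_rate_both_strands:.8g}\t"
                    f"{exp.expected_spacing:.6g}\t{obs.observed_count}\t"
                    f"{obs.scanned_bp}\t{obs.observed_spacing:.6g}\t"
                    f"{z:.4f}\t{'ok' if ok else 'DEVIANT'}\n"
                )

        path = outdir / "density.tsv"
        _atomic_write(path, _write_density)
        manifest.add(path, stage)
        log.info("density: done (%.2fs)", time.monotonic() - t0)
    except Exception as exc:
        manifest.fail(stage, str(exc))
        manifest.write(manifest_path)
        raise StageError(stage, exc) from exc

    manifest.write(manifest_path)
    return manifest.rows
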