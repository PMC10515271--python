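"""Screen orchestration: manifests, the end-to-end pipeline, and reports.

A manifest lists candidate datasets (ChIP FASTQ files with matched inputs,
replicate-paired by position; a single input may be shared across
replicates, as public datasets often do). ``run_screen`` maps every file to
the collapsed unit, builds coverage, normalizes, classifies each replicate
and combines them, then tabulates the screen the way the original was
reported: n candidates, n positive, n rejected. Reports are deterministic
(no timestamps, sorted keys) and written atomically.

GEO/SRA identifiers appearing in manifests are inert metadata; nothing here
touches the network.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .align import KmerIndex, coverage, map_reads
from .annotation import ArrayAnnotation, read_bed
from .classify import ClassifierConfig, classify_candidate, classify_replicates
from .simulate import read_fasta, read_fastq


@dataclass
class ManifestEntry:
    """One candidate dataset: replicate-paired ChIP and input FASTQ paths."""

    name: str
    chip_paths: list[str]
    input_paths: list[str]
    read_length: int | None = None  # inferred from the reads when None

    def __post_init__(self) -> None:
        if not self.chip_paths:
            raise ValueError(f"manifest entry {self.name!r} has no chip files")
        ni, nc = len(self.input_paths), len(self.chip_paths)
        if ni not in (0, 1, nc):
            raise ValueError(
                f"manifest entry {self.name!r}: {ni} input files cannot pair "
                f"with {nc} chip files (expected 0, 1, or {nc})"
            )

    def pairs(self) -> list[tuple[str, str | None]]:
        if not self.input_paths:
            return [(c, None) for c in self.chip_paths]
        if len(self.input_paths) == 1:
            return [(c, self.input_paths[0]) for c in self.chip_paths]
        return list(zip(self.chip_paths, self.input_paths))


@dataclass
class ScreenManifest:
    entries: list[ManifestEntry]
    unit_fasta: str
    annotation_bed: str
    config_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("manifest has no entries")


def read_manifest(path) -> ScreenManifest:
    """Load a manifest from YAML (mapping form) or TSV.

    TSV columns: name, chip, input, read_length; multiple files per cell
    are ';'-separated; the unit FASTA and annotation BED paths come from
    '#unit_fasta=' / '#annotation_bed=' header comments.
    """
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        entries = [
            ManifestEntry(
                e["name"],
                list(e["chip"]),
                list(e.get("input", [])),
                e.get("read_length"),
            )
            for e in doc.get("entries", [])
        ]
        return ScreenManifest(
            entries,
            doc["unit_fasta"],
            doc["annotation_bed"],
            doc.get("config", {}) or {},
        )
    unit_fasta = annotation_bed = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#unit_fasta="):
                unit_fasta = line.split("=", 1)[1]
            elif line.startswith("#annotation_bed="):
                annotation_bed = line.split("=", 1)[1]
            elif line.startswith("#") or not line:
                continue
            elif line.startswith("name\t"):
                continue
            else:
                rows.append(line.split("\t"))
    if unit_fasta is None or annotation_bed is None:
        raise ValueError(f"{path}: missing #unit_fasta= or #annotation_bed= header")
    entries = []
    for r in rows:
        name, chip, inp = r[0], r[1], (r[2] if len(r) > 2 else "")
        rl = int(r[3]) if len(r) > 3 and r[3] else None
        entries.append(
            ManifestEntry(
                name,
                [p for p in chip.split(";") if p],
                [p for p in inp.split(";") if p],
                rl,
            )
        )
    return ScreenManifest(entries, unit_fasta, annotation_bed, {})


@dataclass
class ScreenReport:
    rows: list[dict]
    summary: dict
    config: dict
    version: str = ""

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "summary": self.summary,
            "candidates": self.rows,
        }

    def write_json(self, path) -> None:
        """Atomic, deterministic JSON (sorted keys, no timestamps)."""
        payload = json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"
        d = os.path.dirname(os.path.abspath(path)) or "."
        fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                fh.write(payload)
            os.chmod(tmp, 0o644)
            os.replace(tmp, str(path))
        finally:
            if os.path.exists(tmp):
                os.unlink(tmp)

    def write_tsv(self, path) -> None:
        recs = []
        for r in self.rows:
            call = r.get("call") or {}
            peaks = call.get("peaks", [])
            top = peaks[0] if peaks else None
            recs.append(
                {
                    "candidate": r["name"],
                    "status": r["status"],
                    "label": call.get("label", ""),
                    "flags": ",".join(call.get("flags", [])),
                    "n_peaks": len(peaks),
                    "top_peak": f"{top['start']}-{top['end']}" if top else "",
                    "elements": ",".join(top["elements"]) if top else "",
                }
            )
        pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def run_screen(
    manifest: ScreenManifest,
    config: ClassifierConfig | None = None,
) -> ScreenReport:
    """Run the whole screen over a manifest.

    Per entry: map -> coverage -> ratio -> classify each replicate ->
    combine. Entries without an input are processed as a no-input
    comparison (recorded, never silently skipped): peaks are judged on the
    ChIP coverage alone and only the GA rule applies. Per-entry failures
    are recorded in the report and do not abort other entries.
    """
    if config is None:
        config = ClassifierConfig(**manifest.config_overrides)
    elif manifest.config_overrides:
        from dataclasses import replace

        config = replace(config, **manifest.config_overrides)

    _, unit_seq = read_fasta(manifest.unit_fasta)
    annotation = read_bed(manifest.annotation_bed, unit_length=len(unit_seq))
    index = KmerIndex(unit_seq)

    rows = []
    n_positive = 0
    for entry in manifest.entries:
        try:
            row = _screen_entry(entry, index, annotation, config)
        except Exception as exc:  # recorded, not fatal to the screen
            row = {"name": entry.name, "status": "error", "error": str(exc), "call": None}
        rows.append(row)
        if row.get("call") and row["call"]["label"] == "positive":
            n_positive += 1
    summary = {
        "n_candidates": len(rows),
        "n_positive": n_positive,
        "n_rejected": len(rows) - n_positive,
    }
    from dataclasses import asdict

    return ScreenReport(rows, summary, asdict(config), __version__)


def _screen_entry(
    entry: ManifestEntry,
    index: KmerIndex,
    annotation: ArrayAnnotation,
    config: ClassifierConfig,
) -> dict:
    from .classify import (
        ArtifactFlag,
        CandidateCall,
        _call_runs,
        assign_elements,
        detect_ga_artifact,
    )
    from .normalize import depth_scale, smooth

    calls = []
    no_input = False
    for chip_path, input_path in entry.pairs():
        chip_reads = read_fastq(chip_path, role="chip")
        rl = entry.read_length or chip_reads.read_length
        chip_cov = coverage(map_reads(chip_reads, index), index.unit_length, rl)
        if input_path is None:
            no_input = True
            sm = smooth(depth_scale(chip_cov, config.target_total), config.smooth_window)
            peaks = _call_runs(sm, config.peak_z, config.min_peak_width)
            ga = detect_ga_artifact(peaks, annotation, rl, config)
            flags = {ArtifactFlag.GA_ARTIFACT} if ga else set()
            label = "positive" if any(p not in ga for p in peaks) else "negative"
            calls.append(
                CandidateCall(
                    label,
                    peaks,
                    flags,
                    [assign_elements(p, annotation) for p in peaks],
                    {"comparison": "no_input", "read_length": rl, "n_raw_peaks": len(peaks)},
                )
            )
        else:
            input_reads = read_fastq(input_path, role="input")
            input_cov = coverage(map_reads(input_reads, index), index.unit_length, rl)
            calls.append(classify_candidate(chip_cov, input_cov, annotation, rl, config))
    combined = classify_replicates(calls)
    return {
        "name": entry.name,
        "status": "no-input comparison" if no_input else "ok",
        "call": combined.to_dict(),
    }
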