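"""End-to-end orchestration: extract -> ratios -> discover -> validate.

A :class:`RunConfig` carries every threshold of the procedure with the
standard defaults (detection ratio 0.1, 5 bp merge, 50% presence, 20x
coverage, +/-3 bp boundary windows, 100 background junctions >50 bp from
boundaries, 10% validation ratio, 200-read / top-1/50 long-read support,
10-15 bp truncation offsets).  Runs are deterministic for a fixed seed and
write a manifest echoing parameters and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import (
    MT_LENGTH,
    enumerate_boundaries,
    classify_site,
    load_annotation,
    sample_background_sites,
)
from .cleavage_ratio import compute_ratio_track
from .fragment_ends import (
    FragmentEndTable,
    count_site_events,
    extract_short_read_ends,
)
from .site_discovery import (
    boundary_report,
    cross_sample_filter,
    estimate_background,
    sites_to_frame,
)


@dataclass
class RunConfig:
    """All knobs of one pipeline run, with the procedure's standard defaults."""

    input_dir: str | None = None  # directory of *.sam/*.bam or *.fragments.tsv
    output_dir: str = "mitocleave_run"
    annotation: str = "rcrs"
    genome_length: int = MT_LENGTH
    ratio_threshold: float = 0.1
    merge_window: int = 5
    min_presence: float = 0.5
    min_coverage: int = 20
    boundary_window: int = 3
    background_n: int = 100
    background_min_dist: int = 50
    validation_threshold: float = 0.10
    long_read_min_support: int = 200
    long_read_top_fraction: float = 1.0 / 50.0
    truncation_offsets: tuple[int, int] = (10, 15)
    unique_mapq: int | None = 255
    require_proper_pair: bool = True
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.ratio_threshold <= 1.0):
            raise ValueError("ratio_threshold must be in [0, 1]")
        if not (0.0 <= self.min_presence <= 1.0):
            raise ValueError("min_presence must be in [0, 1]")
        if not (0.0 < self.long_read_top_fraction <= 1.0):
            raise ValueError("long_read_top_fraction must be in (0, 1]")
        if not (0.0 <= self.validation_threshold <= 1.0):
            raise ValueError("validation_threshold must be in [0, 1]")
        if self.min_coverage < 1 or self.merge_window < 0 or self.boundary_window < 0:
            raise ValueError("invalid coverage/window parameters")
        if self.background_n < 1 or self.background_min_dist < 0:
            raise ValueError("invalid background parameters")
        lo, hi = self.truncation_offsets
        if lo > hi or lo < 0:
            raise ValueError("invalid truncation_offsets")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["truncation_offsets"] = list(self.truncation_offsets)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "truncation_offsets" in d:
            d["truncation_offsets"] = tuple(d["truncation_offsets"])
        return cls(**d)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_tables(config: RunConfig) -> list[FragmentEndTable]:
    indir = Path(config.input_dir)
    tables = []
    for path in sorted(indir.glob("*.fragments.tsv")):
        tables.append(FragmentEndTable.from_tsv(path))
    for path in sorted(list(indir.glob("*.sam")) + list(indir.glob("*.bam"))):
        tables.append(
            extract_short_read_ends(
                path,
                sample_id=path.stem,
                require_proper_pair=config.require_proper_pair,
                unique_mapq=config.unique_mapq,
                genome_length=config.genome_length,
            )
        )
    if not tables:
        raise FileNotFoundError(f"no alignment or fragment files in {indir}")
    return tables


def run_pipeline(
    config: RunConfig, tables: list[FragmentEndTable] | None = None
) -> dict:
    """Execute extract -> ratios -> discover -> boundary tests; write artifacts.

    ``tables`` may be passed directly (e.g. from the simulator); otherwise
    they are read from ``config.input_dir``.  Returns the manifest dict.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "mitocleave",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }

    stage = "extract"
    try:
        if tables is None:
            tables = _load_tables(config)
        manifest["stages"][stage] = {
            "samples": len(tables),
            "fragments": [int(len(t)) for t in tables],
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "ratios"
    try:
        tracks = []
        for t in tables:
            counts = count_site_events(t, config.genome_length)
            track = compute_ratio_track(counts)
            track.to_tsv(outdir / f"{t.sample_id}.ratios.tsv")
            tracks.append(track)
        manifest["stages"][stage] = {
            "samples": len(tracks),
            "defined_junctions": [int(t.defined().sum()) for t in tracks],
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "discover"
    try:
        genes = load_annotation(config.annotation, config.genome_length)
        boundaries = enumerate_boundaries(
            genes, ("mRNA", "rRNA"), config.boundary_window, config.genome_length
        )
        sites = cross_sample_filter(
            tracks,
            ratio_threshold=config.ratio_threshold,
            min_coverage=config.min_coverage,
            merge_window=config.merge_window,
            min_presence=config.min_presence,
        )
        for s in sites:
            s.classification, s.boundary_distance = classify_site(
                s.junction, genes, boundaries, genome_length=config.genome_length
            )
        site_frame = sites_to_frame(sites)
        site_frame.to_csv(outdir / "sites.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"candidate_sites": len(sites)}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "boundary_tests"
    try:
        background_sites = sample_background_sites(
            boundaries,
            n=config.background_n,
            min_dist=config.background_min_dist,
            rng_seed=config.seed,
            genome_length=config.genome_length,
        )
        background = estimate_background(
            tracks, background_sites, window=config.boundary_window,
            min_dist=config.background_min_dist,
        )
        report = boundary_report(boundaries, tracks, background, config.alpha)
        report.to_csv(outdir / "boundary_tests.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "boundaries_tested": int(len(report)),
            "significant": int(report["significant"].sum()) if len(report) else 0,
            "background_mean": background.mean,
            "background_sd": background.sd,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    config.to_yaml(outdir / "config.yaml")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
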