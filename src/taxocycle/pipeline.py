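"""End-to-end orchestration: resolve -> search/call -> profile/render.

The pipeline mirrors its three conceptual processes in the output
layout::

    0_resolution/   resolution_report.tsv
    1_hits/         one hit table per resolved taxon
    2_functions/    function_presence.tsv
    3_profiles/     occurrence/abundance tables, polar + heatmap tables
    4_diagrams/     per-sample per-cycle SVG projections
    run_report.json audit trail (versions, counts, warnings, timings)

The parallel unit is one taxon's proteome; results are merged in
deterministic taxon-name order, so every data output is byte-identical
for any worker count.  run_report.json contains wall-clock timings and
is the one file outside that byte-stability contract.
"""

from __future__ import annotations

import json
import logging
import multiprocessing
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .community import profile_samples, read_abundance_table, write_profile_tables
from .diagram import (
    DEFAULT_MIN_DISPLAY,
    heatmap_table,
    load_template,
    packaged_cycles,
    packaged_template,
    plot_heatmap,
    plot_polar,
    polar_summary,
    project_profile,
    render,
)
from .hmmscan import ProfileHMM, call_hits, parse_hmm_file, present_profiles, read_cutoff_table, write_hits_tsv
from .rules import call_functions, default_definitions, load_definitions, write_presence_matrix
from .taxdb import (
    TaxonIndexEntry,
    load_index,
    load_taxon_record,
    parse_affiliations,
    resolve_affiliation,
    write_resolution_report,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(ValueError):
    """Configuration or stage failure, tagged with the failing stage."""


@dataclass
class PipelineConfig:
    affiliations: Path
    archive: Path
    output_dir: Path
    abundances: Path | None = None
    profiles: Path | None = None  # HMMER3 ASCII; packaged markers when None
    rules: Path | None = None  # rule TSV; packaged set when None
    templates_dir: Path | None = None  # SVG+edge-map pairs; packaged when None
    cutoffs: Path | None = None
    cores: int = 1
    min_proteomes: int = 5
    default_cutoff: float = 40.0
    min_display: float = DEFAULT_MIN_DISPLAY
    header: bool = True
    align: str = "left"
    plots: bool = True

    def validate(self) -> None:
        if self.cores < 1:
            raise PipelineError("config: cores must be >= 1")
        for label, path in (
            ("affiliations", self.affiliations),
            ("archive", self.archive),
            ("abundances", self.abundances),
            ("profiles", self.profiles),
            ("rules", self.rules),
            ("cutoffs", self.cutoffs),
        ):
            if path is not None and not Path(path).exists():
                raise PipelineError(f"config: {label} path does not exist: {path}")


def _scan_taxon(
    args: tuple[str, TaxonIndexEntry, Sequence[ProfileHMM], Mapping[str, float] | None, float],
):
    archive, entry, profiles, cutoffs, default_cutoff = args
    record = load_taxon_record(archive, entry)
    seqs = [
        (c.cluster_id, c.consensus_sequence)
        for c in record.clusters
        if c.consensus_sequence
    ]
    if not seqs:
        return entry.taxon_name, [], set()
    hits = call_hits(profiles, seqs, cutoffs, default_cutoff)
    return entry.taxon_name, hits, present_profiles(hits)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the run report (also written as JSON)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "taxocycle",
        "version": __version__,
        "cores": config.cores,
        "stages": {},
        "warnings": [],
    }

    # stage 0: resolution --------------------------------------------------
    t0 = time.perf_counter()
    try:
        affiliations = parse_affiliations(
            config.affiliations, header=config.header, align=config.align
        )
        index = load_index(config.archive)
        lookup = {(e.taxon_name, e.rank): e for e in index}
        resolutions = [resolve_affiliation(a, lookup) for a in affiliations]
    except Exception as exc:
        raise PipelineError(f"resolution stage: {exc}") from exc
    res_dir = out / "0_resolution"
    res_dir.mkdir(exist_ok=True)
    write_resolution_report(resolutions, res_dir / "resolution_report.tsv")
    unresolved = sorted(r.observation_id for r in resolutions if r.status != "resolved")
    report["observations"] = len(resolutions)
    report["unresolved"] = unresolved
    report["stages"]["resolution"] = {"seconds": round(time.perf_counter() - t0, 3)}

    # stage 1: HMM search + function calls ---------------------------------
    t1 = time.perf_counter()
    try:
        if config.profiles is not None:
            profiles = parse_hmm_file(config.profiles)
        else:
            from .markers import default_profiles

            profiles = default_profiles()
        cutoffs = read_cutoff_table(config.cutoffs) if config.cutoffs else None
        definitions = (
            load_definitions(config.rules) if config.rules else default_definitions()
        )
        taxa: dict[str, TaxonIndexEntry] = {}
        for r in resolutions:
            if r.status == "resolved" and r.matched_taxon is not None:
                taxa.setdefault(r.matched_taxon.taxon_name, r.matched_taxon)
        jobs = [
            (str(config.archive), taxa[name], profiles, cutoffs, config.default_cutoff)
            for name in sorted(taxa)
        ]
        if config.cores > 1 and len(jobs) > 1:
            with multiprocessing.get_context("fork").Pool(config.cores) as pool:
                results = pool.map(_scan_taxon, jobs)
        else:
            results = [_scan_taxon(j) for j in jobs]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"search stage: {exc}") from exc
    hits_dir = out / "1_hits"
    hits_dir.mkdir(exist_ok=True)
    taxon_presence: dict[str, set[str]] = {}
    for taxon_name, hits, present in results:
        token = taxon_name.replace(" ", "_").replace("/", "_")
        write_hits_tsv(hits, hits_dir / f"{token}.tsv")
        taxon_presence[taxon_name] = present
    presence_sets = {
        r.observation_id: taxon_presence.get(r.matched_taxon.taxon_name, set())
        for r in resolutions
        if r.status == "resolved" and r.matched_taxon is not None
    }
    presence = call_functions(
        presence_sets, definitions, known_profiles={p.name for p in profiles}
    )
    func_dir = out / "2_functions"
    func_dir.mkdir(exist_ok=True)
    write_presence_matrix(presence, func_dir / "function_presence.tsv")
    report["stages"]["search"] = {"seconds": round(time.perf_counter() - t1, 3)}
    report["taxa_searched"] = len(taxa)
    report["profiles_searched"] = len(profiles)

    # stage 2: profiles + diagrams -----------------------------------------
    t2 = time.perf_counter()
    try:
        abundances = (
            read_abundance_table(config.abundances) if config.abundances else None
        )
        profiles_by_sample = profile_samples(presence, abundances, resolutions, definitions)
        prof_dir = out / "3_profiles"
        write_profile_tables(profiles_by_sample, prof_dir)
        polar = polar_summary(profiles_by_sample, min_display=config.min_display)
        polar.to_csv(prof_dir / "polar_summary.tsv", sep="\t")
        heat = heatmap_table(profiles_by_sample)
        heat.to_csv(prof_dir / "heatmap_table.tsv", sep="\t")
        if config.plots:
            plot_heatmap(heat, prof_dir / "function_heatmap.png")
            plot_polar(polar, prof_dir / "polar_plot.png")
        diag_dir = out / "4_diagrams"
        diag_dir.mkdir(exist_ok=True)
        mode = "abundance" if abundances is not None else "occurrence"
        if config.templates_dir is not None:
            svgs = sorted(Path(config.templates_dir).glob("*.svg"))
            diagrams = [load_template(p) for p in svgs]
        else:
            diagrams = [packaged_template(c) for c in packaged_cycles()]
        for sample in sorted(profiles_by_sample):
            for diagram in diagrams:
                projected = project_profile(profiles_by_sample, diagram, mode, sample)
                render(projected, diag_dir / f"{diagram.name}_{sample}.svg")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"profile stage: {exc}") from exc
    report["stages"]["profile"] = {"seconds": round(time.perf_counter() - t2, 3)}
    report["samples"] = sorted(profiles_by_sample)

    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
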