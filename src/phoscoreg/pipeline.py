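"""End-to-end orchestration: compendium -> sites -> co-occurrence ->
co-regulation -> annotation -> network, with a JSON manifest.

The analysis path is fully deterministic: identical inputs and config
produce byte-identical outputs (all tables and network files are written
in sorted order).  Any stage failure aborts the run with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import annotation as anno
from . import compendium as comp
from . import cooccurrence as cooc
from . import coregulation as coreg
from . import network as netmod
from . import site_stats

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; message carries the stage name and cause."""


@dataclass
class PipelineConfig:
    """Everything a full run needs.

    ``explicit_sites`` (rendered keys like ``MELK_S356``) overrides
    major-site selection.  ``resources`` maps resource kind ->
    file path (kinds may repeat via list values).
    """

    compendium: str
    target: str
    outdir: str
    alias_map: Optional[str] = None
    domains: Optional[str] = None
    resources: dict = field(default_factory=dict)  # kind -> path or [paths]
    filter: comp.FilterConfig = field(default_factory=comp.FilterConfig)
    highconf: coreg.HighConfidenceConfig = field(default_factory=coreg.HighConfidenceConfig)
    k_major: int = 3
    min_count: int = 2
    explicit_sites: Optional[list[str]] = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fc = comp.FilterConfig(**raw.pop("filter", {}))
        hc = coreg.HighConfidenceConfig(**raw.pop("highconf", {}))
        return cls(filter=fc, highconf=hc, **raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


@dataclass
class PipelineResult:
    """In-memory artifacts of a full run (also written to ``outdir``)."""

    calls: comp.DirectionMap
    major_sites: list[comp.SiteKey]
    frequencies: list
    results: list[coreg.CoRegResult]
    highconf: list[coreg.CoRegResult]
    assignments: list[anno.RoleAssignment]
    network: netmod.CoRegNetwork
    manifest: dict


def analyze_observations(
    observations: Sequence[comp.SiteObservation],
    target: str,
    filter_config: Optional[comp.FilterConfig] = None,
    hc_config: Optional[coreg.HighConfidenceConfig] = None,
    explicit_sites: Optional[Sequence[comp.SiteKey]] = None,
    k_major: int = 3,
    min_count: int = 2,
) -> tuple[comp.DirectionMap, list[comp.SiteKey], list[coreg.CoRegResult]]:
    """File-free analysis core: filter, call, select sites, scan PsOPs.

    Returns the condition-level direction map, the major target sites and
    the full per-pair co-regulation results (signs assigned).  Shared by
    the file pipeline and the synthetic-recovery evaluation.
    """
    fc = filter_config or comp.FilterConfig()
    hc = hc_config or coreg.HighConfidenceConfig()
    target = target.upper()
    kept = comp.filter_class1(observations, fc)
    called = comp.apply_directions(kept, fc)
    calls = comp.resolve_conflicts(called)
    profile_obs = [o for o in kept if o.dataset_kind == "profile"]
    if explicit_sites is not None:
        major = list(explicit_sites)
    else:
        freqs = site_stats.detection_frequency(calls, profile_obs, target)
        major = site_stats.select_major_sites(freqs, k=k_major, min_count=min_count)
    results = coreg.scan_psops(calls, major, target, hc)
    return calls, major, results


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write all artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"target": config.target.upper(), "stages": {}, "params": {}}
    manifest["params"]["filter"] = dataclasses.asdict(config.filter)
    manifest["params"]["highconf"] = dataclasses.asdict(config.highconf)

    def record(stage: str, rows_in: int, rows_out: int, **params) -> None:
        manifest["stages"][stage] = {"rows_in": rows_in, "rows_out": rows_out, **params}
        log.info("stage=%s rows_in=%d rows_out=%d %s", stage, rows_in, rows_out, params)

    # --- ingest -----------------------------------------------------------
    @_stage("ingest")
    def ingest():
        alias = comp.read_alias_map(config.alias_map) if config.alias_map else {}
        obs = comp.read_observations(config.compendium, alias_map=alias, config=config.filter)
        return alias, obs

    alias_map, observations = ingest()
    record("ingest", len(observations), len(observations), path=str(config.compendium))

    # --- filter + direction calling --------------------------------------
    @_stage("filter")
    def do_filter():
        return comp.filter_class1(observations, config.filter)

    kept = do_filter()
    record("filter", len(observations), len(kept))

    @_stage("directions")
    def do_directions():
        called = comp.apply_directions(kept, config.filter)
        return called, comp.resolve_conflicts(called)

    called, calls = do_directions()
    record("directions", len(kept), len(calls))
    comp.write_observations(called, outdir / "compendium_called.tsv")

    # --- site statistics ---------------------------------------------------
    @_stage("sites")
    def do_sites():
        profile_obs = [o for o in kept if o.dataset_kind == "profile"]
        freqs = site_stats.detection_frequency(calls, profile_obs, config.target)
        if config.explicit_sites:
            major = [comp.SiteKey.parse(s) for s in config.explicit_sites]
            log.info("explicit site list given; selection stage skipped")
        else:
            major = site_stats.select_major_sites(freqs, k=config.k_major, min_count=config.min_count)
        domains = site_stats.read_domains(config.domains) if config.domains else []
        lolli = site_stats.lollipop_table(freqs, domains, major)
        return freqs, major, lolli

    freqs, major_sites, lolli = do_sites()
    record(
        "sites",
        len(freqs),
        len(major_sites),
        major_sites=[str(s) for s in major_sites],
        selection_skipped=bool(config.explicit_sites),
    )
    lolli.to_csv(outdir / "lollipop.tsv", sep="\t", index=False)

    # --- within-protein co-occurrence -------------------------------------
    @_stage("cooccur")
    def do_cooccur():
        target_sites = sorted(
            {s for (_, s) in calls if s.gene == config.target.upper()}
        )
        if len(target_sites) < 2:
            return None, 0
        m = cooc.cooccurrence_matrix(target_sites, calls)
        cooc.matrix_to_long(m, calls).to_csv(outdir / "cooccurrence_long.tsv", sep="\t", index=False)
        cooc.write_matrix(m, outdir / "cooccurrence_matrix.tsv")
        return m, len(target_sites)

    matrix, n_target_sites = do_cooccur()
    record("cooccur", n_target_sites, 0 if matrix is None else len(matrix.sites))

    # --- PsOP co-regulation ------------------------------------------------
    @_stage("coreg")
    def do_coreg():
        results = coreg.scan_psops(calls, major_sites, config.target, config.highconf)
        hcs = coreg.high_confidence(results)
        coreg.results_to_frame(results).to_csv(outdir / "coreg_results.tsv", sep="\t", index=False)
        if len(major_sites) == 3:
            for sign in ("positive", "negative"):
                sets = {
                    str(m): {r.o_site for r in hcs if r.m_site == m and r.sign == sign}
                    for m in major_sites
                }
                part = coreg.venn_partition(sets)
                coreg.venn_to_frame(part).to_csv(
                    outdir / f"venn_{sign}.tsv", sep="\t", index=False
                )
        return results, hcs

    results, highconf = do_coreg()
    record("coreg", len(results), len(highconf))

    # --- annotation --------------------------------------------------------
    @_stage("annotation")
    def do_annotation():
        resources = []
        for kind, paths in sorted(config.resources.items()):
            for p in [paths] if isinstance(paths, str) else list(paths):
                resources.append(anno.load_resource(p, kind, alias_map))
        assignments = anno.assign_roles(highconf, config.target, resources, major_sites)
        anno.roles_to_frame(assignments).to_csv(outdir / "roles.tsv", sep="\t", index=False)
        return resources, assignments

    resources, assignments = do_annotation()
    record("annotation", len(highconf), len(assignments), n_resources=len(resources))

    # --- network -----------------------------------------------------------
    @_stage("network")
    def do_network():
        net = netmod.build_network(highconf, assignments, major_sites)
        written = []
        written += netmod.write_network(net, "graphml", outdir / "network.graphml")
        written += netmod.write_network(net, "sif", outdir / "network.sif")
        return net, written

    network, files = do_network()
    record("network", len(highconf), network.n_edges, n_nodes=network.n_nodes)

    manifest["outputs"] = sorted(
        str(p.relative_to(outdir)) for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        calls=calls,
        major_sites=major_sites,
        frequencies=freqs,
        results=results,
        highconf=highconf,
        assignments=assignments,
        network=network,
        manifest=manifest,
    )
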