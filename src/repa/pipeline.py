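"""End-to-end orchestration: scan -> strength -> events -> emergence,
with a reproducible run manifest and report rendering.

A run is driven by one :class:`PipelineConfig` document (validated up
front; nothing runs on a schema violation).  Stages execute in
dependency order and each leaves its output file in the run directory;
a stage failure stops the run but keeps completed outputs alongside an
error manifest, so the record-count funnel up to the failure stays
auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .annotation import (extract_windows, derive_introns, open_genome,
                         parse_annotation, read_sites_tsv, write_sites_bed,
                         write_sites_tsv)
from .events import detect_as_events, associate_sites, events_for_sites, \
    type_distribution, write_events_tsv
from .phylo import call_emergence, load_ortholog_table, load_packaged_survey, \
    presence_row, summarize_emergence, write_presence_tsv
from .scan import position_profile, scan_windows, write_calls_tsv
from .strength import train_strength_model
from .synth import GeneratorConfig, generate_genome

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "render_report"]


class ConfigError(ValueError):
    """Configuration failed schema validation (exit code 2 territory)."""


class ScanParams(BaseModel):
    threshold: float = 0.60
    gmin: int = 3
    gmax: int = 8
    intron_span: int = 20
    exon_span: int = 3


class StrengthParams(BaseModel):
    enabled: bool = True
    constraints: str = "adjacent_pairs"
    smoothing: float = 0.5


class OrthologParams(BaseModel):
    enabled: bool = True
    table: str | None = None  # None -> the packaged vertebrate survey
    gmin: int = 3


class PipelineConfig(BaseModel):
    mode: str = "synthetic"  # "synthetic" | "files"
    genome: str | None = None
    gtf: str | None = None
    seed: int = 0
    generator: GeneratorConfig = Field(default_factory=lambda: GeneratorConfig(n_genes=400))
    scan: ScanParams = Field(default_factory=ScanParams)
    strength: StrengthParams = Field(default_factory=StrengthParams)
    orthologs: OrthologParams = Field(default_factory=OrthologParams)

    @classmethod
    def validated(cls, raw: Mapping) -> "PipelineConfig":
        try:
            cfg = cls.model_validate(raw)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc
        if cfg.mode not in ("synthetic", "files"):
            raise ConfigError(f"mode must be synthetic|files, got {cfg.mode!r}")
        if cfg.mode == "files":
            for name in ("genome", "gtf"):
                if getattr(cfg, name) is None:
                    raise ConfigError(f"mode=files requires the {name!r} path")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: Mapping | PipelineConfig, out_dir: str | Path) -> dict:
    """Run all stages; returns the manifest (also written as
    ``manifest.json``).  ``manifest["status"]`` is "ok" or "error"."""
    cfg = config if isinstance(config, PipelineConfig) else \
        PipelineConfig.validated(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_json = cfg.model_dump_json()
    manifest: dict = {
        "tool_version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "input_hashes": {},
        "counts": {},
        "status": "ok",
    }

    def finish(error: str | None = None) -> dict:
        if error:
            manifest["status"] = "error"
            manifest["error"] = error
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    try:
        # stage 0: inputs ------------------------------------------------
        if cfg.mode == "synthetic":
            gen = cfg.generator.model_copy(update={"seed": cfg.seed})
            synth = generate_genome(gen)
            paths = synth.write(out)
            genome_path, gtf_path = paths["fasta"], paths["gtf"]
            manifest["counts"]["truth_sites"] = int(len(synth.truth))
        else:
            genome_path, gtf_path = Path(cfg.genome), Path(cfg.gtf)
        manifest["input_hashes"]["genome"] = _sha256(genome_path)
        manifest["input_hashes"]["gtf"] = _sha256(gtf_path)

        # stage 1: sites -------------------------------------------------
        models = parse_annotation(gtf_path)
        introns = derive_introns(models)
        genome = open_genome(genome_path)
        windows, errors = extract_windows(
            genome, introns, cfg.scan.intron_span, cfg.scan.exon_span
        )
        write_sites_tsv(windows, out / "sites.tsv")
        write_sites_bed(windows, out / "sites.bed")
        manifest["counts"].update(
            transcripts=len(models), introns=len(introns),
            sites=len(windows), site_errors=len(errors),
        )

        # stage 2: scan --------------------------------------------------
        calls = scan_windows(
            windows, cfg.scan.threshold, cfg.scan.gmin, cfg.scan.gmax
        )
        write_calls_tsv(calls, out / "calls.tsv")
        repa_calls = [c for c in calls if c.is_repa]
        gtract_calls = [c for c in repa_calls if c.has_g_tract]
        manifest["counts"].update(
            repa_sites=len(repa_calls), gtract_sites=len(gtract_calls)
        )

        # positional profiles (purine-rich vs pyrimidine-rich sets)
        full = [w for w in windows if not w.truncated]
        repa_ids = {c.site_id for c in repa_calls}
        frames = []
        for label, group in (
            ("repa", [w for w in full if w.site_id in repa_ids]),
            ("constitutive", [w for w in full if w.site_id not in repa_ids]),
        ):
            if group:
                df = position_profile(group).to_frame()
                df.insert(0, "set", label)
                frames.append(df)
        if frames:
            pd.concat(frames).to_csv(out / "profile.tsv", sep="\t", index=False)

        # stage 3: acceptor strength --------------------------------------
        if cfg.strength.enabled:
            want = cfg.scan.intron_span + cfg.scan.exon_span
            repa_w = [w.window for w in full
                      if w.site_id in repa_ids and len(w.window) == want
                      and "N" not in w.window]
            const_w = [w.window for w in full
                       if w.site_id not in repa_ids and len(w.window) == want
                       and "N" not in w.window]
            results = train_strength_model(
                const_w, repa_w, cfg.strength.constraints,
                cfg.strength.smoothing,
                window_spec=(cfg.scan.intron_span, cfg.scan.exon_span),
            )
            scorable = [w for w in full
                        if len(w.window) == want and "N" not in w.window]
            scores = results.score_many([w.window for w in scorable])
            pd.DataFrame({
                "site_id": [w.site_id for w in scorable],
                "strength_bits": scores,
            }).to_csv(out / "scores.tsv", sep="\t", index=False)
            results.to_json(out / "strength_model.json")
            manifest["counts"]["scored_sites"] = len(scorable)

        # stage 4: alternative-splicing events ----------------------------
        events = detect_as_events(models)
        write_events_tsv(events, out / "events.tsv")
        assoc = associate_sites(events, repa_calls)
        n_alt = sum(a["is_alternative"] for a in assoc.values())
        manifest["counts"].update(as_events=len(events), repa_alternative=n_alt)
        repa_events = events_for_sites(events, repa_calls)
        if repa_events:
            dist = type_distribution(
                repa_events, cfg.generator.reference_proportions or None
            )
            dist.to_frame().to_csv(out / "as_types.tsv", sep="\t", index=False)

        # stage 5: vertebrate emergence ------------------------------------
        if cfg.orthologs.enabled:
            sets = (load_ortholog_table(cfg.orthologs.table)
                    if cfg.orthologs.table else load_packaged_survey())
            rows = call_emergence(
                [presence_row(ws, cfg.orthologs.gmin) for ws in sets]
            )
            write_presence_tsv(rows, out / "emergence.tsv")
            summary = summarize_emergence(rows)
            (out / "emergence_summary.json").write_text(
                json.dumps(summary, indent=2)
            )
            manifest["counts"].update(
                ortholog_genes=summary["n_rows"],
                complete_rows=summary["n_complete"],
            )
    except ConfigError:
        raise
    except Exception as exc:  # keep completed outputs + error manifest
        logger.exception("pipeline stage failed")
        return finish(error=f"{type(exc).__name__}: {exc}")
    return finish()


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def render_report(run_dir: str | Path, report_dir: str | Path | None = None) -> dict:
    """Render the run's summary figures (SVG, deterministic bytes) and a
    text summary; empty inputs yield placeholders, never a crash."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    plt.rcParams["svg.hashsalt"] = "repa"

    run = Path(run_dir)
    rep = Path(report_dir) if report_dir else run / "report"
    rep.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    summary_lines: list[str] = []

    def save(fig, name: str) -> None:
        path = rep / name
        fig.savefig(path, format="svg", metadata={"Date": None})
        plt.close(fig)
        written[name] = path

    def placeholder(name: str, msg: str) -> None:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.text(0.5, 0.5, msg, ha="center", va="center")
        ax.set_axis_off()
        logger.warning("report %s: %s", name, msg)
        save(fig, name)

    profile_path = run / "profile.tsv"
    if profile_path.exists():
        prof = pd.read_csv(profile_path, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for label, sub in prof.groupby("set"):
            sub = sub[sub["position"] < 0]
            ax.plot(sub["position"], 100 * sub["purine_fraction"],
                    marker="o", ms=3, label=label)
        ax.set_xlabel("intron-relative position")
        ax.set_ylabel("% A/G")
        ax.legend()
        fig.tight_layout()
        save(fig, "purine_profile.svg")
    else:
        placeholder("purine_profile.svg", "no profile data")

    calls_path = run / "calls.tsv"
    if calls_path.exists():
        from .scan import read_calls_tsv, first_g_histogram, run_length_distribution
        calls = [c for c in read_calls_tsv(calls_path) if c.is_repa and c.has_g_tract]
        if calls:
            hist = first_g_histogram(calls)
            fig, ax = plt.subplots(figsize=(4.5, 3))
            ax.bar(hist.index, hist.values, color="0.3")
            ax.set_xlabel("first G position")
            ax.set_ylabel("sites")
            fig.tight_layout()
            save(fig, "first_g_histogram.svg")
            rl = run_length_distribution(calls)
            fig, ax = plt.subplots(figsize=(3.5, 3.5))
            ax.pie(rl.values, labels=[f"G{k}" for k in rl.index],
                   normalize=True)
            fig.tight_layout()
            save(fig, "run_length_pie.svg")
        else:
            placeholder("first_g_histogram.svg", "no G-tract sites")
            placeholder("run_length_pie.svg", "no G-tract sites")

    types_path = run / "as_types.tsv"
    if types_path.exists():
        dist = pd.read_csv(types_path, sep="\t")
        fig, ax = plt.subplots(figsize=(4.5, 3))
        ax.bar(dist["event_type"], dist["proportion"], color="0.4")
        ax.set_ylabel("proportion of events")
        ax.tick_params(axis="x", rotation=30)
        fig.tight_layout()
        save(fig, "as_type_distribution.svg")

    summ_path = run / "emergence_summary.json"
    if summ_path.exists():
        summ = json.loads(summ_path.read_text())
        fig, ax = plt.subplots(figsize=(4, 3))
        keys = ["n_mammalian", "n_pre_mammalian", "n_absent"]
        ax.bar([k.replace("n_", "") for k in keys], [summ[k] for k in keys],
               color="0.5")
        ax.set_ylabel("complete rows")
        fig.tight_layout()
        save(fig, "emergence_bar.svg")
        summary_lines += [
            f"ortholog rows: {summ['n_rows']}",
            f"n_complete: {summ['n_complete']}",
            f"pct_mammalian: {summ['pct_mammalian']:.1f}",
        ]

    manifest_path = run / "manifest.json"
    if manifest_path.exists():
        counts = json.loads(manifest_path.read_text()).get("counts", {})
        summary_lines = [
            f"{k}: {v}" for k, v in counts.items()
        ] + summary_lines
    (rep / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    written["summary.txt"] = rep / "summary.txt"
    return {k: str(v) for k, v in written.items()}
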