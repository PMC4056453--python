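"""One-shot orchestration: simulate -> conserve -> co-bind -> repeats -> words.

A run is driven by a single declarative :class:`RunConfig` (optionally read
from YAML).  Every stage writes tab-separated outputs under the run
directory, and a machine-readable ``summary.json`` collects the headline
numbers (class fractions, pairwise fractions and their divergence
correlation, co-binding fractions, significant repeats, selected words).
Re-running with an unchanged config and seed reproduces every output
byte-identically; the run log records the resolved value of every
threshold and seed (and no timestamps, so logs are reproducible too).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import cobinding, conservation, repeats as repeats_mod, synthetic, words as words_mod
from .core import BindingEventSet, read_binding_bed, read_features_bed, read_repeatmasker

ALL_STAGES = ["simulate", "conserve", "cobind", "repeats", "words"]


class PipelineError(RuntimeError):
    pass


@dataclass
class Thresholds:
    unique_fdr_cutoff: float = 0.05
    min_bp: int = 1
    n_rand: int = 100
    pwm_cutoff: float = -15.0
    word_min_count: int = 5
    word_fdr: float = 0.05
    repeat_significance: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.unique_fdr_cutoff <= 1):
            raise ValueError("unique_fdr_cutoff must lie in (0, 1]")
        if self.min_bp < 1:
            raise ValueError("min_bp must be >= 1")
        if self.n_rand < 10:
            raise ValueError("n_rand must be >= 10")
        if not (0 < self.word_fdr < 1) or not (0 < self.repeat_significance < 1):
            raise ValueError("FDR thresholds must lie in (0, 1)")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    outdir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    world: synthetic.WorldConfig | None = None
    inputs: dict[str, Any] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seed = int(raw.get("seed", 0))
        world = None
        if "simulate" in raw:
            overrides = dict(raw["simulate"] or {})
            world = synthetic.default_world(seed=seed, **overrides)
        thresholds = Thresholds(**(raw.get("thresholds") or {}))
        return cls(
            outdir=raw.get("outdir", "primatecons_run"),
            seed=seed,
            stages=list(raw.get("stages", ALL_STAGES)),
            world=world,
            inputs=dict(raw.get("inputs") or {}),
            thresholds=thresholds,
        )


def _default_simulation_world(seed: int) -> synthetic.WorldConfig:
    """Study-style world with planted repeat and word structure for a full run."""
    cfg = synthetic.default_world(seed=seed)
    cfg.repeat_spec = [
        synthetic.RepeatSpec("LTR13", 330, planted_enrichment=5.0,
                             milli_div_mean=110, milli_div_sd=15),
        synthetic.RepeatSpec("MLT1J", 330, planted_enrichment=1.0,
                             milli_div_mean=250, milli_div_sd=30,
                             rep_class="LTR", rep_family="MaLR"),
        synthetic.RepeatSpec("AluY", 500, planted_enrichment=1.0,
                             milli_div_mean=40, milli_div_sd=10,
                             rep_class="SINE", rep_family="Alu"),
    ]
    cfg.word_spec = synthetic.WordSpec()
    return cfg


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the requested stages in dependency order; return the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed: {config.seed}", f"stages: {','.join(config.stages)}"]
    for k, v in vars(config.thresholds).items():
        log_lines.append(f"threshold {k}: {v}")
    summary: dict[str, Any] = {"seed": config.seed, "stages": {}}

    world = None
    events: dict[str, dict[str, BindingEventSet]] = {}
    amap = None
    divergence: dict[str, float] = {}
    repeats_by_sp: dict[str, list] = {}
    features_by_sp: dict[str, list] = {}
    word_hits: dict[str, pd.DataFrame] = {}
    transcripts = None
    expression = None

    try:
        if "simulate" in config.stages:
            wc = config.world if config.world is not None else _default_simulation_world(config.seed)
            defaults = _default_simulation_world(config.seed)
            if not wc.repeat_spec:
                wc.repeat_spec = defaults.repeat_spec
            if wc.word_spec is None:
                wc.word_spec = defaults.word_spec
            log_lines.append(f"simulate: n_events={wc.n_events} seed={wc.seed}")
            world = synthetic.generate_world(wc)
            synthetic.write_world(world, outdir / "simulated")
            events = world.events
            amap = world.amap
            divergence = wc.divergence_map
            repeats_by_sp = world.repeats
            word_hits = world.word_hits
            summary["stages"]["simulate"] = {
                "n_species": len(wc.species),
                "n_events": wc.n_events,
                "n_blocks": len(amap),
            }
        else:
            events, amap, divergence = _load_inputs(config)
            repeats_by_sp, features_by_sp, word_hits, transcripts, expression = _load_optional(config)

        anchor = next(iter(events)) if events else None

        if "conserve" in config.stages:
            if amap is None or not events:
                raise PipelineError("conserve stage requires an alignment map and peak sets")
            cls = conservation.classify_conservation(
                {sp: events[sp]["CTCF"] for sp in events}, amap, anchor
            )
            cls.to_frame().to_csv(outdir / "classes.tsv", sep="\t", index=False)
            fractions = {}
            for sp in events:
                if sp == anchor:
                    continue
                fractions[sp] = conservation.pairwise_shared_fraction(
                    events[anchor]["CTCF"], events[sp]["CTCF"], amap
                )
            pd.DataFrame(
                {"species": list(fractions), "shared_fraction": list(fractions.values())}
            ).to_csv(outdir / "pairwise.tsv", sep="\t", index=False, float_format="%.10g")
            block = {
                "anchor": anchor,
                "class_fractions": {k: round(v, 10) for k, v in cls.class_fractions().items()},
                "pairwise_shared": {k: round(v, 10) for k, v in fractions.items()},
            }
            if divergence and len(fractions) >= 3:
                r, p = conservation.overlap_divergence_correlation(fractions, divergence)
                block["divergence_pearson_r"] = round(r, 10)
                block["divergence_pearson_p"] = round(p, 10)
            summary["stages"]["conserve"] = block

        partitions = {}
        if "cobind" in config.stages:
            if not events:
                raise PipelineError("cobind stage requires peak sets")
            for sp in events:
                partitions[sp] = cobinding.classify_cobinding(
                    events[sp]["CTCF"], events[sp]["YY1"]
                )
            rows = [
                {
                    "species": sp,
                    "n_ctcf": part.n_ctcf,
                    "n_yy1": part.n_yy1,
                    "fraction_ctcf_cobound": part.fraction_ctcf_cobound(),
                    "fraction_yy1_cobound": part.fraction_yy1_cobound(),
                }
                for sp, part in sorted(partitions.items())
            ]
            pd.DataFrame(rows).to_csv(outdir / "cobind.tsv", sep="\t", index=False,
                                      float_format="%.10g")
            block = {
                "fraction_ctcf_cobound": {
                    sp: round(p.fraction_ctcf_cobound(), 10) for sp, p in sorted(partitions.items())
                },
                "fraction_yy1_cobound": {
                    sp: round(p.fraction_yy1_cobound(), 10) for sp, p in sorted(partitions.items())
                },
            }
            if world is not None and not features_by_sp:
                features_by_sp = synthetic.generate_cpg_islands(world.config, partitions)
            if features_by_sp:
                assoc = cobinding.feature_association(partitions, features_by_sp, "cpg_island")
                assoc.fractions.to_csv(outdir / "cpg_association.tsv", sep="\t",
                                       float_format="%.10g")
                block["cpg_p_value"] = None if assoc.p_value is None else round(assoc.p_value, 10)
            if world is not None and transcripts is None:
                transcripts, labels = synthetic.generate_transcripts(world.config, partitions[anchor])
                expr_df = synthetic.generate_expression(world.config, labels)
                expression = dict(zip(expr_df.transcript_id, expr_df.log2_estimate))
                expr_df.to_csv(outdir / "expression.tsv", sep="\t", index=False,
                               float_format="%.10g")
            if transcripts is not None and expression is not None:
                comp = cobinding.expression_comparison(partitions[anchor], transcripts, expression)
                comp.summaries.to_csv(outdir / "expression_summary.tsv", sep="\t",
                                      float_format="%.10g")
                block["expression_p_ctcf_vs_cobound"] = (
                    None if comp.p_ctcf_vs_cobound is None else round(comp.p_ctcf_vs_cobound, 12)
                )
            summary["stages"]["cobind"] = block

        if "repeats" in config.stages:
            if not repeats_by_sp:
                raise PipelineError("repeats stage requires repeat annotation")
            genome_of = (
                {s.name: s.genome for s in world.config.species}
                if world is not None
                else config.inputs.get("genomes", {})
            )
            frames = []
            for sp in sorted(repeats_by_sp):
                if not repeats_by_sp[sp]:
                    continue
                res = repeats_mod.repeat_enrichment_test(
                    events[sp]["CTCF"], repeats_by_sp[sp], genome_of[sp],
                    n_rand=config.thresholds.n_rand, seed=config.seed,
                )
                frames.append(res)
            res_all = pd.concat(frames, ignore_index=True)
            res_all.to_csv(outdir / "repeat_enrichment.tsv", sep="\t", index=False,
                           float_format="%.10g")
            sig = res_all[res_all.p_adj <= config.thresholds.repeat_significance]
            summary["stages"]["repeats"] = {
                "n_families_tested": int(len(res_all)),
                "significant": sorted(sig.rep_name.unique().tolist()),
            }

        if "words" in config.stages:
            if not word_hits:
                raise PipelineError("words stage requires per-species motif-word hits")
            bound = {sp: events[sp]["CTCF"] for sp in word_hits}
            table = words_mod.build_word_table(
                word_hits, bound, min_count=config.thresholds.word_min_count
            )
            focal = (
                (world.config.word_spec.species or anchor)
                if world is not None and world.config.word_spec
                else config.inputs.get("word_focal", anchor)
            )
            comparison = [sp for sp in table.species if sp != focal]
            scores = words_mod.norm_word_scores(table, focal, comparison)
            selected, cutoff = words_mod.select_specific_words(
                scores, fdr=config.thresholds.word_fdr
            )
            table.counts.to_csv(outdir / "word_counts.tsv", sep="\t")
            scores.to_csv(outdir / "word_scores.tsv", sep="\t", index=False,
                          float_format="%.10g")
            summary["stages"]["words"] = {
                "focal": focal,
                "n_words": int(len(table.counts)),
                "selected": sorted(selected),
                "normword_cutoff": cutoff if cutoff != float("inf") else "inf",
            }
    finally:
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _load_inputs(config: RunConfig):
    inputs = config.inputs
    peaks = inputs.get("peaks")
    if not peaks:
        raise PipelineError("missing input: peaks (per-species BED paths)")
    events: dict[str, dict[str, BindingEventSet]] = {}
    for sp, by_factor in peaks.items():
        events[sp] = {}
        for factor, path in by_factor.items():
            if not Path(path).exists():
                raise PipelineError(f"missing input file: {path}")
            events[sp][factor] = read_binding_bed(path, sp, factor)
        events[sp].setdefault("YY1", BindingEventSet(sp, "YY1"))
    amap = None
    if "map" in inputs:
        if not Path(inputs["map"]).exists():
            raise PipelineError(f"missing input file: {inputs['map']}")
        amap = conservation.read_block_table(inputs["map"])
    elif "conserve" in config.stages:
        raise PipelineError("missing input: map (alignment block table)")
    divergence = {k: float(v) for k, v in (inputs.get("divergence") or {}).items()}
    return events, amap, divergence


def _load_optional(config: RunConfig):
    inputs = config.inputs
    repeats_by_sp = {}
    for sp, path in (inputs.get("repeats") or {}).items():
        if not Path(path).exists():
            raise PipelineError(f"missing input file: {path}")
        repeats_by_sp[sp] = read_repeatmasker(path)
    features_by_sp = {}
    for sp, path in (inputs.get("features") or {}).items():
        if not Path(path).exists():
            raise PipelineError(f"missing input file: {path}")
        features_by_sp[sp] = read_features_bed(path, "cpg_island")
    word_hits = {}
    for sp, path in (inputs.get("word_hits") or {}).items():
        if not Path(path).exists():
            raise PipelineError(f"missing input file: {path}")
        word_hits[sp] = pd.read_csv(path, sep="\t")
    transcripts = None
    expression = None
    if "expression" in inputs:
        path = inputs["expression"]
        if not Path(path).exists():
            raise PipelineError(f"missing input file: {path}")
        transcripts, expression = read_expression_tsv(path)
    return repeats_by_sp, features_by_sp, word_hits, transcripts, expression


def read_expression_tsv(path: str | Path):
    """Expression TSV: transcript_id, chrom, start, end, log2_estimate."""
    from .core import FeatureAnnotation, GenomicInterval

    df = pd.read_csv(path, sep="\t")
    needed = {"transcript_id", "log2_estimate"}
    if not needed.issubset(df.columns):
        raise ValueError(f"expression TSV must contain columns {sorted(needed)}")
    transcripts = None
    if {"chrom", "start", "end"}.issubset(df.columns):
        transcripts = [
            FeatureAnnotation(
                "transcript",
                GenomicInterval(r.chrom, int(r.start), int(r.end)),
                str(r.transcript_id),
            )
            for r in df.itertuples(index=False)
        ]
    expression = dict(zip(df.transcript_id.astype(str), df.log2_estimate.astype(float)))
    return transcripts, expression
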