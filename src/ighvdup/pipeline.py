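"""End-to-end pipeline: simulate → design → assay → phase → blocks → clock.

The pipeline strings the modules together on a single config object and
writes every artifact (FASTA, BED, TSV, JSON) into an output directory with
a manifest recording stage provenance.  Sub-seeds are derived from the
master seed by hashing the stage name, so adding a stage never perturbs the
randomness of the others.

The default configuration emulates the study conditions: a ~90 kb region
produced by planting a 24,696 bp unit as two complete tandem copies plus a
961 bp truncated copy (each copy mutated at 2.2%, i.e. ~4.4% pairwise),
tags at ~5 kb spacing, six donors with 49–60 sperm each under 5% dropout /
1% false-positive noise.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ioutil
from .assay import (DetectionRules, NoiseModel, classify_tags,
                    delimit_polymorphic_region, find_undetectable_runs,
                    phase_sperm, simulate_sperm_panel)
from .clock import ClockParams, clock_report
from .divergence import DivergenceConfig, build_divergence_table
from .dotplot import DotPlotParams, find_repeat_units
from .region import AnnotatedRegion
from .synthetic import (DuplicationSpec, VariantSpec, build_ancestral_region,
                        default_gene_templates, make_donor_haplotypes,
                        plant_duplication)
from .tags import OligoSet, design_oligos, select_tags


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2^31), independent across stages."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RegionConfig:
    ancestral_length: int = 65_000
    unit_span: tuple[int, int] = (20_000, 44_696)  # 24,696 bp unit
    n_complete: int = 2
    partial_length: int = 961
    per_copy_divergence: float = 0.022


@dataclass(frozen=True)
class TagConfig:
    spacing: int = 5000
    max_len: int = 225
    tag_len: int = 150


@dataclass(frozen=True)
class DonorConfig:
    name: str
    h1: VariantSpec = field(default_factory=VariantSpec)
    h2: VariantSpec = field(default_factory=VariantSpec)


def default_donors() -> tuple[DonorConfig, ...]:
    """Six donors mirroring the observed haplotype diversity: most haplotypes
    intact, one lacking the whole repeat array, two lacking one copy, one
    copy-intact but extra-diverged."""
    return (
        DonorConfig("d1"),
        DonorConfig("d2", h1=VariantSpec(delete_units=(0, 1, 2)),
                    h2=VariantSpec(delete_units=(1,))),
        DonorConfig("d3"),
        DonorConfig("d4", h2=VariantSpec(delete_units=(0,))),
        DonorConfig("d5", h2=VariantSpec(extra_divergence=0.02)),
        DonorConfig("d6", h1=VariantSpec(delete_units=(1,))),
    )


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "pipeline_out"
    master_seed: int = 0
    region: RegionConfig = field(default_factory=RegionConfig)
    tags: TagConfig = field(default_factory=TagConfig)
    donors: tuple[DonorConfig, ...] = field(default_factory=default_donors)
    noise: NoiseModel = field(default_factory=NoiseModel)
    rules: DetectionRules = field(default_factory=DetectionRules)
    dotplot: DotPlotParams = field(default_factory=DotPlotParams)
    min_unit: int = 500
    n_sperm_range: tuple[int, int] = (49, 60)
    divergence: DivergenceConfig = field(default_factory=DivergenceConfig)
    clock: ClockParams = field(default_factory=ClockParams)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def build_reference_region(cfg: PipelineConfig) -> AnnotatedRegion:
    """The duplicated reference region the study conditions presuppose."""
    templates = default_gene_templates(stage_seed(cfg.master_seed, "templates"))
    unit_start, unit_end = cfg.region.unit_span
    unit_len = unit_end - unit_start
    # two flanking genes outside the unit and as many genes inside it as the
    # unit can hold (six at study scale); the first unit gene sits within the
    # future partial-copy prefix
    margin, min_gap = 200, 50
    inner, used = [], 2 * margin
    for t in templates[1:-1]:
        need = len(t.seq) + (min_gap if inner else 0)
        if used + need > unit_len:
            break
        inner.append(t)
        used += need
    if not inner:
        raise ValueError("unit_span too small for any gene segment")
    inner_offsets = [unit_start + margin]
    step = (unit_len - 2 * margin - sum(len(t.seq) for t in inner)) // max(
        len(inner) - 1, 1
    )
    for t in inner[:-1]:
        inner_offsets.append(inner_offsets[-1] + len(t.seq) + step)
    templates = [templates[0]] + inner + [templates[-1]]
    offsets = [unit_start // 2] + inner_offsets + [
        (unit_end + cfg.region.ancestral_length - len(templates[-1].seq)) // 2
    ]
    ancestral = build_ancestral_region(
        cfg.region.ancestral_length,
        templates,
        seed=stage_seed(cfg.master_seed, "ancestral"),
        name="regionII",
        offsets=offsets,
    )
    dup = DuplicationSpec(
        unit_length=unit_len,
        n_complete=cfg.region.n_complete,
        partial_length=cfg.region.partial_length,
        per_copy_divergence=cfg.region.per_copy_divergence,
        seed=stage_seed(cfg.master_seed, "duplication"),
    )
    return plant_duplication(ancestral, cfg.region.unit_span, dup)


def run_pipeline(cfg: PipelineConfig = PipelineConfig()) -> dict:
    """Execute all stages and return the artifact manifest.

    The manifest lists every output file with the stage that produced it;
    re-running with the same config and master seed is byte-identical.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": cfg.master_seed, "stages": {}, "files": {}}
    log: list[str] = []

    def note(stage: str, **params):
        manifest["stages"][stage] = {"seed": stage_seed(cfg.master_seed, stage),
                                     **params}
        log.append(f"{stage}: {params}")

    def emit(stage: str, name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["files"][name] = stage

    t0 = time.time()
    # --- simulate ---------------------------------------------------------
    try:
        region = build_reference_region(cfg)
        note("simulate", length=len(region),
             n_repeat_units=len(region.features_of("repeat_unit")))
        emit("simulate", "reference.fasta", lambda p: ioutil.write_fasta(p, [region]))
        emit("simulate", "reference_features.bed",
             lambda p: ioutil.write_bed(p, region))
    except Exception as e:  # noqa: BLE001 - stage tagging
        raise StageError("simulate", e) from e

    # --- design tags ------------------------------------------------------
    try:
        sel = select_tags(region, spacing=cfg.tags.spacing, max_len=cfg.tags.max_len,
                          tag_len=cfg.tags.tag_len)
        oligos: dict[str, OligoSet] = {}
        designed = []
        for t in sel.tags:
            try:
                oligos[t.name] = design_oligos(t, region)
                designed.append(t)
            except Exception:
                continue  # tags whose oligo layout fails are dropped
        note("design", n_tags=len(designed), n_skipped_intervals=len(sel.skipped))
        emit("design", "tags.tsv",
             lambda p: ioutil.write_tag_table(p, designed, oligos))
    except StageError:
        raise
    except Exception as e:
        raise StageError("design", e) from e

    ordered_tags = [t.name for t in designed]
    oligo_list = [oligos[name] for name in ordered_tags]

    # --- assay + phase ----------------------------------------------------
    calls = []
    hap_regions: dict[str, AnnotatedRegion] = {}
    try:
        rng = np.random.default_rng(stage_seed(cfg.master_seed, "assay"))
        for donor in cfg.donors:
            h1, h2 = make_donor_haplotypes(
                region, (donor.h1, donor.h2),
                seed=stage_seed(cfg.master_seed, f"haplotypes:{donor.name}"),
            )
            hap_regions[f"{donor.name}_H1"] = h1
            hap_regions[f"{donor.name}_H2"] = h2
            n_sperm = int(rng.integers(cfg.n_sperm_range[0],
                                       cfg.n_sperm_range[1] + 1))
            noise = NoiseModel(cfg.noise.dropout, cfg.noise.false_positive,
                               seed=stage_seed(cfg.master_seed, f"noise:{donor.name}"))
            matrix, _truth = simulate_sperm_panel(
                (h1, h2), oligo_list, n_sperm, noise, donor=donor.name,
                rules=cfg.rules,
            )
            emit("assay", f"genotypes_{donor.name}.tsv",
                 lambda p, m=matrix: ioutil.write_matrix_tsv(p, m))
            (c1, c2), _assign = phase_sperm(matrix)
            calls += [c1, c2]
        note("assay", n_donors=len(cfg.donors),
             dropout=cfg.noise.dropout, false_positive=cfg.noise.false_positive)
        emit("phase", "haplotypes.tsv",
             lambda p: ioutil.write_haplotype_table(p, calls, ordered_tags))
        emit("phase", "haplotype_sequences.fasta",
             lambda p: ioutil.write_fasta(p, list(hap_regions.values())))
    except StageError:
        raise
    except Exception as e:
        raise StageError("assay", e) from e

    # --- classify / delimit ----------------------------------------------
    try:
        classes = classify_tags(calls)
        runs = {f"{c.donor}/{c.label}": find_undetectable_runs(c, ordered_tags)
                for c in calls}
        span = delimit_polymorphic_region(classes, ordered_tags)
        note("classify",
             n_polymorphic=sum(v == "polymorphic" for v in classes.values()),
             span=[span.first_tag, span.last_tag],
             flanks=[span.flank_left, span.flank_right])
        emit("classify", "tag_classes.json",
             lambda p: p.write_text(json.dumps(classes, indent=1)))
        emit("classify", "undetectable_runs.tsv",
             lambda p: ioutil.write_runs_tsv(p, runs))
    except Exception as e:
        raise StageError("classify", e) from e

    # --- duplicate blocks -------------------------------------------------
    try:
        blocks = {"reference": find_repeat_units(region.seq, cfg.dotplot,
                                                 min_unit=cfg.min_unit)}
        note("blocks", min_unit=cfg.min_unit, window=cfg.dotplot.window,
             n_copies=[len(b.copies) for b in blocks["reference"]])
        emit("blocks", "repeat_blocks.tsv",
             lambda p: ioutil.write_blocks_tsv(p, blocks))
    except Exception as e:
        raise StageError("blocks", e) from e

    # --- divergence -------------------------------------------------------
    try:
        pairs = []
        ref_units = region.features_of("repeat_unit")
        genes = region.features_of("gene_segment")
        complete = [u for u in ref_units
                    if u.length >= 0.9 * (cfg.region.unit_span[1]
                                          - cfg.region.unit_span[0])]
        if len(complete) >= 2:
            u1, u2 = complete[0], complete[1]
            g1 = [g for g in genes if g.start >= u1.start and g.end <= u1.end]
            g2 = [g for g in genes if g.start >= u2.start and g.end <= u2.end]
            for a, b in zip(g1, g2):
                pairs.append((a.name, region.slice_seq(a.start, a.end),
                              b.name, region.slice_seq(b.start, b.end),
                              "paralogous"))
        records, summaries = build_divergence_table(pairs, cfg.divergence)
        note("divergence", n_pairs=len(pairs),
             pooled={k: s.pooled_percent for k, s in summaries.items()})
        emit("divergence", "divergence.tsv", lambda p: pd.DataFrame(
            [r.__dict__ for r in records]).to_csv(p, sep="\t", index=False))
    except Exception as e:
        raise StageError("divergence", e) from e

    # --- clock ------------------------------------------------------------
    try:
        if len(complete) >= 2:
            # the generator is substitution-only, so the complete copies are
            # colinear and their divergence is a direct per-base comparison
            u1, u2 = complete[0], complete[1]
            s1 = region.slice_seq(u1.start, u1.end)
            s2 = region.slice_seq(u2.start, u2.end)
            n = min(len(s1), len(s2))
            d = sum(x != y for x, y in zip(s1[:n], s2[:n])) / n
        else:
            d = 0.0
        report = clock_report(d, cfg.clock)
        note("clock", measured_divergence=round(d, 4), **report.formatted())
        emit("clock", "clock.json",
             lambda p: p.write_text(json.dumps(
                 {"divergence": d, **asdict(report)}, indent=1)))
    except Exception as e:
        raise StageError("clock", e) from e

    log.append(f"total runtime: {time.time() - t0:.2f}s")
    (out / "run.log").write_text("\n".join(log) + "\n")
    manifest["files"]["run.log"] = "pipeline"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
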