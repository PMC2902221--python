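"""End-to-end pipeline: simulate/load -> preprocess -> segment -> filter ->
dye-swap concordance -> loop attribution -> CNVR merge -> summary.

Every stage logs its input/output counts; a provenance manifest (resolved
configuration, seeds, package version) is written next to the outputs so a
run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, calling, cnvr, io, preprocess, segmentation, synthetic
from .exceptions import InvalidArgumentError
from .synthetic import LoopDesign, PlantedCNV, ProbeRatioTable

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults."""

    ratio_threshold: float = 0.4
    min_probes: int = 5
    penalty: float | None = None  # None = BIC-style default per profile
    n_quantiles: int = 100
    span: float = 0.3
    spatial: bool = True
    normalize: bool = True
    min_overlap: float = 0.5
    n_perm: int = 10_000
    seed: int = 0
    coords: str = "0-half-open"

    def __post_init__(self) -> None:
        if self.ratio_threshold < 0:
            raise InvalidArgumentError("ratio_threshold must be non-negative")
        if self.min_probes < 1:
            raise InvalidArgumentError("min_probes must be >= 1")
        if not 0 < self.min_overlap <= 1:
            raise InvalidArgumentError("min_overlap must be in (0, 1]")
        if self.n_perm < 1:
            raise InvalidArgumentError("n_perm must be >= 1")
        if not 0 < self.span <= 1:
            raise InvalidArgumentError("span must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    candidate_calls: dict[str, list[segmentation.CandidateCall]]
    pair_calls: list[calling.PairCall]
    cnv_calls: list[calling.CNVCall]
    cnvrs: list[cnvr.CNVR]
    summary: cnvr.CnvrSummary
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_calling_pipeline(
    tables: dict[str, ProbeRatioTable],
    design: LoopDesign,
    genome_length: int,
    config: PipelineConfig | None = None,
    preprocessed: bool = False,
) -> PipelineResult:
    """Run the calling stages on in-memory per-array tables."""
    config = config or PipelineConfig()
    counts: dict[str, int] = {"arrays": len(tables)}
    candidate_calls: dict[str, list[segmentation.CandidateCall]] = {}
    n_segments = 0
    for array_id, table in tables.items():
        if not preprocessed:
            table = preprocess.preprocess_table(
                table,
                span=config.span,
                n_quantiles=config.n_quantiles,
                spatial=config.spatial,
                normalize=config.normalize,
            )
        segments = segmentation.segment_table(table, penalty=config.penalty)
        n_segments += len(segments)
        candidate_calls[array_id] = segmentation.filter_segments(
            segments,
            ratio_threshold=config.ratio_threshold,
            min_probes=config.min_probes,
        )
    counts["segments"] = n_segments
    counts["candidate_calls"] = sum(len(v) for v in candidate_calls.values())
    pair_calls, cnv_calls = calling.call_cnvs(
        candidate_calls, design, min_overlap=config.min_overlap
    )
    counts["pair_calls"] = len(pair_calls)
    counts["cnv_calls"] = len(cnv_calls)
    regions = cnvr.merge_calls(cnv_calls)
    counts["cnvrs"] = len(regions)
    summary = cnvr.summarize(regions, genome_length)
    for stage, n in counts.items():
        logger.info("stage %-16s n=%d", stage, n)
    return PipelineResult(
        candidate_calls=candidate_calls,
        pair_calls=pair_calls,
        cnv_calls=cnv_calls,
        cnvrs=regions,
        summary=summary,
        stage_counts=counts,
    )


@dataclass
class SimulationSpec:
    """Parameters of a fully synthetic experiment."""

    n_animals: int = 8
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    gap_fraction: float = 0.0
    median_spacing: int = 301
    probe_length: int = 60
    n_cnvs_per_animal: int = 3
    cnv_size_range: tuple[int, int] = (3_000, 30_000)
    loss_fraction: float = 0.664
    noise_sd: float = 0.2
    dye_bias: float = 0.0
    spatial_amplitude: float = 0.0
    x_chromosome: bool = False


def simulate_inputs(spec: SimulationSpec, seed: int = 0):
    """Generate genome, panel, probes, truth, design and array tables."""
    genome = synthetic.make_genome(
        spec.n_chromosomes,
        spec.chromosome_length,
        gap_fraction=spec.gap_fraction,
        seed=seed,
        x_chromosome=spec.x_chromosome,
    )
    panel = synthetic.make_panel(spec.n_animals, seed=seed + 1)
    probes = synthetic.tile_probes(
        genome,
        median_spacing=spec.median_spacing,
        probe_length=spec.probe_length,
        seed=seed + 2,
    )
    truth = synthetic.plant_cnvs(
        panel,
        genome,
        spec.n_cnvs_per_animal,
        size_range=spec.cnv_size_range,
        loss_fraction=spec.loss_fraction,
        seed=seed + 3,
    )
    design = synthetic.make_loop_design(panel)
    tables = synthetic.simulate_experiment(
        design,
        probes,
        truth,
        panel,
        noise_sd=spec.noise_sd,
        dye_bias=spec.dye_bias,
        spatial_amplitude=spec.spatial_amplitude,
        seed=seed + 4,
    )
    return genome, panel, probes, truth, design, tables


def evaluate_recovery(
    truth: list[PlantedCNV],
    calls: list[calling.CNVCall],
    min_overlap: float = 0.5,
) -> dict:
    """Compare CNV calls against a planted truth set.

    A planted CNV is *recovered* when some call overlaps >= min_overlap of
    it; recovery is split by whether the recovering call also has the right
    animal and direction. Wrong-direction counts calls whose locus matches
    a planted CNV but whose state contradicts it.
    """
    recovered = correct = wrong_direction = wrong_animal = 0
    per_state = {"loss": [0, 0], "gain": [0, 0]}  # [recovered&correct, total]
    for cnv in truth:
        per_state[cnv.state][1] += 1
        hits = [
            c
            for c in calls
            if c.chrom == cnv.chrom
            and min(c.end, cnv.end) - max(c.start, cnv.start) >= min_overlap * cnv.size
        ]
        if not hits:
            continue
        recovered += 1
        good = [h for h in hits if h.animal == cnv.animal and h.state == cnv.state]
        if good:
            correct += 1
            per_state[cnv.state][0] += 1
        elif any(h.animal == cnv.animal for h in hits):
            wrong_direction += 1
        else:
            wrong_animal += 1
    return {
        "n_planted": len(truth),
        "recovered": recovered,
        "correct": correct,
        "wrong_direction": wrong_direction,
        "wrong_animal": wrong_animal,
        "recall": correct / len(truth) if truth else 1.0,
        "recall_loss": (
            per_state["loss"][0] / per_state["loss"][1] if per_state["loss"][1] else 1.0
        ),
        "recall_gain": (
            per_state["gain"][0] / per_state["gain"][1] if per_state["gain"][1] else 1.0
        ),
    }


def run_pipeline(
    outdir,
    config: PipelineConfig | None = None,
    sim_spec: SimulationSpec | None = None,
    design: LoopDesign | None = None,
    tables: dict[str, ProbeRatioTable] | None = None,
    genome_length: int | None = None,
) -> PipelineResult:
    """Execute the full pipeline and write artifacts under ``outdir``.

    Either a :class:`SimulationSpec` (synthetic run) or a design plus
    per-array tables and a genome length must be supplied.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth: list[PlantedCNV] = []
    if sim_spec is not None:
        genome, panel, probes, truth, design, tables = simulate_inputs(
            sim_spec, seed=config.seed
        )
        genome_length = genome.total_length
        io.write_design_sheet(design, outdir / "design.tsv")
        io.write_panel(panel, outdir / "panel.tsv")
        io.write_truth_bed(truth, outdir / "truth.bed")
        io.write_chrom_sizes(genome, outdir / "chrom.sizes")
    if design is None or tables is None or genome_length is None:
        raise InvalidArgumentError(
            "need either sim_spec or (design, tables, genome_length)"
        )
    result = run_calling_pipeline(tables, design, genome_length, config)
    io.write_calls_bed(result.cnv_calls, outdir / "cnv_calls.bed")
    io.write_cnvr_bed(result.cnvrs, outdir / "cnvrs.bed")
    io.write_json(result.summary.as_dict(), outdir / "summary.json")
    manifest = {
        "version": __version__,
        "config": config.as_dict(),
        "stage_counts": result.stage_counts,
    }
    if truth:
        manifest["recovery"] = evaluate_recovery(truth, result.cnv_calls)
    io.write_json(manifest, outdir / "manifest.json")
    return result
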