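"""Copy-number-variable regions: cross-animal merging and summary statistics.

Overlapping per-animal calls of the same direction are merged (single
linkage, >= 1 bp overlap) into CNVRs; gains and losses never mix. The
summary reproduces the catalogue-style table: counts, mean/median sizes,
size range, total base-pair content and percent of genome per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calling import CNVCall
from .exceptions import InvalidArgumentError

DEFAULT_SIZE_BIN_EDGES = (5_000, 10_000, 20_000, 50_000, 100_000, 500_000, 2_000_000)


@dataclass(frozen=True)
class CNVR:
    """A merged copy-number-variable region of one direction."""

    chrom: str
    start: int
    end: int
    type: str  # "gain" | "loss"
    calls: tuple[CNVCall, ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidArgumentError("CNVR must have end > start")
        if self.type not in ("gain", "loss"):
            raise InvalidArgumentError(f"invalid CNVR type {self.type!r}")

    @property
    def animals(self) -> frozenset[str]:
        return frozenset(c.animal for c in self.calls)

    @property
    def n_animals(self) -> int:
        return max(1, len(self.animals))

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class ClassSummary:
    count: int = 0
    mean_size: int = 0
    median_size: int = 0
    min_size: int = 0
    max_size: int = 0
    content: int = 0
    percent_of_genome: float = 0.0
    histogram: list[int] = field(default_factory=list)


@dataclass
class CnvrSummary:
    loss: ClassSummary
    gain: ClassSummary
    all: ClassSummary
    genome_length: int
    size_bin_edges: tuple[int, ...]
    mean_cnvs_per_animal: float | None = None

    def as_dict(self) -> dict:
        out = {}
        for name in ("loss", "gain", "all"):
            s: ClassSummary = getattr(self, name)
            out[name] = {
                "count": s.count,
                "mean_size": s.mean_size,
                "median_size": s.median_size,
                "size_range": [s.min_size, s.max_size],
                "content": s.content,
                "percent_of_genome": s.percent_of_genome,
                "histogram": s.histogram,
            }
        out["genome_length"] = self.genome_length
        out["size_bin_edges"] = list(self.size_bin_edges)
        if self.mean_cnvs_per_animal is not None:
            out["mean_cnvs_per_animal"] = self.mean_cnvs_per_animal
        return out


def merge_calls(calls: list[CNVCall]) -> list[CNVR]:
    """Merge overlapping calls into CNVRs, separately per direction.

    Merging uses >= 1 bp overlap (bookended adjacency does not merge), is
    idempotent and independent of input order; the result is sorted by
    (chrom, start).
    """
    regions: list[CNVR] = []
    for cnv_type in ("loss", "gain"):
        per_chrom: dict[str, list[CNVCall]] = {}
        for call in calls:
            if call.state == cnv_type:
                per_chrom.setdefault(call.chrom, []).append(call)
        for chrom, group in per_chrom.items():
            group.sort(key=lambda c: (c.start, c.end))
            current = [group[0]]
            cur_end = group[0].end
            for call in group[1:]:
                if call.start < cur_end:  # strict overlap only
                    current.append(call)
                    cur_end = max(cur_end, call.end)
                else:
                    regions.append(_build_region(chrom, cnv_type, current))
                    current = [call]
                    cur_end = call.end
            regions.append(_build_region(chrom, cnv_type, current))
    regions.sort(key=lambda r: (r.chrom, r.start, r.type))
    return regions


def _build_region(chrom: str, cnv_type: str, group: list[CNVCall]) -> CNVR:
    return CNVR(
        chrom=chrom,
        start=min(c.start for c in group),
        end=max(c.end for c in group),
        type=cnv_type,
        calls=tuple(group),
    )


def merge_regions(regions: list[CNVR]) -> list[CNVR]:
    """Re-merge a CNVR list (used for idempotence checks and BED input)."""
    calls = []
    for region in regions:
        if region.calls:
            calls.extend(region.calls)
        else:
            calls.append(
                CNVCall(
                    animal="?",
                    chrom=region.chrom,
                    start=region.start,
                    end=region.end,
                    state=region.type,
                    supporting_pairs=(frozenset({"?"}), frozenset({"??"})),
                )
            )
    return merge_calls(calls)


def _summarize_sizes(
    sizes: np.ndarray, genome_length: int, edges: tuple[int, ...]
) -> ClassSummary:
    if len(sizes) == 0:
        return ClassSummary(histogram=[0] * (len(edges) + 1))
    content = int(sizes.sum())
    hist = np.histogram(sizes, bins=[0, *edges, np.inf])[0]
    return ClassSummary(
        count=len(sizes),
        mean_size=int(round(content / len(sizes))),
        median_size=int(round(float(np.median(sizes)))),
        min_size=int(sizes.min()),
        max_size=int(sizes.max()),
        content=content,
        percent_of_genome=round(100.0 * content / genome_length, 3),
        histogram=[int(h) for h in hist],
    )


def summarize(
    cnvrs: list[CNVR],
    genome_length: int,
    size_bin_edges: tuple[int, ...] = DEFAULT_SIZE_BIN_EDGES,
) -> CnvrSummary:
    """Catalogue summary per direction and overall.

    Mean size is content/count rounded to the nearest bp; percent of genome
    is rounded to 3 decimals.
    """
    if genome_length <= 0:
        raise InvalidArgumentError("genome length must be positive")
    sizes = {
        "loss": np.array([r.size for r in cnvrs if r.type == "loss"], dtype=np.int64),
        "gain": np.array([r.size for r in cnvrs if r.type == "gain"], dtype=np.int64),
    }
    sizes["all"] = np.concatenate([sizes["loss"], sizes["gain"]])
    per_animal = None
    counts: dict[str, int] = {}
    for region in cnvrs:
        for call in region.calls:
            counts[call.animal] = counts.get(call.animal, 0) + 1
    if counts:
        per_animal = round(sum(counts.values()) / len(counts), 2)
    return CnvrSummary(
        loss=_summarize_sizes(sizes["loss"], genome_length, size_bin_edges),
        gain=_summarize_sizes(sizes["gain"], genome_length, size_bin_edges),
        all=_summarize_sizes(sizes["all"], genome_length, size_bin_edges),
        genome_length=genome_length,
        size_bin_edges=tuple(size_bin_edges),
        mean_cnvs_per_animal=per_animal,
    )
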