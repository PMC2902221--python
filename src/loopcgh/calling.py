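"""Dye-swap concordance and loop-design CNV attribution.

A candidate segment only becomes evidence when its dye-swap mate shows the
same locus with the opposite raw sign (true copy-number signal flips with
dye orientation; dye artifacts do not). Concordant pairs from two
hybridizations sharing exactly one animal are then attributed to that
animal: relatively amplified in both -> gain, relatively depleted -> loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .exceptions import DesignConsistencyError, InvalidArgumentError
from .segmentation import CandidateCall
from .synthetic import Hybridization, LoopDesign

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 0.5


@dataclass(frozen=True)
class PairCall:
    """Aberration confirmed by both arrays of one dye-swap pair."""

    animals: frozenset[str]
    chrom: str
    start: int
    end: int
    up_animal: str  # the animal with relatively more copies
    arrays: tuple[str, str]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidArgumentError("pair call must have end > start")
        if self.up_animal not in self.animals:
            raise InvalidArgumentError("up_animal must belong to the pair")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CNVCall:
    """Per-animal gain/loss call supported by >= 2 dye-swap pairs."""

    animal: str
    chrom: str
    start: int
    end: int
    state: str  # "gain" | "loss"
    supporting_pairs: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if self.state not in ("gain", "loss"):
            raise InvalidArgumentError(f"invalid state {self.state!r}")
        if len(self.supporting_pairs) < 2:
            raise InvalidArgumentError("a CNV call needs >= 2 supporting pairs")

    @property
    def size(self) -> int:
        return self.end - self.start


def reciprocal_overlap(
    a_start: int, a_end: int, b_start: int, b_end: int
) -> float:
    """Overlap as a fraction of the *longer* interval (0 when disjoint)."""
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return inter / max(a_end - a_start, b_end - b_start)


def pair_concordance(
    calls_a: list[CandidateCall],
    calls_b: list[CandidateCall],
    hyb_a: Hybridization,
    hyb_b: Hybridization,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> list[PairCall]:
    """Keep aberrations seen on both dye-swap mates with flipped signs.

    The emitted interval is the intersection of the mates' segments, and
    the direction records which animal of the pair is relatively amplified.
    """
    if hyb_a.cy3_animal != hyb_b.cy5_animal or hyb_a.cy5_animal != hyb_b.cy3_animal:
        raise DesignConsistencyError(
            f"{hyb_a.array_id} and {hyb_b.array_id} are not dye-swap mates"
        )
    if not 0 < min_overlap <= 1:
        raise InvalidArgumentError("min_overlap must be in (0, 1]")
    out: list[PairCall] = []
    # segmentation may fragment one aberration into several same-sign
    # segments on one mate; concordance therefore compares merged same-sign
    # segment groups, not single segments
    for sign in (1, -1):
        side_a = _merge_same_sign(calls_a, sign)
        side_b = _merge_same_sign(calls_b, -sign)
        for chrom in set(side_a) & set(side_b):
            for ga_start, ga_end, ga_arrays in side_a[chrom]:
                for gb_start, gb_end, gb_arrays in side_b[chrom]:
                    inter = min(ga_end, gb_end) - max(ga_start, gb_start)
                    if inter <= 0:
                        continue
                    if inter < min_overlap * max(
                        ga_end - ga_start, gb_end - gb_start
                    ):
                        continue
                    up = hyb_a.cy3_animal if sign > 0 else hyb_a.cy5_animal
                    out.append(
                        PairCall(
                            animals=hyb_a.pair,
                            chrom=chrom,
                            start=max(ga_start, gb_start),
                            end=min(ga_end, gb_end),
                            up_animal=up,
                            arrays=(
                                sorted(ga_arrays)[0],
                                sorted(gb_arrays)[0],
                            ),
                        )
                    )
    out.sort(key=lambda p: (p.chrom, p.start, p.end))
    return out


def _merge_same_sign(
    calls: list[CandidateCall], sign: int, max_gap_factor: float = 0.5
) -> dict[str, list[tuple[int, int, set[str]]]]:
    """Per-chromosome merged intervals of same-sign candidate segments.

    Segments separated by less than ``max_gap_factor`` of the combined span
    are treated as fragments of one aberration.
    """
    per_chrom: dict[str, list[CandidateCall]] = {}
    for c in calls:
        if c.sign == sign:
            per_chrom.setdefault(c.chrom, []).append(c)
    merged: dict[str, list[tuple[int, int, set[str]]]] = {}
    for chrom, group in per_chrom.items():
        group.sort(key=lambda c: (c.start, c.end))
        runs: list[tuple[int, int, set[str]]] = []
        cur_s, cur_e, arrays = group[0].start, group[0].end, {group[0].array_id}
        for c in group[1:]:
            gap = c.start - cur_e
            span = max(c.end, cur_e) - cur_s
            if gap <= max_gap_factor * span * 0.5:
                cur_e = max(cur_e, c.end)
                arrays.add(c.array_id)
            else:
                runs.append((cur_s, cur_e, arrays))
                cur_s, cur_e, arrays = c.start, c.end, {c.array_id}
        runs.append((cur_s, cur_e, arrays))
        merged[chrom] = runs
    return merged


def _cluster_by_overlap(
    calls: list[PairCall], min_overlap: float
) -> list[list[PairCall]]:
    """Single-linkage clusters of pair calls with reciprocal overlap."""
    clusters: list[list[PairCall]] = []
    parent = list(range(len(calls)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            if calls[i].chrom != calls[j].chrom:
                continue
            ro = reciprocal_overlap(
                calls[i].start, calls[i].end, calls[j].start, calls[j].end
            )
            if ro >= min_overlap:
                parent[find(i)] = find(j)
    groups: dict[int, list[PairCall]] = {}
    for i, call in enumerate(calls):
        groups.setdefault(find(i), []).append(call)
    return list(groups.values())


def attribute_to_animal(
    pair_calls: list[PairCall],
    design: LoopDesign,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> list[CNVCall]:
    """Attribute clustered pair calls to the single animal they share.

    A cluster supported by >= 2 distinct pairs that have exactly one animal
    in common becomes a CNV call for that animal, gain if it is relatively
    up in every supporting pair, loss if relatively down. Clusters with
    contradictory directions are dropped with a warning.
    """
    known = design.animals
    for call in pair_calls:
        if not call.animals <= known:
            raise DesignConsistencyError(
                f"pair call references animals outside the design: {set(call.animals)}"
            )
    out: list[CNVCall] = []
    for cluster in _cluster_by_overlap(pair_calls, min_overlap):
        pairs = {c.animals for c in cluster}
        if len(pairs) < 2:
            continue
        common = frozenset.intersection(*pairs)
        if len(common) != 1:
            continue
        (animal,) = common
        directions = {
            ("up" if c.up_animal == animal else "down") for c in cluster
        }
        if len(directions) != 1:
            logger.warning(
                "conflicting directions for %s at %s:%d-%d; locus dropped",
                animal,
                cluster[0].chrom,
                min(c.start for c in cluster),
                max(c.end for c in cluster),
            )
            continue
        state = "gain" if directions.pop() == "up" else "loss"
        out.append(
            CNVCall(
                animal=animal,
                chrom=cluster[0].chrom,
                start=min(c.start for c in cluster),
                end=max(c.end for c in cluster),
                state=state,
                supporting_pairs=tuple(sorted(pairs, key=sorted)),
            )
        )
    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.animal))
    return out


def call_cnvs(
    candidate_calls: dict[str, list[CandidateCall]],
    design: LoopDesign,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
) -> tuple[list[PairCall], list[CNVCall]]:
    """Run concordance over every dye-swap pair, then loop attribution."""
    pair_calls: list[PairCall] = []
    for hyb_a, hyb_b in design.dye_swap_pairs():
        pair_calls.extend(
            pair_concordance(
                candidate_calls.get(hyb_a.array_id, []),
                candidate_calls.get(hyb_b.array_id, []),
                hyb_a,
                hyb_b,
                min_overlap=min_overlap,
            )
        )
    return pair_calls, attribute_to_animal(pair_calls, design, min_overlap)
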