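"""False-positive-rate estimation from control hybridizations.

Two estimators:

* sex-mismatch — on male-vs-female arrays every chrX probe has a known
  expected dosage direction; aberrant length is the chrX footprint called
  in the *wrong* direction, divided by chrX length times the number of
  arrays;
* self-self — an animal hybridized against itself has no true signal, so
  any called footprint is false, reported at single-array stringency and at
  dye-swap-concordant stringency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import segmentation
from .calling import pair_concordance
from .exceptions import DesignConsistencyError, InvalidArgumentError
from .segmentation import CandidateCall
from .synthetic import Hybridization, ProbeRatioTable


def truncate_percent(rate: float, decimals: int = 2) -> float:
    """Percent truncated (not rounded) to ``decimals`` decimal places.

    Truncation matches the reporting convention of the worked example this
    module reproduces (25,694,212 / (88,516,663 * 8) prints as 3.62%).
    """
    scale = 10**decimals
    return math.floor(rate * 100.0 * scale) / scale


@dataclass(frozen=True)
class FprReport:
    method: str  # "sex_mismatch" | "self_self"
    aberrant_bp: int
    denominator_bp: int
    n_arrays: int
    stringency: str = "single_array"

    def __post_init__(self) -> None:
        if self.n_arrays < 1:
            raise InvalidArgumentError("n_arrays must be >= 1")
        if self.denominator_bp <= 0:
            raise InvalidArgumentError("denominator length must be positive")

    @property
    def rate(self) -> float:
        return self.aberrant_bp / (self.denominator_bp * self.n_arrays)

    @property
    def percent(self) -> float:
        decimals = 2 if self.method == "sex_mismatch" else 4
        return truncate_percent(self.rate, decimals)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "stringency": self.stringency,
            "aberrant_bp": self.aberrant_bp,
            "denominator_bp": self.denominator_bp,
            "n_arrays": self.n_arrays,
            "rate": self.rate,
            "percent": self.percent,
        }


def sex_mismatch_fpr_from_lengths(
    aberrant_bp: int, chrx_length: int, n_arrays: int
) -> FprReport:
    """The worked-example arithmetic on pre-measured lengths."""
    if n_arrays < 1:
        raise InvalidArgumentError("n_arrays must be >= 1")
    return FprReport("sex_mismatch", int(aberrant_bp), int(chrx_length), n_arrays)


def _wrong_direction_bp_segments(
    calls: list[CandidateCall], expected_sign: int, chrom: str
) -> int:
    return sum(
        c.size for c in calls if c.chrom == chrom and c.sign == -expected_sign
    )


def _wrong_direction_bp_probes(
    table: ProbeRatioTable,
    expected_sign: int,
    chrom: str,
    ratio_threshold: float,
) -> int:
    frame = table.frame[table.frame["chrom"] == chrom]
    ratios = frame["ratio"].to_numpy()
    wrong = (ratios * -expected_sign) >= ratio_threshold
    return int((frame["end"] - frame["start"]).to_numpy()[wrong].sum())


def sex_mismatch_fpr(
    per_array: list[list[CandidateCall]] | list[ProbeRatioTable],
    chrx_length: int,
    expected_signs: list[int],
    chrom: str = "chrX",
    level: str = "segment",
    ratio_threshold: float = segmentation.DEFAULT_RATIO_THRESHOLD,
) -> FprReport:
    """Measure wrong-direction chrX footprint over sex-mismatched arrays.

    ``expected_signs`` gives, per array, the sign chrX dosage should take
    (-1 when the male is the test/Cy3 animal). ``level`` chooses whether
    the aberrant length is summed over filtered candidate segments or over
    individual probes beyond the ratio threshold.
    """
    if len(per_array) == 0:
        raise InvalidArgumentError("need at least one array")
    if len(expected_signs) != len(per_array):
        raise InvalidArgumentError("expected_signs must match per_array")
    if any(s not in (-1, 1) for s in expected_signs):
        raise InvalidArgumentError("expected_signs entries must be -1 or +1")
    aberrant = 0
    for item, sign in zip(per_array, expected_signs):
        if level == "segment":
            aberrant += _wrong_direction_bp_segments(item, sign, chrom)
        elif level == "probe":
            aberrant += _wrong_direction_bp_probes(item, sign, chrom, ratio_threshold)
        else:
            raise InvalidArgumentError("level must be 'segment' or 'probe'")
    return FprReport("sex_mismatch", aberrant, int(chrx_length), len(per_array))


def _called_bp(calls: list[CandidateCall]) -> int:
    """Footprint of candidate calls with per-chromosome overlap collapsing."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in calls:
        per_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    total = 0
    for intervals in per_chrom.values():
        intervals.sort()
        cur_s, cur_e = intervals[0]
        for s, e in intervals[1:]:
            if s < cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total


def self_self_fpr(
    table_a: ProbeRatioTable,
    table_b: ProbeRatioTable,
    hyb_a: Hybridization,
    hyb_b: Hybridization,
    genome_length: int,
    penalty: float | None = None,
    ratio_threshold: float = segmentation.DEFAULT_RATIO_THRESHOLD,
    min_probes: int = segmentation.DEFAULT_MIN_PROBES,
    min_overlap: float = 0.5,
) -> dict[str, FprReport]:
    """Run a self-self dye-swap pair through segmentation and concordance.

    Returns reports at both stringencies: ``single_array`` (footprint called
    on either array, per array) and ``concordant`` (footprint surviving
    dye-swap concordance).
    """
    if len({hyb_a.cy3_animal, hyb_a.cy5_animal, hyb_b.cy3_animal, hyb_b.cy5_animal}) != 1:
        raise DesignConsistencyError("self-self pair must involve a single animal")
    calls = {}
    for table, hyb in ((table_a, hyb_a), (table_b, hyb_b)):
        segments = segmentation.segment_table(table, penalty=penalty)
        calls[hyb.array_id] = segmentation.filter_segments(
            segments, ratio_threshold=ratio_threshold, min_probes=min_probes
        )
    single_bp = sum(_called_bp(v) for v in calls.values())
    pair_calls = pair_concordance(
        calls[hyb_a.array_id], calls[hyb_b.array_id], hyb_a, hyb_b, min_overlap
    )
    concordant_bp = _called_bp(
        [
            CandidateCall(
                array_id="pair",
                chrom=p.chrom,
                start_index=0,
                end_index=0,
                start=p.start,
                end=p.end,
                mean=0.0,
                n_probes=1,
            )
            for p in pair_calls
        ]
    ) if pair_calls else 0
    return {
        "single_array": FprReport(
            "self_self", single_bp, int(genome_length), 2, "single_array"
        ),
        "concordant": FprReport(
            "self_self", concordant_bp, int(genome_length), 1, "concordant"
        ),
    }
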