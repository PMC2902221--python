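"""Permutation tests of CNVR association with genomic feature sets.

Each permutation re-places every CNVR independently, uniformly at random on
its own chromosome (length preserved, assembly gaps avoided when the genome
model carries them) and recomputes the overlap statistic, giving an
empirical null for enrichment or depletion. GC content of the CNVR
footprint can be compared against the genome-wide value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnvr import CNVR
from .exceptions import (
    DataError,
    InvalidArgumentError,
    PlacementError,
)
from .synthetic import GenomeModel


@dataclass
class FeatureSet:
    """A named collection of genomic intervals with optional attributes."""

    name: str
    frame: pd.DataFrame  # columns: chrom, start, end [, identity, evidence]

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required <= set(self.frame.columns):
            raise InvalidArgumentError(
                f"feature set {self.name!r} needs columns {sorted(required)}"
            )
        if len(self.frame) and not (self.frame["start"] < self.frame["end"]).all():
            raise InvalidArgumentError(
                f"feature set {self.name!r} has intervals with start >= end"
            )

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class PermutationResult:
    feature_set: str
    observed: int
    null: np.ndarray
    n_perm: int
    p_value: float
    mode: str  # "enrichment" | "depletion"
    statistic: str = "count"

    def as_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "observed": int(self.observed),
            "null_mean": float(self.null.mean()),
            "null_sd": float(self.null.std()),
            "n_perm": self.n_perm,
            "p_value": self.p_value,
            "mode": self.mode,
            "statistic": self.statistic,
        }


def filter_sd_features(features: FeatureSet, identity_cutoff: float = 94.0) -> FeatureSet:
    """Drop high-identity duplications supported by sequence comparison only.

    Intervals with identity above the cutoff are kept only when confirmed
    by read-depth evidence (evidence 'WSSD' or 'both').
    """
    frame = features.frame
    if "identity" not in frame.columns or "evidence" not in frame.columns:
        return features
    confirmed = frame["evidence"].isin(["WSSD", "both"])
    keep = (frame["identity"] <= identity_cutoff) | confirmed
    return FeatureSet(features.name, frame[keep].reset_index(drop=True))


def _merged_intervals(frame: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome sorted, merged (starts, ends) arrays."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in frame.groupby("chrom", sort=False):
        ivals = sub[["start", "end"]].sort_values("start").to_numpy()
        starts, ends = [], []
        cur_s, cur_e = int(ivals[0, 0]), int(ivals[0, 1])
        for s, e in ivals[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, int(e))
            else:
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = int(s), int(e)
        starts.append(cur_s)
        ends.append(cur_e)
        out[str(chrom)] = (np.asarray(starts), np.asarray(ends))
    return out


def _overlaps_any(
    starts: np.ndarray,
    ends: np.ndarray,
    f_starts: np.ndarray,
    f_ends: np.ndarray,
) -> np.ndarray:
    """Boolean per query interval: overlaps >= 1 bp of the merged features."""
    idx = np.searchsorted(f_ends, starts, side="right")
    ok = idx < len(f_starts)
    hit = np.zeros(len(starts), dtype=bool)
    hit[ok] = f_starts[idx[ok]] < ends[ok]
    return hit


def overlap_count(
    cnvrs: list[CNVR], features: FeatureSet, chroms: set[str] | None = None
) -> tuple[int, float]:
    """Number and fraction of CNVRs overlapping >= 1 feature interval."""
    if chroms is not None:
        unknown = set(features.frame["chrom"].astype(str)) - chroms
        if unknown:
            raise DataError(f"features on unknown chromosomes: {sorted(unknown)}")
    if not cnvrs:
        return 0, 0.0
    merged = _merged_intervals(features.frame) if len(features) else {}
    count = 0
    for region in cnvrs:
        if region.chrom not in merged:
            continue
        f_starts, f_ends = merged[region.chrom]
        if _overlaps_any(
            np.array([region.start]), np.array([region.end]), f_starts, f_ends
        )[0]:
            count += 1
    return count, count / len(cnvrs)


def _random_starts(
    rng: np.random.Generator,
    n: int,
    limit: int,
    size: int,
    gaps: list[tuple[int, int]],
    max_rounds: int = 200,
) -> np.ndarray:
    """n random placements of an interval of ``size`` in [0, limit], gap-free."""
    starts = rng.integers(0, limit + 1, n)
    if not gaps:
        return starts
    g_starts = np.array([g[0] for g in gaps])
    g_ends = np.array([g[1] for g in gaps])
    for _ in range(max_rounds):
        bad = _overlaps_any(starts, starts + size, g_starts, g_ends)
        n_bad = int(bad.sum())
        if n_bad == 0:
            return starts
        starts[bad] = rng.integers(0, limit + 1, n_bad)
    raise PlacementError(
        f"could not place an interval of {size} bp clear of gaps"
    )


def permutation_test(
    cnvrs: list[CNVR],
    features: FeatureSet,
    genome: GenomeModel,
    n_perm: int = 10_000,
    seed: int | None = None,
    mode: str = "enrichment",
    statistic: str = "count",
) -> PermutationResult:
    """Empirical overlap test by random re-placement of each CNVR.

    The p-value uses the +1 correction: (1 + #{null >= observed}) / (1 +
    n_perm) for enrichment, mirrored for depletion.
    """
    if mode not in ("enrichment", "depletion"):
        raise InvalidArgumentError("mode must be 'enrichment' or 'depletion'")
    if statistic not in ("count", "bp"):
        raise InvalidArgumentError("statistic must be 'count' or 'bp'")
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    merged = _merged_intervals(features.frame) if len(features) else {}

    def measure(starts: np.ndarray, ends: np.ndarray, chrom: str) -> np.ndarray:
        if chrom not in merged:
            return np.zeros(len(starts))
        f_starts, f_ends = merged[chrom]
        if statistic == "count":
            return _overlaps_any(starts, ends, f_starts, f_ends).astype(float)
        bp = np.zeros(len(starts))
        for fs, fe in zip(f_starts, f_ends):
            bp += np.clip(
                np.minimum(ends, fe) - np.maximum(starts, fs), 0, None
            )
        return bp

    observed = 0.0
    null = np.zeros(n_perm)
    for region in cnvrs:
        length = genome.lengths.get(region.chrom)
        if length is None:
            raise DataError(f"CNVR on unknown chromosome {region.chrom}")
        limit = length - region.size
        if limit < 0:
            raise PlacementError(
                f"CNVR {region.chrom}:{region.start}-{region.end} exceeds "
                "its chromosome"
            )
        observed += float(
            measure(
                np.array([region.start]), np.array([region.end]), region.chrom
            )[0]
        )
        starts = _random_starts(
            rng, n_perm, limit, region.size, genome.sorted_gaps(region.chrom)
        )
        null += measure(starts, starts + region.size, region.chrom)

    if mode == "enrichment":
        exceed = int((null >= observed).sum())
    else:
        exceed = int((null <= observed).sum())
    p = (1 + exceed) / (1 + n_perm)
    return PermutationResult(
        feature_set=features.name,
        observed=int(observed) if statistic == "count" else observed,
        null=null,
        n_perm=n_perm,
        p_value=p,
        mode=mode,
        statistic=statistic,
    )


def _gc_counts(seq: str) -> tuple[int, int]:
    """(gc, unambiguous) base counts; non-ACGT bases are excluded."""
    up = seq.upper()
    gc = up.count("G") + up.count("C")
    at = up.count("A") + up.count("T")
    return gc, gc + at


def gc_compare(
    cnvrs: list[CNVR],
    sequences,
    genome: GenomeModel | None = None,
    allow_empty: bool = False,
) -> tuple[float | None, float]:
    """GC fraction inside the CNVR footprint vs genome-wide.

    ``sequences`` is a mapping chrom -> sequence (a dict of strings or a
    ``pyfaidx.Fasta``). The CNVR footprint is merged first so shared bases
    are counted once; ambiguous bases are excluded from both numerator and
    denominator. Genome-wide GC skips assembly gaps when ``genome`` given
    (gap Ns are excluded as ambiguous regardless).
    """
    names = (
        list(sequences.keys())
        if isinstance(sequences, dict)
        else [str(k) for k in sequences.keys()]
    )
    gc_all = n_all = 0
    for name in names:
        seq = str(sequences[name])
        if genome is not None:
            pieces, pos = [], 0
            for s, e in genome.sorted_gaps(name):
                pieces.append(seq[pos:s])
                pos = e
            pieces.append(seq[pos:])
            seq = "".join(pieces)
        gc, n = _gc_counts(seq)
        gc_all += gc
        n_all += n
    genome_gc = gc_all / n_all if n_all else 0.0

    if not cnvrs:
        if allow_empty:
            return None, genome_gc
        raise DataError("empty CNVR set; pass allow_empty=True for genome GC only")
    footprint = _merged_intervals(
        pd.DataFrame(
            [(r.chrom, r.start, r.end) for r in cnvrs],
            columns=["chrom", "start", "end"],
        )
    )
    gc_in = n_in = 0
    for chrom, (starts, ends) in footprint.items():
        if chrom not in names:
            raise DataError(f"no sequence for chromosome {chrom}")
        seq = str(sequences[chrom])
        for s, e in zip(starts, ends):
            gc, n = _gc_counts(seq[s:e])
            gc_in += gc
            n_in += n
    if n_in == 0:
        raise DataError("CNVR footprint contains no unambiguous bases")
    return gc_in / n_in, genome_gc
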