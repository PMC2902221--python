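"""Synthetic two-color array-CGH experiments.

Generates every ingredient of a dye-swap loop experiment — genome model,
tiled probe map, animal panel, planted copy-number variants, hybridization
design and per-array two-channel intensities — so that the downstream
pipeline can be exercised and validated against a known truth set.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DesignConsistencyError,
    InvalidArgumentError,
    PlacementError,
)

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "x", "y", "design_id"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names, lengths and (optionally) assembly-gap intervals."""

    names: tuple[str, ...]
    lengths: dict[str, int]
    gaps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.names:
            length = self.lengths.get(name)
            if length is None or length <= 0:
                raise InvalidArgumentError(
                    f"chromosome {name!r} must have a positive length, got {length}"
                )
        for chrom, intervals in self.gaps.items():
            if chrom not in self.lengths:
                raise InvalidArgumentError(f"gap on unknown chromosome {chrom!r}")
            prev_end = 0
            for start, end in sorted(intervals):
                if start < 0 or end > self.lengths[chrom] or start >= end:
                    raise InvalidArgumentError(
                        f"gap ({chrom}, {start}, {end}) outside chromosome bounds"
                    )
                if start < prev_end:
                    raise InvalidArgumentError(
                        f"overlapping gaps on {chrom} near position {start}"
                    )
                prev_end = end

    @property
    def total_length(self) -> int:
        return sum(self.lengths[name] for name in self.names)

    def gap_length(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return sum(e - s for s, e in self.gaps.get(chrom, []))
        return sum(self.gap_length(name) for name in self.names)

    def sorted_gaps(self, chrom: str) -> list[tuple[int, int]]:
        return sorted(self.gaps.get(chrom, []))


@dataclass(frozen=True)
class AnimalPanel:
    """The set of sampled animals with their sexes."""

    animals: tuple[str, ...]
    sex: dict[str, str]
    breed: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.animals)) != len(self.animals):
            raise InvalidArgumentError("animal ids must be unique")
        for animal in self.animals:
            if self.sex.get(animal) not in ("male", "female"):
                raise InvalidArgumentError(
                    f"animal {animal!r} must be 'male' or 'female', "
                    f"got {self.sex.get(animal)!r}"
                )

    def __len__(self) -> int:
        return len(self.animals)


@dataclass(frozen=True)
class PlantedCNV:
    """Ground-truth copy-number variant planted in one animal.

    ``copies`` is the absolute copy number (diploid background is 2):
    1 encodes a heterozygous loss, 3 a single-copy gain.
    """

    animal: str
    chrom: str
    start: int
    end: int
    copies: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidArgumentError("planted CNV must have end > start")
        if self.copies < 0 or self.copies == 2:
            raise InvalidArgumentError("copies must be a non-diploid state >= 0")

    @property
    def state(self) -> str:
        return "loss" if self.copies < 2 else "gain"

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Hybridization:
    """One array: the animal labeled with Cy3 vs the animal labeled with Cy5."""

    array_id: str
    cy3_animal: str
    cy5_animal: str
    design_id: int = 1

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.cy3_animal, self.cy5_animal))


@dataclass(frozen=True)
class LoopDesign:
    """Dye-swap loop design: hybridizations plus the swap-mate pairing."""

    hybridizations: tuple[Hybridization, ...]
    swap_mate: dict[str, str]

    def __post_init__(self) -> None:
        by_id = {h.array_id: h for h in self.hybridizations}
        if len(by_id) != len(self.hybridizations):
            raise DesignConsistencyError("array ids must be unique")
        for array_id, mate_id in self.swap_mate.items():
            if array_id not in by_id or mate_id not in by_id:
                raise DesignConsistencyError(f"swap mate of {array_id} missing")
            a, b = by_id[array_id], by_id[mate_id]
            if self.swap_mate.get(mate_id) != array_id:
                raise DesignConsistencyError("swap-mate pairing is not symmetric")
            if a.cy3_animal != b.cy5_animal or a.cy5_animal != b.cy3_animal:
                raise DesignConsistencyError(
                    f"arrays {array_id}/{mate_id} are not dye-swap mates"
                )

    def __getitem__(self, array_id: str) -> Hybridization:
        for h in self.hybridizations:
            if h.array_id == array_id:
                return h
        raise KeyError(array_id)

    @property
    def animals(self) -> set[str]:
        out: set[str] = set()
        for h in self.hybridizations:
            out.update((h.cy3_animal, h.cy5_animal))
        return out

    def dye_swap_pairs(self) -> list[tuple[Hybridization, Hybridization]]:
        """Each dye-swap pair once, as (array, mate) in array-id order."""
        pairs = []
        for array_id, mate_id in self.swap_mate.items():
            if array_id < mate_id:
                pairs.append((self[array_id], self[mate_id]))
        return pairs


@dataclass
class ProbeRatioTable:
    """Per-array probe-level intensities and log2(Cy3/Cy5) ratios.

    ``frame`` columns: probe_id, chrom, start, end, x, y, ch1 (Cy3), ch2
    (Cy5), ratio. Rows are sorted by (chrom, start).
    """

    frame: pd.DataFrame
    array_id: str
    cy3_animal: str
    cy5_animal: str

    def __len__(self) -> int:
        return len(self.frame)

    def copy(self) -> "ProbeRatioTable":
        return ProbeRatioTable(
            self.frame.copy(), self.array_id, self.cy3_animal, self.cy5_animal
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_genome(
    n_chromosomes: int,
    lengths: int | list[int],
    gap_fraction: float = 0.0,
    seed: int = 0,
    x_chromosome: bool = False,
    mean_gap_size: int = 5_000,
) -> GenomeModel:
    """Build a genome model with randomly placed non-overlapping gaps.

    ``gap_fraction`` of the total length (within rounding of individual gap
    sizes) is covered by gaps. With ``x_chromosome`` the last chromosome is
    named ``chrX`` and participates in sex-dosage simulation.
    """
    if n_chromosomes < 1:
        raise InvalidArgumentError("need at least one chromosome")
    if not 0 <= gap_fraction < 0.5:
        raise InvalidArgumentError("gap_fraction must be in [0, 0.5)")
    if isinstance(lengths, int):
        lengths = [lengths] * n_chromosomes
    if len(lengths) != n_chromosomes:
        raise InvalidArgumentError("lengths must match n_chromosomes")
    names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    if x_chromosome:
        names[-1] = "chrX"
    length_map = dict(zip(names, lengths))
    model = GenomeModel(tuple(names), length_map)  # validates lengths

    rng = np.random.default_rng(seed)
    gaps: dict[str, list[tuple[int, int]]] = {}
    if gap_fraction > 0:
        for name in names:
            length = length_map[name]
            target = int(round(gap_fraction * length))
            if target == 0:
                continue
            n_gaps = max(1, int(round(target / mean_gap_size)))
            # split the gap budget and the remaining sequence at random
            gap_sizes = rng.multinomial(target, np.full(n_gaps, 1.0 / n_gaps))
            gap_sizes = np.maximum(gap_sizes, 1)
            free = length - int(gap_sizes.sum())
            spacing = rng.dirichlet(np.ones(n_gaps + 1)) * free
            starts = np.floor(np.cumsum(spacing[:-1]) + np.cumsum(
                np.concatenate([[0], gap_sizes[:-1]])
            )).astype(int)
            gaps[name] = [
                (int(s), int(s + g)) for s, g in zip(starts, gap_sizes)
            ]
    return GenomeModel(tuple(names), length_map, gaps)


def make_panel(
    n_animals: int,
    male_fraction: float = 0.5,
    seed: int = 0,
    breeds: tuple[str, ...] = ("breedA", "breedB"),
) -> AnimalPanel:
    """Random animal panel with ids ``a1..aN``."""
    if n_animals < 1:
        raise InvalidArgumentError("need at least one animal")
    rng = np.random.default_rng(seed)
    animals = tuple(f"a{i + 1}" for i in range(n_animals))
    sexes = {
        a: ("male" if rng.random() < male_fraction else "female") for a in animals
    }
    breed = {a: breeds[i % len(breeds)] for i, a in enumerate(animals)}
    return AnimalPanel(animals, sexes, breed)


def tile_probes(
    genome: GenomeModel,
    median_spacing: int = 301,
    probe_length: int = 60,
    jitter: float = 0.0,
    seed: int = 0,
    n_designs: int = 1,
) -> pd.DataFrame:
    """Tile probes along each chromosome, skipping assembly gaps.

    Start-to-start steps are ``median_spacing`` scaled by a symmetric
    multiplicative jitter, so the empirical median spacing stays on target.
    Returns a :data:`PROBE_COLUMNS` data frame sorted by (chrom, start).
    """
    if median_spacing <= probe_length:
        raise InvalidArgumentError("median_spacing must exceed probe_length")
    if not 0 <= jitter < 1:
        raise InvalidArgumentError("jitter must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for ci, chrom in enumerate(genome.names):
        length = genome.lengths[chrom]
        gaps = genome.sorted_gaps(chrom)
        design_id = (ci % n_designs) + 1
        pos = 0
        gi = 0
        while pos + probe_length <= length:
            # hop over any gap the probe would touch
            while gi < len(gaps) and gaps[gi][1] <= pos:
                gi += 1
            if gi < len(gaps) and pos + probe_length > gaps[gi][0]:
                pos = gaps[gi][1]
                gi += 1
                continue
            rows.append((chrom, pos, pos + probe_length, design_id))
            step = median_spacing
            if jitter > 0:
                step = max(
                    probe_length + 1,
                    int(round(median_spacing * (1.0 + jitter * (2 * rng.random() - 1)))),
                )
            pos += step
    n = len(rows)
    nx = max(1, int(math.ceil(math.sqrt(n))))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "design_id"])
    frame.insert(0, "probe_id", [f"P{i:07d}" for i in range(n)])
    frame["x"] = np.arange(n) % nx
    frame["y"] = np.arange(n) // nx
    return frame[PROBE_COLUMNS]


def theoretical_resolution(
    median_spacing: int, median_probe_length: int, min_probes: int
) -> int:
    """Smallest detectable event: spacing*(k-1) + probe_length*k for k probes."""
    if median_spacing <= 0 or median_probe_length <= 0 or min_probes <= 0:
        raise InvalidArgumentError("all inputs must be positive")
    return median_spacing * (min_probes - 1) + median_probe_length * min_probes


def plant_cnvs(
    panel: AnimalPanel,
    genome: GenomeModel,
    n_per_animal: int,
    size_range: tuple[int, int] = (2_000, 50_000),
    loss_fraction: float = 0.664,
    seed: int = 0,
    disjoint: bool = True,
    exclude_chroms: tuple[str, ...] = ("chrX",),
    max_tries: int = 1_000,
) -> list[PlantedCNV]:
    """Plant per-animal CNVs uniformly at random, avoiding assembly gaps.

    Sizes are log-uniform over ``size_range``. With ``disjoint`` (default)
    planted intervals never overlap across animals, avoiding the loop
    design's shared-CNV blind spot.
    """
    lo, hi = size_range
    if lo < 1_000:
        raise InvalidArgumentError("CNVs are >= 1 kb by definition")
    if hi < lo:
        raise InvalidArgumentError("size_range must be (min, max) with max >= min")
    if not 0 <= loss_fraction <= 1:
        raise InvalidArgumentError("loss_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = [c for c in genome.names if c not in exclude_chroms]
    if not chroms:
        raise InvalidArgumentError("no eligible chromosomes to plant CNVs on")
    weights = np.array([genome.lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    placed: list[PlantedCNV] = []
    for animal in panel.animals:
        for _ in range(n_per_animal):
            size = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
            copies = 1 if rng.random() < loss_fraction else 3
            for _try in range(max_tries):
                chrom = str(rng.choice(chroms, p=weights))
                limit = genome.lengths[chrom] - size
                if limit <= 0:
                    continue
                start = int(rng.integers(0, limit))
                end = start + size
                if any(s < end and start < e for s, e in genome.sorted_gaps(chrom)):
                    continue
                if disjoint and any(
                    c.chrom == chrom and c.start < end and start < c.end
                    for c in placed
                ):
                    continue
                placed.append(PlantedCNV(animal, chrom, start, end, copies))
                break
            else:
                raise PlacementError(
                    f"could not place a {size} bp CNV for {animal} "
                    f"after {max_tries} tries"
                )
    return placed


def make_loop_design(panel: AnimalPanel, n_designs: int = 1) -> LoopDesign:
    """Ring loop design: animal k vs k+1, each pair in both dye orientations."""
    if len(panel) < 3:
        raise InvalidArgumentError("a loop design needs at least 3 animals")
    hybs: list[Hybridization] = []
    swap: dict[str, str] = {}
    for i, animal in enumerate(panel.animals):
        partner = panel.animals[(i + 1) % len(panel)]
        fwd = f"A{i + 1:02d}f"
        rev = f"A{i + 1:02d}r"
        design_id = (i % n_designs) + 1
        hybs.append(Hybridization(fwd, animal, partner, design_id))
        hybs.append(Hybridization(rev, partner, animal, design_id))
        swap[fwd] = rev
        swap[rev] = fwd
    return LoopDesign(tuple(hybs), swap)


def make_self_self_design(animal: str = "a1") -> LoopDesign:
    """A single dye-swap pair of one animal against itself."""
    hybs = (
        Hybridization("S01f", animal, animal),
        Hybridization("S01r", animal, animal),
    )
    return LoopDesign(hybs, {"S01f": "S01r", "S01r": "S01f"})


# ---------------------------------------------------------------------------
# intensity simulation
# ---------------------------------------------------------------------------


def _copy_number(
    animal: str,
    panel: AnimalPanel,
    chrom: np.ndarray,
    mid: np.ndarray,
    truth: list[PlantedCNV],
) -> np.ndarray:
    copies = np.full(len(chrom), 2.0)
    if panel.sex.get(animal) == "male":
        copies[chrom == "chrX"] = 1.0
    for cnv in truth:
        if cnv.animal != animal:
            continue
        hit = (chrom == cnv.chrom) & (mid >= cnv.start) & (mid < cnv.end)
        copies[hit] = cnv.copies
    return copies


def _spatial_field(
    x: np.ndarray, y: np.ndarray, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Mean-centered low-order polynomial surface with max |field| = amplitude."""
    if amplitude == 0:
        return np.zeros(len(x))
    u = 2.0 * (x - x.min()) / max(1, x.max() - x.min()) - 1.0
    v = 2.0 * (y - y.min()) / max(1, y.max() - y.min()) - 1.0
    c = rng.normal(size=5)
    f = c[0] * u + c[1] * v + c[2] * u * v + c[3] * u**2 + c[4] * v**2
    f -= f.mean()
    peak = np.abs(f).max()
    if peak > 0:
        f *= amplitude / peak
    return f


def simulate_hybridization(
    hyb: Hybridization,
    probes: pd.DataFrame,
    truth: list[PlantedCNV],
    panel: AnimalPanel,
    noise_sd: float = 0.1,
    dye_bias: float = 0.0,
    spatial_amplitude: float = 0.0,
    intensity_scale: float = 1_000.0,
    intensity_sigma: float = 1.0,
    seed: int = 0,
) -> ProbeRatioTable:
    """Simulate one array's two-channel intensities.

    The expected log2(Cy3/Cy5) per probe is the copy-ratio term plus dye
    bias plus a smooth spatial field over the grid, with Gaussian noise of
    ``noise_sd`` on top. Channel 2 is drawn log-normal so that quantile
    normalization has realistic intensity structure to work on.
    """
    for animal in (hyb.cy3_animal, hyb.cy5_animal):
        if animal not in panel.animals:
            raise DesignConsistencyError(f"unknown animal {animal!r} in design")
    rng = np.random.default_rng(seed)
    chrom = probes["chrom"].to_numpy()
    mid = ((probes["start"] + probes["end"]) // 2).to_numpy()
    copies3 = _copy_number(hyb.cy3_animal, panel, chrom, mid, truth)
    copies5 = _copy_number(hyb.cy5_animal, panel, chrom, mid, truth)
    with np.errstate(divide="ignore"):
        true_log2 = np.log2(np.maximum(copies3, 0.25) / np.maximum(copies5, 0.25))

    x = probes["x"].to_numpy()
    y = probes["y"].to_numpy()
    spatial = _spatial_field(x, y, spatial_amplitude, rng)
    noise = rng.normal(0.0, noise_sd, len(probes)) if noise_sd > 0 else 0.0

    base = intensity_scale * rng.lognormal(0.0, intensity_sigma, len(probes))
    # each channel scales with its own animal's copy state, so channel
    # distributions stay comparable when aberration content is balanced
    ch2 = base * np.maximum(copies5, 0.25) / 2.0
    ch1 = (
        base
        * np.maximum(copies3, 0.25)
        / 2.0
        * np.power(2.0, dye_bias + spatial + noise)
    )

    frame = probes[["probe_id", "chrom", "start", "end", "x", "y"]].copy()
    frame["ch1"] = ch1
    frame["ch2"] = ch2
    frame["ratio"] = np.log2(ch1 / ch2)
    return ProbeRatioTable(frame, hyb.array_id, hyb.cy3_animal, hyb.cy5_animal)


def simulate_experiment(
    design: LoopDesign,
    probes: pd.DataFrame,
    truth: list[PlantedCNV],
    panel: AnimalPanel,
    noise_sd: float = 0.1,
    dye_bias: float = 0.0,
    spatial_amplitude: float = 0.0,
    seed: int = 0,
) -> dict[str, ProbeRatioTable]:
    """Simulate every hybridization in a design with per-array fresh noise."""
    root = np.random.default_rng(seed)
    tables = {}
    for hyb in design.hybridizations:
        tables[hyb.array_id] = simulate_hybridization(
            hyb,
            probes,
            truth,
            panel,
            noise_sd=noise_sd,
            dye_bias=dye_bias,
            spatial_amplitude=spatial_amplitude,
            seed=int(root.integers(0, 2**63 - 1)),
        )
    return tables
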