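"""File dialects: probe tables, design sheets, BED feature sets, FASTA, JSON.

All genomic output is 0-based half-open (BED dialect) and carries a header
comment declaring it. Inputs may declare 1-based closed coordinates, which
are converted on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import CNVCall
from .cnvr import CNVR
from .enrichment import FeatureSet
from .exceptions import DesignConsistencyError, FormatError
from .synthetic import (
    AnimalPanel,
    GenomeModel,
    Hybridization,
    LoopDesign,
    PlantedCNV,
    ProbeRatioTable,
)

COORD_COMMENT = "# coords=0-based,half-open"

PROBE_TABLE_COLUMNS = [
    "probe_id",
    "chrom",
    "start",
    "end",
    "x",
    "y",
    "ch1",
    "ch2",
]


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_probe_table(
    path,
    array_id: str | None = None,
    cy3_animal: str = "",
    cy5_animal: str = "",
    coords: str = "0-half-open",
) -> ProbeRatioTable:
    """Read a probe TSV into a :class:`ProbeRatioTable`.

    Requires probe_id/chrom/start/end/x/y plus either both channels or a
    ratio column. Unsorted rows are sorted with a warning; 1-based closed
    coordinates are converted when ``coords='1-closed'``.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].split():
                if "=" in token:
                    key, _, value = token.partition("=")
                    meta[key] = value
    frame = _read_tsv(path)
    for col in ["probe_id", "chrom", "start", "end", "x", "y"]:
        if col not in frame.columns:
            raise FormatError(f"missing column: {col}")
    has_channels = {"ch1", "ch2"} <= set(frame.columns)
    if not has_channels and "ratio" not in frame.columns:
        raise FormatError("missing column: ch1/ch2 (or ratio)")
    if coords == "1-closed":
        frame["start"] = frame["start"] - 1
    elif coords != "0-half-open":
        raise FormatError(f"unknown coordinate dialect {coords!r}")
    if not frame[["chrom", "start"]].equals(
        frame[["chrom", "start"]].sort_values(["chrom", "start"]).reset_index(drop=True)
    ):
        import logging

        logging.getLogger(__name__).warning("probe table %s unsorted; sorting", path)
        frame = frame.sort_values(["chrom", "start"]).reset_index(drop=True)
    if has_channels and "ratio" not in frame.columns:
        frame["ratio"] = np.log2(frame["ch1"] / frame["ch2"])
    stem = Path(path).stem.removesuffix(".probes")
    return ProbeRatioTable(
        frame,
        array_id or meta.get("array_id", stem),
        cy3_animal or meta.get("cy3", ""),
        cy5_animal or meta.get("cy5", ""),
    )


def write_probe_table(table: ProbeRatioTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT + "\n")
        fh.write(f"# array_id={table.array_id}")
        if table.cy3_animal:
            fh.write(f" cy3={table.cy3_animal} cy5={table.cy5_animal}")
        fh.write("\n")
        table.frame.to_csv(fh, sep="\t", index=False)


def write_design_sheet(design: LoopDesign, path) -> None:
    rows = [
        (h.array_id, h.cy3_animal, h.cy5_animal, h.design_id, design.swap_mate[h.array_id])
        for h in design.hybridizations
    ]
    pd.DataFrame(
        rows, columns=["array_id", "cy3_animal", "cy5_animal", "design_id", "swap_mate"]
    ).to_csv(path, sep="\t", index=False)


def read_design_sheet(path) -> LoopDesign:
    frame = _read_tsv(path)
    for col in ["array_id", "cy3_animal", "cy5_animal", "swap_mate"]:
        if col not in frame.columns:
            raise FormatError(f"missing column: {col}")
    hybs = tuple(
        Hybridization(
            str(r.array_id),
            str(r.cy3_animal),
            str(r.cy5_animal),
            int(getattr(r, "design_id", 1)),
        )
        for r in frame.itertuples()
    )
    swap = {str(r.array_id): str(r.swap_mate) for r in frame.itertuples()}
    try:
        return LoopDesign(hybs, swap)
    except DesignConsistencyError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise DesignConsistencyError(str(exc)) from exc


def write_panel(panel: AnimalPanel, path) -> None:
    pd.DataFrame(
        [(a, panel.sex[a], panel.breed.get(a, "")) for a in panel.animals],
        columns=["animal", "sex", "breed"],
    ).to_csv(path, sep="\t", index=False)


def read_panel(path) -> AnimalPanel:
    frame = _read_tsv(path)
    for col in ["animal", "sex"]:
        if col not in frame.columns:
            raise FormatError(f"missing column: {col}")
    animals = tuple(str(a) for a in frame["animal"])
    sex = dict(zip(animals, frame["sex"]))
    breed = (
        dict(zip(animals, frame["breed"].fillna("")))
        if "breed" in frame.columns
        else {}
    )
    return AnimalPanel(animals, sex, breed)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path, name: str | None = None) -> FeatureSet:
    """Read a BED file (0-based half-open); extra columns are preserved.

    Column 4 becomes ``name``, 5 ``identity`` when numeric, 6 ``evidence``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: invalid interval {start}-{end}")
            rows.append([parts[0], start, end, *parts[3:]])
    max_extra = max((len(r) - 3 for r in rows), default=0)
    extra_names = ["name", "identity", "evidence"][:max_extra] + [
        f"col{i}" for i in range(7, 4 + max_extra)
    ]
    columns = ["chrom", "start", "end"] + extra_names[:max_extra]
    frame = pd.DataFrame(
        [r + [None] * (len(columns) - len(r)) for r in rows], columns=columns
    )
    if "identity" in frame.columns:
        frame["identity"] = pd.to_numeric(frame["identity"], errors="coerce")
    return FeatureSet(name or Path(path).stem, frame)


def write_bed(frame: pd.DataFrame, path, extra_columns: list[str] = ()) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT + "\n")
        cols = ["chrom", "start", "end", *extra_columns]
        frame[cols].to_csv(fh, sep="\t", index=False, header=False)


def write_truth_bed(truth: list[PlantedCNV], path) -> None:
    frame = pd.DataFrame(
        [(c.chrom, c.start, c.end, f"{c.animal}:{c.state}") for c in truth],
        columns=["chrom", "start", "end", "name"],
    )
    write_bed(frame, path, extra_columns=["name"])


def write_calls_bed(calls: list[CNVCall], path) -> None:
    frame = pd.DataFrame(
        [(c.chrom, c.start, c.end, f"{c.animal}:{c.state}") for c in calls],
        columns=["chrom", "start", "end", "name"],
    )
    write_bed(frame, path, extra_columns=["name"])


def write_cnvr_bed(cnvrs: list[CNVR], path) -> None:
    frame = pd.DataFrame(
        [(r.chrom, r.start, r.end, f"{r.type};{r.n_animals}") for r in cnvrs],
        columns=["chrom", "start", "end", "name"],
    )
    write_bed(frame, path, extra_columns=["name"])


def read_calls_bed(path) -> list[CNVCall]:
    """Read a calls BED written by :func:`write_calls_bed`."""
    features = read_bed(path)
    calls = []
    for row in features.frame.itertuples():
        animal, state = str(row.name).split(":")
        calls.append(
            CNVCall(
                animal=animal,
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                state=state,
                supporting_pairs=(frozenset({animal}), frozenset({animal, "?"})),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# genome FASTA
# ---------------------------------------------------------------------------


def write_genome_fasta(
    genome: GenomeModel,
    path,
    gc: float = 0.42,
    seed: int = 0,
    line_width: int = 70,
) -> None:
    """Random sequence at the requested GC, gaps rendered as N runs."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for chrom in genome.names:
            length = genome.lengths[chrom]
            seq = alphabet[rng.choice(4, size=length, p=p)]
            for s, e in genome.sorted_gaps(chrom):
                seq[s:e] = "N"
            fh.write(f">{chrom}\n")
            text = "".join(seq)
            for i in range(0, length, line_width):
                fh.write(text[i : i + line_width] + "\n")


def write_chrom_sizes(genome: GenomeModel, path) -> None:
    pd.DataFrame(
        [(name, genome.lengths[name]) for name in genome.names]
    ).to_csv(path, sep="\t", index=False, header=False)


def read_chrom_sizes(path, gaps_bed=None) -> GenomeModel:
    frame = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    gaps: dict[str, list[tuple[int, int]]] = {}
    if gaps_bed is not None:
        for row in read_bed(gaps_bed).frame.itertuples():
            gaps.setdefault(str(row.chrom), []).append((int(row.start), int(row.end)))
    return GenomeModel(
        tuple(str(c) for c in frame["chrom"]),
        dict(zip(frame["chrom"].astype(str), frame["length"].astype(int))),
        gaps,
    )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    raise TypeError(f"cannot serialize {type(obj)}")
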