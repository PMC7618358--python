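"""Readers and writers for the package's text formats.

Conventions: junction-read and integration tables carry 1-based positions
(the coordinate printed by mapping pipelines); BED and bedGraph exports are
0-based half-open. Every reader validates the documented header and reports
malformed rows with their line number.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from hoplandscape.calling import INTEGRATION_COLUMNS, READ_COLUMNS
from hoplandscape.errors import DataIntegrityError
from hoplandscape.landscape import SortedPopulation

POPULATION_COLUMNS = [
    "experiment", "gate", "fluo", "recorded", "total_recorded", "sorted_cells",
    "n_replicates", "min_replicates",
]

TRACK_TSV_COLUMNS = [
    "chrom", "start", "end", "score", "n_integrations", "boot_median",
    "ci_low", "ci_high", "masked",
]


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise DataIntegrityError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataIntegrityError(f"{path}: missing required columns {missing}")
    return df


def read_reads(path: str | Path) -> pd.DataFrame:
    """Read a junction-read TSV (documented header, 1-based positions)."""
    df = _read_table(path, READ_COLUMNS)
    bad = df.index[df["position"].isna() | (df["mapq"] < 0)]
    if len(bad):
        raise DataIntegrityError(f"{path}: malformed row at line {bad[0] + 2}")
    return df


def write_reads(reads: pd.DataFrame, path: str | Path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def read_integrations(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, INTEGRATION_COLUMNS)
    bad = df.index[(df["unique_reads"] < 1) | df["position"].isna()]
    if len(bad):
        raise DataIntegrityError(f"{path}: malformed row at line {bad[0] + 2}")
    return df


def write_integrations(integrations: pd.DataFrame, path: str | Path) -> None:
    integrations.to_csv(path, sep="\t", index=False)


def write_integrations_bed(integrations: pd.DataFrame, path: str | Path) -> None:
    """BED6 export: start is the 1-based position minus one, width 1."""
    bed = pd.DataFrame(
        {
            "chrom": integrations["chrom"],
            "start": integrations["position"] - 1,
            "end": integrations["position"],
            "name": [
                f"{p}:{r}" for p, r in zip(integrations["pool"], integrations["replicate"])
            ],
            "score": integrations["unique_reads"],
            "strand": integrations["orientation"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_populations(path: str | Path) -> list[SortedPopulation]:
    df = _read_table(path, POPULATION_COLUMNS)
    return [
        SortedPopulation(
            experiment=str(row["experiment"]),
            gate=str(row["gate"]),
            fluo=float(row["fluo"]),
            recorded=int(row["recorded"]),
            total_recorded=int(row["total_recorded"]),
            sorted_cells=int(row["sorted_cells"]),
            n_replicates=int(row["n_replicates"]),
            min_replicates=int(row["min_replicates"]),
        )
        for _, row in df.iterrows()
    ]


def write_populations(populations: list[SortedPopulation], path: str | Path) -> None:
    pd.DataFrame([vars(p) for p in populations])[POPULATION_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def write_track_bedgraph(track: pd.DataFrame, path: str | Path, value: str = "score") -> None:
    """bedGraph export of an expression track; masked windows are omitted."""
    unmasked = track[~track["masked"].astype(bool)]
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="expression_score"\n')
        for _, row in unmasked.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t{row[value]:.6g}\n")


def write_track_tsv(track: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in TRACK_TSV_COLUMNS if c in track.columns]
    track[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_track_tsv(path: str | Path) -> pd.DataFrame:
    return _read_table(path, ["chrom", "start", "end", "score", "n_integrations", "masked"])
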