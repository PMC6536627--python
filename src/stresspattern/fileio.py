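"""Readers and writers for the pipeline's plain-text formats.

Matrices travel as TSV (transcript ids in the first column, sample ids in
the header), animal-level tables as CSV, gene sets as GMT, dendrograms as
Newick, and configuration as YAML — UTF-8 throughout.
"""

from __future__ import annotations

import dataclasses
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import PhenoSimConfig, SimulationConfig


class ParseError(ValueError):
    """Malformed input file; the message carries file and line context."""


def read_expression(path) -> pd.DataFrame:
    """Read a log2 expression TSV into a transcripts x samples DataFrame.

    The first column holds transcript ids, the header row sample ids.
    Ragged rows, non-numeric cells, non-finite values and duplicate
    transcript ids raise :class:`ParseError` with a line number (header
    is line 1).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        line = int(np.where(df.index == dup)[0][1]) + 2
        raise ParseError(f"{path}:{line}: duplicate transcript id {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.where(bad)[0][0]) + 2
            raise ParseError(f"{path}:{line}: non-numeric value in column {col!r}")
        df[col] = coerced
    if df.isna().any().any() or not np.isfinite(df.to_numpy()).all():
        row = int(np.where(~np.isfinite(df.to_numpy()).all(axis=1))[0][0]) + 2
        raise ParseError(f"{path}:{row}: missing or non-finite value")
    df.index.name = "transcript"
    return df


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="transcript")


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "strain", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    return df


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    """Read an animal-level CSV table (phenotypes or fecal CORT)."""
    return pd.read_csv(path)


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "passes" in df.columns:
        df["passes"] = df["passes"].astype(bool)
    return df


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def write_truth(truth, path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def atomic_write_text(text: str, path) -> None:
    """Write text to ``path`` via a temp file + rename (atomic on POSIX)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def config_to_yaml(config, path) -> None:
    data = dataclasses.asdict(config)
    # YAML cannot round-trip tuple keys; flatten to joined strings
    for key in ("overlap_spec", "concordance_spec"):
        if key in data:
            data[key] = {"&".join(k): v for k, v in data[key].items()}
    atomic_write_text(yaml.safe_dump(data, sort_keys=False), path)


def simulation_config_from_yaml(path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("overlap_spec", "concordance_spec"):
        if key in data:
            data[key] = {tuple(k.split("&")): v for k, v in data[key].items()}
    for key in ("strains", "treatments"):
        if key in data:
            data[key] = tuple(data[key])
    if "baseline_mean_range" in data:
        data["baseline_mean_range"] = tuple(data["baseline_mean_range"])
    return SimulationConfig(**data)


def pheno_config_from_yaml(path) -> PhenoSimConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if "strains" in data:
        data["strains"] = tuple(data["strains"])
    if "fcort_baseline" in data:
        data["fcort_baseline"] = {k: tuple(v) for k, v in data["fcort_baseline"].items()}
    return PhenoSimConfig(**data)
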