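"""Delimited-text readers and writers for every pipeline artefact.

All formats are plain CSV with a header row, mirroring the layout in which
field studies deposit binned life-table data:

* **records** — one row per individual; birth events are serialised as
  ``age:sex`` pairs joined by ``;`` (e.g. ``"4:F;6:M"``), observation
  fractions as ``age:fraction`` pairs. Floats round-trip exactly via
  ``repr``.
* **counts** — one row per age class with columns ``age, entries, deaths,
  disappearances, censors`` and, for female tables, the fertility columns
  ``weight_sum, weighted_births, weighted_sons, weighted_daughters,
  n_mothers``. A header map (dict or YAML file) adapts deposits whose
  column names differ.
* **life table** — ``x, N, c, dp, N_q, q, l`` plus ``m, N_m`` for females.
* **Leslie matrix** — a dense delimited matrix.
* **envelope** — long format ``statistic, age, point, lower, upper`` with
  the seed and replicate count in a ``#`` comment header.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bootstrap import BootstrapEnvelope
from .census import AgeClassCounts, FertilityCounts
from .errors import ValidationError
from .records import IndividualRecord
from .survival import LifeTable

__all__ = [
    "write_records",
    "read_records",
    "write_counts",
    "read_counts",
    "write_life_table",
    "read_life_table",
    "write_leslie",
    "write_envelope",
    "write_summary",
    "load_yaml",
]

RECORD_COLUMNS = ["id", "sex", "entry_age", "exit_age", "fate", "births", "obs_fraction"]
COUNT_COLUMNS = ["age", "entries", "deaths", "disappearances", "censors"]
FERTILITY_COLUMNS = [
    "weight_sum",
    "weighted_births",
    "weighted_sons",
    "weighted_daughters",
    "n_mothers",
]


def _encode_births(births) -> str:
    return ";".join(f"{age}:{sex}" for age, sex in births)


def _decode_births(text: str) -> list[tuple[int, str]]:
    if not text:
        return []
    out = []
    for item in text.split(";"):
        age, _, sex = item.partition(":")
        out.append((int(age), sex))
    return out


def _encode_obs(obs: dict[int, float]) -> str:
    return ";".join(f"{age}:{frac!r}" for age, frac in sorted(obs.items()))


def _decode_obs(text: str) -> dict[int, float]:
    if not text:
        return {}
    out = {}
    for item in text.split(";"):
        age, _, frac = item.partition(":")
        out[int(age)] = float(frac)
    return out


def write_records(records, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.id,
                    rec.sex,
                    rec.entry_age,
                    rec.exit_age,
                    rec.fate,
                    _encode_births(rec.births),
                    _encode_obs(rec.obs_fraction),
                ]
            )


def read_records(path) -> list[IndividualRecord]:
    """Read and validate a records file; all row-level problems are
    collected and reported together with their line numbers."""
    records = []
    problems = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(RECORD_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValidationError(
                f"{path}: missing column(s) {sorted(missing)} in header"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = IndividualRecord(
                    id=row["id"],
                    sex=row["sex"],
                    entry_age=int(row["entry_age"]),
                    exit_age=int(row["exit_age"]),
                    fate=row["fate"],
                    births=_decode_births(row["births"]),
                    obs_fraction=_decode_obs(row["obs_fraction"]),
                )
                rec.validate()
                records.append(rec)
            except (ValidationError, ValueError, KeyError) as err:
                problems.append(f"line {lineno}: {err}")
    if problems:
        raise ValidationError(
            f"{path}: {len(problems)} malformed row(s):\n" + "\n".join(problems)
        )
    return records


def write_counts(counts: AgeClassCounts, path, fertility: FertilityCounts | None = None) -> None:
    """Write a binned count table; female tables may carry the fertility
    tally columns alongside the mortality counts."""
    data = {
        "age": np.arange(counts.n_classes),
        "entries": counts.t,
        "deaths": counts.d,
        "disappearances": counts.p,
        "censors": counts.c,
    }
    if fertility is not None:
        if fertility.n_classes != counts.n_classes:
            raise ValidationError(
                "fertility and mortality tables cover different age ranges"
            )
        data["weight_sum"] = fertility.weight_sum
        data["weighted_births"] = fertility.weighted_births
        data["weighted_sons"] = fertility.weighted_sons
        data["weighted_daughters"] = fertility.weighted_daughters
        data["n_mothers"] = fertility.n_mothers
    pd.DataFrame(data).to_csv(path, index=False)


def _apply_header_map(df: pd.DataFrame, header_map) -> pd.DataFrame:
    if header_map is None:
        return df
    if isinstance(header_map, (str, Path)):
        header_map = load_yaml(header_map)
    return df.rename(columns=dict(header_map))


def read_counts(
    path, sex: str, header_map=None
) -> tuple[AgeClassCounts, FertilityCounts | None]:
    """Read a binned count table (and its fertility columns, when present).

    ``header_map`` — a dict or YAML file mapping the file's column names
    onto the canonical ones — adapts externally deposited tables whose
    headers differ from ours.
    """
    df = _apply_header_map(pd.read_csv(path), header_map)
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    df = df.sort_values("age").reset_index(drop=True)
    if not np.array_equal(df["age"].to_numpy(), np.arange(len(df))):
        raise ValidationError(f"{path}: age column must run 0..n-1 without gaps")
    counts = AgeClassCounts(
        sex=sex,
        t=df["entries"].to_numpy(),
        d=df["deaths"].to_numpy(),
        p=df["disappearances"].to_numpy(),
        c=df["censors"].to_numpy(),
    )
    fertility = None
    if set(FERTILITY_COLUMNS) <= set(df.columns):
        fertility = FertilityCounts(
            weighted_births=df["weighted_births"].to_numpy(),
            weight_sum=df["weight_sum"].to_numpy(),
            n_mothers=df["n_mothers"].to_numpy(),
            weighted_sons=df["weighted_sons"].to_numpy(),
            weighted_daughters=df["weighted_daughters"].to_numpy(),
        )
    return counts, fertility


def write_life_table(lt: LifeTable, counts: AgeClassCounts | None, path) -> None:
    """One row per age class up to omega: at-risk counts, censoring
    adjustment, mortality, survivorship, and (for females) fertility."""
    n = lt.omega + 1
    data: dict[str, np.ndarray] = {"x": np.arange(n)}
    if counts is not None:
        data["N"] = counts.N[:n]
        data["c"] = counts.c[:n]
        data["dp"] = counts.dp[:n]
    if lt.N_q is not None:
        data["N_q"] = lt.N_q
    data["q"] = lt.q
    data["l"] = lt.l
    if lt.m is not None:
        data["m"] = lt.m
    if lt.N_m is not None:
        data["N_m"] = lt.N_m
    pd.DataFrame(data).to_csv(path, index=False)


def read_life_table(path, sex: str | None = None) -> LifeTable:
    df = pd.read_csv(path)
    for col in ("x", "q", "l"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    omega = int(df["x"].iloc[-1])
    return LifeTable(
        sex=sex,
        q=df["q"].to_numpy(),
        l=df["l"].to_numpy(),
        m=df["m"].to_numpy() if "m" in df.columns else None,
        N_q=df["N_q"].to_numpy() if "N_q" in df.columns else None,
        N_m=df["N_m"].to_numpy() if "N_m" in df.columns else None,
        omega=omega,
    )


def write_leslie(A: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(A, dtype=float), delimiter=",")


def write_envelope(env: BootstrapEnvelope, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# n_reps={env.n_reps} seed={env.seed}\n")
        writer = csv.writer(fh)
        writer.writerow(["statistic", "age", "point", "lower", "upper"])
        for name, (point, lo, hi) in env.scalars.items():
            writer.writerow([name, "", point, lo, hi])
        for name, bands in env.per_age.items():
            for x in range(len(bands["point"])):
                writer.writerow(
                    [name, x, bands["point"][x], bands["lower"][x], bands["upper"][x]]
                )


def write_summary(summary: dict, path) -> None:
    def _clean(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        json.dump(_clean(summary), fh, indent=2)
        fh.write("\n")


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping at top level")
    return data
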