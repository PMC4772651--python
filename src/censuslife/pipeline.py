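"""End-to-end pipeline: records → counts → life table → demography → bootstrap.

The pipeline accepts either raw individual records (the form the simulator
produces) or pre-binned count tables (the form long-term studies deposit),
runs the sex-specific stages, and writes every artefact as delimited text.
Male runs stop after survivorship — fertility and the Leslie machinery
need a female table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as cio
from .bootstrap import bootstrap_ci
from .census import AgeClassCounts, FertilityCounts, tabulate_counts, tabulate_fertility
from .demography import build_leslie, summarize
from .errors import ValidationError
from .fertility import age_first_reproduction, age_specific_fertility, sex_ratio
from .records import FEMALE, MALE
from .survival import (
    LifeTable,
    actuarial_mortality,
    apply_disappearance_policy,
    survivorship,
    truncate_at_last_death,
)
from .synthetic import SimulationConfig, simulate_population

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "assemble_life_table", "run_pipeline"]


def assemble_life_table(
    counts: AgeClassCounts,
    fertility_counts: FertilityCounts | None = None,
    disappearances: str = "deaths",
) -> LifeTable:
    """Estimate a truncated life table from binned counts; when fertility
    tallies are supplied (female tables), attach ``m`` and ``N_m`` over
    the same ``0..omega`` range (padding with zeros past the observed
    fertile ages)."""
    counts = apply_disappearance_policy(counts, disappearances)
    q, _ = actuarial_mortality(counts)
    l = survivorship(q)
    lt = truncate_at_last_death(counts, q[: counts.n_classes], l[: counts.n_classes])
    if fertility_counts is not None:
        m, n_m = age_specific_fertility(fertility_counts)
        size = lt.omega + 1
        lt.m = _fit_length(m, size)
        lt.N_m = _fit_length(n_m, size)
        lt.validate()
    return lt


def _fit_length(v: np.ndarray, size: int) -> np.ndarray:
    if len(v) >= size:
        return np.asarray(v[:size], dtype=float)
    return np.concatenate([np.asarray(v, dtype=float), np.zeros(size - len(v))])


@dataclass
class RunConfig:
    """One pipeline run.

    Exactly one input mode must be active: ``simulate`` (a
    :class:`SimulationConfig`), ``records_path`` (an individual-records
    file) or ``counts_path`` (a pre-binned count table). The
    ``disappearances`` policy routes permanent disappearances into the
    mortality numerator (``"deaths"``) or the censored column
    (``"censored"``).
    """

    outdir: str | Path
    simulate: SimulationConfig | None = None
    records_path: str | Path | None = None
    counts_path: str | Path | None = None
    sex: str = FEMALE
    truncate_age: int | None = None
    disappearances: str = "deaths"
    n_reps: int = 4999
    seed: int = 0
    run_bootstrap: bool = True
    afr_known_age_only: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        modes = [
            self.simulate is not None,
            self.records_path is not None,
            self.counts_path is not None,
        ]
        if sum(modes) != 1:
            raise ValidationError(
                "exactly one of simulate / records_path / counts_path required"
            )
        if self.sex not in (FEMALE, MALE):
            raise ValidationError(f"sex must be F or M, got {self.sex!r}")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        if self.disappearances not in ("deaths", "censored"):
            raise ValidationError(
                f"disappearances must be 'deaths' or 'censored', got "
                f"{self.disappearances!r}"
            )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every applicable stage and write its artefacts.

    Returns a map from artefact name to the written path. Stage failures
    propagate with the stage name prefixed, so partial output on disk is
    identifiable from the log.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    records = None
    counts = fc = None
    if config.simulate is not None:
        logger.info("stage simulate: seed=%d", config.simulate.seed)
        records = simulate_population(config.simulate)
        outputs["records"] = outdir / "records.csv"
        cio.write_records(records, outputs["records"])
    elif config.records_path is not None:
        records = cio.read_records(config.records_path)
        logger.info("stage read_records: %d records", len(records))
    else:
        counts, fc = cio.read_counts(config.counts_path, sex=config.sex)
        logger.info("stage read_counts: %d age classes", counts.n_classes)

    if records is not None:
        counts = tabulate_counts(records, sex=config.sex, truncate_age=config.truncate_age)
        if config.sex == FEMALE:
            fc = tabulate_fertility(records, n_classes=counts.n_classes)
        logger.info(
            "stage tabulate: sex=%s, %d classes, %d entries",
            config.sex,
            counts.n_classes,
            int(counts.t.sum()),
        )
        outputs["counts"] = outdir / f"counts_{config.sex}.csv"
        cio.write_counts(counts, outputs["counts"], fertility=fc)

    lt = assemble_life_table(
        counts,
        fertility_counts=fc if config.sex == FEMALE else None,
        disappearances=config.disappearances,
    )
    logger.info("stage lifetable: omega=%d", lt.omega)
    outputs["life_table"] = outdir / f"life_table_{config.sex}.csv"
    cio.write_life_table(lt, counts, outputs["life_table"])

    if config.sex == MALE:
        logger.info("male run: stopping after survivorship")
        return outputs

    afr = None
    summary_extra: dict = {}
    if records is not None:
        try:
            afr = age_first_reproduction(records, known_age_only=config.afr_known_age_only)
            summary_extra["median_afr"] = afr.median
            summary_extra["afr_iqr"] = [afr.q1, afr.q3]
        except ValidationError:
            logger.warning("no reproducing females: AFR skipped")
        try:
            sr = sex_ratio(records)
            summary_extra["sex_ratio"] = {
                "n_sexed": sr.n_sexed,
                "prop_female": sr.prop_female,
                "ci": [sr.ci_low, sr.ci_high],
            }
        except ValidationError:
            logger.warning("no sexed newborns: sex ratio skipped")

    summary = summarize(lt, afr=afr)
    logger.info(
        "stage demography: R0=%.4f G=%s lambda=%.4f",
        summary.R0,
        f"{summary.G:.4f}" if summary.G is not None else "NA",
        summary.lam,
    )
    outputs["leslie"] = outdir / "leslie.csv"
    cio.write_leslie(build_leslie(lt), outputs["leslie"])
    outputs["summary"] = outdir / "summary.json"
    cio.write_summary(
        {
            "R0": summary.R0,
            "G": summary.G,
            "lambda": summary.lam,
            "w": summary.w,
            "v": summary.v,
            "e": summary.e,
            "surv_to_median_afr": summary.surv_to_median_afr,
            **summary_extra,
        },
        outputs["summary"],
    )

    if config.run_bootstrap:
        logger.info("stage bootstrap: n_reps=%d seed=%d", config.n_reps, config.seed)
        env = bootstrap_ci(lt, n_reps=config.n_reps, seed=config.seed)
        outputs["envelope"] = outdir / "bootstrap_envelope.csv"
        cio.write_envelope(env, outputs["envelope"])
    return outputs
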