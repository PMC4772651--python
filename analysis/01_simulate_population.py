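"""Simulate the reference study population and bin it into count tables.

Generates the individual-based census (5000 founding births under the
reference schedule, with end-of-study censoring, male-biased disappearance
and a small unsexed-newborn fraction), then reduces it to the per-sex
per-age-class count tables that every later stage consumes. The raw
records (one row per animal, ~1 MB) go to scratch/; the binned tables go
to results/.
"""

from pathlib import Path

from censuslife import io as cio
from censuslife import default_config, simulate_population, tabulate_counts, tabulate_fertility
from censuslife.records import DEATH, DISAPPEARANCE, FEMALE, MALE, UNKNOWN

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY = default_config(n_births=5000, seed=1)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    records = simulate_population(STUDY)
    cio.write_records(records, SCRATCH / "records.csv")

    n_unknown = sum(1 for r in records if r.sex == UNKNOWN)
    n_deaths = sum(1 for r in records if r.fate == DEATH)
    n_disappeared = sum(1 for r in records if r.fate == DISAPPEARANCE)
    print(f"simulated {len(records)} individuals "
          f"({STUDY.n_births} founding births, seed={STUDY.seed})")
    print(f"  deaths: {n_deaths}, permanent disappearances: {n_disappeared}, "
          f"censored: {len(records) - n_deaths - n_disappeared}")
    print(f"  unsexed newborns: {n_unknown} "
          f"({100 * n_unknown / len(records):.1f}%)")

    for sex in (FEMALE, MALE):
        counts = tabulate_counts(records, sex)
        fc = tabulate_fertility(records, n_classes=counts.n_classes) if sex == FEMALE else None
        out = RESULTS / f"counts_{sex}.csv"
        cio.write_counts(counts, out, fertility=fc)
        print(f"  sex {sex}: {int(counts.t.sum())} individuals in "
              f"{counts.n_classes} age classes -> {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
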