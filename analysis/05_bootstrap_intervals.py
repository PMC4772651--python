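"""Parametric-bootstrap confidence limits for the female life-history
statistics.

Resamples the estimated life table 4999 times (binomial deaths with
ceil-rounded at-risk counts; per-female Poisson daughters with
ceil-rounded weight sums), recomputes every statistic per replicate, and
reports the 2.5th/97.5th percentile envelopes.
"""

import sys
from importlib import import_module
from pathlib import Path

from censuslife import io as cio
from censuslife import bootstrap_ci
from censuslife.records import FEMALE

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

sys.path.insert(0, str(Path(__file__).parent))
STUDY = import_module("01_simulate_population").STUDY

N_REPS = 4999
SEED = 20240301


def main() -> None:
    lt = cio.read_life_table(RESULTS / "life_table_F.csv", sex=FEMALE)
    env = bootstrap_ci(lt, n_reps=N_REPS, seed=SEED)
    out = RESULTS / "bootstrap_envelope_F.csv"
    cio.write_envelope(env, out)

    print(f"parametric bootstrap: {env.n_reps} replicates (seed={env.seed})")
    for name, label in (("R0", "net reproductive rate"),
                        ("G", "generation time (yr)"),
                        ("lam", "growth rate lambda")):
        point, lo, hi = env.scalars[name]
        print(f"  {label:24s} {point:.4f}  95% CI [{lo:.4f}, {hi:.4f}]")
    if env.n_undefined_G:
        print(f"  ({env.n_undefined_G} replicates had R0* = 0 and were "
              "excluded from the G percentiles)")
    band = env.per_age["l"]
    print("  survivorship envelope by age:")
    for x in range(lt.omega + 1):
        print(f"    l_{x}: {band['point'][x]:.3f} "
              f"[{band['lower'][x]:.3f}, {band['upper'][x]:.3f}]")
    print(f"wrote {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
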