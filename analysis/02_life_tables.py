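"""Estimate sex-specific life tables from the binned count tables.

Reads the count tables written by 01_simulate_population.py, applies the
actuarial estimator (censoring-adjusted at-risk counts, disappearances
pooled with deaths) and truncates each table at its last observed death.
The female table carries the observation-weighted fertility schedule; the
male pipeline stops at survivorship, as male fertility is unobservable in
a matrilineal census.
"""

from pathlib import Path

import numpy as np

from censuslife import io as cio
from censuslife import assemble_life_table
from censuslife.records import FEMALE, MALE

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    for sex in (FEMALE, MALE):
        counts, fc = cio.read_counts(RESULTS / f"counts_{sex}.csv", sex=sex)
        lt = assemble_life_table(counts, fertility_counts=fc)
        out = RESULTS / f"life_table_{sex}.csv"
        cio.write_life_table(lt, counts, out)
        print(f"sex {sex}: table truncated at omega={lt.omega} "
              f"(last observed death) -> {out.relative_to(ROOT)}")
        print("  x    N_q      q_x      l_x" + ("      m_x     N_m" if lt.m is not None else ""))
        for x in range(lt.omega + 1):
            row = f"  {x}  {lt.N_q[x]:7.1f}  {lt.q[x]:.4f}  {lt.l[x]:.4f}"
            if lt.m is not None:
                row += f"  {lt.m[x]:.4f}  {lt.N_m[x]:6.1f}"
            print(row)
        if sex == FEMALE:
            print(f"  survivorship to omega: {lt.l[lt.omega]:.3f}; "
                  f"peak fertility {lt.m.max():.3f} daughters/female/yr "
                  f"at age {int(np.argmax(lt.m))}")


if __name__ == "__main__":
    main()
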