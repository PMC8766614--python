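"""Map the constriction stability landscape of the membrane model.

Computes the dispersion relation omega(q) for a soft, a near-marginal and
a stiff membrane at regulated FtsZ level, the critical rigidity/FtsZ lines,
the quantized unstable modes as a function of cell length, and the
four-region proliferation state diagram.  Writes everything under
results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from memdiv.constriction import (
    CriticalLine,
    MembraneParams,
    classify_state,
    critical_ftsz,
    critical_rigidity,
    dispersion,
    state_diagram,
    unstable_modes,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    p = MembraneParams()
    q = np.linspace(0.0, 4.0, 401)

    rows = []
    for label, kappa in [("kappa0", 12.0), ("2kappa0", 24.0),
                         ("3kappa0", 36.0)]:
        d = dispersion(p.with_(kappa=kappa), q)
        rows.append(
            pd.DataFrame(dict(q=q, omega=d.omega, kappa=kappa, label=label))
        )
        print(
            f"kappa = {kappa:5.1f} kBT: "
            f"{'stable' if d.stable else 'unstable'}, "
            f"omega_max = {d.omega_max:8.2f} 1/h at q* = {d.q_star:.2f} 1/um"
        )
    pd.concat(rows).to_csv(OUT / "dispersion_curves.csv", index=False)

    kc = critical_rigidity(p.u_0, p)
    uc = critical_ftsz(p.kappa_0, p)
    print(f"\ncritical rigidity at u_h = {p.u_0}: kappa_crit = {kc:.1f} kBT "
          f"(= {kc / p.kappa_0:.1f} kappa_0)")
    print(f"critical FtsZ at kappa_0: u_crit = {uc:.3f}")

    mode_rows = []
    for L in np.arange(0.5, 6.01, 0.25):
        n = unstable_modes(p.with_(L_cell=L))
        mode_rows.append(dict(L_cell=L, n_unstable=len(n)))
    dfm = pd.DataFrame(mode_rows)
    dfm.to_csv(OUT / "unstable_modes_vs_length.csv", index=False)
    L_min = dfm.loc[dfm.n_unstable > 0, "L_cell"].min()
    print(f"shortest cell with an unstable division mode: L = {L_min} um")

    kg = np.linspace(1.0, 72.0, 72)
    ug = np.linspace(0.01, 0.9, 45)
    sd = state_diagram(kg, ug, p)
    sd.to_csv(OUT / "state_diagram.csv", index=False)
    frac = sd.region.value_counts(normalize=True).sort_index()
    print("\nstate-diagram region occupancy on the grid:")
    for r, f in frac.items():
        print(f"  region {r}: {100 * f:.1f}%")


if __name__ == "__main__":
    main()
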