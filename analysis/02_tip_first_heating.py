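"""Where does heating start on a branched cast?  At the sharp terminal tips.

Solves the field on the 0.5 mm branched reference domain (fine enough to
resolve the ~0.77 mm terminal branch radii), then steps the bioheat equation
until the first tissue voxel crosses 50 degC and reports where that voxel
sits relative to the cast's terminal tips.

Writes results/tip_first_heating.json.
"""

import json
import pathlib

import numpy as np

import airwayrfa as a
from airwayrfa import experiments as exp
from airwayrfa.io import write_json

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    table = a.default_table()
    domain, _ = exp.reference_branched_domain(
        seed=0, depth=3, config={"spacing": 0.5, "sheath_length": 20.0})
    sol = a.solve_potential(domain, table, 1.0)
    tips = np.array(domain.tip_voxels)

    max_u = np.array(np.unravel_index(np.argmax(sol.U), sol.U.shape))
    u_tip_dist = int(np.abs(tips - max_u).max(axis=1).min())

    solver = a.BioheatSolver(domain, table, scheme="implicit", dt=0.5)
    state = solver.make_state()
    U = sol.U * 80.0**2
    tissue = np.isin(domain.labels, [int(l) for l in exp.TISSUE_LABELS])
    first = None
    while state.t < 60.0:
        solver.step_implicit(state, U, 0.5)
        hot = tissue & (state.T >= 50.0)
        if hot.any():
            idx = np.array(np.unravel_index(
                np.argmax(np.where(hot, state.T, -np.inf)), state.T.shape))
            first = {"t_s": state.t, "voxel": idx.tolist(),
                     "chebyshev_to_tip": int(np.abs(tips - idx).max(axis=1).min())}
            break

    payload = {
        "max_sar_voxel": max_u.tolist(),
        "max_sar_chebyshev_to_tip": u_tip_dist,
        "first_tissue_voxel_50C": first,
        "n_terminal_tips": len(tips),
    }
    write_json(OUT / "tip_first_heating.json", payload)
    print(json.dumps(payload, indent=1))


if __name__ == "__main__":
    main()
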