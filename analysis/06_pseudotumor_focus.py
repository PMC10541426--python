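"""Heat focusing in a pseudotumor enclosed by the branched cast.

The muscle-like tumor surrogate conducts current and heat better than the
aerated parenchyma around it, so a tumor inside the cast envelope runs
hotter than parenchyma at the same distance from the metal; a tumor at the
lesion margin is only partially covered.

Writes results/pseudotumor.json.
"""

import json
import pathlib

import numpy as np

from airwayrfa import experiments as exp
from airwayrfa.io import write_json

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    enclosed = exp.pseudotumor_focus({"duration_s": 300.0, "tumor_radius": 8.0})
    # margin position: push the tumor laterally out of the cast envelope
    _, tree = exp.reference_branched_domain(seed=0, depth=3)
    domain, _ = exp.reference_branched_domain(seed=0, depth=3)
    tips = np.array([domain.voxel_center(v) for v in domain.tip_voxels])
    center = tips.mean(axis=0) + np.array([0.0, 18.0, 0.0])
    margin = exp.pseudotumor_focus({"duration_s": 300.0, "tumor_radius": 8.0,
                                    "tumor_center": center.tolist()})
    payload = {"enclosed": enclosed, "margin": margin,
               "coverage_drop": enclosed["tumor_core_coverage"]
               - margin["tumor_core_coverage"]}
    write_json(OUT / "pseudotumor.json", payload)
    print(json.dumps(payload, indent=1))


if __name__ == "__main__":
    main()
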