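"""Liquid-metal cast versus saline / gold-nanoparticle infusates.

Same bronchus, same drive: the equipotential metal cast couples the full
amplitude into tissue everywhere along its surface, while a conductive fluid
column (0.113 or 0.138 S/m) fed at the injection point drops almost all of
the drive along its own resistance.  Reports necrotic-core volumes and the
lesion regularity index per medium.

Writes results/fluid_comparison.{csv,json}.
"""

import json
import pathlib

from airwayrfa import experiments as exp

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    res = exp.compare_fluids({"duration_s": 180.0})
    res.table.to_csv(OUT / "fluid_comparison.csv", index=False)
    res.to_json(OUT / "fluid_comparison.json")
    print(res.table.to_string(index=False))
    print(json.dumps(res.summary, indent=1))


if __name__ == "__main__":
    main()
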