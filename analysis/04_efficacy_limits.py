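"""Bronchial length and diameter limits of effective ablation.

Sweeps the straight-electrode length (3-8 cm at 3 mm diameter) and diameter
(2-8 mm at 3 cm length) at fixed 80 V drive for 5 minutes and reports the
largest effective length and the smallest ineffective diameter, judged by
whether the distal target tissue reaches 60 degC.

Writes results/sweep_length.{csv,json} and results/sweep_diameter.{csv,json}.
"""

import json
import pathlib

from airwayrfa import experiments as exp

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    res = exp.sweep_length(exp.SweepSpec("length", [3, 4, 5, 6, 7, 8]))
    res.table.to_csv(OUT / "sweep_length.csv", index=False)
    res.to_json(OUT / "sweep_length.json")
    print(res.table.to_string(index=False))
    print(json.dumps(res.summary, indent=1))

    res = exp.sweep_diameter(exp.SweepSpec("diameter", [2, 3, 4, 5, 6, 8]))
    res.table.to_csv(OUT / "sweep_diameter.csv", index=False)
    res.to_json(OUT / "sweep_diameter.json")
    print(res.table.to_string(index=False))
    print(json.dumps(res.summary, indent=1))


if __name__ == "__main__":
    main()
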