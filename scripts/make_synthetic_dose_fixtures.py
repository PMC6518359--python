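"""Regenerate the synthetic dosimetry fixtures packaged with invpetdose.

Both files are labelled synthetic: they are constructed, documented
stand-ins with the right structure and magnitudes, not the output of
any human-phantom dosimetry code.

* ``svalue_sphere_cu64_synthetic.csv`` — unit-density-sphere
  self-dose S-values for Cu-64 over 0.01-10 g, generated from the
  power law S(m) = 70 m^-0.95 mGy/(MBq h). The prefactor follows
  from near-complete local absorption of the ~0.12 MeV mean
  beta/Auger energy per decay in a 1 g sphere; the exponent < 1 in
  magnitude reflects growing photon self-absorption with size.
* ``smatrix_synthetic.csv`` — a small adult-phantom-style organ
  S-factor matrix (mSv/(MBq h)): diagonally dominant with cross-organ
  terms falling off with anatomical separation, organ masses, and
  tissue weighting factors summing to 1.

Run from the repository root:

    python scripts/make_synthetic_dose_fixtures.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

OUT = Path(__file__).resolve().parents[1] / "src" / "invpetdose" / "data"

SPHERE_A = 70.0  # mGy/(MBq h) at 1 g
SPHERE_B = -0.95


def write_sphere_table() -> None:
    masses = np.array([0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0])
    s = SPHERE_A * masses**SPHERE_B
    pd.DataFrame({"mass_g": masses, "s_mGy_per_MBq_h": s}).to_csv(
        OUT / "svalue_sphere_cu64_synthetic.csv", index=False
    )


ORGANS = ["liver", "kidneys", "spleen", "lungs", "brain", "stomach", "intestines", "remainder"]
MASSES_G = {  # adult male reference-style masses
    "liver": 1800.0,
    "kidneys": 310.0,
    "spleen": 180.0,
    "lungs": 1000.0,
    "brain": 1400.0,
    "stomach": 150.0,
    "intestines": 1000.0,
    "remainder": 68160.0,
}
WEIGHTS = {
    "liver": 0.04,
    "kidneys": 0.02,
    "spleen": 0.02,
    "lungs": 0.12,
    "brain": 0.01,
    "stomach": 0.12,
    "intestines": 0.12,
    "remainder": 0.55,
}
# rough torso coordinates (cm) to make cross-dose fall off with distance
POS = {
    "liver": (0.0, 0.0),
    "kidneys": (4.0, -4.0),
    "spleen": (-8.0, 0.0),
    "lungs": (0.0, 10.0),
    "brain": (0.0, 40.0),
    "stomach": (-5.0, 3.0),
    "intestines": (0.0, -12.0),
    "remainder": (0.0, -25.0),
}

DELTA = 0.069  # mGy g / (MBq h): mean local energy per decay for Cu-64


def write_smatrix() -> None:
    rows = {}
    for tgt in ORGANS:
        row = {}
        for src in ORGANS:
            if src == tgt:
                row[src] = DELTA * 1000.0 / MASSES_G[tgt]  # self-dose ~ Delta/m
            else:
                dx = POS[tgt][0] - POS[src][0]
                dy = POS[tgt][1] - POS[src][1]
                dist = np.hypot(dx, dy)
                # photon cross-dose: inverse-square-ish falloff, small
                row[src] = DELTA * 40.0 / MASSES_G[tgt] / (1.0 + dist**2)
        rows[tgt] = row
    df = pd.DataFrame(rows).T[ORGANS]
    df.insert(0, "mass_g", [MASSES_G[o] for o in df.index])
    df["tissue_weight"] = [WEIGHTS[o] for o in df.index]
    df.index.name = "organ"
    df.to_csv(OUT / "smatrix_synthetic.csv", float_format="%.6g")


if __name__ == "__main__":
    write_sphere_table()
    write_smatrix()
    print(f"fixtures written to {OUT}")
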