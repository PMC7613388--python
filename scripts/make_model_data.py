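"""Regenerate the vendored leaf-optics coefficient tables and soil endmembers.

The tables under src/npvret/data/ are synthetic stand-ins built from smooth
analytic forms. They encode the qualitative constraints the retrieval chain
relies on, without reproducing any proprietary measurement set:

* pigment coefficients (chlorophyll, carotenoid, anthocyanin, brown) are
  exactly zero above 900 nm, so the SWIR is pigment-invariant;
* water absorption peaks near 970/1200/1450/1940 nm and rises toward 2500 nm;
* protein absorbs near 1510/2054/2172 nm;
* the carbon-based-constituent (lignocellulose) coefficient has its main
  features near 1730, 2100 and 2300 nm on a baseline rising through the SWIR;
* the dry soil endmember is bright and featureless near 2100 nm; the wet one
  is darker with water dips at 1450/1940 nm.

Run from the repository root:  python scripts/make_model_data.py
"""

import json
from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parents[1] / "src" / "npvret" / "data"

WL = np.arange(400, 2501, dtype=float)


def gauss(center, width):
    return np.exp(-0.5 * ((WL - center) / width) ** 2)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    n_refr = 1.40 + 0.14 * np.exp(-(WL - 400.0) / 800.0)

    kab = 0.065 * gauss(430, 35) + 0.045 * gauss(480, 40) + 0.085 * gauss(670, 30) \
        + 0.025 * gauss(620, 45)
    kcar = 0.11 * gauss(450, 30) + 0.075 * gauss(480, 25)
    kant = 0.065 * gauss(550, 40)
    kbrown = 1.1 * gauss(450, 120) + 0.45 * gauss(620, 110)

    # hard zero above 900 nm: pigments must not touch the SWIR
    vis = WL <= 900.0
    for arr in (kab, kcar, kant, kbrown):
        arr[~vis] = 0.0

    kw = (
        1.5 * gauss(970, 40)
        + 4.0 * gauss(1200, 55)
        + 32.0 * gauss(1450, 50)
        + 105.0 * gauss(1940, 60)
        + 40.0 * gauss(2700, 400)
        + 3.0 * sigmoid((WL - 1850.0) / 150.0)
    )

    kp = 60.0 * gauss(1510, 45) + 90.0 * gauss(2054, 45) + 130.0 * gauss(2172, 55)

    kcbc = (
        35.0 * sigmoid((WL - 1500.0) / 200.0)
        + 20.0 * gauss(1215, 40)
        + 60.0 * gauss(1730, 55)
        + 110.0 * gauss(2100, 80)
        + 85.0 * gauss(2300, 70)
        + 50.0 * gauss(2480, 120)
    )

    tiny = [kab, kcar, kant, kbrown, kw, kp, kcbc]
    for arr in tiny:
        arr[arr < 1e-10] = 0.0

    coeff = np.column_stack([WL, n_refr, kab, kcar, kant, kbrown, kw, kp, kcbc])
    header = "wavelength_nm,refractive_index,kab,kcar,kant,kbrown,kw,kp,kcbc"
    np.savetxt(OUT / "leaf_coefficients.csv", coeff, delimiter=",",
               header=header, comments="", fmt="%.8g")

    dry = 0.16 + 0.24 * sigmoid((WL - 800.0) / 500.0)
    wet = 0.55 * dry * (1.0 - 0.35 * gauss(1450, 80) - 0.50 * gauss(1940, 100))
    wet = np.clip(wet, 0.02, None)
    soil = np.column_stack([WL, dry, wet])
    np.savetxt(OUT / "soil_endmembers.csv", soil, delimiter=",",
               header="wavelength_nm,dry,wet", comments="", fmt="%.8g")

    manifest = {
        "generator": "scripts/make_model_data.py",
        "wavelength_nm": [400, 2500, 1],
        "files": ["leaf_coefficients.csv", "soil_endmembers.csv"],
        "provenance": "synthetic analytic tables; see generator docstring for the "
                      "qualitative constraints they encode",
        "constraints": {
            "pigments_zero_above_nm": 900,
            "water_peaks_nm": [970, 1200, 1450, 1940],
            "protein_peaks_nm": [1510, 2054, 2172],
            "cbc_features_nm": [1730, 2100, 2300],
            "soil_featureless_near_nm": 2100,
        },
    }
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
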