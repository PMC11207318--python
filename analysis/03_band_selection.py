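#!/usr/bin/env python
"""Score every band with the three selection algorithms on the scene.

Computes PCA-MV band power, LCMV-CBS tau, and RF importance curves from the
reflectance cube of 02_calibrate.py, extracts band definitions from each,
and writes the score curves (CSV) plus the derived configurations (JSON).
The packaged canonical suite (including the tabulated seven-band RF sensor)
is written alongside for comparison.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from hyperyield.datacube import FieldLayout, YieldTable, read_cube
from hyperyield.band_selection import (
    SpectralConfig,
    lcmv_cbs_scores,
    pca_mv_scores,
    rf_importance_scores,
    select_bands,
)
from hyperyield.experiment import campaign_config_suite
from hyperyield.yield_regression import subplot_mean_spectra

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    refl = read_cube(BASE / "scene" / "reflectance.img")
    layout = FieldLayout.from_csv(BASE / "scene" / "layout.csv")
    yields = YieldTable.from_csv(BASE / "scene" / "yields.csv")
    wl = refl.wavelengths

    rng = np.random.default_rng(SEED)
    X = refl.values.reshape(refl.n_bands, -1).T
    X = X[rng.choice(X.shape[0], min(60_000, X.shape[0]), replace=False)].astype(float)

    _, pca = pca_mv_scores(X, wavelengths=wl)
    _, lcmv = lcmv_cbs_scores(X, epsilon=10.0, wavelengths=wl)
    feats = subplot_mean_spectra(refl, layout)
    y = np.array([yields[i] for i in feats.ids])
    rf = rf_importance_scores(feats.frame.to_numpy(), y, seed=SEED, wavelengths=wl)

    pd.DataFrame(
        {"wavelength_nm": wl, "pca_rho": pca.scores, "lcmv_tau": lcmv.scores, "rf_importance": rf.scores}
    ).to_csv(BASE / "band_scores.csv", index=False)

    out = BASE / "configs"
    out.mkdir(parents=True, exist_ok=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for label, scores in (("pca", pca), ("lcmv", lcmv), ("rf", rf)):
            k = 1.0 if label == "lcmv" else 2.0
            bands = select_bands(scores, noise_floor_k=k)
            print(f"{label:5s}: {[(round(b.center), round(b.fwhm)) for b in bands]}")
            if bands:
                SpectralConfig(f"{label}-derived", bands).to_json(out / f"{label}_derived.json")
    for cfg in campaign_config_suite():
        cfg.to_json(out / f"{cfg.name}.json")
    print(f"score curves and {len(campaign_config_suite())} canonical configs written to {out}")


if __name__ == "__main__":
    main()
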