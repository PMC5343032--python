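"""Screen the spectral-index registry against grain yield and Δ13C.

For each hydric condition (WS, FI, pooled WS+FI) and spectra stage, every
registry index is regressed against the trait (simple least squares) and
ranked by r².  The headline pattern: pooling the two regimes raises r² far
above either single regime.  In this synthetic scene the red-edge and
soil-adjusted structure indices (RE, SAVI2, WDVI) edge out the water family
(NDWI, WI), which ranks close behind for GY and Δ13C.  Writes
results/index_screening.csv.
"""

from pathlib import Path

import pandas as pd

import spectraits as st

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    spectra, traits = st.make_benchmark_fixture(seed=SEED)
    trimmed = st.trim_noise_bands(spectra)
    registry = st.builtin_registry()

    rows = []
    for trait, tstage in (("GY", "m"), ("D13C", "m")):
        values = traits.get(trait, tstage)
        for stage in ("AN", "GF"):
            for env in ("WS", "FI", "WS+FI"):
                sub = (trimmed if env == "WS+FI" else trimmed.select(
                    trimmed.meta["environment"].eq(env).to_numpy()))
                X, y = st.align(sub, values, stage=stage)
                m = st.SpectraMatrix(
                    meta=sub.meta.loc[X.index].copy(), reflectance=X)
                table = st.compute_all(m, registry)
                ranked = st.screen_indices(table, y)
                best = ranked.iloc[0]
                rows.append({"trait": trait, "stage": stage, "env": env,
                             "best_sri": best["index"],
                             "r2": round(float(best["r2"]), 3),
                             "rmse": round(float(best["rmse"]), 3)})
                print(f"{trait:5s} {stage} {env:6s} best {best['index']:<16s}"
                      f" r2={best['r2']:.2f}")

    pd.DataFrame(rows).to_csv(OUT / "index_screening.csv", index=False)
    print(f"\nwrote {OUT / 'index_screening.csv'}")
    print("note the pooled WS+FI rows: combining regimes widens the trait "
          "range and lifts r2 well above the single-regime screens.")


if __name__ == "__main__":
    main()
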