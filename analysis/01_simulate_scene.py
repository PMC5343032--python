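"""Simulate the two-regime wheat panel used by the downstream analyses.

64 genotypes x 2 replicates under fully irrigated (FI) and water-stressed
(WS) regimes, traits drawn to the published per-regime ranges/means, one
canopy spectrum (350-2500 nm) per plot at anthesis (AN) and grain filling
(GF).  The full-resolution spectra table is ~10 MB, so the scene lands in
scratch/scene/ (regenerable from the seed); downstream drivers regenerate
the scene in memory rather than reading these files.
"""

from pathlib import Path

import spectraits as st

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "scratch" / "scene"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    spectra, traits = st.make_benchmark_fixture(seed=SEED)
    st.write_spectra(spectra, OUT / "spectra.csv", float_format="%.6g")
    st.write_traits(traits, OUT / "traits.csv")

    gy = traits.get("GY", "m")
    print(f"scene: {len(spectra)} spectra, {len(traits)} trait records")
    for env in ("FI", "WS"):
        sub = gy.filter(like=f"_{env}")
        print(f"  GY {env}: range {sub.min():.1f}-{sub.max():.1f} t/ha, "
              f"mean {sub.mean():.1f}")
    print(f"wrote {OUT / 'spectra.csv'} and {OUT / 'traits.csv'}")


if __name__ == "__main__":
    main()
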