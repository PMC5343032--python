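import numpy as np
import pandas as pd
import pytest

import spectraits as st
from spectraits.spectra_io import SpectraMatrix


@pytest.fixture(scope="session")
def scene():
    """Default synthetic benchmark scene: 64 genotypes x 2 reps x 2 regimes."""
    return st.make_benchmark_fixture(seed=5)


@pytest.fixture(scope="session")
def strided_scene(scene):
    """Noise-trimmed scene thinned to every 4th band for fast model fits."""
    spectra, traits = scene
    trimmed = st.trim_noise_bands(spectra)
    keep = trimmed.wavelengths[::4]
    thin = SpectraMatrix(meta=trimmed.meta.copy(),
                         reflectance=trimmed.reflectance.loc[:, keep].copy())
    return thin, traits


@pytest.fixture(scope="session")
def gy_gf(strided_scene):
    """(X, y) for grain yield at maturity against grain-filling spectra."""
    spectra, traits = strided_scene
    return st.align(spectra, traits.get("GY", "m"), stage="GF")


def make_spectra(values, wavelengths, ids=None, env="FI", stage="AN"):
    """Small hand-built SpectraMatrix for unit tests."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = ids or [f"obs{i}" for i in range(len(values))]
    meta = pd.DataFrame({"genotype_id": [f"g{i}" for i in range(len(values))],
                         "environment": env, "stage": stage},
                        index=pd.Index(ids, name="observation_id"))
    refl = pd.DataFrame(values, index=meta.index, columns=list(wavelengths))
    return SpectraMatrix(meta=meta, reflectance=refl)
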