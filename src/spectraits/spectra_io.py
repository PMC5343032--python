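"""Reading, validating and manipulating canopy reflectance spectra and trait tables.

A :class:`SpectraMatrix` holds one row per plot observation and one column per
wavelength (integer nm on a strictly increasing 1-nm grid inside 350–2500 nm),
with reflectance stored as a fraction in [0, 1].  A :class:`TraitTable` holds
the agronomic / physiological trait measurements keyed to the same plot
observations, in long format, each value tagged with its measurement stage
(``an`` anthesis, ``gf`` grain filling, ``m`` maturity).

Field spectroradiometer exports use either fractional or percent reflectance;
percent files are auto-detected (maximum value > 1.5) and rescaled with a
logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateSpectrumError,
    FormatError,
    ParseError,
)

logger = logging.getLogger(__name__)

WAVELENGTH_MIN = 350
WAVELENGTH_MAX = 2500

#: metadata columns expected at the front of a spectra file, in order
META_COLUMNS = ("observation_id", "genotype_id", "environment", "stage")

ENVIRONMENTS = ("FI", "WS")
SPECTRA_STAGES = ("AN", "GF")
TRAIT_STAGES = ("an", "gf", "m")
TRAITS = ("SM2", "KPS", "TKW", "GY", "Chl", "WSC", "WSCC", "D13C", "LAI")

#: default noise-deletion regions (nm, inclusive): detector edges and the
#: atmospheric water-vapour windows of field ASD-class instruments
DEFAULT_NOISE_REGIONS = ((350, 399), (1350, 1480), (1800, 1980), (2401, 2500))


@dataclass
class ReadOptions:
    """Dialect settings for :func:`read_spectra`.

    strict
        Reject out-of-range reflectance with a :class:`ParseError` naming the
        offending cell; when False, out-of-range cells become NaN.
    percent_autoscale
        Divide by 100 when the table maximum exceeds 1.5 (percent convention).
    """

    strict: bool = True
    percent_autoscale: bool = True
    sep: str = ","


@dataclass
class SpectraMatrix:
    """Plot-observation x wavelength reflectance table with plot metadata.

    ``meta`` is indexed by ``observation_id`` with columns ``genotype_id``,
    ``environment`` and ``stage``; ``reflectance`` shares the same index and
    has integer-nm columns.
    """

    meta: pd.DataFrame
    reflectance: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- container protocol ------------------------------------------------
    @property
    def wavelengths(self) -> np.ndarray:
        return self.reflectance.columns.to_numpy(dtype=int)

    @property
    def observation_ids(self) -> pd.Index:
        return self.reflectance.index

    @property
    def n_observations(self) -> int:
        return len(self.reflectance)

    def __len__(self) -> int:
        return self.n_observations

    def band(self, nm: int) -> pd.Series:
        """Reflectance at one wavelength for every observation."""
        if nm not in self.reflectance.columns:
            raise KeyError(f"wavelength {nm} nm not on the grid")
        return self.reflectance[nm]

    def select(self, mask) -> "SpectraMatrix":
        """Row subset by boolean mask or index list; metadata kept aligned."""
        return SpectraMatrix(self.meta.loc[mask].copy(), self.reflectance.loc[mask].copy())

    def validate(self) -> None:
        wl = self.reflectance.columns.to_numpy()
        try:
            wl = wl.astype(int)
        except (TypeError, ValueError) as exc:  # pragma: no cover - defensive
            raise FormatError(f"non-integer wavelength labels: {exc}") from exc
        if len(wl) == 0:
            raise DegenerateSpectrumError("empty wavelength grid")
        if np.any(np.diff(wl) <= 0):
            raise FormatError("wavelength grid is not strictly increasing")
        if wl[0] < WAVELENGTH_MIN or wl[-1] > WAVELENGTH_MAX:
            raise FormatError(
                f"wavelengths outside [{WAVELENGTH_MIN}, {WAVELENGTH_MAX}] nm"
            )
        if not self.meta.index.equals(self.reflectance.index):
            raise FormatError("meta and reflectance indexes differ")
        if self.reflectance.index.has_duplicates:
            dupes = self.reflectance.index[self.reflectance.index.duplicated()]
            raise FormatError(f"duplicate observation_id: {list(dupes[:5])}")
        vals = self.reflectance.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ParseError("reflectance outside [0, 1] after validation")


@dataclass
class TraitTable:
    """Long-format trait measurements keyed by plot observation.

    Columns: ``observation_id, trait, measurement_stage, value``.  Missing
    measurements are simply absent rows, never sentinel-coded.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["observation_id", "trait", "measurement_stage", "value"]))

    def __post_init__(self) -> None:
        required = ["observation_id", "trait", "measurement_stage", "value"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"trait table missing columns {missing}")
        self.data = self.data.loc[:, required].reset_index(drop=True)
        key = self.data[["observation_id", "trait", "measurement_stage"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise FormatError(f"duplicate trait entry {tuple(dup)}")
        vals = pd.to_numeric(self.data["value"], errors="coerce")
        if vals.isna().any() and self.data["value"].notna().any():
            bad = self.data.loc[vals.isna() & self.data["value"].notna()]
            if len(bad):
                raise ParseError(f"non-numeric trait value in rows {bad.index[:5].tolist()}")
        if not np.isfinite(vals.dropna()).all():
            raise ParseError("non-finite trait value")
        self.data["value"] = vals

    def get(self, trait: str, stage: str) -> pd.Series:
        """Values of one (trait, measurement stage), indexed by observation_id."""
        sub = self.data[(self.data["trait"] == trait)
                        & (self.data["measurement_stage"] == stage)]
        return sub.set_index("observation_id")["value"]

    def traits(self) -> list[tuple[str, str]]:
        pairs = self.data[["trait", "measurement_stage"]].drop_duplicates()
        return [tuple(r) for r in pairs.itertuples(index=False)]

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# file I/O


def read_spectra(path, options: ReadOptions | None = None) -> SpectraMatrix:
    """Read a delimited spectra table into a validated :class:`SpectraMatrix`.

    Expected header: ``observation_id,genotype_id,environment,stage,350,351,...``
    Wavelength labels are parsed to integer nm and must be strictly increasing.
    """
    opts = options or ReadOptions()
    df = pd.read_csv(path, sep=opts.sep, dtype=str)
    cols = list(df.columns)
    n_meta = len(META_COLUMNS)
    if cols[:n_meta] != list(META_COLUMNS):
        raise FormatError(
            f"expected leading columns {META_COLUMNS}, got {cols[:n_meta]}")
    wl_labels = cols[n_meta:]
    if not wl_labels:
        raise FormatError("no wavelength columns")
    try:
        wl = [int(w) for w in wl_labels]
    except ValueError as exc:
        raise FormatError(f"non-integer wavelength label: {exc}") from exc
    if any(b - a <= 0 for a, b in zip(wl, wl[1:])):
        raise FormatError("wavelength labels not strictly increasing")

    meta = df.iloc[:, :n_meta].set_index("observation_id")
    refl = df.iloc[:, n_meta:].copy()
    refl.columns = wl
    refl.index = meta.index

    numeric = refl.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & refl.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric reflectance at observation "
            f"{refl.index[r]!r}, {wl[c]} nm", row=refl.index[r], column=wl[c])

    vals = numeric.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if opts.percent_autoscale and finite.size and finite.max() > 1.5:
        logger.warning("reflectance maximum %.3g > 1.5: assuming percent scale, "
                       "dividing by 100", finite.max())
        numeric = numeric / 100.0
        vals = numeric.to_numpy(dtype=float)

    out_of_range = (vals < 0.0) | (vals > 1.0)
    out_of_range &= np.isfinite(vals)
    if out_of_range.any():
        if opts.strict:
            r, c = np.argwhere(out_of_range)[0]
            raise ParseError(
                f"reflectance {vals[r, c]:g} outside [0, 1] at observation "
                f"{numeric.index[r]!r}, {wl[c]} nm",
                row=numeric.index[r], column=wl[c])
        numeric = numeric.mask(pd.DataFrame(out_of_range, index=numeric.index,
                                            columns=numeric.columns))
        logger.warning("masked %d out-of-range reflectance cells", out_of_range.sum())

    return SpectraMatrix(meta=meta, reflectance=numeric)


def write_spectra(m: SpectraMatrix, path, sep: str = ",", float_format: str = "%.17g") -> None:
    """Write a :class:`SpectraMatrix` in the layout :func:`read_spectra` expects."""
    out = pd.concat([m.meta, m.reflectance], axis=1)
    out.index.name = "observation_id"
    out.to_csv(path, sep=sep, float_format=float_format)


def read_traits(path, sep: str = ",") -> TraitTable:
    """Read a long-format trait table (``observation_id,trait,measurement_stage,value``)."""
    df = pd.read_csv(path, sep=sep)
    return TraitTable(df)


def write_traits(t: TraitTable, path, sep: str = ",") -> None:
    t.data.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# spectra operations


def average_scans(scans: SpectraMatrix, group_key: str | None = None) -> SpectraMatrix:
    """Average repeated scans per plot (arithmetic mean per wavelength).

    ``group_key`` is a meta column naming the group; by default rows are
    grouped by their ``observation_id`` index (repeated ids = repeated scans).
    Idempotent on already-averaged matrices.
    """
    refl = scans.reflectance
    meta = scans.meta
    if group_key is None:
        groups = refl.index
    else:
        if group_key not in meta.columns:
            raise AlignmentError(f"unknown group column {group_key!r}")
        groups = meta[group_key]
    averaged = refl.groupby(groups, sort=False).mean()
    meta_first = meta.groupby(groups, sort=False).first()
    averaged.index.name = "observation_id"
    meta_first.index.name = "observation_id"
    return SpectraMatrix(meta=meta_first, reflectance=averaged)


def stack_scans(scans: list[SpectraMatrix]) -> SpectraMatrix:
    """Concatenate scan matrices that share one wavelength grid."""
    if not scans:
        raise AlignmentError("no scan matrices given")
    wl0 = scans[0].wavelengths
    for s in scans[1:]:
        if not np.array_equal(s.wavelengths, wl0):
            raise AlignmentError("scan matrices have mismatched wavelength grids")
    meta = pd.concat([s.meta for s in scans])
    refl = pd.concat([s.reflectance for s in scans])
    out = SpectraMatrix.__new__(SpectraMatrix)  # skip duplicate-id validation
    out.meta = meta
    out.reflectance = refl
    return out


def trim_noise_bands(m: SpectraMatrix,
                     regions=DEFAULT_NOISE_REGIONS) -> SpectraMatrix:
    """Drop wavelengths inside any [lo, hi] nm region (inclusive ends).

    Pure column selection: retained reflectance values and all metadata are
    unchanged.  Removing every band raises :class:`DegenerateSpectrumError`.
    """
    wl = m.wavelengths
    keep = np.ones(len(wl), dtype=bool)
    for lo, hi in regions:
        if lo > hi:
            raise ValueError(f"noise region [{lo}, {hi}] has lo > hi")
        if lo < WAVELENGTH_MIN or hi > WAVELENGTH_MAX:
            raise ValueError(f"noise region [{lo}, {hi}] outside the spectral range")
        keep &= ~((wl >= lo) & (wl <= hi))
    if not keep.any():
        raise DegenerateSpectrumError("noise regions removed every wavelength")
    return SpectraMatrix(meta=m.meta.copy(),
                         reflectance=m.reflectance.loc[:, wl[keep]].copy())


def align(spectra: SpectraMatrix, trait_values: pd.Series,
          stage: str | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Join spectra rows with trait values on the plot observation key.

    Spectra observation ids either equal the trait plot ids directly, or carry
    an ``@STAGE`` suffix (the synthetic generator's convention for one spectrum
    per plot per assessment stage).  Returns (X, y) restricted to the common
    observations, X indexed by spectra observation id.
    """
    m = spectra if stage is None else spectra.select(
        (spectra.meta["stage"] == stage).to_numpy())
    ids = m.observation_ids
    plot_of = {oid: (oid.rsplit("@", 1)[0] if "@" in str(oid) else oid)
               for oid in ids}
    keep = [oid for oid in ids if plot_of[oid] in trait_values.index]
    X = m.reflectance.loc[keep]
    y = pd.Series([trait_values[plot_of[o]] for o in keep], index=keep,
                  name=trait_values.name)
    return X, y
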