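"""Spectral reflectance index (SRI) registry and bulk evaluator.

An SRI is a scalar combination of reflectance at a handful of wavelengths,
``R_lambda`` denoting reflectance at ``lambda`` nm.  Three kinds exist here:

* ``normalized_difference`` — (Ra − Rb)/(Ra + Rb) for an ordered pair (a; b),
  the NDSI/NDWI/NDTI/PRI/NRI/RE family;
* ``ratio`` — Ra/Rb, the SR/WI/CI/RBI family;
* ``expression`` — an explicit formula over ``R`` symbols (MTCI, SAVI2,
  TCARI variants, DATT, MCARI, SIPI, WDVI, BI, AI, PRI*CI, ...).

Expressions are plain text (e.g. ``1.5*(R807 - R736)/(R807 + R736 + 0.5)``)
compiled once with sympy, so a registry round-trips through a simple
line-oriented text format and users can extend it toward larger index sets
with the :func:`ndsi` / :func:`sr` constructors.

Undefined evaluations (zero denominators) become NaN rather than exceptions so
that downstream screening keeps running on degenerate spectra.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sympy

from .errors import FormatError
from .spectra_io import WAVELENGTH_MAX, WAVELENGTH_MIN, SpectraMatrix

logger = logging.getLogger(__name__)

KINDS = ("normalized_difference", "ratio", "expression")

_R_SYMBOL = re.compile(r"^R(\d{3,4})$")


@dataclass(frozen=True)
class IndexDefinition:
    """A named spectral reflectance index.

    ``wavelengths`` is the ordered nm list the formula refers to; for the
    two-band kinds the formula is implied by the pair order.  ``note`` records
    provenance for indices instantiated from their standard literature forms.
    """

    name: str
    kind: str
    wavelengths: tuple[int, ...]
    expression: str | None = None
    note: str = ""
    _func: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown index kind {self.kind!r}")
        for nm in self.wavelengths:
            if not (WAVELENGTH_MIN <= nm <= WAVELENGTH_MAX):
                raise ValueError(f"{self.name}: wavelength {nm} nm out of range")
        if self.kind in ("normalized_difference", "ratio"):
            if len(self.wavelengths) != 2:
                raise ValueError(f"{self.name}: {self.kind} needs exactly 2 bands")
        if self.kind == "expression":
            if not self.expression:
                raise ValueError(f"{self.name}: expression kind without expression")
            object.__setattr__(self, "_func", _compile(self.expression, self.wavelengths))

    def evaluate(self, bands: dict[int, np.ndarray | float]):
        """Evaluate on reflectance arrays/scalars keyed by wavelength."""
        if self.kind == "normalized_difference":
            a, b = self.wavelengths
            num = bands[a] - bands[b]
            den = bands[a] + bands[b]
            return _safe_divide(num, den)
        if self.kind == "ratio":
            a, b = self.wavelengths
            return _safe_divide(bands[a], bands[b])
        args = [bands[nm] for nm in self.wavelengths]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self._func(*args)
        return _nan_nonfinite(out)


def _safe_divide(num, den):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(num, dtype=float) / np.asarray(den, dtype=float)
    return _nan_nonfinite(out)


def _nan_nonfinite(out):
    out = np.asarray(out, dtype=float)
    if out.ndim == 0:
        return float(out) if np.isfinite(out) else float("nan")
    out[~np.isfinite(out)] = np.nan
    return out


def _compile(expression: str, wavelengths: tuple[int, ...]):
    symbols = [sympy.Symbol(f"R{nm}") for nm in wavelengths]
    expr = sympy.sympify(expression, rational=False)
    free = {str(s) for s in expr.free_symbols}
    declared = {f"R{nm}" for nm in wavelengths}
    if not free <= declared:
        raise ValueError(f"expression uses undeclared bands {sorted(free - declared)}")
    return sympy.lambdify(symbols, expr, modules="numpy")


# ---------------------------------------------------------------------------
# constructors for the generic two-band families


def ndsi(a: int, b: int, name: str | None = None, note: str = "") -> IndexDefinition:
    """Normalized-difference index (Ra − Rb)/(Ra + Rb)."""
    return IndexDefinition(name or f"NDSI({a};{b})", "normalized_difference",
                           (a, b), note=note)


def sr(a: int, b: int, name: str | None = None, note: str = "") -> IndexDefinition:
    """Simple-ratio index Ra/Rb."""
    return IndexDefinition(name or f"SR({a};{b})", "ratio", (a, b), note=note)


def expression_index(name: str, expression: str, wavelengths,
                     note: str = "") -> IndexDefinition:
    return IndexDefinition(name, "expression", tuple(wavelengths), expression, note)


# ---------------------------------------------------------------------------
# built-in registry


def _nd(name, a, b, note=""):
    return IndexDefinition(name, "normalized_difference", (a, b), note=note)


def _ratio(name, a, b, note=""):
    return IndexDefinition(name, "ratio", (a, b), note=note)


_LIT = "standard literature form at the cited bands"


def builtin_registry() -> list[IndexDefinition]:
    """Every index referenced by the benchmark report, with printed or
    standard-literature formulas instantiated at the cited wavelengths."""
    defs = [
        # water indices (NIR bands, canopy hydration)
        _nd("NWI-3", 970, 920),
        _ratio("WI2", 970, 900),
        _ratio("WI(950;900)", 950, 900),
        _ratio("WI(900;970)", 900, 970),
        _ratio("WI(970;900)", 970, 900),
        _nd("NDWI(970;920)", 970, 920),
        _nd("NDWI(970;850)", 970, 850),
        _nd("NDWI(870;1260)", 870, 1260),
        # chlorophyll / red edge
        expression_index("MTCI", "(R800 - R750)/(R750 - R670)", (800, 750, 670)),
        expression_index(
            "TCARI2",
            "3*((R700 - R600) - (0.2*(R700 - R550))*(R700/(R850 + R670)))",
            (700, 600, 550, 850, 670)),
        expression_index(
            "TCARI", "3*((R700 - R670) - 0.2*(R700 - R550)*(R700/R670))",
            (700, 670, 550), note=_LIT),
        expression_index(
            "MCARI", "((R700 - R670) - 0.2*(R700 - R550))*(R700/R670)",
            (700, 670, 550), note=_LIT),
        expression_index("DATT", "(R850 - R710)/(R850 - R680)", (850, 710, 680)),
        _nd("PRI(550;531)", 550, 531, note=_LIT),
        _nd("PRI(512;531)", 512, 531, note=_LIT),
        _nd("NRI", 1510, 660, note=_LIT),
        _nd("RE", 780, 670, note="red-edge normalized difference; " + _LIT),
        expression_index("SIPI", "(R800 - R440)/(R800 - R680)", (800, 440, 680),
                         note=_LIT),
        expression_index(
            "PRI*CI",
            "((R530 - R570)/(R530 + R570))*(R760/R700 - 1)",
            (570, 530, 760, 700),
            note="Garbulsky-style product of PRI(570;530) and CI(760;700)"),
        # structure / soil-adjusted
        expression_index("SAVI2", "1.5*(R807 - R736)/(R807 + R736 + 0.5)",
                         (807, 736)),
        expression_index("SAVI2(800;670)", "1.5*(R800 - R670)/(R800 + R670 + 0.5)",
                         (800, 670)),
        expression_index("WDVI", "R830 - 1.06*R660", (830, 660),
                         note="weighted difference VI, soil-line slope 1.06; " + _LIT),
        expression_index("BI", "sqrt((R460**2 + R660**2)/2)", (460, 660),
                         note="brightness index; " + _LIT),
        expression_index("AI", "(R740 - R691) - (R887 - R698)",
                         (740, 887, 691, 698),
                         note="double-difference form; " + _LIT),
        # generic normalized differences named in the report
        _nd("NDSI(403;830)", 403, 830),
        _nd("NDSI(543;548)", 543, 548),
        _nd("NDSI(933;948)", 933, 948),
        _nd("NDSI(410;550)", 410, 550),
        _nd("NDSI(1060;1118)", 1060, 1118),
        _nd("NDSI(940;1122)", 940, 1122),
        _nd("NDSI(442;438)", 442, 438),
        _nd("NDSI(503;483)", 503, 483),
        _nd("NDTI(1650;2215)", 1650, 2215, note=_LIT),
        # generic ratios named in the report
        _ratio("SR(550;670)", 550, 670),
        _ratio("SR(690;655)", 690, 655),
        _ratio("SR(960;950)", 960, 950),
        _ratio("SR(440;685)", 440, 685),
        _ratio("CI(415;695)", 415, 695),
        _ratio("RBI(695;445)", 695, 445),
    ]
    names = [d.name for d in defs]
    if len(set(names)) != len(names):  # pragma: no cover - registry bug guard
        raise ValueError("duplicate names in builtin registry")
    return defs


# how the benchmark report spells index references -> registry names
_ALIASES = {
    "SAVI": "SAVI2",
    "SAVI 2": "SAVI2(800;670)",
    "SAVI2": "SAVI2",
    "DATT": "DATT",
    "Datt": "DATT",
    "PRI * CI": "PRI*CI",
    "PRI*CI": "PRI*CI",
    "MTCI": "MTCI",
    "TCARI": None,  # arity-dependent, resolved below
    "NWI-3": "NWI-3",
    "WI2": "WI2",
}


def resolve(registry: list[IndexDefinition], reference: str) -> IndexDefinition:
    """Look up a report-style reference like ``"NDSI (403;830)"`` or ``"NWI-3"``.

    Family references resolve through their wavelength signature, so both
    ``"TCARI (700;670;550)"`` and ``"TCARI (700;600;550;850;670)"`` find the
    right entry.
    """
    by_name = {d.name: d for d in registry}
    ref = reference.strip()
    if ref in by_name:
        return by_name[ref]
    m = re.match(r"^(.*?)\s*\(([\d;\s]+)\)$", ref)
    if not m:
        if ref in _ALIASES and _ALIASES[ref] in by_name:
            return by_name[_ALIASES[ref]]
        raise KeyError(f"no index definition for {reference!r}")
    family = m.group(1).strip()
    bands = tuple(int(x) for x in re.split(r"[;\s]+", m.group(2).strip()) if x)
    canonical = _ALIASES.get(family, family)
    candidates = [f"{canonical}({';'.join(map(str, bands))})" if canonical else None,
                  f"{family}({';'.join(map(str, bands))})",
                  canonical, family]
    for cand in candidates:
        if cand and cand in by_name:
            d = by_name[cand]
            if set(bands) <= set(d.wavelengths) or d.wavelengths == bands:
                return d
    # last resort: any entry of this family (prefix match, so "TCARI" finds
    # the five-band TCARI2 variant) with the same band signature
    for d in registry:
        base = d.name.split("(")[0]
        if any(base.startswith(f) for f in (family, canonical) if f) \
                and set(d.wavelengths) == set(bands):
            return d
    raise KeyError(f"no index definition for {reference!r}")


# ---------------------------------------------------------------------------
# evaluation


def compute_index(spectrum: pd.Series | dict, d: IndexDefinition) -> float:
    """Evaluate one index on a single spectrum (Series indexed by nm).

    Raises KeyError naming the nm for a band missing from the grid; a zero
    denominator yields NaN (undefined, not an error).
    """
    bands = {}
    for nm in d.wavelengths:
        if nm not in spectrum:
            raise KeyError(f"band {nm} nm unavailable for index {d.name}")
        bands[nm] = float(spectrum[nm])
    return float(d.evaluate(bands))


def compute_all(m: SpectraMatrix,
                registry: list[IndexDefinition] | None = None) -> pd.DataFrame:
    """Evaluate every registry index on every observation.

    Returns an observation x index DataFrame in registry order.  An index
    whose bands were trimmed from the grid yields an all-NaN column plus a
    logged warning; undefined evaluations are NaN.
    """
    registry = builtin_registry() if registry is None else registry
    grid = set(int(w) for w in m.wavelengths)
    out = {}
    for d in registry:
        missing = [nm for nm in d.wavelengths if nm not in grid]
        if missing:
            logger.warning("index %s needs trimmed band(s) %s nm; column is all-missing",
                           d.name, missing)
            out[d.name] = np.full(m.n_observations, np.nan)
            continue
        bands = {nm: m.band(nm).to_numpy(dtype=float) for nm in d.wavelengths}
        out[d.name] = d.evaluate(bands)
    return pd.DataFrame(out, index=m.observation_ids)


# ---------------------------------------------------------------------------
# registry text format: one record per line, pipe-separated


def save_registry(registry: list[IndexDefinition], path) -> None:
    with open(path, "w") as fh:
        fh.write("# name | kind | wavelengths | expression | note\n")
        for d in registry:
            wl = ";".join(str(w) for w in d.wavelengths)
            fh.write(f"{d.name} | {d.kind} | {wl} | {d.expression or ''} | {d.note}\n")


def load_registry(path) -> list[IndexDefinition]:
    defs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("|")]
            if len(parts) != 5:
                raise FormatError(f"registry line {lineno}: expected 5 fields")
            name, kind, wl, expr, note = parts
            wavelengths = tuple(int(x) for x in wl.split(";") if x)
            defs.append(IndexDefinition(name, kind, wavelengths,
                                        expr or None, note))
    return defs
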