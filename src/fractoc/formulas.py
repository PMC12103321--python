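"""Empirical-formula arithmetic and the material registry.

A liquid TOC analyzer reports carbon, not polymer, so every conversion
between a measured organic-carbon concentration and a particle mass
concentration goes through the carbon mass fraction of the material:
``w_C = 12.011 * nC / M`` for a repeat unit or compound of molar mass
``M``.  Polystyrene, for example, is (C8H8)_n and carries 92.26 % carbon
by mass; potassium hydrogen phthalate (the TC calibrant) carries 47.05 %
and sodium carbonate (the TIC calibrant) 11.33 %.

The registry ships the materials used throughout the package (PS, PE,
PP, PVC, PET, cellulose and the two calibrants) as a versioned JSON
resource.  Polyolefin repeat units are modeled as (CH2)_n / (C3H6)_n,
PVC as (C2H3Cl)_n, PET as (C10H8O4)_n and cellulose as anhydroglucose
(C6H10O5)_n.  Gold doping of in-house PE/PP/PVC particles is ignored in
the carbon-fraction math (the dopant mass fraction is not specified);
this is a documented limitation, as are copolymers and surfactant
carbon.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "ATOMIC_WEIGHTS",
    "FormulaError",
    "PolymerSpec",
    "parse_formula",
    "molar_mass",
    "carbon_mass_fraction",
    "registry",
    "get_material",
]

# IUPAC 2021 conventional atomic weights, 5 significant figures.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Ti": 47.867,
    "Mn": 54.938,
    "Fe": 55.845,
    "Cu": 63.546,
    "Zn": 65.38,
    "Br": 79.904,
    "I": 126.90,
    "Au": 196.97,
}


class FormulaError(ValueError):
    """Malformed or chemically unusable empirical formula."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation empirical formula into an element→count map.

    Counts default to 1 (``"Na2CO3"`` → ``{"Na": 2, "C": 1, "O": 3}``).
    Underscores and whitespace are tolerated, so subscript-mangled
    strings such as ``"C_8_H_5_KO_4_"`` parse as intended.  Unknown
    element symbols and zero counts are rejected with the offending
    position named.
    """
    cleaned = text.replace("_", "").replace(" ", "")
    if not cleaned:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN.match(cleaned, pos)
        if m is None or not m.group(1):
            raise FormulaError(
                f"malformed token at position {pos} in {text!r}"
            )
        symbol, digits = m.groups()
        if symbol not in ATOMIC_WEIGHTS:
            raise FormulaError(
                f"unknown element {symbol!r} at position {pos} in {text!r}"
            )
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(
                f"count must be >= 1 for {symbol!r} at position {pos}"
            )
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return counts


def molar_mass(formula: dict[str, int]) -> float:
    """Molar mass (g/mol) of an element→count map."""
    try:
        return sum(ATOMIC_WEIGHTS[el] * n for el, n in formula.items())
    except KeyError as exc:  # element without tabulated weight
        raise FormulaError(f"no atomic weight tabulated for {exc}") from None


def carbon_mass_fraction(formula: dict[str, int] | str) -> float:
    """Mass fraction of carbon, in (0, 1], of a formula or formula string."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if formula.get("C", 0) <= 0:
        raise FormulaError("formula contains no carbon")
    return ATOMIC_WEIGHTS["C"] * formula["C"] / molar_mass(formula)


@dataclass(frozen=True)
class PolymerSpec:
    """A material identified by its repeat-unit or compound formula.

    ``carbon_fraction`` is recomputed from the formula and stored at the
    two-decimal-percent precision quoted on calibrant certificates and
    data sheets (92.26 %C for polystyrene, 47.05 %C for potassium
    hydrogen phthalate, ...), which is the value practitioners plug into
    carbon/mass conversions.  ``density`` (g/cm^3) is optional and only
    required for particle mass/sedimentation arithmetic.
    """

    name: str
    formula: tuple[tuple[str, int], ...]
    carbon_fraction: float
    density: float | None = None

    @classmethod
    def from_formula(
        cls, name: str, formula: str | dict[str, int], density: float | None = None
    ) -> "PolymerSpec":
        counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
        return cls(
            name=name,
            formula=tuple(sorted(counts.items())),
            carbon_fraction=round(carbon_mass_fraction(counts), 4),
            density=density,
        )

    @property
    def formula_map(self) -> dict[str, int]:
        return dict(self.formula)


_REGISTRY: dict[str, PolymerSpec] | None = None


def registry() -> dict[str, PolymerSpec]:
    """The bundled material registry, keyed by material name.

    Loaded once from the versioned JSON resource; stored carbon
    fractions are sanity-checked against recomputation at load time.
    """
    global _REGISTRY
    if _REGISTRY is None:
        raw = json.loads(
            resources.files("fractoc.data").joinpath("materials.json").read_text()
        )
        out: dict[str, PolymerSpec] = {}
        for entry in raw["materials"]:
            spec = PolymerSpec.from_formula(
                entry["name"], entry["formula"], entry.get("density")
            )
            stored = entry["carbon_fraction"]
            if abs(stored - spec.carbon_fraction) > 5e-5:
                raise FormulaError(
                    f"registry entry {entry['name']!r}: stored carbon fraction "
                    f"{stored} disagrees with recomputed {spec.carbon_fraction:.6f}"
                )
            out[spec.name] = spec
        _REGISTRY = out
    return _REGISTRY


def get_material(name: str) -> PolymerSpec:
    """Look up a registered material (case-insensitive on the name)."""
    reg = registry()
    if name in reg:
        return reg[name]
    lowered = {k.lower(): v for k, v in reg.items()}
    if name.lower() in lowered:
        return lowered[name.lower()]
    raise KeyError(f"material {name!r} not in registry ({sorted(reg)})")
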