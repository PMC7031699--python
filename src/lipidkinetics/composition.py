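"""Membrane composition and system configuration.

An in vivo-mimetic plasma-membrane model is described by an asymmetric
two-leaflet mole-fraction table over ten lipid species.  Each species
carries the rule used to reduce its coarse-grained bead model to a single
representative point for in-plane analyses: glycerophospholipids are
represented by the midpoint of the two glycerol beads (GL1/GL2),
sphingolipids and glycolipids by the midpoint of the sphingosine backbone
beads (AM1/AM2), and cholesterol by its hydroxyl bead (ROH).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "LipidSpecies",
    "MembraneComposition",
    "SystemConfig",
    "build_default_composition",
    "default_species_table",
    "validate_composition",
    "realize_counts",
    "composition_to_yaml",
    "composition_from_yaml",
]

LIPID_CLASSES = frozenset(
    {"glycerophospholipid", "sphingolipid", "glycolipid", "sterol", "phosphoinositide"}
)

#: bead-reduction rule per lipid class (named-bead(NAME) also accepted)
BEAD_RULES = frozenset({"glycerol-midpoint", "sphingosine-midpoint", "hydroxyl-bead"})


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species with its representative-bead reduction rule.

    Parameters
    ----------
    name : str
        Short identifier, unique within a composition (e.g. ``"POPC"``).
    lipid_class : str
        One of ``glycerophospholipid``, ``sphingolipid``, ``glycolipid``,
        ``sterol``, ``phosphoinositide``.
    representative_bead_rule : str
        ``glycerol-midpoint``, ``sphingosine-midpoint``, ``hydroxyl-bead``
        or ``named-bead(NAME)``.
    charge : int
        Net head-group charge in elementary charges.
    """

    name: str
    lipid_class: str
    representative_bead_rule: str
    charge: int = 0

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        rule = self.representative_bead_rule
        if rule not in BEAD_RULES and not (
            rule.startswith("named-bead(") and rule.endswith(")")
        ):
            raise ValueError(f"unknown representative-bead rule {rule!r}")

    def representative_bead_names(self) -> tuple[str, ...]:
        """Bead names the rule resolves to (one or two beads)."""
        rule = self.representative_bead_rule
        if rule == "glycerol-midpoint":
            return ("GL1", "GL2")
        if rule == "sphingosine-midpoint":
            return ("AM1", "AM2")
        if rule == "hydroxyl-bead":
            return ("ROH",)
        return (rule[len("named-bead(") : -1],)


@dataclass
class MembraneComposition:
    """Per-leaflet species -> mole-fraction table.

    Fractions are stored as mole fractions (not percentages); each leaflet
    must sum to 1 within 1e-9.  A species present in both leaflets (e.g.
    cholesterol) is one species; leaflet membership of individual molecules
    is dynamic and handled by the leaflet-assignment stage.
    """

    species: dict[str, LipidSpecies]
    upper: dict[str, float]
    lower: dict[str, float]

    def leaflet(self, name: str) -> dict[str, float]:
        if name not in ("upper", "lower"):
            raise KeyError(name)
        return self.upper if name == "upper" else self.lower

    def all_species_names(self) -> list[str]:
        pooled = set(self.upper) | set(self.lower)
        return sorted(pooled)


@dataclass
class SystemConfig:
    """Global system parameters shared by the generator and the analyses."""

    box_nm: tuple[float, float, float] = (17.0, 17.0, 18.0)
    temperature_K: float = 323.0
    salt_M: float = 0.15
    frame_stride_ns: float = 1.0
    total_time_us: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.box_nm):
            raise ValueError("box lengths must be positive")
        if not (0 < self.frame_stride_ns <= self.total_time_us * 1e3):
            raise ValueError("require total_time >= frame_stride > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.total_time_us * 1e3 / self.frame_stride_ns)) + 1


def default_species_table() -> dict[str, LipidSpecies]:
    """The ten species of the in vivo-mimetic bilayer with their bead rules."""
    make = LipidSpecies
    return {
        s.name: s
        for s in (
            make("POPC", "glycerophospholipid", "glycerol-midpoint", 0),
            make("DOPC", "glycerophospholipid", "glycerol-midpoint", 0),
            make("POPE", "glycerophospholipid", "glycerol-midpoint", 0),
            make("DOPE", "glycerophospholipid", "glycerol-midpoint", 0),
            make("Sph", "sphingolipid", "sphingosine-midpoint", 0),
            make("GM3", "glycolipid", "sphingosine-midpoint", -1),
            make("POPS", "glycerophospholipid", "glycerol-midpoint", -1),
            make("DOPS", "glycerophospholipid", "glycerol-midpoint", -1),
            make("PIP2", "phosphoinositide", "glycerol-midpoint", -5),
            make("CHOL", "sterol", "hydroxyl-bead", 0),
        )
    }


def build_default_composition() -> MembraneComposition:
    """The asymmetric ten-species plasma-membrane mimetic.

    Upper (extracellular) leaflet: POPC 20%, DOPC 20%, POPE 5%, DOPE 5%,
    Sph 15%, GM3 10%, Chol 25%.  Lower (cytoplasmic) leaflet: POPC 5%,
    DOPC 5%, POPE 20%, DOPE 20%, POPS 8%, DOPS 7%, PIP2 10%, Chol 25%.
    """
    upper = {
        "POPC": 0.20,
        "DOPC": 0.20,
        "POPE": 0.05,
        "DOPE": 0.05,
        "Sph": 0.15,
        "GM3": 0.10,
        "CHOL": 0.25,
    }
    lower = {
        "POPC": 0.05,
        "DOPC": 0.05,
        "POPE": 0.20,
        "DOPE": 0.20,
        "POPS": 0.08,
        "DOPS": 0.07,
        "PIP2": 0.10,
        "CHOL": 0.25,
    }
    return MembraneComposition(species=default_species_table(), upper=upper, lower=lower)


def validate_composition(c: MembraneComposition) -> list[str]:
    """Check composition invariants; violations are returned, not raised.

    Each violation string names the leaflet, the species and the rule that
    failed.  An empty list means the composition is valid.
    """
    violations: list[str] = []
    for leaflet_name in ("upper", "lower"):
        table = c.leaflet(leaflet_name)
        for name, frac in table.items():
            if frac < 0:
                violations.append(
                    f"{leaflet_name}/{name}: fraction {frac} violates non-negativity"
                )
            if name not in c.species:
                violations.append(
                    f"{leaflet_name}/{name}: species not defined in species table"
                )
        total = sum(table.values())
        if not math.isclose(total, 1.0, rel_tol=0.0, abs_tol=1e-9):
            violations.append(
                f"{leaflet_name}/*: fractions sum to {total!r}, violates sum-to-1"
            )
    return violations


def realize_counts(
    c: MembraneComposition, n_upper: int, n_lower: int
) -> dict[str, dict[str, int]]:
    """Discretize leaflet fractions into molecule counts.

    Largest-remainder rounding with alphabetical tie-break: each species
    gets floor(fraction*n); the remaining molecules go to the species with
    the largest fractional remainders, ties resolved by species name.
    Per-leaflet counts sum exactly to the requested totals.
    """
    if n_upper <= 0 or n_lower <= 0:
        raise ValueError("leaflet molecule counts must be positive")
    out: dict[str, dict[str, int]] = {}
    for leaflet_name, n in (("upper", n_upper), ("lower", n_lower)):
        table = c.leaflet(leaflet_name)
        if not table:
            raise ValueError(f"{leaflet_name} leaflet has no species")
        names = sorted(table)
        quotas = [table[s] * n for s in names]
        counts = [int(math.floor(q)) for q in quotas]
        short = n - sum(counts)
        remainders = sorted(
            range(len(names)), key=lambda i: (-(quotas[i] - counts[i]), names[i])
        )
        for i in remainders[:short]:
            counts[i] += 1
        out[leaflet_name] = dict(zip(names, counts))
    return out


# ---------------------------------------------------------------------------
# YAML serialization.  The file stores fractions with an explicit units key;
# percentages are accepted on read and converted.

def composition_to_yaml(
    c: MembraneComposition, path: str | Path | None = None
) -> str:
    doc = {
        "units": "fraction",
        "species": {
            name: {
                "class": sp.lipid_class,
                "representative_bead_rule": sp.representative_bead_rule,
                "charge": sp.charge,
            }
            for name, sp in sorted(c.species.items())
        },
        "leaflets": {
            "upper": {k: c.upper[k] for k in sorted(c.upper)},
            "lower": {k: c.lower[k] for k in sorted(c.lower)},
        },
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def composition_from_yaml(source: str | Path) -> MembraneComposition:
    text = Path(source).read_text() if isinstance(source, Path) else source
    if isinstance(source, str) and "\n" not in source and Path(source).exists():
        text = Path(source).read_text()
    doc = yaml.safe_load(text)
    units = doc.get("units", "fraction")
    scale = 0.01 if units in ("percent", "percentage", "%") else 1.0
    species = {
        name: LipidSpecies(
            name=name,
            lipid_class=entry["class"],
            representative_bead_rule=entry["representative_bead_rule"],
            charge=int(entry.get("charge", 0)),
        )
        for name, entry in doc["species"].items()
    }
    leaflets: Mapping[str, Mapping[str, float]] = doc["leaflets"]
    upper = {k: float(v) * scale for k, v in leaflets["upper"].items()}
    lower = {k: float(v) * scale for k, v in leaflets["lower"].items()}
    return MembraneComposition(species=species, upper=upper, lower=lower)
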