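"""Seeded generator of synthetic cremation deposits.

The generator emulates the statistical structure a pyre-site deposit is
assumed to have, in three stages:

1. **community** — a small community of successive nuclear families dies
   over several generations; each death is assigned an age/sex class
   (default structure: half subadults, adults split 1:1 by sex) and a
   cremated skeleton mass drawn from a truncated normal around the class
   mean (defaults 2,500 / 1,800 / 500 g);
2. **fragmentation** — each skeleton's mass is split into the recorded
   categories: tooth, < 20 mm (undetermined), > 20 mm cranial and > 20 mm
   post-cranial, with the < 20 mm fraction Beta-distributed around the
   target pooled fragmentation index (default 340, i.e. a mean small-
   fragment fraction of 340/440) and the cranial fraction of the > 20 mm
   mass around ``cranial_fraction`` (default 0.15);
3. **deposition** — an optional collection step removes up to a per-class
   collected mass per individual (largest pieces first: the > 20 mm
   categories are depleted before the < 20 mm and tooth residue), then
   each remaining category is split into lots and scattered around the
   pyre centre by an isotropic 2-D Gaussian, quantised to 25 cm grid
   cells and clipped to the grid edge.

One master seed derives independent per-stage streams, so every stage —
and the composed pipeline — is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .deposit import (
    DEFAULT_CELL_SIZE,
    DEFAULT_N_COLUMNS,
    DEFAULT_ROW_ALPHABET,
    Deposit,
    FragmentRecord,
    SquareID,
    StratumID,
)

#: Per-class cremated-skeleton mass models, grams: (mean, sd).  Means follow
#: regional Bronze Age urn maxima; spreads are a quarter of the modern
#: reference ranges (males 2-3 kg, females 1.5-2.5 kg), subadults scaled
#: proportionally.
DEFAULT_CLASS_MASSES: dict[str, tuple[float, float]] = {
    "adult_male": (2500.0, 250.0),
    "adult_female": (1800.0, 250.0),
    "subadult": (500.0, 125.0),
}


class SimulationError(ValueError):
    """Invalid simulation parameters."""


@dataclass
class SimulationParams:
    """Parameters of the synthetic deposit generator (all stages)."""

    generations: int = 8
    family_size: int = 6
    sex_ratio: float = 0.5           # P(male | adult death)
    subadult_fraction: float = 0.5   # P(subadult | death)
    class_masses: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MASSES)
    )
    assignment: str = "expected"     # 'expected' (deterministic ratios) | 'multinomial'
    fragmentation_target: float = 340.0  # expected pooled index, lt20/ge20*100
    frag_concentration: float = 50.0     # Beta concentration; 0 = no noise
    cranial_fraction: float = 0.15       # expected cranial share of ge20 mass
    cranial_concentration: float = 50.0  # Beta concentration; 0 = no noise
    tooth_fraction: float = 0.008        # tooth share of total mass
    pyre_centre: tuple[str, int] = ("G", 4)
    scatter_sd: float = 0.5              # metres; no published value exists
    n_lots: int = 20                     # lots per individual per category
    collection: Optional[dict[str, float]] = None  # grams removed per individual
    us: int = 11
    row_alphabet: str = DEFAULT_ROW_ALPHABET
    n_columns: int = DEFAULT_N_COLUMNS
    cell_size: float = DEFAULT_CELL_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations <= 0 or self.family_size <= 0:
            raise SimulationError("generations and family size must be positive")
        for p, name in ((self.sex_ratio, "sex_ratio"), (self.subadult_fraction, "subadult_fraction"),
                        (self.cranial_fraction, "cranial_fraction"), (self.tooth_fraction, "tooth_fraction")):
            if not (0.0 <= p <= 1.0):
                raise SimulationError(f"{name} must be in [0, 1], got {p}")
        for name, (mean, sd) in self.class_masses.items():
            if mean <= 0 or sd < 0:
                raise SimulationError(f"class {name}: mean must be > 0 and sd >= 0")
        if self.scatter_sd < 0:
            raise SimulationError("scatter_sd must be >= 0")
        if self.fragmentation_target < 0:
            raise SimulationError("fragmentation_target must be >= 0")
        if self.assignment not in ("expected", "multinomial"):
            raise SimulationError("assignment must be 'expected' or 'multinomial'")
        SquareID(*self.pyre_centre).indices(self.row_alphabet)
        if self.pyre_centre[1] > self.n_columns:
            raise SimulationError("pyre centre outside the declared grid")

    @property
    def n_individuals(self) -> int:
        return self.generations * self.family_size

    def streams(self) -> dict[str, np.random.Generator]:
        """Independent per-stage RNG streams derived from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "community": np.random.default_rng(children[0]),
            "fragmentation": np.random.default_rng(children[1]),
            "spatial": np.random.default_rng(children[2]),
        }


@dataclass(frozen=True)
class DeathRoster:
    """The individuals cremated on site: (class label, skeleton mass in g)."""

    individuals: tuple[tuple[str, float], ...]

    @property
    def total_mass(self) -> float:
        return float(sum(m for _, m in self.individuals))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for label, _ in self.individuals:
            out[label] = out.get(label, 0) + 1
        return out


def _truncated_normal(mean: float, sd: float, size: int,
                      rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    from scipy import stats

    a = (0.0 - mean) / sd  # truncate at zero: masses are positive
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def simulate_community(params: SimulationParams,
                       rng: Optional[np.random.Generator] = None) -> DeathRoster:
    """Generate the death roster: ``generations x family_size`` individuals.

    With ``assignment='expected'`` (default) class counts follow the
    death-structure probabilities deterministically (rounded to integers),
    matching the fixed ratios the budget model assumes; with
    ``'multinomial'`` each death is an independent categorical draw.
    """
    rng = params.streams()["community"] if rng is None else rng
    n = params.n_individuals
    if params.assignment == "expected":
        n_sub = round(n * params.subadult_fraction)
        n_adult = n - n_sub
        n_male = round(n_adult * params.sex_ratio)
        n_female = n_adult - n_male
        labels = (
            ["adult_male"] * n_male + ["adult_female"] * n_female + ["subadult"] * n_sub
        )
    else:
        probs = [
            (1 - params.subadult_fraction) * params.sex_ratio,
            (1 - params.subadult_fraction) * (1 - params.sex_ratio),
            params.subadult_fraction,
        ]
        labels = [
            ("adult_male", "adult_female", "subadult")[k]
            for k in rng.choice(3, size=n, p=probs)
        ]
    individuals = []
    for label in labels:
        mean, sd = params.class_masses[label]
        mass = float(_truncated_normal(mean, sd, 1, rng)[0])
        individuals.append((label, mass))
    return DeathRoster(tuple(individuals))


def _beta_fraction(mean: float, concentration: float,
                   rng: np.random.Generator) -> float:
    if concentration <= 0 or mean in (0.0, 1.0):
        return mean
    return float(rng.beta(mean * concentration, (1 - mean) * concentration))


def fragment_individual(mass: float, params: SimulationParams,
                        rng: Optional[np.random.Generator] = None) -> dict[str, float]:
    """Split one skeleton's mass into the four recorded categories.

    Returns ``{'lt20', 'ge20_cranial', 'ge20_postcranial', 'tooth'}`` masses
    summing exactly to the input.  With the noise concentrations at 0 the
    split is the deterministic expectation: the < 20 mm fraction of the
    non-tooth mass is ``F / (F + 100)`` for fragmentation target ``F``.
    """
    if mass <= 0:
        raise SimulationError("mass must be positive")
    rng = params.streams()["fragmentation"] if rng is None else rng
    tooth = params.tooth_fraction * mass
    rest = mass - tooth
    f = params.fragmentation_target
    p_lt = f / (f + 100.0)
    p_lt = _beta_fraction(p_lt, params.frag_concentration, rng)
    lt20 = p_lt * rest
    ge20 = rest - lt20
    c = _beta_fraction(params.cranial_fraction, params.cranial_concentration, rng)
    cranial = c * ge20
    return {
        "lt20": lt20,
        "ge20_cranial": cranial,
        "ge20_postcranial": ge20 - cranial,
        "tooth": tooth,
    }


#: Collection (ossilegium) depletes categories in this order: the larger,
#: identifiable > 20 mm pieces are picked first, minute residue last.
_COLLECTION_ORDER = ("ge20_cranial", "ge20_postcranial", "lt20", "tooth")

_CATEGORY_FIELDS = {
    "lt20": ("lt20", "undetermined"),
    "ge20_cranial": ("ge20", "cranial"),
    "ge20_postcranial": ("ge20", "postcranial"),
    "tooth": ("tooth", "tooth"),
}


def _collect(categories: dict[str, float], target: float) -> dict[str, float]:
    """Remove up to ``target`` grams, largest-fragment categories first."""
    remaining = dict(categories)
    to_remove = target
    for cat in _COLLECTION_ORDER:
        if to_remove <= 0:
            break
        taken = min(remaining[cat], to_remove)
        remaining[cat] -= taken
        to_remove -= taken
    return remaining


def deposit_spatially(roster_categories: list[tuple[str, dict[str, float]]],
                      params: SimulationParams,
                      rng: Optional[np.random.Generator] = None) -> Deposit:
    """Scatter per-individual category masses onto the excavation grid.

    Each individual's surviving per-category mass is split into
    ``n_lots`` equal lots; each lot lands at the pyre centre plus an
    isotropic Gaussian displacement (sd = ``scatter_sd`` metres),
    quantised to the 25 cm grid and clipped to the nearest edge cell so
    mass is conserved.  The optional collection step runs first.
    """
    rng = params.streams()["spatial"] if rng is None else rng
    centre = SquareID(*params.pyre_centre)
    ci, cj = centre.indices(params.row_alphabet)
    if cj >= params.n_columns:
        raise SimulationError("pyre centre outside the declared grid")
    n_rows = len(params.row_alphabet)
    sd_cells = params.scatter_sd / params.cell_size
    accum: dict[tuple[int, int, str], float] = {}
    for label, cats in roster_categories:
        if params.collection:
            cats = _collect(cats, params.collection.get(label, 0.0))
        for cat, mass in cats.items():
            if mass <= 0:
                continue
            lot = mass / params.n_lots
            if sd_cells == 0:
                offsets = np.zeros((params.n_lots, 2))
            else:
                offsets = rng.normal(0.0, sd_cells, size=(params.n_lots, 2))
            ii = np.clip(np.rint(ci + offsets[:, 0]).astype(int), 0, n_rows - 1)
            jj = np.clip(np.rint(cj + offsets[:, 1]).astype(int), 0, params.n_columns - 1)
            for i, j in zip(ii, jj):
                key = (int(i), int(j), cat)
                accum[key] = accum.get(key, 0.0) + lot
    stratum = StratumID(params.us)
    records = [
        FragmentRecord(
            square=SquareID(params.row_alphabet[i], j + 1),
            stratum=stratum,
            size_class=_CATEGORY_FIELDS[cat][0],
            region=_CATEGORY_FIELDS[cat][1],
            weight=w,
        )
        for (i, j, cat), w in sorted(accum.items())
        if w > 0
    ]
    return Deposit(records, row_alphabet=params.row_alphabet,
                   n_columns=params.n_columns, cell_size=params.cell_size)


def params_from_yaml(path) -> SimulationParams:
    """Load SimulationParams from a YAML mapping of field names to values."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "pyre_centre" in data:
        row, col = data["pyre_centre"]
        data["pyre_centre"] = (str(row), int(col))
    if "class_masses" in data:
        data["class_masses"] = {
            k: (float(v[0]), float(v[1])) for k, v in data["class_masses"].items()
        }
    return SimulationParams(**data)


def params_to_yaml(params: SimulationParams, path) -> None:
    import dataclasses

    import yaml

    data = dataclasses.asdict(params)
    data["pyre_centre"] = list(params.pyre_centre)
    data["class_masses"] = {k: list(v) for k, v in params.class_masses.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def roster_to_csv(roster: DeathRoster, path) -> None:
    """Export the death roster as a two-column CSV (class, mass_g)."""
    import pandas as pd

    pd.DataFrame(roster.individuals, columns=["class", "mass_g"]).to_csv(
        path, index=False
    )


def simulate_deposit(params: SimulationParams,
                     return_roster: bool = False):
    """End-to-end generation: community -> fragmentation -> deposition.

    Fully reproducible for a given ``params.seed``; the three stages use
    independent derived streams.
    """
    streams = params.streams()
    roster = simulate_community(params, streams["community"])
    frag_rng = streams["fragmentation"]
    roster_categories = [
        (label, fragment_individual(mass, params, frag_rng))
        for label, mass in roster.individuals
    ]
    deposit = deposit_spatially(roster_categories, params, streams["spatial"])
    if return_roster:
        return deposit, roster
    return deposit
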