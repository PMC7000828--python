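"""Ugi library enumeration and mass bookkeeping.

The four-component Ugi reaction condenses an amine, an aldehyde (or
ketone), a carboxylic acid, and an isocyanide into a single bis-amide
product, releasing one water. A library is the full Cartesian product of
the reagent sets; with the packaged 5 amine x 5 aldehyde x 12 acid x 5
isocyanide plate this gives 1500 products, whose monoisotopic masses fall
mostly between 500 and 700 Da.

Enumeration order is frozen: nested loops amine -> aldehyde -> acid ->
isocyanide with the amine index varying slowest. Library indices are
0-based internally; all user-facing I/O (CSV export, CLI) is 1-based.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .elements import (
    C13_ABUNDANCE,
    C13_MASS_SHIFT,
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    WATER_MASS,
)
from .formula import ChemicalFormula, monoisotopic_mass, parse_formula

ROLES = ("amine", "aldehyde", "acid", "isocyanide")

#: Supported singly-charged cation adducts: cation mass minus one electron.
ADDUCT_MASS = {
    "H": MONOISOTOPIC_MASS["H"] - ELECTRON_MASS,
    "Na": MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS,
    "K": MONOISOTOPIC_MASS["K"] - ELECTRON_MASS,
}


@dataclass(frozen=True)
class Reagent:
    """One Ugi input with its role and formula; mass is derived."""

    name: str
    role: str
    formula: ChemicalFormula

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class UgiProduct:
    """A four-component condensation product.

    ``reagent_ids`` are 0-based indices into the role-grouped reagent
    lists, ordered (amine, aldehyde, acid, isocyanide).
    """

    reagent_ids: tuple[int, int, int, int]
    formula: ChemicalFormula
    M: float  # monoisotopic mass, Da


@dataclass
class CompoundLibrary:
    """Deterministically ordered list of enumerated Ugi products."""

    products: list[UgiProduct]
    reagents: dict[str, list[Reagent]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.products)

    def __getitem__(self, i: int) -> UgiProduct:
        return self.products[i]

    @property
    def masses(self) -> np.ndarray:
        return np.array([p.M for p in self.products])

    def product_name(self, i: int) -> str:
        p = self.products[i]
        names = [
            self.reagents[role][j].name
            for role, j in zip(ROLES, p.reagent_ids)
        ]
        return " + ".join(names)

    def to_frame(self) -> pd.DataFrame:
        """Library export table; indices and names are 1-based/user-facing."""
        rows = []
        for i, p in enumerate(self.products):
            row = {"index": i + 1}
            for role, j in zip(ROLES, p.reagent_ids):
                row[role] = self.reagents[role][j].name if self.reagents else j + 1
            row["formula"] = p.formula.hill()
            row["M"] = p.M
            for adduct in ("H", "Na", "K"):
                row[f"[M+{adduct}]+"] = adduct_mz(p.M, adduct)
            rows.append(row)
        return pd.DataFrame(rows)


def load_reagents(path: str | Path | None = None) -> dict[str, list[Reagent]]:
    """Read a reagent CSV (columns name, role, formula) grouped by role.

    With no path, loads the packaged plate: the 5 amines, 5 aldehydes,
    12 Boc-protected carboxylic acids, and 5 isocyanides.
    """
    if path is None:
        with resources.files("ugimem.data").joinpath("reagents.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    missing = {"name", "role", "formula"} - set(table.columns)
    if missing:
        raise ValueError(f"reagent CSV missing columns: {sorted(missing)}")
    groups: dict[str, list[Reagent]] = {role: [] for role in ROLES}
    for rec in table.itertuples(index=False):
        groups[rec.role].append(
            Reagent(name=rec.name, role=rec.role, formula=parse_formula(rec.formula))
        )
    return groups


def ugi_condense(
    amine: Reagent, aldehyde: Reagent, acid: Reagent, isocyanide: Reagent,
    reagent_ids: tuple[int, int, int, int] = (0, 0, 0, 0),
) -> UgiProduct:
    """Condense four reagents into one product: sum of formulas minus H2O."""
    quartet = (amine, aldehyde, acid, isocyanide)
    for reagent, role in zip(quartet, ROLES):
        if reagent.role != role:
            raise ValueError(
                f"expected a reagent with role {role!r}, got {reagent.role!r} "
                f"({reagent.name})"
            )
    formula = amine.formula + aldehyde.formula + acid.formula + isocyanide.formula
    formula = formula - ChemicalFormula({"H": 2, "O": 1})
    return UgiProduct(
        reagent_ids=reagent_ids,
        formula=formula,
        M=monoisotopic_mass(formula),
    )


def enumerate_library(reagents: dict[str, Sequence[Reagent]]) -> CompoundLibrary:
    """Enumerate the full Cartesian product of the four reagent groups.

    Order is amine slowest, then aldehyde, acid, isocyanide fastest, and
    is identical on every run.
    """
    for role in ROLES:
        if not reagents.get(role):
            raise ValueError(f"no reagents with role {role!r}")
    products = []
    groups = [list(reagents[role]) for role in ROLES]
    for ids in itertools.product(*(range(len(g)) for g in groups)):
        quartet = tuple(group[i] for group, i in zip(groups, ids))
        products.append(ugi_condense(*quartet, reagent_ids=ids))
    return CompoundLibrary(
        products=products, reagents={role: list(reagents[role]) for role in ROLES}
    )


def adduct_mz(M: float, adduct: str, subtract_electron: bool = True) -> float:
    """m/z of the singly charged [M+X]+ ion, X in {H, Na, K}.

    The electron mass is subtracted by default (appropriate at FT-ICR
    mass accuracy); pass ``subtract_electron=False`` for coarse matching.
    """
    if M < 0:
        raise ValueError("M must be non-negative")
    try:
        cation = ADDUCT_MASS[adduct]
    except KeyError:
        raise ValueError(
            f"unsupported adduct {adduct!r}; expected one of {sorted(ADDUCT_MASS)}"
        ) from None
    if not subtract_electron:
        cation = cation + ELECTRON_MASS
    return M + cation


def isotope_envelope(
    formula: ChemicalFormula, n_peaks: int = 3
) -> list[tuple[float, float]]:
    """Carbon-binomial isotope envelope, peak-0 normalized.

    Returns ``n_peaks`` pairs (mass offset in Da, abundance relative to
    the monoisotopic peak). Only 13C substitution is modeled: for a
    molecule with ``nC`` carbons the M+k abundance ratio is
    ``C(nC, k) * (p/q)**k`` with p = 0.0107. Adequate for the CHNO-rich
    Ugi products this package targets; heteroatom isotopes (S, Cl) are
    not convolved.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    n_carbon = formula.get("C", 0)
    ratio = C13_ABUNDANCE / (1.0 - C13_ABUNDANCE)
    peaks = [(0.0, 1.0)]
    coeff = 1.0
    for k in range(1, n_peaks):
        if k > n_carbon:
            peaks.append((k * C13_MASS_SHIFT, 0.0))
            continue
        coeff *= (n_carbon - k + 1) / k * ratio
        peaks.append((k * C13_MASS_SHIFT, coeff))
    return peaks


def select_compound_subset(
    library: CompoundLibrary,
    n: int,
    tol_ppm: float = 15.0,
    n_isotopes: int = 3,
    reference_mass: float | None = None,
    exclude: Iterable[int] = (),
) -> list[int]:
    """Pick n products whose sodiated peaks are mutually resolvable.

    Greedy scan in library order: a product is accepted if its [M+H]+,
    [M+Na]+ and [M+K]+ peaks (and their 13C satellites) stay more than
    2 * tol_ppm away from every already-reserved peak of earlier picks
    and of the optional reference calibrant — so a peak-lookup window of
    +/-tol_ppm around any detection target can never contain another
    subset member's signal. Returns 1-based library indices. Compounds
    that are mass-degenerate in the library are thereby never co-selected
    for direct (single-peak-readable) mappings.
    """
    excluded = set(exclude)
    reserved: list[float] = []
    targets: list[float] = []

    def peaks_of(M: float) -> list[float]:
        return [
            adduct_mz(M, adduct) + k * C13_MASS_SHIFT
            for adduct in ("H", "Na", "K")
            for k in range(n_isotopes)
        ]

    if reference_mass is not None:
        reserved.extend(peaks_of(reference_mass))
        targets.append(adduct_mz(reference_mass, "Na"))
    chosen: list[int] = []
    for i, product in enumerate(library.products):
        if i + 1 in excluded:
            continue
        mine = peaks_of(product.M)
        my_target = adduct_mz(product.M, "Na")
        min_sep = 2 * tol_ppm * 1e-6
        ok = all(
            abs(mz - t) / t > min_sep for mz in mine for t in targets
        ) and all(
            abs(my_target - mz) / my_target > min_sep for mz in reserved
        )
        if ok:
            chosen.append(i + 1)
            reserved.extend(mine)
            targets.append(my_target)
            if len(chosen) == n:
                return chosen
    raise ValueError(
        f"could only find {len(chosen)} of {n} mutually resolvable products"
    )


def mass_collisions(
    library: CompoundLibrary | Iterable[float], tol_ppm: float = 5.0
) -> list[list[int]]:
    """Group products whose masses agree within ``tol_ppm``.

    Returns groups (0-based product indices) of size >= 2, each group
    sorted, groups ordered by their smallest member. Grouping is
    transitive-closure over the pairwise |dM|/M <= tol relation.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    masses = (
        library.masses if isinstance(library, CompoundLibrary)
        else np.asarray(list(library), dtype=float)
    )
    n = len(masses)
    if n == 0:
        return []
    order = np.argsort(masses, kind="stable")
    sorted_m = masses[order]
    # Union adjacent-in-mass products within tolerance; transitive closure
    # follows because the relation is checked on consecutive sorted pairs.
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in range(n - 1):
        m0, m1 = sorted_m[a], sorted_m[a + 1]
        ref = max(m0, 1e-12)
        if (m1 - m0) / ref <= tol_ppm * 1e-6:
            ra, rb = find(order[a]), find(order[a + 1])
            if ra != rb:
                parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = [sorted(g) for g in groups.values() if len(g) >= 2]
    out.sort(key=lambda g: g[0])
    return out
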