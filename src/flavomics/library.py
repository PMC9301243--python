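"""The flavonoid building-block model.

Aglycones, glycosyl/acyl residues, composition of conjugates, combinatorial
decomposition of precursor masses, family and glycosylation-degree
classification, and systematic naming.

Residue formulas are stored *dehydrated* (the condensation water is already
removed), so conjugate composition is pure element-wise addition:
aglycone + residues = conjugate, with no further water correction.
"""

from __future__ import annotations

import csv
import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .chem import (
    ElementCounts,
    adduct_mz,
    format_formula,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
)

__all__ = [
    "FAMILIES",
    "GLYCO_CLASSES",
    "AglyconeRecord",
    "ResidueRecord",
    "CompoundRecord",
    "SuspectLibrary",
    "compose_compound",
    "decompose_mass",
    "classify_glyco",
    "assign_isomer_indices",
    "default_library",
    "load_library",
    "save_library",
]

FAMILIES = ("anthocyanidin", "flavone", "isoflavone", "pterocarpan", "flavanone")
GLYCO_CLASSES = ("Agly", "Gly", "GlyGly", "GlyGlyGly")

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


@dataclass(frozen=True)
class AglyconeRecord:
    """A sugar-free flavonoid core.

    ``neutral_mass`` is the neutral-atom monoisotopic sum of ``formula``;
    for permanently charged species (``is_native_cation``) the formula
    carries charge +1 and the detected ion is the cation itself.
    """

    name: str
    family: str
    formula: ElementCounts
    is_native_cation: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def ion_mz(self) -> float:
        """m/z of the aglycone's detected ion ([M+H]+ or native cation)."""
        if self.is_native_cation:
            return adduct_mz(self.neutral_mass, "M+")
        return adduct_mz(self.neutral_mass, "[M+H]+")


@dataclass(frozen=True)
class ResidueRecord:
    """A dehydrated glycosyl or acyl residue."""

    key: str
    formula: ElementCounts
    klass: str  # "sugar" | "acyl"

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)


def _agly(name: str, family: str, formula: str, cation: bool = False) -> AglyconeRecord:
    return AglyconeRecord(name, family, parse_formula(formula), cation)


#: Aglycones required to compose the packaged compound table.  Peonidin is a
#: flavylium cation; afrormosin uses C17H14O5 (consistent with its printed
#: mass and all of its conjugate formulas).
DEFAULT_AGLYCONES: tuple[AglyconeRecord, ...] = (
    _agly("Peonidin", "anthocyanidin", "C16H13O6+", cation=True),
    _agly("Apigenin", "flavone", "C15H10O5"),
    _agly("Tricin", "flavone", "C17H14O7"),
    _agly("Chrysoeriol", "flavone", "C16H12O6"),
    _agly("Naringenin Chalcone", "flavanone", "C15H12O5"),
    _agly("Daidzein", "isoflavone", "C15H10O4"),
    _agly("Formononetin", "isoflavone", "C16H12O4"),
    _agly("Biochanin A", "isoflavone", "C16H12O5"),
    _agly("Afrormosin", "isoflavone", "C17H14O5"),
    _agly("Irisolidone", "isoflavone", "C17H14O6"),
    _agly("Medicarpin", "pterocarpan", "C16H14O4"),
)

DEFAULT_RESIDUES: tuple[ResidueRecord, ...] = (
    ResidueRecord("Glc", parse_formula("C6H10O5"), "sugar"),
    ResidueRecord("GlcA", parse_formula("C6H8O6"), "sugar"),
    ResidueRecord("Mal", parse_formula("C3H2O3"), "acyl"),
    ResidueRecord("Fer", parse_formula("C10H8O3"), "acyl"),
    ResidueRecord("Cou", parse_formula("C9H6O2"), "acyl"),
)


@dataclass(frozen=True)
class CompoundRecord:
    """An aglycone plus a residue multiset, with derived mass quantities."""

    name: str
    aglycone: AglyconeRecord
    residues: tuple[str, ...]  # sorted residue keys
    formula: ElementCounts
    retention_time: float | None = None
    isomer_index: str | None = None

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def precursor_mz(self) -> float:
        if self.aglycone.is_native_cation:
            return adduct_mz(self.neutral_mass, "M+")
        return adduct_mz(self.neutral_mass, "[M+H]+")

    @property
    def family(self) -> str:
        return self.aglycone.family

    @property
    def glyco_class(self) -> str:
        return classify_glyco(self)[0]

    @property
    def acylated(self) -> bool:
        return classify_glyco(self)[1]

    @property
    def formula_str(self) -> str:
        return format_formula(self.formula)


@dataclass
class SuspectLibrary:
    """Aglycones, residues and the compound table they compose."""

    aglycones: list[AglyconeRecord] = field(default_factory=list)
    residues: list[ResidueRecord] = field(default_factory=list)
    compounds: list[CompoundRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.compounds]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate compound names: {dupes}")
        agly_names = {a.name for a in self.aglycones}
        for c in self.compounds:
            if c.aglycone.name not in agly_names:
                raise ValueError(f"compound {c.name!r} uses unknown aglycone")

    def aglycone(self, name: str) -> AglyconeRecord:
        for a in self.aglycones:
            if a.name == name:
                return a
        raise KeyError(f"unknown aglycone {name!r}")

    def residue(self, key: str) -> ResidueRecord:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(f"unknown residue key {key!r}")

    def compound(self, name: str) -> CompoundRecord:
        for c in self.compounds:
            if c.name == name:
                return c
        raise KeyError(f"unknown compound {name!r}")

    def __len__(self) -> int:
        return len(self.compounds)

    def family_census(self) -> dict[str, int]:
        counts = Counter(c.family for c in self.compounds)
        return {fam: counts.get(fam, 0) for fam in FAMILIES}


def _residue_sort_key(residues: Sequence[ResidueRecord]) -> list[str]:
    """Naming order: acyl keys first, then sugars, alphabetical within class."""
    acyls = sorted(r.key for r in residues if r.klass == "acyl")
    sugars = sorted(r.key for r in residues if r.klass == "sugar")
    return acyls + sugars


def compose_compound(
    aglycone: AglyconeRecord,
    residue_keys: Iterable[str],
    library: SuspectLibrary | None = None,
    name: str | None = None,
    retention_time: float | None = None,
    max_residues: int = 4,
) -> CompoundRecord:
    """Compose a conjugate from an aglycone and a residue-key multiset.

    The derived formula is the element-wise sum of the aglycone formula and
    the dehydrated residue formulas.  The default name is
    ``"<Aglycone> <acyl keys><sugar keys>"`` (e.g. ``"Medicarpin MalGlc"``);
    positional isomer numerals are attached separately by
    :func:`assign_isomer_indices`.
    """
    residue_table = {r.key: r for r in (library.residues if library else DEFAULT_RESIDUES)}
    keys = list(residue_keys)
    if len(keys) > max_residues:
        raise ValueError(f"residue multiset of size {len(keys)} exceeds max {max_residues}")
    try:
        recs = [residue_table[k] for k in keys]
    except KeyError as exc:
        raise KeyError(f"unknown residue key {exc.args[0]!r}") from None

    formula = aglycone.formula
    for r in recs:
        formula = formula + r.formula
    ordered = _residue_sort_key(recs)
    if name is None:
        suffix = "".join(ordered)
        name = f"{aglycone.name} {suffix}".strip()
    return CompoundRecord(
        name=name,
        aglycone=aglycone,
        residues=tuple(ordered),
        formula=formula,
        retention_time=retention_time,
    )


def classify_glyco(c: CompoundRecord) -> tuple[str, bool]:
    """Glycosylation class (by sugar count) and acylation flag."""
    sugar_keys = {r.key for r in DEFAULT_RESIDUES if r.klass == "sugar"}
    acyl_keys = {r.key for r in DEFAULT_RESIDUES if r.klass == "acyl"}
    n_sugar = sum(1 for k in c.residues if k in sugar_keys)
    acylated = any(k in acyl_keys for k in c.residues)
    if n_sugar >= len(GLYCO_CLASSES):
        raise ValueError(f"{c.name}: {n_sugar} sugars exceeds supported classes")
    return GLYCO_CLASSES[n_sugar], acylated


def decompose_mass(
    precursor_mz: float,
    library: SuspectLibrary,
    tol_ppm: float = 10.0,
    max_residues: int = 4,
    max_sugars: int = 3,
    max_acyls: int = 1,
) -> list[tuple[AglyconeRecord, tuple[str, ...], float]]:
    """All (aglycone, residue multiset) explanations of a precursor m/z.

    Exhaustive over every aglycone x residue multiset with at most
    ``max_residues`` residues (``max_sugars`` sugars, ``max_acyls`` acyls),
    keeping combinations whose composed precursor m/z lies within
    ``tol_ppm``.  Sorted by |ppm error|, then fewest residues, then name.
    """
    if precursor_mz <= 0:
        raise ValueError("precursor m/z must be positive")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not library.aglycones or not library.residues:
        raise ValueError("empty library")

    out: list[tuple[AglyconeRecord, tuple[str, ...], float]] = []
    keys = [r.key for r in library.residues]
    sugar_keys = {r.key for r in library.residues if r.klass == "sugar"}
    for agly in library.aglycones:
        for size in range(max_residues + 1):
            for combo in itertools.combinations_with_replacement(keys, size):
                n_sugar = sum(1 for k in combo if k in sugar_keys)
                if n_sugar > max_sugars or size - n_sugar > max_acyls:
                    continue
                comp = compose_compound(agly, combo, library, max_residues=max_residues)
                err = ppm_error(precursor_mz, comp.precursor_mz)
                if abs(err) <= tol_ppm:
                    out.append((agly, comp.residues, err))
    out.sort(key=lambda t: (abs(t[2]), len(t[1]), t[0].name, t[1]))
    return out


def assign_isomer_indices(compounds: Sequence[CompoundRecord]) -> list[CompoundRecord]:
    """Assign Roman-numeral positional-isomer indices by ascending RT.

    Compounds sharing an identical (aglycone, residue multiset) composition
    and forming a group of size >= 2 receive I, II, III ... in retention-time
    order; singletons get no index.  Equal RTs within a group are broken by
    input order and flagged with a warning.
    """
    by_comp: dict[tuple[str, tuple[str, ...]], list[int]] = {}
    for i, c in enumerate(compounds):
        by_comp.setdefault((c.aglycone.name, c.residues), []).append(i)

    result = list(compounds)
    for key, idxs in by_comp.items():
        if len(idxs) < 2:
            continue
        for i in idxs:
            if compounds[i].retention_time is None:
                raise ValueError(
                    f"missing retention time for {compounds[i].name!r} in "
                    f"multi-member composition group {key[0]} {''.join(key[1])}"
                )
        rts = [compounds[i].retention_time for i in idxs]
        if len(set(rts)) < len(rts):
            warnings.warn(
                f"co-eluting identical compositions in group {key[0]} "
                f"{''.join(key[1])}; ties broken by input order",
                stacklevel=2,
            )
        order = sorted(range(len(idxs)), key=lambda j: (rts[j], j))
        for rank, j in enumerate(order):
            i = idxs[j]
            numeral = _ROMAN[rank]
            base = compounds[i].name
            result[i] = replace(compounds[i], isomer_index=numeral,
                                name=f"{base} {numeral}")
    return result


# ---------------------------------------------------------------------------
# serialization


def _read_rows(lines: Iterable[str]) -> list[dict[str, str]]:
    reader = csv.DictReader(lines, delimiter="\t")
    return [row for row in reader]


def _library_from_rows(
    rows: list[dict[str, str]],
    aglycones: Sequence[AglyconeRecord] = DEFAULT_AGLYCONES,
    residues: Sequence[ResidueRecord] = DEFAULT_RESIDUES,
) -> SuspectLibrary:
    lib = SuspectLibrary(list(aglycones), list(residues), [])
    agly_map = {a.name: a for a in lib.aglycones}
    compounds = []
    for row in rows:
        agly = agly_map[row["aglycone"]]
        res = [k for k in (row.get("residues") or "").split(",") if k]
        rt = float(row["rt_min"]) if row.get("rt_min") else None
        compounds.append(
            compose_compound(agly, res, lib, name=row["name"], retention_time=rt)
        )
    lib.compounds = compounds
    lib.__post_init__()
    return lib


def default_library() -> SuspectLibrary:
    """The packaged 46-entry flavonoid suspect library."""
    ref = resources.files("flavomics.data").joinpath("compounds.tsv")
    rows = _read_rows(ref.read_text().splitlines())
    return _library_from_rows(rows)


def load_library(path: str | Path) -> SuspectLibrary:
    """Load a compound table (TSV: peak, rt_min, name, aglycone, residues)."""
    with open(path) as fh:
        rows = _read_rows(fh)
    return _library_from_rows(rows)


def save_library(lib: SuspectLibrary, path: str | Path) -> None:
    """Write the compound table in the same TSV dialect read by load_library."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["peak", "rt_min", "name", "aglycone", "residues", "formula"])
        for i, c in enumerate(lib.compounds, start=1):
            rt = "" if c.retention_time is None else f"{c.retention_time:.2f}"
            w.writerow([i, rt, c.name, c.aglycone.name, ",".join(c.residues),
                        c.formula_str])
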