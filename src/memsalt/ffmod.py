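"""Lennard–Jones C12 pair-scaling tables for ion–ion and ion–lipid tuning.

Heteroatomic 12-6 parameters default to the geometric-mean combination rule
C_ij = √(C_ii·C_jj) for both C6 and C12.  The binding-calibration scheme
overrides three groups of pairs on top of that rule, touching C12 only:

* Na⁺–Cl⁻:           C12 × s_NaCl (default 1.33),
* Cl⁻–lipid tails    (types LP2, LP3, LH1): C12 × s_Cl (default 0.057),
* Na⁺–every lipid type: C12 × s_Na (3.2 for variant 'm1', 3.0 for 'm2').

Variant 'o' applies no overrides.  Overrides carry a provenance tag so a
scaled table cannot be scaled twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

S_NACL_DEFAULT = 1.33
S_CL_DEFAULT = 0.057
S_NA_BY_VARIANT = {"m1": 3.2, "m2": 3.0}
TAIL_TYPES_DEFAULT = frozenset({"LP2", "LP3", "LH1"})


class TableError(ValueError):
    """LJ table lacks a required type, or scaling would be applied twice."""


@dataclass(frozen=True)
class LJTable:
    """Homoatomic C6/C12 parameters plus explicit pair overrides.

    ``types`` maps atom type → (C6, C12) in kJ·mol⁻¹·nm⁶ / kJ·mol⁻¹·nm¹².
    ``pair_overrides`` maps a sorted (type_i, type_j) tuple →
    (C6_ij, C12_ij).  ``lipid_types``/``tail_types`` tag the lipid atom
    types for the scaling scope; ``na_type``/``cl_type`` name the ions.
    """

    types: dict
    lipid_types: frozenset = frozenset()
    tail_types: frozenset = TAIL_TYPES_DEFAULT
    na_type: str = "NA+"
    cl_type: str = "CL-"
    pair_overrides: dict = field(default_factory=dict)
    provenance: str = "base"  # base | scaled:<variant>

    def __post_init__(self) -> None:
        for t, (c6, c12) in self.types.items():
            if c6 < 0 or c12 < 0:
                raise TableError(f"negative LJ parameter for type {t}")
        for pair, (c6, c12) in self.pair_overrides.items():
            if tuple(sorted(pair)) != tuple(pair):
                raise TableError(f"override key {pair} not sorted")
            if c6 < 0 or c12 < 0:
                raise TableError(f"negative override for pair {pair}")


def combine(table: LJTable, type_i: str, type_j: str) -> tuple[float, float]:
    """Heteroatomic (C6_ij, C12_ij): an explicit pair override if present,
    else the geometric-mean combination of the homoatomic parameters."""
    key = tuple(sorted((type_i, type_j)))
    if key in table.pair_overrides:
        return table.pair_overrides[key]
    try:
        c6i, c12i = table.types[type_i]
        c6j, c12j = table.types[type_j]
    except KeyError as exc:
        raise TableError(f"type {exc.args[0]!r} missing from table") from exc
    return float(np.sqrt(c6i * c6j)), float(np.sqrt(c12i * c12j))


def apply_scalings(base: LJTable, variant: str,
                   s_nacl: float = S_NACL_DEFAULT,
                   s_cl: float = S_CL_DEFAULT,
                   s_na: float | None = None) -> LJTable:
    """Return a table with the variant's C12 pair overrides installed.

    Variant 'o' returns the base unchanged (fresh provenance tag); 'm1'/'m2'
    scale the Na⁺–Cl⁻, Cl⁻–tail and Na⁺–lipid C12 values on top of the
    combination rule.  C6 is never touched.  Raises if ``base`` has already
    been scaled.
    """
    if variant not in {"o", "m1", "m2"}:
        raise ValueError(f"unknown variant {variant!r}")
    if base.provenance != "base":
        raise TableError("table already carries scaling overrides")
    if variant == "o":
        return replace(base, provenance="scaled:o")
    if s_na is None:
        s_na = S_NA_BY_VARIANT[variant]
    for required in (base.na_type, base.cl_type):
        if required not in base.types:
            raise TableError(f"ion type {required!r} missing from table")
    if not base.lipid_types:
        raise TableError("table has no lipid types tagged")
    missing_tails = base.tail_types - base.lipid_types
    if missing_tails:
        raise TableError(f"tail types {sorted(missing_tails)} not among lipid types")
    overrides = dict(base.pair_overrides)

    def scale(ti: str, tj: str, factor: float) -> None:
        c6, c12 = combine(base, ti, tj)
        overrides[tuple(sorted((ti, tj)))] = (c6, c12 * factor)

    scale(base.na_type, base.cl_type, s_nacl)
    for t in sorted(base.tail_types):
        scale(base.cl_type, t, s_cl)
    for t in sorted(base.lipid_types):
        scale(base.na_type, t, s_na)
    return replace(base, pair_overrides=overrides, provenance=f"scaled:{variant}")


def write_pair_table(path, table: LJTable) -> None:
    """Write all pairwise parameters as TSV (type_i, type_j, C6, C12, origin)."""
    names = sorted(table.types)
    lines = ["type_i\ttype_j\tC6_kJmol_nm6\tC12_kJmol_nm12\torigin"]
    for a in names:
        for b in names:
            if b < a:
                continue
            c6, c12 = combine(table, a, b)
            origin = ("override" if tuple(sorted((a, b))) in table.pair_overrides
                      else "combination")
            lines.append(f"{a}\t{b}\t{c6:.10e}\t{c12:.10e}\t{origin}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def gromacs_nonbond_params(table: LJTable) -> str:
    """Render the pair overrides as a GROMACS-style [nonbond_params] block."""
    lines = ["[ nonbond_params ]", "; i    j    func  c6            c12"]
    for (a, b), (c6, c12) in sorted(table.pair_overrides.items()):
        lines.append(f"  {a:<6s} {b:<6s} 1     {c6:.6e}  {c12:.6e}")
    return "\n".join(lines) + "\n"
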