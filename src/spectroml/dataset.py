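"""Diatomic constants tables: records, derived quantities, CSV I/O.

A :class:`SpectroRecord` holds one molecule in one electronic state (ground
``X`` or first excited ``A``) with its equilibrium distance R_e (Å), harmonic
frequency ω_e (cm⁻¹) and, optionally, the first anharmonic correction ω_e x_e
(cm⁻¹) and the binding energy D_0 (eV).  A :class:`SpectroDataset` is an
ordered collection of such records with per-target "views" (a record enters a
target's view only when every quantity the target needs is present) plus a
molecule-level join of the X and A states used by the cross-state features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .constants import CM1_TO_EV
from .elements import (
    ElementRecord,
    FormulaError,
    get_element_table,
    parse_diatomic_formula,
)

__all__ = [
    "SpectroRecord",
    "SpectroDataset",
    "Molecule",
    "TARGETS",
    "reduced_mass",
    "dissociation_energy",
    "radius_ratio",
    "binding_label",
    "BINDING_TRANSFORMS",
    "load_dataset",
]

logger = logging.getLogger(__name__)

#: Supported prediction targets.
TARGETS = ("Re", "we", "Dlabel", "Re_A", "we_A")


def reduced_mass(mass1: float, mass2: float) -> float:
    """Reduced mass m = m₁m₂/(m₁+m₂) in u."""
    if mass1 <= 0 or mass2 <= 0:
        raise ValueError("masses must be positive")
    return mass1 * mass2 / (mass1 + mass2)


def dissociation_energy(
    D0: float,
    we: float,
    wexe: Optional[float] = None,
    *,
    missing_wexe: str = "error",
) -> float:
    """Potential-well depth D_e = D_0 + ω_e/2 − ω_e x_e/4, in eV.

    ``we`` and ``wexe`` are given in cm⁻¹ and converted internally.
    ``missing_wexe`` controls what happens when ``wexe`` is ``None``:
    ``"error"`` (default) raises, ``"zero"`` treats it as 0 with a warning.
    """
    if D0 < 0:
        raise ValueError("D0 must be >= 0")
    if we < 0:
        raise ValueError("we must be >= 0")
    if wexe is None:
        if missing_wexe == "zero":
            logger.warning("missing we*xe treated as 0 in D_e")
            wexe = 0.0
        else:
            raise ValueError("we*xe missing (pass missing_wexe='zero' to ignore)")
    return D0 + 0.5 * we * CM1_TO_EV - 0.25 * wexe * CM1_TO_EV


@dataclass
class SpectroRecord:
    """One molecule/state row of the constants table."""

    formula: str
    atom1: ElementRecord
    atom2: ElementRecord
    state: str = "X"
    Re: float = float("nan")
    we: float = float("nan")
    wexe: Optional[float] = None
    D0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.state not in ("X", "A"):
            raise ValueError(f"{self.formula}: state must be X or A")
        if self.atom1.symbol == self.atom2.symbol:
            raise ValueError(f"{self.formula}: homonuclear molecules excluded")
        if not (self.Re > 0):
            raise ValueError(f"{self.formula}: Re must be > 0")
        if not (self.we > 0):
            raise ValueError(f"{self.formula}: we must be > 0")

    @property
    def m(self) -> float:
        """Reduced mass in u."""
        return reduced_mass(self.atom1.mass, self.atom2.mass)


def radius_ratio(record: SpectroRecord) -> float:
    """R_e over the sum of the empirical atomic radii, R_e/(R₁+R₂).

    Values near 1 indicate covalent bonding; markedly smaller values
    ionic-leaning, markedly larger van-der-Waals-leaning bonds.
    """
    for atom in (record.atom1, record.atom2):
        if not (atom.radius > 0):
            raise ValueError(f"missing radius for element {atom.symbol}")
    return record.Re / (record.atom1.radius + record.atom2.radius)


@dataclass
class Molecule:
    """X/A-state join for one formula (feature-building convenience)."""

    formula: str
    atom1: ElementRecord
    atom2: ElementRecord
    Re_X: float = float("nan")
    we_X: float = float("nan")
    wexe: Optional[float] = None
    D0: Optional[float] = None
    Re_A: Optional[float] = None
    we_A: Optional[float] = None

    @property
    def m(self) -> float:
        return reduced_mass(self.atom1.mass, self.atom2.mass)


@dataclass
class SpectroDataset:
    """Ordered collection of :class:`SpectroRecord` with target views."""

    records: list[SpectroRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            key = (r.formula, r.state)
            if key in seen:
                raise ValueError(f"duplicate record for {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def molecules(self) -> list[Molecule]:
        """Join X and A rows per formula, X-row order preserved."""
        by_formula: dict[str, Molecule] = {}
        order: list[str] = []
        for r in self.records:
            if r.state != "X":
                continue
            by_formula[r.formula] = Molecule(
                formula=r.formula,
                atom1=r.atom1,
                atom2=r.atom2,
                Re_X=r.Re,
                we_X=r.we,
                wexe=r.wexe,
                D0=r.D0,
            )
            order.append(r.formula)
        for r in self.records:
            if r.state != "A":
                continue
            mol = by_formula.get(r.formula)
            if mol is None:
                mol = Molecule(formula=r.formula, atom1=r.atom1, atom2=r.atom2)
                by_formula[r.formula] = mol
                order.append(r.formula)
            mol.Re_A = r.Re
            mol.we_A = r.we
        return [by_formula[f] for f in order]

    def to_frame(self, derived: bool = False) -> pd.DataFrame:
        """Tabular echo of the records; ``derived`` adds m, D_e, radius ratio."""
        rows = []
        for r in self.records:
            row = {
                "formula": r.formula,
                "state": r.state,
                "Re": r.Re,
                "we": r.we,
                "wexe": r.wexe,
                "D0": r.D0,
            }
            if derived:
                row["m"] = r.m
                row["radius_ratio"] = radius_ratio(r)
                if r.D0 is not None and r.wexe is not None:
                    row["De"] = dissociation_energy(r.D0, r.we, r.wexe)
                else:
                    row["De"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path, derived: bool = False) -> None:
        self.to_frame(derived=derived).to_csv(path, index=False)


#: Shipped binding-energy label transforms (see :func:`binding_label`).
BINDING_TRANSFORMS = ("ln_zz_over_de", "identity_De", "sqrt_De")


def binding_label(
    mol,
    transform: str = "ln_zz_over_de",
    *,
    missing_wexe: str = "error",
) -> float:
    """Regression label derived from the binding energy.

    The well depth D_e is first reconstructed from D_0, ω_e and ω_e x_e.  The
    default label ``ln_zz_over_de`` is ln(Z₁Z₂/D_e), the combination that is
    linear in R_e under the exponential electron-density model; the shipped
    alternatives are ``identity_De`` (D_e itself, eV) and ``sqrt_De`` (√D_e).

    Works on any object with ``atom1``, ``atom2``, ``D0``, ``we_X``/``we`` and
    ``wexe`` attributes.
    """
    we = getattr(mol, "we_X", None)
    if we is None or (isinstance(we, float) and np.isnan(we)):
        we = mol.we
    if mol.D0 is None:
        raise ValueError(f"{mol.formula}: D0 missing for binding label")
    de = dissociation_energy(mol.D0, we, mol.wexe, missing_wexe=missing_wexe)
    if de <= 0:
        raise ValueError(f"{mol.formula}: nonpositive D_e = {de:.4g} eV")
    if transform == "identity_De":
        return de
    if transform == "sqrt_De":
        return float(np.sqrt(de))
    if transform == "ln_zz_over_de":
        return float(np.log(mol.atom1.Z * mol.atom2.Z / de))
    raise ValueError(f"unknown binding transform {transform!r}")


_REQUIRED_COLUMNS = ("formula", "Re", "we")


def load_dataset(
    path,
    column_map: Optional[dict[str, str]] = None,
    state: Optional[str] = None,
    *,
    strict: bool = False,
    d0_unit: str = "eV",
) -> SpectroDataset:
    """Load a constants CSV into a :class:`SpectroDataset`.

    Parameters
    ----------
    path:
        CSV file with a header row; required columns ``formula``, ``Re``,
        ``we``; optional ``state`` (default X), ``wexe``, ``D0``.
    column_map:
        Mapping from the file's column names to the canonical ones.
    state:
        When given, overrides/provides the state for every row.
    strict:
        If True, any bad row is a hard error; otherwise bad rows are skipped
        and reported with their line numbers.
    d0_unit:
        ``"eV"`` (default) or ``"cm-1"``; D_0 values are converted to eV.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if d0_unit not in ("eV", "cm-1"):
        raise ValueError("d0_unit must be 'eV' or 'cm-1'")

    table = get_element_table()
    records: list[SpectroRecord] = []
    failures: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            atom1, atom2 = parse_diatomic_formula(str(row["formula"]), table)
            wexe = row.get("wexe")
            d0 = row.get("D0")
            wexe = None if pd.isna(wexe) else float(wexe)
            d0 = None if pd.isna(d0) else float(d0)
            if d0 is not None and d0_unit == "cm-1":
                d0 *= CM1_TO_EV
            row_state = state or (str(row["state"]) if "state" in df.columns and not pd.isna(row.get("state")) else "X")
            records.append(
                SpectroRecord(
                    formula=str(row["formula"]),
                    atom1=atom1,
                    atom2=atom2,
                    state=row_state,
                    Re=float(row["Re"]),
                    we=float(row["we"]),
                    wexe=wexe,
                    D0=d0,
                )
            )
        except (FormulaError, ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"line {line}: {exc}") from exc
            failures.append((line, str(exc)))

    if failures:
        for line, msg in failures:
            logger.warning("skipped line %d: %s", line, msg)
    ds = SpectroDataset(records)
    n_x = sum(1 for r in ds.records if r.state == "X")
    n_d0 = sum(1 for r in ds.records if r.state == "X" and r.D0 is not None)
    n_a = sum(1 for r in ds.records if r.state == "A")
    logger.info(
        "loaded %d records (%d X-state, %d with D0, %d A-state), %d skipped",
        len(ds), n_x, n_d0, n_a, len(failures),
    )
    return ds
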