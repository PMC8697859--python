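"""Feature recipes mapping molecules to numeric vectors.

A :class:`FeatureSpec` names an ordered list of feature tokens and a target.
The tokens cover the periodic-table descriptors (group/period of each atom,
isotope-aware groups, their averages), cross-state spectroscopic quantities
(R_e⁻¹ of the X or A state, ω_e of the X state), the electron-transfer
descriptor D(IP, EA), and the transformed predictors used by the classical
linear baselines.

Because a diatomic AB is the same molecule as BA, training sets can be
*permutation augmented*: every row is duplicated with the atom-indexed tokens
exchanged (g1↔g2, p1↔p2, g1_iso↔g2_iso), which makes downstream kernel models
exactly symmetric under atom exchange.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

from .dataset import Molecule, SpectroDataset, binding_label
from .elements import ElementRecord

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "FeaturizationError",
    "g_iso",
    "d_ip_ea",
    "build_features",
    "permutation_augment",
    "predicted_Re_feature",
    "PRESETS",
    "get_preset",
]

logger = logging.getLogger(__name__)

#: Floor applied to predicted R_e before inversion (Å).
RE_HAT_FLOOR = 0.5


class FeaturizationError(ValueError):
    """Raised when a feature token cannot be resolved for a record."""


def g_iso(element: ElementRecord, delta: float = 0.1) -> float:
    """Isotope-aware group number.

    Equal to the plain group for every element except the hydrogen isotopes,
    which are offset by ``delta`` per extra neutron so that H→1.0, D→1.1,
    T→1.2 under the default ``delta`` = 0.1.  The offset separates the
    isotopes while perturbing the group geometry minimally.
    """
    if element.Z != 1:
        return float(element.group)
    mass_number = element.mass_number if element.mass_number is not None else 1
    return float(element.group) + delta * (mass_number - 1)


def _d_default(a: ElementRecord, b: ElementRecord) -> float:
    # cost of moving an electron toward the more electronegative atom
    if b.chi > a.chi:
        return a.IP - b.EA
    if a.chi > b.chi:
        return b.IP - a.EA
    return 0.5 * ((a.IP - b.EA) + (b.IP - a.EA))


def _d_chi_weighted(a: ElementRecord, b: ElementRecord) -> float:
    return abs(a.chi - b.chi) * _d_default(a, b)


#: Pluggable functional forms for the electron-transfer descriptor.
D_FORMS: dict[str, Callable[[ElementRecord, ElementRecord], float]] = {
    "default": _d_default,
    "chi_weighted": _d_chi_weighted,
}


def d_ip_ea(a: ElementRecord, b: ElementRecord, form: str = "default") -> float:
    """Electron-transfer descriptor D(IP, EA) in eV (symmetric in a, b)."""
    for atom in (a, b):
        for attr in ("IP", "EA", "chi"):
            v = getattr(atom, attr)
            if v is None or not np.isfinite(v):
                raise FeaturizationError(f"missing {attr} for element {atom.symbol}")
    try:
        fn = D_FORMS[form]
    except KeyError:
        raise FeaturizationError(f"unknown D(IP,EA) form {form!r}") from None
    return fn(a, b)


#: token -> token under atom exchange; symmetric tokens map to themselves.
SWAP_MAP = {
    "g1": "g2",
    "g2": "g1",
    "p1": "p2",
    "p2": "p1",
    "g1_iso": "g2_iso",
    "g2_iso": "g1_iso",
}


@dataclass(frozen=True)
class FeatureSpec:
    """Named recipe mapping molecules to feature vectors.

    Attributes
    ----------
    name:
        Identifier used in reports.
    target:
        One of ``Re``, ``we``, ``Dlabel``, ``Re_A``, ``we_A``.
    components:
        Ordered feature tokens.
    augment:
        Whether to apply atom-swap augmentation to training matrices.
    delta_iso:
        Isotope offset of :func:`g_iso`.
    d_form:
        Functional form of D(IP, EA) (see :data:`D_FORMS`).
    averages_use_iso:
        If True, ḡ averages the isotope-aware groups instead of the plain ones.
    binding_transform:
        Label transform for the ``Dlabel`` target.
    """

    name: str
    target: str
    components: tuple[str, ...]
    augment: bool = True
    delta_iso: float = 0.1
    d_form: str = "default"
    averages_use_iso: bool = False
    binding_transform: str = "ln_zz_over_de"

    def swap_image(self) -> tuple[str, ...]:
        return tuple(SWAP_MAP.get(t, t) for t in self.components)

    def swap_permutation(self) -> np.ndarray:
        """Column permutation realizing the atom swap on a feature matrix."""
        image = self.swap_image()
        perm = []
        for tok in image:
            try:
                perm.append(self.components.index(tok))
            except ValueError:
                raise FeaturizationError(
                    f"swap image token {tok!r} absent from components {self.components}"
                ) from None
        return np.asarray(perm, dtype=int)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "target": self.target,
            "components": list(self.components),
            "augment": self.augment,
            "delta_iso": self.delta_iso,
            "d_form": self.d_form,
            "averages_use_iso": self.averages_use_iso,
            "binding_transform": self.binding_transform,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        d = dict(d)
        d["components"] = tuple(d["components"])
        return cls(**d)


@dataclass
class FeatureMatrix:
    """Numeric design matrix with labels and row identities."""

    X: np.ndarray
    y: np.ndarray
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != len(self.row_ids):
            raise ValueError("inconsistent FeatureMatrix dimensions")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise FeaturizationError("feature matrix contains NaN/Inf")

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(self.X[idx], self.y[idx], [self.row_ids[i] for i in idx])


def _present(value) -> bool:
    return value is not None and np.isfinite(value)


def _token_value(mol: Molecule, tok: str, spec: FeatureSpec, context: dict) -> float:
    a, b = mol.atom1, mol.atom2
    if tok == "g1":
        return float(a.group)
    if tok == "g2":
        return float(b.group)
    if tok == "p1":
        return float(a.period)
    if tok == "p2":
        return float(b.period)
    if tok == "g1_iso":
        return g_iso(a, spec.delta_iso)
    if tok == "g2_iso":
        return g_iso(b, spec.delta_iso)
    if tok == "g_bar":
        if spec.averages_use_iso:
            return 0.5 * (g_iso(a, spec.delta_iso) + g_iso(b, spec.delta_iso))
        return 0.5 * (a.group + b.group)
    if tok == "p_bar":
        return 0.5 * (a.period + b.period)
    if tok in ("Re", "Re_X"):
        if not _present(mol.Re_X):
            raise FeaturizationError(f"{mol.formula}: Re(X) missing")
        return float(mol.Re_X)
    if tok == "inv_Re_X":
        if not _present(mol.Re_X):
            raise FeaturizationError(f"{mol.formula}: Re(X) missing")
        return 1.0 / float(mol.Re_X)
    if tok == "inv_Re2_X":
        if not _present(mol.Re_X):
            raise FeaturizationError(f"{mol.formula}: Re(X) missing")
        return 1.0 / float(mol.Re_X) ** 2
    if tok == "inv_Re_A":
        if not _present(mol.Re_A):
            raise FeaturizationError(f"{mol.formula}: Re(A) missing")
        return 1.0 / float(mol.Re_A)
    if tok == "we_X":
        if not _present(mol.we_X):
            raise FeaturizationError(f"{mol.formula}: we(X) missing")
        return float(mol.we_X)
    if tok in ("Re_hat", "inv_Re_hat"):
        re_hat = context.get("Re_hat", {}).get(mol.formula)
        if re_hat is None:
            raise FeaturizationError(
                f"{mol.formula}: predicted Re required by token {tok!r} "
                "(supply via context['Re_hat'])"
            )
        re_hat = max(float(re_hat), RE_HAT_FLOOR)
        return re_hat if tok == "Re_hat" else 1.0 / re_hat
    if tok == "log_zz":
        return float(np.log(a.Z * b.Z))
    if tok == "parr_transform":
        # transformed electron-density predictor for ω_e: √(Z₁Z₂/m)·e^(−ξ′R_e)
        if not _present(mol.Re_X):
            raise FeaturizationError(f"{mol.formula}: Re(X) missing")
        return float(np.sqrt(a.Z * b.Z / mol.m) * np.exp(-0.97 * mol.Re_X))
    if tok == "D_ip_ea":
        return d_ip_ea(a, b, spec.d_form)
    raise FeaturizationError(f"unknown feature token {tok!r}")


def _target_value(mol: Molecule, spec: FeatureSpec) -> Optional[float]:
    t = spec.target
    if t == "Re":
        return mol.Re_X if _present(mol.Re_X) else None
    if t == "we":
        return mol.we_X if _present(mol.we_X) else None
    if t == "Re_A":
        return mol.Re_A if _present(mol.Re_A) else None
    if t == "we_A":
        return mol.we_A if _present(mol.we_A) else None
    if t == "Dlabel":
        if mol.D0 is None or not _present(mol.we_X):
            return None
        try:
            return binding_label(mol, spec.binding_transform, missing_wexe="zero")
        except ValueError:
            return None
    raise FeaturizationError(f"unknown target {t!r}")


def build_features(
    dataset: SpectroDataset | list[Molecule],
    spec: FeatureSpec,
    context: Optional[dict] = None,
) -> FeatureMatrix:
    """Assemble the feature matrix and label vector for ``spec``.

    Molecules lacking the target label, or any quantity a token needs, are
    dropped and logged.  ``context`` carries externally computed columns
    (currently ``"Re_hat"``: formula → predicted R_e for the hat tokens).
    """
    molecules = dataset.molecules() if isinstance(dataset, SpectroDataset) else dataset
    context = context or {}
    rows, ys, ids, dropped = [], [], [], 0
    for mol in molecules:
        y = _target_value(mol, spec)
        if y is None:
            dropped += 1
            continue
        try:
            rows.append([_token_value(mol, t, spec, context) for t in spec.components])
        except FeaturizationError as exc:
            logger.warning("dropping %s: %s", mol.formula, exc)
            dropped += 1
            continue
        ys.append(y)
        ids.append(mol.formula)
    if not rows:
        raise FeaturizationError(f"no usable records for spec {spec.name!r}")
    if dropped:
        logger.info("spec %s: dropped %d/%d molecules", spec.name, dropped, len(molecules))
    return FeatureMatrix(np.asarray(rows, float), np.asarray(ys, float), ids)


def permutation_augment(fm: FeatureMatrix, spec: FeatureSpec) -> FeatureMatrix:
    """Append the atom-swapped image of every row (labels copied).

    The output has 2n rows; ``row_ids`` are duplicated so augmented rows stay
    attributable to their molecule.
    """
    perm = spec.swap_permutation()
    X_sw = fm.X[:, perm]
    return FeatureMatrix(
        np.vstack([fm.X, X_sw]),
        np.concatenate([fm.y, fm.y]),
        fm.row_ids + fm.row_ids,
    )


def predicted_Re_feature(
    molecules: list[Molecule],
    train_mask: np.ndarray,
    *,
    model=None,
    seed: int = 0,
) -> dict[str, float]:
    """Predicted ground-state R_e for every molecule, fitted on the training rows only.

    Fits a GP on (g1, g2, p1, p2) with permutation augmentation using only the
    molecules flagged by ``train_mask`` (aligned with ``molecules``; no test
    leakage), predicts all rows, and floors the predictions at 0.5 Å.
    Returns formula → R̂_e; the hat tokens invert it where needed.
    """
    from .gp import GaussianProcessBasisRegressor

    base_spec = FeatureSpec("re_hat_inner", "Re", ("g1", "g2", "p1", "p2"))
    train_mask = np.asarray(train_mask, bool)
    if train_mask.shape[0] != len(molecules):
        raise ValueError("train_mask length does not match molecules")
    # restrict the inner fit to molecules whose ground-state Re is known
    usable = [i for i, m in enumerate(molecules) if _target_value(m, base_spec) is not None]
    fm = build_features([molecules[i] for i in usable], base_spec)
    fit_rows = [k for k, i in enumerate(usable) if train_mask[i]]
    if not fit_rows:
        raise FeaturizationError("no training molecules with known Re for R̂_e model")
    train = permutation_augment(fm.subset(fit_rows), base_spec)
    if model is None:
        model = GaussianProcessBasisRegressor(
            kernel="exponential", basis="linear", random_state=seed
        )
    model.fit(train.X, train.y)
    raw = model.predict(fm.X)
    preds = np.maximum(raw, RE_HAT_FLOOR)
    n_clip = int(np.sum(raw < RE_HAT_FLOOR))
    if n_clip:
        logger.info("predicted_Re_feature: %d predictions floored at %.2f Å", n_clip, RE_HAT_FLOOR)
    return dict(zip(fm.row_ids, preds))


def _spec(name, target, components, **kw) -> FeatureSpec:
    return FeatureSpec(name=name, target=target, components=tuple(components), **kw)


#: Named presets for every experiment-grid row (ground state and A state).
PRESETS: dict[str, FeatureSpec] = {
    s.name: s
    for s in [
        # --- ground-state R_e ---
        _spec("table1_Re_gp", "Re", ("g1", "g2", "p1", "p2")),
        _spec("table1_Re_lr", "Re", ("log_zz",), augment=False),
        # --- ground-state ω_e (true-R_e and predicted-R_e variants) ---
        _spec("table1_we_gp_true", "we", ("inv_Re_X", "g1", "g2", "p1", "p2")),
        _spec("table1_we_gp_hat", "we", ("inv_Re_hat", "g1", "g2", "p1", "p2")),
        _spec("table1_we_gp_iso_true", "we", ("inv_Re_X", "g1_iso", "g2_iso", "p1", "p2")),
        _spec("table1_we_gp_iso_hat", "we", ("inv_Re_hat", "g1_iso", "g2_iso", "p1", "p2")),
        _spec("table1_we_gp_iso_pbar_true", "we",
              ("inv_Re_X", "g1_iso", "g2_iso", "p1", "p2", "p_bar")),
        _spec("table1_we_gp_iso_pbar_hat", "we",
              ("inv_Re_hat", "g1_iso", "g2_iso", "p1", "p2", "p_bar")),
        _spec("table1_we_gp_iso_gbar_true", "we",
              ("inv_Re_X", "g1_iso", "g2_iso", "p1", "p2", "g_bar")),
        _spec("table1_we_gp_iso_gbar_hat", "we",
              ("inv_Re_hat", "g1_iso", "g2_iso", "p1", "p2", "g_bar")),
        _spec("table1_we_lr_parr", "we", ("parr_transform",), augment=False),
        _spec("table1_we_lr_invre2", "we", ("inv_Re2_X",), augment=False),
        # --- ground-state binding label ---
        _spec("table1_D_gp_true", "Dlabel", ("Re_X", "g_bar", "p_bar")),
        _spec("table1_D_gp_hat", "Dlabel", ("Re_hat", "g_bar", "p_bar")),
        _spec("table1_D_lr", "Dlabel", ("Re_X",), augment=False),
        # --- A-state R_e ---
        _spec("table2_ReA_gp", "Re_A", ("Re_X", "g1", "g2", "p1", "p2")),
        _spec("table2_ReA_gp_dipea", "Re_A",
              ("Re_X", "g1", "g2", "p1", "p2", "D_ip_ea")),
        # --- A-state ω_e ---
        _spec("table2_weA_gp_gbar", "we_A",
              ("we_X", "inv_Re_X", "inv_Re_A", "g1_iso", "g2_iso", "p1", "p2", "g_bar")),
        _spec("table2_weA_gp_iso", "we_A",
              ("we_X", "inv_Re_X", "inv_Re_A", "g1_iso", "g2_iso", "p1", "p2")),
        _spec("table2_weA_gp", "we_A",
              ("we_X", "inv_Re_X", "inv_Re_A", "g1", "g2", "p1", "p2")),
    ]
}


def get_preset(name: str, **overrides) -> FeatureSpec:
    """Look up a preset, optionally overriding fields (e.g. ``augment=False``)."""
    if name.startswith("preset:"):
        name = name[len("preset:"):]
    try:
        spec = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return replace(spec, **overrides) if overrides else spec
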