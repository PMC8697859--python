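"""Synthetic diatomic-constants datasets with known ground truth.

The generator emulates the *statistical* structure the analysis assumes — it
is not a physical spectra simulator.  Element pairs are drawn without
replacement from a periodic-table pool; the equilibrium distance comes from
one of three truth models, all expressible in the classical relations the
baselines target so that every pipeline stage has a known optimum:

* ``smooth_gp_surface`` — R_e* drawn from a GP over (ḡ, p̄) (Matérn 5/2,
  σ_f = 0.4 Å, l = 3.0, mean 0.55·p̄ + 0.9 Å), clipped to [0.8, 4.5] Å;
* ``parr_exact`` — R_e* from the exponential electron-density relation
  Z₁Z₂ = A·exp(ξR_e) (defaults ξ = 2.0, A = 10);
* ``badger_exact`` — R_e* from the smooth mean surface plus scatter.

ω_e* follows the mass-adjusted Morse-type link ω = K/(R_e³√m) (exact for
``badger_exact``; the generating rule is R_e³·ω_e·√m = const), except under
``parr_exact`` where ω_e* comes from the electron-density force constant.
The well depth obeys D_e = A_D·m·ω_e²·R_e³ (l = 3), the anharmonicity is set
to ω_e x_e = 0.01·ω_e (typical scale, a synthetic convention), and D_0
inverts the D_e/D_0 relation.  Independent Gaussian noise is added per
config; the noiseless truth is returned as a sidecar table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .constants import CM1_TO_EV
from .dataset import SpectroDataset, SpectroRecord, load_dataset  # noqa: F401
from .elements import get_element_table
from .gp import _kernel_matrix
from scipy.spatial.distance import squareform, pdist

__all__ = ["SynthConfig", "generate", "make_fixture", "DEFAULT_POOL"]

logger = logging.getLogger(__name__)

#: Default element pool: main-group and transition metals over periods 1–6.
DEFAULT_POOL = [
    "H", "D", "Li", "Be", "B", "C", "N", "O", "F",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl",
    "K", "Ca", "Sc", "Ti", "Cr", "Mn", "Fe", "Ni", "Cu", "Zn", "Ga", "Se", "Br",
    "Rb", "Sr", "Y", "Zr", "Ag", "Cd", "In", "Sn", "Sb", "Te", "I",
    "Cs", "Ba", "La", "Hf", "W", "Pt", "Au", "Hg", "Pb", "Bi",
]

#: Morse-type link constant: ω_e = K_MORSE/(R_e³·√m)  [cm⁻¹·Å³·u^½].
K_MORSE = 2.0e4
#: Well-depth prefactor A_D in D_e = A_D·m·ω_e²·R_e³  [eV·u⁻¹·cm²·Å⁻³].
A_DE = 2.0e-7
#: Anharmonicity fraction ω_e x_e / ω_e.
WEXE_FRACTION = 0.01

TRUTHS = ("smooth_gp_surface", "parr_exact", "badger_exact")


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration (defaults are the standard study conditions)."""

    n_molecules: int = 250
    noise_Re: float = 0.05  # additive sd, Å
    noise_we: float = 0.03  # relative sd
    noise_D0: float = 0.05  # relative sd
    seed: int = 0
    truth: str = "smooth_gp_surface"
    element_pool: tuple[str, ...] = tuple(DEFAULT_POOL)
    a_state: bool = False
    # truth-model parameters
    xi: float = 2.0          # parr_exact decay constant (Å⁻¹)
    A: float = 10.0          # parr_exact prefactor
    parr_C: float = 1.0      # electron-density force-constant scale (eV/Å²)
    parr_xi_we: float = 1.0  # decay constant in the ω_e link (Å⁻¹)

    def __post_init__(self) -> None:
        if self.n_molecules < 30:
            raise ValueError("n_molecules must be >= 30")
        if min(self.noise_Re, self.noise_we, self.noise_D0) < 0:
            raise ValueError("noise levels must be >= 0")
        if self.truth not in TRUTHS:
            raise ValueError(f"truth must be one of {TRUTHS}")


def _sample_pairs(config: SynthConfig, rng: np.random.Generator):
    table = get_element_table()
    pool = [table[s] for s in config.element_pool]
    if len(pool) < 10 or len({e.period for e in pool}) < 3:
        raise ValueError("element pool must have >= 10 elements over >= 3 periods")
    n_pairs = len(pool) * (len(pool) - 1) // 2
    if config.n_molecules > n_pairs:
        raise ValueError(
            f"pool supports only {n_pairs} unique heteronuclear pairs, "
            f"{config.n_molecules} requested"
        )
    chosen: list[tuple] = []
    seen: set[frozenset] = set()
    guard = 0
    while len(chosen) < config.n_molecules:
        guard += 1
        if guard > 200 * config.n_molecules:
            raise RuntimeError("pair sampling failed to converge; shrink constraints")
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[i], pool[j]
        key = frozenset((a.symbol, b.symbol))
        if key in seen:
            continue
        if config.truth == "parr_exact":
            re_true = (np.log(a.Z * b.Z) - np.log(config.A)) / config.xi
            if not (0.5 <= re_true <= 6.0):
                continue
        seen.add(key)
        chosen.append((a, b))
    return chosen


def generate(config: SynthConfig) -> tuple[SpectroDataset, pd.DataFrame]:
    """Generate a synthetic dataset; returns (dataset, truth sidecar).

    The sidecar holds the noiseless truth per molecule and carries the
    generator parameters in ``DataFrame.attrs["params"]``.  Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2024]))
    pairs = _sample_pairs(config, rng)
    n = len(pairs)
    g_bar = np.array([(a.group + b.group) / 2.0 for a, b in pairs])
    p_bar = np.array([(a.period + b.period) / 2.0 for a, b in pairs])
    m = np.array([a.mass * b.mass / (a.mass + b.mass) for a, b in pairs])
    zz = np.array([a.Z * b.Z for a, b in pairs], dtype=float)

    mean_surface = 0.55 * p_bar + 0.9
    if config.truth == "smooth_gp_surface":
        U = np.column_stack([g_bar, p_bar])
        K = _kernel_matrix(squareform(pdist(U)), "matern52", 0.4, 3.0)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        re_true = np.clip(mean_surface + L @ rng.standard_normal(n), 0.8, 4.5)
    elif config.truth == "parr_exact":
        re_true = (np.log(zz) - np.log(config.A)) / config.xi
    else:  # badger_exact
        re_true = np.clip(mean_surface + 0.3 * rng.standard_normal(n), 0.8, 4.5)

    if config.truth == "parr_exact":
        k_force = 4.0 * np.pi * config.parr_C * zz * np.exp(-2.0 * config.parr_xi_we * re_true)
        from .constants import force_constant_to_wavenumber

        we_true = np.array(
            [force_constant_to_wavenumber(k, mi) for k, mi in zip(k_force, m)]
        )
    else:
        we_true = K_MORSE / (re_true**3 * np.sqrt(m))

    wexe_true = WEXE_FRACTION * we_true
    de_true = A_DE * m * we_true**2 * re_true**3
    d0_true = de_true - (0.5 * we_true - 0.25 * wexe_true) * CM1_TO_EV
    if np.any(d0_true <= 0):
        raise RuntimeError("generator produced nonpositive D0; adjust constants")

    re_obs = np.maximum(re_true + config.noise_Re * rng.standard_normal(n), 0.3)
    we_obs = np.maximum(we_true * (1.0 + config.noise_we * rng.standard_normal(n)), 1.0)
    d0_obs = np.maximum(d0_true * (1.0 + config.noise_D0 * rng.standard_normal(n)), 1e-3)

    records = []
    truth_rows = []
    for i, (a, b) in enumerate(pairs):
        formula = a.symbol + b.symbol
        records.append(
            SpectroRecord(
                formula=formula, atom1=a, atom2=b, state="X",
                Re=float(re_obs[i]), we=float(we_obs[i]),
                wexe=float(wexe_true[i]), D0=float(d0_obs[i]),
            )
        )
        truth_rows.append(
            {
                "formula": formula, "Re_true": re_true[i], "we_true": we_true[i],
                "wexe_true": wexe_true[i], "De_true": de_true[i], "D0_true": d0_true[i],
            }
        )

    if config.a_state:
        re_a_true = 1.08 * re_true + 0.05
        we_a_true = 0.9 * K_MORSE / (re_a_true**3 * np.sqrt(m))
        re_a_obs = np.maximum(re_a_true + config.noise_Re * rng.standard_normal(n), 0.3)
        we_a_obs = np.maximum(we_a_true * (1.0 + config.noise_we * rng.standard_normal(n)), 1.0)
        for i, (a, b) in enumerate(pairs):
            records.append(
                SpectroRecord(
                    formula=a.symbol + b.symbol, atom1=a, atom2=b, state="A",
                    Re=float(re_a_obs[i]), we=float(we_a_obs[i]),
                )
            )
            truth_rows[i]["Re_A_true"] = re_a_true[i]
            truth_rows[i]["we_A_true"] = we_a_true[i]

    truth = pd.DataFrame(truth_rows)
    truth.attrs["params"] = {
        **asdict(config),
        "element_pool": list(config.element_pool),
        "K_MORSE": K_MORSE,
        "A_DE": A_DE,
        "wexe_fraction": WEXE_FRACTION,
    }
    return SpectroDataset(records), truth


def make_fixture(
    kind: str = "tiny", seed: int = 0, out_dir: Optional[str] = None
) -> dict[str, str]:
    """Write a ready-to-load fixture; returns the file paths.

    ``tiny`` is a 40-molecule set for fast unit tests; ``standard`` is a
    250-molecule set with ~75% D_0 coverage and ~50% A-state coverage,
    mirroring the 256/197/131 proportions of the reference experimental
    compilation.  Regeneration under a fixed seed is byte-identical.
    """
    if kind == "tiny":
        config = SynthConfig(n_molecules=40, seed=seed)
        d0_cov, a_cov = 1.0, 0.0
    elif kind == "standard":
        config = SynthConfig(n_molecules=250, seed=seed, a_state=True)
        d0_cov, a_cov = 0.75, 0.5
    else:
        raise ValueError("kind must be 'tiny' or 'standard'")

    dataset, truth = generate(config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4099]))
    x_records = [r for r in dataset.records if r.state == "X"]
    n = len(x_records)
    drop_d0 = set(rng.choice(n, size=int(round((1 - d0_cov) * n)), replace=False))
    keep_a = set(rng.choice(n, size=int(round(a_cov * n)), replace=False))
    kept = []
    for i, r in enumerate(x_records):
        if i in drop_d0:
            r.D0 = None
            r.wexe = None
        kept.append(r)
    a_by_formula = {r.formula: r for r in dataset.records if r.state == "A"}
    for i, r in enumerate(x_records):
        if i in keep_a and r.formula in a_by_formula:
            kept.append(a_by_formula[r.formula])
    dataset = SpectroDataset(kept)

    out = Path(out_dir) if out_dir else Path(".")
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "data": str(out / f"{kind}_data.csv"),
        "truth": str(out / f"{kind}_truth.csv"),
        "params": str(out / f"{kind}_generator.json"),
    }
    dataset.to_csv(paths["data"])
    truth.to_csv(paths["truth"], index=False)
    with open(paths["params"], "w", encoding="utf-8") as fh:
        json.dump(truth.attrs["params"], fh, indent=2, sort_keys=True)
    logger.info("wrote %s fixture: %s", kind, paths["data"])
    return paths
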