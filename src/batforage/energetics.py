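"""Diet tables and the energy model.

Converts prey body lengths to dry masses with per-order power laws
(mass_mg = a * length_mm^b) weighted by the relative abundance of the two
dominant orders in each foraging niche — ground diet: Carabidae (78%) and
Orthoptera (22%); aerial diet: Diptera (65%) and Lepidoptera (35%) — then
to caloric values (25.4 kJ/g dry mass for ground prey, 21.3 kJ/g for
aerial prey), and aggregates nightly intake, assimilated energy (50–82%
assimilation efficiency) and the prey-profitability index

    P = prey caloric value / (handling time + time between attacks)
        * success ratio          [J/s]

An independent estimate of aerial prey dry mass comes from the ratio of
per-capture mastication counts between aerial and ground prey, anchored
to the ground-prey mass from DNA metabarcoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "PreyRecord",
    "MassModel",
    "EnergyConfig",
    "ProfitabilityInputs",
    "load_mass_model",
    "classify_niche",
    "length_to_drymass",
    "aerial_mass_from_chewratio",
    "caloric_value",
    "nightly_intake",
    "assimilated_energy",
    "fmr_allometric",
    "profitability",
]

MG_PER_G = 1000.0
J_PER_KJ = 1000.0


@dataclass
class PreyRecord:
    otu: str
    order: str
    niche: str  # 'ground' | 'aerial' | 'both'
    body_length_mm: float


@dataclass
class MassModel:
    """Per-order length-mass power laws with niche composition weights.

    ``coefficients``: order -> (a, b) with mass_mg = a * length_mm ** b.
    ``order_weights``: niche -> {order: weight}; weights per niche sum to 1.
    """

    coefficients: dict
    order_weights: dict = field(
        default_factory=lambda: {
            "ground": {"Carabidae": 0.78, "Orthoptera": 0.22},
            "aerial": {"Diptera": 0.65, "Lepidoptera": 0.35},
        }
    )

    def __post_init__(self):
        for niche, w in self.order_weights.items():
            s = sum(w.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"order weights for {niche!r} sum to {s:g}, not 1")
        for order, (a, b) in self.coefficients.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"non-positive power-law coefficient for {order!r}")


@dataclass
class EnergyConfig:
    caloric_density_kj_g: dict = field(default_factory=lambda: {"ground": 25.4, "aerial": 21.3})
    assimilation: tuple = (0.50, 0.82)
    fmr_exponent: float = 0.7
    aerial_mass_mg: dict = field(default_factory=lambda: {"lower": 3.0, "higher": 21.2})
    ground_mass_mg: float = 67.5


@dataclass
class ProfitabilityInputs:
    prey_caloric_value_j: float
    handling_time_s: float
    time_between_attacks_s: float
    success_ratio: float


def load_mass_model() -> MassModel:
    """Load the shipped per-order length-mass coefficient table.

    The coefficients are editable defaults (typical insect length-mass
    allometries on the mg/mm scale); the energy arithmetic elsewhere in
    this module anchors to already-converted mean dry masses and does not
    depend on them.
    """
    with resources.files("batforage.data").joinpath("length_mass_coefficients.csv").open() as f:
        df = pd.read_csv(f, comment="#")
    return MassModel(coefficients={r["order"]: (float(r["a"]), float(r["b"])) for _, r in df.iterrows()})


def classify_niche(diet: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop prey occupying both niches and return niche proportions.

    Returns (filtered table, {'aerial': p, 'ground': p}).
    """
    if len(diet) == 0:
        raise ValueError("empty diet table")
    kept = diet[diet["niche"].isin(["ground", "aerial"])].reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError("no prey left after dropping niche='both' records")
    props = kept["niche"].value_counts(normalize=True).to_dict()
    return kept, {n: float(props.get(n, 0.0)) for n in ("aerial", "ground")}


def length_to_drymass(length_mm: float, niche: str, model: MassModel) -> float:
    """Dry mass (mg) as the niche-weighted average of per-order power laws."""
    if length_mm <= 0:
        raise ValueError("length must be > 0")
    if niche not in model.order_weights:
        raise ValueError(f"unknown niche {niche!r}")
    mass = 0.0
    for order, w in model.order_weights[niche].items():
        if order not in model.coefficients:
            raise ValueError(f"missing length-mass coefficients for order {order!r}")
        a, b = model.coefficients[order]
        mass += w * a * length_mm**b
    return mass


def aerial_mass_from_chewratio(ground_mass_mg: float, chews_ground: float, chews_aerial: float) -> float:
    """Aerial prey dry mass from the mastication-count ratio.

    Bats chew longer on larger prey, so the per-capture chew-count ratio
    scales the ground-prey reference mass.
    """
    if chews_ground <= 0:
        raise ValueError("ground chew count must be > 0")
    return ground_mass_mg * (chews_aerial / chews_ground)


def caloric_value(drymass_mg: float, niche: str, cfg: EnergyConfig | None = None) -> float:
    """Energy content of one prey item in joules."""
    cfg = cfg or EnergyConfig()
    if drymass_mg < 0:
        raise ValueError("mass must be >= 0")
    if niche not in cfg.caloric_density_kj_g:
        raise ValueError(f"unknown niche {niche!r}")
    return (drymass_mg / MG_PER_G) * cfg.caloric_density_kj_g[niche] * J_PER_KJ


def nightly_intake(
    successes: dict,
    cfg: EnergyConfig | None = None,
) -> tuple[float, float]:
    """Nightly ingested energy (kJ) for the lower and higher aerial prey
    mass estimates.

    ``successes``: {'glean': n_ground_captures, 'hawk': n_aerial_captures}.
    """
    cfg = cfg or EnergyConfig()
    ng = successes.get("glean", 0)
    na = successes.get("hawk", 0)
    if ng < 0 or na < 0:
        raise ValueError("success counts must be >= 0")
    ground_j = caloric_value(cfg.ground_mass_mg, "ground", cfg)
    out = []
    for est in ("lower", "higher"):
        aerial_j = caloric_value(cfg.aerial_mass_mg[est], "aerial", cfg)
        out.append((ng * ground_j + na * aerial_j) / J_PER_KJ)
    return out[0], out[1]


def assimilated_energy(intake_kj: float, efficiency: float) -> float:
    """Metabolizable energy after assimilation losses."""
    if not (0.0 < efficiency <= 1.0):
        raise ValueError("assimilation efficiency must be in (0, 1]")
    return intake_kj * efficiency


def fmr_allometric(fmr_ref_kj: float, mass_ref_g: float, mass_target_g: float, exponent: float = 0.7) -> float:
    """Field metabolic rate scaled allometrically between body masses."""
    if mass_ref_g <= 0 or mass_target_g <= 0:
        raise ValueError("masses must be > 0")
    return fmr_ref_kj * (mass_target_g / mass_ref_g) ** exponent


def profitability(inp: ProfitabilityInputs) -> float:
    """Prey profitability P = calories / (handling + search) * success (J/s)."""
    denom = inp.handling_time_s + inp.time_between_attacks_s
    if denom <= 0:
        raise ValueError("handling time + time between attacks must be > 0")
    if not (0.0 <= inp.success_ratio <= 1.0):
        raise ValueError("success ratio must be in [0, 1]")
    return inp.prey_caloric_value_j / denom * inp.success_ratio
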