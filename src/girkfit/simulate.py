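"""Synthetic Gβγ/Na⁺ titration data with the bilayer experiment's design.

The generator emulates the planar-bilayer titration: for each Na⁺ level
(default 0, 8, 32 mM) and each Ni-NTA-lipid mole fraction (default 0
plus eight log-spaced points across 2×10⁻⁴–0.015, the range accessible
in the bilayer), three replicate bilayers are "measured" as the model
activity plus Gaussian noise (σ = 0.03 on the normalized-current scale,
chosen to match the error-bar scale of the real recordings), truncated
at zero because normalized inward current cannot be negative.  Mean and
SEM = sd/√n over replicates are recorded, mirroring how the real data
are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import TitrationDataset
from .model import predicted_activity
from .variants import GatingParameters, VariantSpec, get_variant

__all__ = [
    "SyntheticDesign",
    "make_design",
    "simulate_dataset",
    "simulate_bilayer_raw",
    "simulate_cell_na_experiment",
]

_X_MAX_DEFAULT = 0.015


def _default_x_grid() -> tuple[float, ...]:
    return (0.0,) + tuple(np.geomspace(2e-4, _X_MAX_DEFAULT, 8))


@dataclass(frozen=True)
class SyntheticDesign:
    """Grid and noise description of one simulated titration experiment."""

    na_levels: tuple[float, ...] = (0.0, 8.0, 32.0)
    x_g_grid: tuple[float, ...] = field(default_factory=_default_x_grid)
    n_rep: int = 3
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "na_levels", tuple(float(v) for v in self.na_levels))
        object.__setattr__(self, "x_g_grid", tuple(float(v) for v in self.x_g_grid))
        if any(v < 0 for v in self.na_levels):
            raise ValueError("na_levels must be non-negative")
        if any(not 0 <= v <= _X_MAX_DEFAULT for v in self.x_g_grid):
            raise ValueError(
                f"x_g_grid values must lie in [0, {_X_MAX_DEFAULT}]"
            )
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_points(self) -> int:
        return len(self.na_levels) * len(self.x_g_grid)

    def to_dict(self) -> dict:
        return asdict(self)


def make_design(**overrides) -> SyntheticDesign:
    """Default design merged with keyword overrides, validated."""
    return SyntheticDesign(**overrides)


def simulate_dataset(
    params: GatingParameters,
    variant: VariantSpec | str,
    design: SyntheticDesign | None = None,
    seed: int | None = None,
) -> TitrationDataset:
    """Draw one synthetic titration dataset from the gating model.

    Per grid point, ``n_rep`` replicate activities are drawn as model
    prediction + N(0, noise_sd), truncated at 0; the recorded mean and
    SEM summarize the replicates.  Reproducible: the same seed yields
    the identical dataset.  ``seed`` defaults to ``design.seed``.
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    if design is None:
        design = SyntheticDesign()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows = []
    for na in design.na_levels:
        for x in design.x_g_grid:
            mu = predicted_activity(x, na, params, variant)
            if design.noise_sd == 0:
                mean, sd = float(mu), 0.0
            else:
                draws = mu + rng.normal(0.0, design.noise_sd, size=design.n_rep)
                draws = np.maximum(draws, 0.0)
                mean = float(draws.mean())
                sd = float(draws.std(ddof=1)) if design.n_rep > 1 else 0.0
            rows.append(
                {
                    "variant": variant.name,
                    "na_mM": na,
                    "ni_nta_fraction": x,
                    "normalized_current_mean": mean,
                    "sem": sd / np.sqrt(design.n_rep),
                    "n_rep": design.n_rep,
                }
            )
    return TitrationDataset(pd.DataFrame(rows))


def simulate_bilayer_raw(
    params: GatingParameters,
    variant: VariantSpec | str,
    x_g: float,
    na: float,
    n_channels: int = 100,
    unit_current: float = 1.0,
) -> tuple[float, float, float]:
    """One bilayer "measurement": raw, fully-activated, normalized current.

    The fully-activated current is the reference obtained by fusing
    lipid-anchored Gβγ; by convention its activity is 1, so the fitted θ
    absorbs the true full-activation scale (which is why fitted θ can
    exceed 1).  Normalization cancels channel count and unit current.
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if unit_current <= 0:
        raise ValueError("unit_current must be positive")
    a = predicted_activity(x_g, na, params, variant)
    raw = n_channels * unit_current * a
    full = n_channels * unit_current * 1.0
    return raw, full, raw / full


def simulate_cell_na_experiment(
    mix_fraction_girk14: float,
    params14: GatingParameters,
    params4: GatingParameters,
    na_pair: tuple[float, float] = (0.0, 30.0),
    x_g_effective: float = 0.001,
) -> float:
    """Predicted Na⁺ fold-change of whole-cell GIRK current.

    Models a cell expressing a mixture of GIRK1/4 hetero-tetramers
    (fraction ``mix_fraction_girk14``) and GIRK4 homo-tetramers; the
    population current at each Na⁺ level is the mixture-weighted sum of
    the two variants' activities at a common effective Gβγ density.
    Returns current(high Na⁺)/current(low Na⁺).  A ratio near 1 at
    mix_fraction ≈ 1 captures why pacemaker-cell GIRK current, carried
    predominantly by GIRK1/4, is insensitive to intracellular Na⁺.
    """
    if not 0 <= mix_fraction_girk14 <= 1:
        raise ValueError("mix_fraction_girk14 must lie in [0, 1]")
    v14 = get_variant("GIRK1_4")
    v4 = get_variant("GIRK4")
    lo, hi = na_pair

    def pop_current(na: float) -> float:
        a14 = predicted_activity(x_g_effective, na, params14, v14)
        a4 = predicted_activity(x_g_effective, na, params4, v4)
        return mix_fraction_girk14 * a14 + (1 - mix_fraction_girk14) * a4

    denom = pop_current(lo)
    if denom <= 0:
        raise ZeroDivisionError("population current at low Na⁺ is zero")
    return pop_current(hi) / denom
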