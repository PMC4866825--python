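"""Channel variants and gating parameters.

Cardiac GIRK channels are tetramers carrying four Gβγ-binding sites and up
to four intracellular Na⁺-binding sites.  Three variants are modelled:

``GIRK4``
    Homo-tetramer.  All four Na⁺ sites are functional, so the occupancy
    grid spans 0–4 Na⁺ × 0–4 Gβγ (25 states).
``GIRK1_4``
    Hetero-tetramer with two GIRK1 subunits.  The GIRK1 Na⁺ site is
    defective and behaves as if Na⁺ were permanently bound, so only two
    sites titrate and the Na⁺ index runs 2–4 (15 states).
``GIRK1N217D_4``
    Hetero-tetramer in which the N217D point mutation restores the GIRK1
    Na⁺ site, recovering the full 0–4 Na⁺ grid (25 states).

The open state requires full Gβγ occupancy (j = 4 by default); its
conductance factor θ depends on Na⁺ occupancy i.  For the homo-tetramer
and the N217D variant θ interpolates linearly between θ(0) and θ(4); for
GIRK1/4 each accessible θ(i) is an independent parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "GatingParameters",
    "VariantSpec",
    "VARIANTS",
    "get_variant",
    "REFERENCE_PARAMETERS",
]


@dataclass(frozen=True)
class GatingParameters:
    """Parameter vector of the equilibrium gating model.

    Parameters
    ----------
    k_db : float
        Gβγ equilibrium dissociation constant for the ligand-free channel,
        in units of Ni-NTA-lipid mole fraction.
    k_dn : float
        Na⁺ equilibrium dissociation constant, mM.
    b : float
        Per-step Gβγ cooperativity factor: the j-th Gβγ binds with
        microscopic dissociation constant ``k_db * b**(j-1)``.  b < 1
        means positive cooperativity.
    eta : float
        Gβγ–Na⁺ cross-cooperativity: each bound Na⁺ multiplies every Gβγ
        dissociation constant by eta (and reciprocally, each bound Gβγ
        multiplies the Na⁺ constant by eta).  eta < 1 means Na⁺ raises
        Gβγ affinity.
    theta : mapping int -> float
        Normalized activity of the fully Gβγ-occupied open state, keyed
        by Na⁺ occupancy i.  In interpolated mode only the anchors
        ``theta[0]`` and ``theta[4]`` are required; in free mode one
        value per accessible i.  Values above 1 are legal because the
        normalization reference is the experimentally fully-activated
        current, not the model maximum.
    """

    k_db: float
    k_dn: float
    b: float
    eta: float
    theta: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("k_db", "k_dn", "b", "eta"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v!r}")
        for i, v in self.theta.items():
            if not (0 <= i <= 4):
                raise ValueError(f"theta index {i} outside 0..4")
            if v < 0:
                raise ValueError(f"theta[{i}] must be >= 0, got {v!r}")
        object.__setattr__(self, "theta", dict(self.theta))

    def replace(self, **changes) -> "GatingParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class VariantSpec:
    """Structural description of one channel variant's occupancy grid."""

    name: str
    n_variable_na_sites: int
    i_baseline: int
    theta_mode: str  # "interpolated" | "free"

    def __post_init__(self) -> None:
        if self.i_baseline + self.n_variable_na_sites != 4:
            raise ValueError("baseline + variable Na sites must equal 4")
        if self.theta_mode not in ("interpolated", "free"):
            raise ValueError(f"unknown theta_mode {self.theta_mode!r}")

    @property
    def i_range(self) -> range:
        """Accessible Na⁺ occupancy indices (inclusive of both ends)."""
        return range(self.i_baseline, 5)

    @property
    def n_states(self) -> int:
        return len(self.i_range) * 5

    @property
    def free_theta_indices(self) -> tuple[int, ...]:
        """θ indices that are independent parameters for this variant."""
        if self.theta_mode == "interpolated":
            return (0, 4)
        return tuple(self.i_range)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        """Full parameter-vector names in canonical order."""
        return ("k_db", "k_dn", "b", "eta") + tuple(
            f"theta_{i}_4" for i in self.free_theta_indices
        )


VARIANTS: dict[str, VariantSpec] = {
    "GIRK4": VariantSpec("GIRK4", 4, 0, "interpolated"),
    "GIRK1_4": VariantSpec("GIRK1_4", 2, 2, "free"),
    "GIRK1N217D_4": VariantSpec("GIRK1N217D_4", 4, 0, "interpolated"),
}


def get_variant(name: str) -> VariantSpec:
    """Look up a variant by name, raising a clear error for unknown names."""
    try:
        return VARIANTS[name]
    except KeyError:
        raise KeyError(
            f"unknown variant {name!r}; expected one of {sorted(VARIANTS)}"
        ) from None


# Published estimates from bilayer Gβγ/Na⁺ titrations of the purified
# channels; used as simulation ground truth and as fit sanity anchors.
REFERENCE_PARAMETERS: dict[str, GatingParameters] = {
    "GIRK4": GatingParameters(
        k_db=0.004, k_dn=50.0, b=0.6, eta=0.7, theta={0: 0.6, 4: 1.2}
    ),
    "GIRK1_4": GatingParameters(
        k_db=0.004, k_dn=50.0, b=0.6, eta=0.8, theta={2: 1.1, 3: 1.2, 4: 1.1}
    ),
    "GIRK1N217D_4": GatingParameters(
        k_db=0.0024, k_dn=50.0, b=0.6, eta=0.71, theta={0: 0.45, 4: 1.1}
    ),
}
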