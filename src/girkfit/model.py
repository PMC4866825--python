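"""Equilibrium occupancy model for Gβγ/Na⁺ gating of GIRK channels.

The channel is treated as a grand-canonical binding polynomial over joint
occupancy states (i Na⁺, j Gβγ).  Relative to the reference state
(minimal Na⁺ occupancy, no Gβγ) the statistical weight of state (i, j) is

    w(i, j) = C(n_var, i - i0) * (na / K_dn)**(i - i0)
            * C(4, j) * (x_g / K_db)**j
            * b**(-j*(j-1)/2) * eta**(-i*j)

with n_var the number of titratable Na⁺ sites and i0 the permanently
occupied baseline (2 for GIRK1/4, else 0).  The factor b**(-j(j-1)/2)
encodes successive-site Gβγ cooperativity (the j-th Gβγ binds with
dissociation constant K_db * b**(j-1)); eta**(-i*j) encodes the mutual
effect of the two ligands on each other's affinity.  Na⁺ binding itself
is non-cooperative (binomial with a single K_dn).

Only states with full Gβγ occupancy conduct; predicted normalized
activity is the θ-weighted probability of those states,

    A(x_g, na) = Σ_i θ(i) w(i, 4) / Σ_{i,j} w(i, j).

Gβγ concentration is expressed throughout as Ni-NTA-lipid mole fraction;
K_db is calibrated in the same units.  The 1:3 sGβγ:Ni-NTA stoichiometry
conversion (`gbg_surface_density`) is for reporting only and never enters
the weights.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.special import comb, logsumexp

from .variants import GatingParameters, VariantSpec

__all__ = [
    "StateIndex",
    "enumerate_states",
    "theta_open",
    "state_weight",
    "weight_matrix",
    "occupancy_distribution",
    "predicted_activity",
    "fold_activation",
    "gbg_surface_density",
    "collapsed_reference_model",
    "CollapsedGbgModel",
]


class StateIndex(NamedTuple):
    """One ligand-occupancy state: i Na⁺ ions and j Gβγ molecules bound."""

    i: int
    j: int


def enumerate_states(variant: VariantSpec) -> list[StateIndex]:
    """Full occupancy grid of a variant, i-major then j, stable order.

    GIRK4 and GIRK1(N217D)/4 have 25 states (i, j = 0..4); GIRK1/4 has
    15 states (i = 2..4, j = 0..4).
    """
    return [StateIndex(i, j) for i in variant.i_range for j in range(5)]


def theta_open(i: int, params: GatingParameters, variant: VariantSpec) -> float:
    """Open-state activity factor θ(i) for the i-Na⁺, fully-Gβγ-bound state.

    Interpolated mode: θ(i) = θ(0) + (θ(4) − θ(0)) · i/4.
    Free mode: θ(i) looked up directly.
    """
    if i not in variant.i_range:
        raise ValueError(
            f"Na occupancy i={i} outside {variant.name} range "
            f"[{variant.i_baseline}, 4]"
        )
    th = params.theta
    if variant.theta_mode == "interpolated":
        try:
            t0, t4 = th[0], th[4]
        except KeyError as exc:
            raise ValueError(
                "interpolated theta mode requires theta[0] and theta[4]"
            ) from exc
        return t0 + (t4 - t0) * i / 4.0
    try:
        return th[i]
    except KeyError as exc:
        raise ValueError(f"free theta mode requires theta[{i}]") from exc


def _theta_row(params: GatingParameters, variant: VariantSpec) -> np.ndarray:
    return np.array([theta_open(i, params, variant) for i in variant.i_range])


def _check_conditions(x_g, na) -> tuple[np.ndarray, np.ndarray]:
    x_g = np.asarray(x_g, dtype=float)
    na = np.asarray(na, dtype=float)
    if np.any(x_g < 0):
        raise ValueError("x_g must be non-negative")
    if np.any(na < 0):
        raise ValueError("na must be non-negative")
    return x_g, na


def weight_matrix(
    x_g,
    na,
    params: GatingParameters,
    variant: VariantSpec,
) -> np.ndarray:
    """Statistical weights of all occupancy states.

    Parameters
    ----------
    x_g, na : array_like, broadcastable
        Gβγ concentration (Ni-NTA mole fraction) and Na⁺ concentration
        (mM).
    params, variant
        Model parameters and occupancy-grid description.

    Returns
    -------
    ndarray, shape broadcast(x_g, na).shape + (n_i, 5)
        w[..., a, j] is the weight of the state with i = i_baseline + a
        Na⁺ and j Gβγ bound.  The reference state has weight exactly 1.
    """
    x_g, na = _check_conditions(x_g, na)
    i0 = variant.i_baseline
    i_vals = np.arange(i0, 5)
    k_vals = i_vals - i0  # titratable Na occupancy
    j_vals = np.arange(5)

    # Occupancy factors; 0**0 == 1 handles na == 0 and x_g == 0 exactly.
    na_fac = comb(variant.n_variable_na_sites, k_vals) * (
        na[..., None] / params.k_dn
    ) ** k_vals  # (..., n_i)
    g_fac = (
        comb(4, j_vals)
        * (x_g[..., None] / params.k_db) ** j_vals
        * params.b ** (-j_vals * (j_vals - 1) / 2.0)
    )  # (..., 5)
    cross = params.eta ** (-np.outer(i_vals, j_vals).astype(float))  # (n_i, 5)
    w = na_fac[..., :, None] * g_fac[..., None, :] * cross
    return w


def state_weight(
    s: StateIndex,
    x_g: float,
    na: float,
    params: GatingParameters,
    variant: VariantSpec,
) -> float:
    """Weight of a single state relative to the reference state."""
    i, j = s
    if i not in variant.i_range or not (0 <= j <= 4):
        raise ValueError(f"state {s!r} invalid for variant {variant.name}")
    w = weight_matrix(x_g, na, params, variant)
    return float(w[..., i - variant.i_baseline, j])


def occupancy_distribution(
    x_g,
    na,
    params: GatingParameters,
    variant: VariantSpec,
) -> np.ndarray:
    """Equilibrium state probabilities; normalized over the full grid."""
    w = weight_matrix(x_g, na, params, variant)
    z = w.sum(axis=(-2, -1), keepdims=True)
    if not np.all(np.isfinite(z)):
        # overflow guard: renormalize in log space
        with np.errstate(divide="ignore"):
            logw = np.log(w)
        logz = logsumexp(logw, axis=(-2, -1), keepdims=True)
        return np.exp(logw - logz)
    return w / z


def predicted_activity(
    x_g,
    na,
    params: GatingParameters,
    variant: VariantSpec,
    j_open: int = 4,
) -> np.ndarray | float:
    """Predicted normalized activity A(x_g, na).

    The conducting states are those with exactly ``j_open`` Gβγ bound
    (4 under the standard model; other values support open-stoichiometry
    model comparison).  Each conducting state contributes its θ(i)
    factor weighted by its equilibrium probability.

    Returns a scalar for scalar inputs, else the broadcast array.
    """
    if not (1 <= j_open <= 4):
        raise ValueError("j_open must be in 1..4")
    p = occupancy_distribution(x_g, na, params, variant)
    th = _theta_row(params, variant)
    a = np.einsum("...i,i->...", p[..., :, j_open], th)
    if a.ndim == 0:
        return float(a)
    return a


def fold_activation(
    x_g: float,
    na_lo: float,
    na_hi: float,
    params: GatingParameters,
    variant: VariantSpec,
) -> float:
    """Ratio of predicted activity at na_hi versus na_lo, same x_g.

    Quantifies Na⁺ sensitivity at one Gβγ density; ≥ 1 whenever eta < 1
    and θ is non-decreasing in i.
    """
    lo = predicted_activity(x_g, na_lo, params, variant)
    if lo <= 0:
        raise ZeroDivisionError(
            "predicted activity at the reference Na level is zero"
        )
    return predicted_activity(x_g, na_hi, params, variant) / lo


def gbg_surface_density(ni_nta_fraction):
    """Convert Ni-NTA-lipid mole fraction to sGβγ surface mole fraction.

    One His-tagged soluble Gβγ occupies three Ni-NTA lipids, so the
    actual Gβγ density is one third the Ni-NTA density.  Reporting-only:
    K_db is calibrated in Ni-NTA units and this factor never enters the
    model weights.
    """
    f = np.asarray(ni_nta_fraction, dtype=float)
    if np.any(f < 0):
        raise ValueError("ni_nta_fraction must be non-negative")
    out = f / 3.0
    return float(out) if out.ndim == 0 else out


class CollapsedGbgModel:
    """Five-state Gβγ-only model with an effective dissociation constant.

    Represents GIRK1/4 at zero Na⁺: the permanently Na⁺-occupied baseline
    collapses the Na⁺ dimension, leaving a single Gβγ ladder whose
    effective dissociation constant is K_db·η² (two permanently bound
    Na⁺, each contributing one factor of η).
    """

    def __init__(self, k_d_effective: float, b: float, theta_open: float):
        if k_d_effective <= 0 or b <= 0:
            raise ValueError("k_d_effective and b must be positive")
        self.k_d_effective = k_d_effective
        self.b = b
        self.theta_open = theta_open

    def weights(self, x_g) -> np.ndarray:
        x_g = np.asarray(x_g, dtype=float)
        if np.any(x_g < 0):
            raise ValueError("x_g must be non-negative")
        j = np.arange(5)
        return (
            comb(4, j)
            * (x_g[..., None] / self.k_d_effective) ** j
            * self.b ** (-j * (j - 1) / 2.0)
        )

    def predicted_activity(self, x_g):
        w = self.weights(x_g)
        a = self.theta_open * w[..., 4] / w.sum(axis=-1)
        return float(a) if a.ndim == 0 else a


def collapsed_reference_model(
    params: GatingParameters,
    variant: VariantSpec | None = None,
) -> CollapsedGbgModel:
    """Collapse the GIRK1/4 model at na = 0 into a Gβγ-only ladder.

    The result's predicted activity equals the full 15-state model
    evaluated at na = 0 (an algebraic identity: with two Na⁺ permanently
    bound, eta**(-2j) folds into the Gβγ constant as K_db·η²).
    """
    from .variants import VARIANTS

    if variant is None:
        variant = VARIANTS["GIRK1_4"]
    k_eff = params.k_db * params.eta**variant.i_baseline
    th = theta_open(variant.i_baseline, params, variant)
    return CollapsedGbgModel(k_eff, params.b, th)
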