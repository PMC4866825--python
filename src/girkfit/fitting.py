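"""Nonlinear least-squares fitting of the gating model to titrations.

The public surface follows the Model/Results idiom: build a
:class:`GirkTitrationModel` from a :class:`~girkfit.data.TitrationDataset`
(or a DataFrame / CSV), call :meth:`~GirkTitrationModel.fit`, and read
estimates, standard errors, adjusted R² and diagnostics off the returned
:class:`GirkFitResults`.

Fitting is bounded multi-start nonlinear least squares: ``n_starts``
log-uniform initializations inside the bounds, each refined with a
trust-region reflective solver, best weighted SSR kept.  The multi-start
matters because the Gβγ cooperativity b and the cross term η trade off
against each other and create local minima.  Dissociation constants and
cooperativity factors are optimized on a log10 scale; θ factors on a
linear scale.  Standard errors come from the curvature (Gauss–Newton
approximation) of the objective at the optimum; a residual-resampling
bootstrap is available as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data import TitrationDataset, read_titration_csv
from .model import predicted_activity
from .variants import GatingParameters, VariantSpec, get_variant

__all__ = [
    "DEFAULT_BOUNDS",
    "SEM_FLOOR",
    "residual_vector",
    "adjusted_r2",
    "GirkTitrationModel",
    "GirkFitResults",
    "fit_variant",
    "select_open_stoichiometry",
    "bootstrap_errors",
]

# Generous log-scale boxes around the published estimates.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_db": (1e-5, 1.0),
    "k_dn": (1.0, 5000.0),
    "b": (0.05, 5.0),
    "eta": (0.05, 5.0),
    "theta": (0.0, 3.0),
}

# Floor on SEM weights to keep near-zero SEMs from dominating the fit.
SEM_FLOOR = 0.005

_LOG_SCALE = {"k_db", "k_dn", "b", "eta"}


def _vector_to_params(
    names: Sequence[str], values: Sequence[float], variant: VariantSpec
) -> GatingParameters:
    d = dict(zip(names, values))
    theta = {
        i: d[f"theta_{i}_4"] for i in variant.free_theta_indices
    }
    return GatingParameters(
        k_db=d["k_db"], k_dn=d["k_dn"], b=d["b"], eta=d["eta"], theta=theta
    )


def _params_to_vector(
    params: GatingParameters, variant: VariantSpec
) -> dict[str, float]:
    out = {
        "k_db": params.k_db,
        "k_dn": params.k_dn,
        "b": params.b,
        "eta": params.eta,
    }
    for i in variant.free_theta_indices:
        out[f"theta_{i}_4"] = params.theta[i]
    return out


def residual_vector(
    params: GatingParameters,
    dataset: TitrationDataset,
    variant: VariantSpec | None = None,
    weighting: str = "unweighted",
    sem_floor: float = SEM_FLOOR,
    j_open: int = 4,
) -> np.ndarray:
    """Per-point residuals (observed − predicted) / weight.

    ``weighting`` is ``"unweighted"`` (weight 1, the default) or
    ``"sem_weighted"`` (weight ``max(sem, sem_floor)``).
    """
    if variant is None:
        variant = get_variant(dataset.variant_name)
    elif dataset.variants != [variant.name]:
        raise ValueError(
            f"dataset variants {dataset.variants} do not match "
            f"{variant.name!r}"
        )
    pred = predicted_activity(
        dataset.x_g, dataset.na, params, variant, j_open=j_open
    )
    resid = dataset.mean_activity - np.atleast_1d(pred)
    if weighting == "unweighted":
        return resid
    if weighting == "sem_weighted":
        return resid / np.maximum(dataset.sem, sem_floor)
    raise ValueError(f"unknown weighting mode {weighting!r}")


def adjusted_r2(
    residual_sum: float, dataset: TitrationDataset, n_free: int
) -> float:
    """Adjusted coefficient of determination.

    R² = 1 − SSR/SST with SST about the dataset mean (unweighted), then
    penalized: 1 − (1 − R²)(n − 1)/(n − n_free − 1).
    """
    y = dataset.mean_activity
    n = len(y)
    if n <= n_free + 1:
        raise ValueError("need n_points > n_free + 1 for adjusted R²")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("dataset has zero variance; R² undefined")
    r2 = 1.0 - residual_sum / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_free - 1)


def _bounds_for(name: str, bounds: Mapping[str, tuple[float, float]]):
    if name in bounds:
        return bounds[name]
    if name.startswith("theta"):
        return bounds.get("theta", DEFAULT_BOUNDS["theta"])
    return DEFAULT_BOUNDS[name]


class GirkTitrationModel:
    """Equilibrium gating model bound to one titration dataset.

    Parameters
    ----------
    dataset : TitrationDataset
        Titration points; must cover a single variant.
    variant : VariantSpec or str, optional
        Defaults to the variant named in the dataset.
    weighting : {"unweighted", "sem_weighted"}
        Residual weighting for the objective.
    fixed : mapping, optional
        Parameter name -> value held constant during the fit, e.g.
        ``{"b": 0.6, "theta_4_4": 1.1}`` for the N217D protocol where the
        Gβγ cooperativity and the saturating θ are carried over from the
        GIRK1/4 fit.
    bounds : mapping, optional
        Overrides of the default per-parameter boxes; key ``"theta"``
        applies to every θ.
    j_open : int
        Number of bound Gβγ required for conduction (4 for the standard
        model; other values support stoichiometry comparison).
    """

    def __init__(
        self,
        dataset: TitrationDataset,
        variant: VariantSpec | str | None = None,
        weighting: str = "unweighted",
        fixed: Mapping[str, float] | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        j_open: int = 4,
    ):
        self.dataset = dataset
        if variant is None:
            variant = dataset.variant_name
        if isinstance(variant, str):
            variant = get_variant(variant)
        if dataset.variants != [variant.name]:
            raise ValueError(
                f"dataset variants {dataset.variants} do not match "
                f"{variant.name!r}"
            )
        self.variant = variant
        if weighting not in ("unweighted", "sem_weighted"):
            raise ValueError(f"unknown weighting mode {weighting!r}")
        self.weighting = weighting
        self.fixed = dict(fixed or {})
        unknown = set(self.fixed) - set(variant.parameter_names)
        if unknown:
            raise ValueError(
                f"fixed parameter(s) {sorted(unknown)} not in "
                f"{variant.parameter_names}"
            )
        self.bounds = dict(bounds or {})
        self.j_open = j_open
        self.param_names = variant.parameter_names
        self.free_names = tuple(
            n for n in self.param_names if n not in self.fixed
        )
        n_cond = len(
            self.dataset.frame[["na_mM", "ni_nta_fraction"]].drop_duplicates()
        )
        if n_cond < len(self.free_names):
            raise ValueError(
                f"dataset has {n_cond} distinct conditions but "
                f"{len(self.free_names)} free parameters"
            )

    # -- constructors -------------------------------------------------
    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, **kwargs
    ) -> "GirkTitrationModel":
        return cls(TitrationDataset(frame), **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "GirkTitrationModel":
        return cls(read_titration_csv(path), **kwargs)

    # -- internals ----------------------------------------------------
    def _full_values(self, free_values: Sequence[float]) -> GatingParameters:
        d = dict(self.fixed)
        d.update(zip(self.free_names, free_values))
        return _vector_to_params(self.param_names, [d[n] for n in self.param_names], self.variant)

    def _residuals_free(self, free_values: Sequence[float]) -> np.ndarray:
        params = self._full_values(free_values)
        return residual_vector(
            params,
            self.dataset,
            self.variant,
            weighting=self.weighting,
            j_open=self.j_open,
        )

    def _transform(self, free_values: np.ndarray) -> np.ndarray:
        out = np.array(free_values, dtype=float)
        for k, n in enumerate(self.free_names):
            if n in _LOG_SCALE:
                out[k] = np.log10(out[k])
        return out

    def _untransform(self, z: np.ndarray) -> np.ndarray:
        out = np.array(z, dtype=float)
        for k, n in enumerate(self.free_names):
            if n in _LOG_SCALE:
                out[k] = 10.0 ** out[k]
        return out

    def _free_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for n in self.free_names:
            a, b_ = _bounds_for(n, self.bounds)
            lo.append(a)
            hi.append(b_)
        return np.array(lo), np.array(hi)

    def _curvature_se(
        self, free_values: np.ndarray
    ) -> tuple[np.ndarray, bool]:
        """Standard errors from the Gauss–Newton curvature at the optimum."""
        r0 = self._residuals_free(free_values)
        n, p = len(r0), len(free_values)
        if n <= p:
            return np.full(p, np.nan), False
        lo, hi = self._free_bounds()
        J = np.empty((n, p))
        for k in range(p):
            h = max(abs(free_values[k]), 1e-10) * 1e-6
            up = np.array(free_values)
            dn = np.array(free_values)
            # one-sided near a bound so perturbed values stay feasible
            up[k] = min(free_values[k] + h, hi[k])
            dn[k] = max(free_values[k] - h, lo[k])
            J[:, k] = (self._residuals_free(up) - self._residuals_free(dn)) / (
                up[k] - dn[k]
            )
        ssr = float(r0 @ r0)
        s2 = ssr / (n - p)
        jtj = J.T @ J
        try:
            cov = s2 * np.linalg.inv(jtj)
            ok = True
        except np.linalg.LinAlgError:
            cov = s2 * np.linalg.pinv(jtj)
            ok = False
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(cov))
        return se, ok

    # -- fitting ------------------------------------------------------
    def fit(
        self,
        n_starts: int = 32,
        seed: int = 0,
        start_params: GatingParameters | None = None,
        max_nfev: int | None = None,
    ) -> "GirkFitResults":
        """Multi-start bounded least squares; deterministic given seed.

        ``start_params`` adds one deterministic initialization (e.g. a
        previous fit) ahead of the random ones.
        """
        rng = np.random.default_rng(seed)
        lo, hi = self._free_bounds()
        # log-uniform draws; linear-scale θ floors at 1e-3 for the draw only
        draw_lo = np.maximum(lo, 1e-3)
        starts = 10 ** (
            rng.uniform(np.log10(draw_lo), np.log10(hi), size=(n_starts, len(lo)))
        )
        init_list = [np.clip(s, lo, hi) for s in starts]
        if start_params is not None:
            full = _params_to_vector(start_params, self.variant)
            init_list.insert(
                0,
                np.clip(
                    np.array([full[n] for n in self.free_names]), lo, hi
                ),
            )

        zlo = self._transform(np.maximum(lo, 1e-300))
        zhi = self._transform(hi)

        def obj(z):
            return self._residuals_free(self._untransform(z))

        best = None
        any_success = False
        for x0 in init_list:
            try:
                sol = least_squares(
                    obj,
                    self._transform(x0),
                    bounds=(zlo, zhi),
                    method="trf",
                    xtol=1e-15,
                    ftol=1e-15,
                    gtol=1e-15,
                    max_nfev=max_nfev,
                )
            except Exception:
                continue
            any_success = any_success or sol.status > 0
            ssr = 2 * sol.cost
            if best is None or ssr < best[0]:
                best = (ssr, sol)
        if best is None:
            raise RuntimeError("all optimizer starts failed")
        ssr, sol = best
        free_hat = self._untransform(sol.x)
        se, se_ok = self._curvature_se(free_hat)

        at_bounds = [
            n
            for n, v, a, b_ in zip(self.free_names, free_hat, lo, hi)
            if v <= a * (1 + 1e-8) + 1e-300 or v >= b_ * (1 - 1e-8)
        ]
        if at_bounds:
            warnings.warn(
                f"parameter(s) at bounds: {at_bounds}", RuntimeWarning
            )

        params = self._full_values(free_hat)
        # adjusted R² always on the unweighted scale
        resid_unw = residual_vector(
            params, self.dataset, self.variant, weighting="unweighted",
            j_open=self.j_open,
        )
        adj = adjusted_r2(
            float(resid_unw @ resid_unw), self.dataset, len(self.free_names)
        )
        return GirkFitResults(
            model=self,
            params=params,
            free_estimates=dict(zip(self.free_names, free_hat)),
            bse=dict(zip(self.free_names, se)),
            fixed=dict(self.fixed),
            ssr=float(ssr),
            adj_r2=float(adj),
            converged=bool(any_success and se_ok),
            at_bounds=at_bounds,
            n_starts=len(init_list),
            seed=seed,
        )


@dataclass
class GirkFitResults:
    """Estimates, uncertainties and diagnostics of one titration fit."""

    model: GirkTitrationModel
    params: GatingParameters
    free_estimates: dict[str, float]
    bse: dict[str, float]
    fixed: dict[str, float]
    ssr: float
    adj_r2: float
    converged: bool
    at_bounds: list[str] = field(default_factory=list)
    n_starts: int = 0
    seed: int = 0

    @property
    def nobs(self) -> int:
        return len(self.model.dataset)

    @property
    def n_free(self) -> int:
        return len(self.free_estimates)

    @property
    def residuals(self) -> np.ndarray:
        return residual_vector(
            self.params,
            self.model.dataset,
            self.model.variant,
            weighting="unweighted",
            j_open=self.model.j_open,
        )

    def predict(self, x_g, na):
        """Model activity at new conditions under the fitted parameters."""
        return predicted_activity(
            x_g, na, self.params, self.model.variant, j_open=self.model.j_open
        )

    def bootstrap(
        self, n_boot: int = 200, seed: int = 0, n_starts: int = 1
    ) -> pd.DataFrame:
        return bootstrap_errors(
            self.model.dataset,
            self.model.variant,
            self,
            n_boot=n_boot,
            seed=seed,
            n_starts=n_starts,
        )

    def to_dict(self) -> dict:
        """JSON-serializable record of the fit (estimates, SEs, protocol)."""
        return {
            "variant": self.model.variant.name,
            "weighting": self.model.weighting,
            "j_open": self.model.j_open,
            "estimates": self.free_estimates,
            "standard_errors": {
                k: (None if not np.isfinite(v) else v)
                for k, v in self.bse.items()
            },
            "fixed_map": self.fixed,
            "adjusted_r2": self.adj_r2,
            "residual_sum": self.ssr,
            "n_points": self.nobs,
            "n_free": self.n_free,
            "converged": self.converged,
            "at_bounds": self.at_bounds,
            "n_starts": self.n_starts,
            "seed": self.seed,
        }

    def summary(self) -> str:
        lines = [
            "Equilibrium gating model fit",
            "=" * 46,
            f"variant:        {self.model.variant.name}",
            f"n points:       {self.nobs}    n free: {self.n_free}",
            f"weighting:      {self.model.weighting}",
            f"adjusted R2:    {self.adj_r2:.4f}",
            f"weighted SSR:   {self.ssr:.6g}",
            f"converged:      {self.converged}"
            + (f"    at bounds: {self.at_bounds}" if self.at_bounds else ""),
            "-" * 46,
            f"{'parameter':<12}{'estimate':>12}{'std err':>12}  ",
        ]
        for name in self.model.param_names:
            if name in self.fixed:
                lines.append(
                    f"{name:<12}{self.fixed[name]:>12.4g}{'(fixed)':>12}"
                )
            else:
                se = self.bse[name]
                se_s = f"{se:.3g}" if np.isfinite(se) else "nan"
                lines.append(
                    f"{name:<12}{self.free_estimates[name]:>12.4g}{se_s:>12}"
                )
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_fit(self, ax=None, n_curve: int = 120):
        """Overlay fitted activation curves on the data points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.model.dataset.frame
        xmax = df["ni_nta_fraction"].max()
        xs = np.linspace(0, xmax, n_curve)
        for na, sub in df.groupby("na_mM"):
            line = ax.errorbar(
                sub["ni_nta_fraction"],
                sub["normalized_current_mean"],
                yerr=sub["sem"],
                fmt="o",
                label=f"{na:g} mM Na$^+$",
            )
            ax.plot(
                xs,
                self.predict(xs, np.full_like(xs, na)),
                color=line[0].get_color(),
            )
        ax.set_xlabel("Ni-NTA-lipid mole fraction")
        ax.set_ylabel("normalized current")
        ax.legend()
        return ax


def fit_variant(
    dataset: TitrationDataset,
    variant: VariantSpec | str | None = None,
    fixed: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 32,
    seed: int = 0,
    weighting: str = "unweighted",
    j_open: int = 4,
    start_params: GatingParameters | None = None,
) -> GirkFitResults:
    """One-call fit of a titration dataset (see :class:`GirkTitrationModel`)."""
    model = GirkTitrationModel(
        dataset,
        variant=variant,
        weighting=weighting,
        fixed=fixed,
        bounds=bounds,
        j_open=j_open,
    )
    return model.fit(n_starts=n_starts, seed=seed, start_params=start_params)


def select_open_stoichiometry(
    dataset: TitrationDataset,
    variant: VariantSpec | str | None = None,
    j_open_candidates: Iterable[int] = (1, 2, 3, 4),
    seed: int = 0,
    n_starts: int = 8,
    weighting: str = "unweighted",
) -> pd.DataFrame:
    """Refit under each candidate Gβγ open stoichiometry; rank by SSR.

    For candidate k the conducting states are those with exactly k Gβγ
    bound (the occupancy grid itself is unchanged).  Returns a DataFrame
    ordered best-first, with ties within 1e−9 SSR broken toward the
    smaller stoichiometry.
    """
    cands = sorted(set(int(k) for k in j_open_candidates))
    if not cands:
        raise ValueError("j_open_candidates must be non-empty")
    if any(k < 1 or k > 4 for k in cands):
        raise ValueError("candidates must lie in 1..4")
    rows = []
    for k in cands:
        res = fit_variant(
            dataset,
            variant=variant,
            n_starts=n_starts,
            seed=seed,
            weighting=weighting,
            j_open=k,
        )
        rows.append(
            {
                "j_open": k,
                "ssr": res.ssr,
                "adjusted_r2": res.adj_r2,
                "converged": res.converged,
            }
        )
    df = pd.DataFrame(rows)
    # rank: SSR ascending; ties within 1e-9 go to the smaller stoichiometry
    order = sorted(
        range(len(df)),
        key=lambda a: (round(df["ssr"][a] / 1e-9) * 1e-9, df["j_open"][a]),
    )
    return df.iloc[order].reset_index(drop=True)


def bootstrap_errors(
    dataset: TitrationDataset,
    variant: VariantSpec | str | None,
    fit: GirkFitResults,
    n_boot: int = 200,
    seed: int = 0,
    n_starts: int = 1,
) -> pd.DataFrame:
    """Residual-resampling bootstrap uncertainty for a converged fit.

    Resamples the unweighted residuals with replacement, adds them back
    to the fitted values, refits (warm-started at the point estimates),
    and summarizes the replicate estimates.  Deterministic given seed.
    """
    if n_boot < 50:
        warnings.warn(
            f"n_boot={n_boot} is small; intervals will be unstable",
            UserWarning,
        )
    if variant is None:
        variant = fit.model.variant
    if isinstance(variant, str):
        variant = get_variant(variant)
    rng = np.random.default_rng(seed)
    fitted = np.atleast_1d(
        predicted_activity(
            dataset.x_g, dataset.na, fit.params, variant, j_open=fit.model.j_open
        )
    )
    resid = dataset.mean_activity - fitted
    draws = []
    base = dataset.frame
    for _ in range(n_boot):
        y = fitted + rng.choice(resid, size=len(resid), replace=True)
        df = base.copy()
        df["normalized_current_mean"] = np.maximum(y, 0.0)
        res = fit_variant(
            TitrationDataset(df),
            variant=variant,
            fixed=fit.fixed,
            n_starts=n_starts,
            seed=int(rng.integers(2**31)),
            weighting=fit.model.weighting,
            j_open=fit.model.j_open,
            start_params=fit.params,
        )
        draws.append(res.free_estimates)
    reps = pd.DataFrame(draws)
    return pd.DataFrame(
        {
            "estimate": [fit.free_estimates[n] for n in reps.columns],
            "boot_sd": reps.std(ddof=1),
            "ci_2.5": reps.quantile(0.025),
            "ci_97.5": reps.quantile(0.975),
        },
        index=reps.columns,
    )
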