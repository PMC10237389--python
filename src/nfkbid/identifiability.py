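"""Linear (sensitivity/SVD) and Monte Carlo parameter identifiability.

Linear analysis
---------------
The sensitivity matrix S has one row per normalized measurement and one
column per parameter, with log-log entries

    s_ij = ∂ ln y_i / ∂ ln θ_j,

computed by central finite differences with a 1% increase/decrease of each
parameter; y_i are the ρ-shifted, geometric-mean-normalized observables, so
within each series every column sums to ~0. All derived quantities —
singular values, per-parameter column norms ‖S_j‖ and perpendicular
components ‖S_j⊥‖ — are divided by √dim, where dim = N − n_series is the
number of independent data points; this makes them invariant under simple
repetition of an experiment.

* A vanishing (scaled) singular value signals structural non-identifiability.
* ‖S_j⊥‖, the part of S_j orthogonal to the span of all other columns,
  measures how far a change in θ_j can be compensated by the others.
* R_j = ln(σ_linear,j)/ln(σ_data), the ratio of parameter-estimation error
  to measurement error under iid lognormal noise, is the ℓ₂-norm of row j of
  the pseudo-inverse (SᵀS)⁻¹Sᵀ, computed via the more stable QR route (row
  norms of R_a⁻¹). Hence σ_linear,j = σ_data^{R_j}.

Monte Carlo analysis
--------------------
For each noise level σ_data, k perturbed measurement sets are drawn
(lognormal, median = true value) and the 13 parameters refitted to each; the
geometric SD of the k estimates, σ_carlo,j = exp(SD(ln θ_j,k)), is the
practical-identifiability counterpart of σ_linear,j. Replicate r uses RNG
seed base_seed + r independently of the noise level, so levels share the
underlying noise draws (common random numbers), which sharpens the
level-to-level comparison at small k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.stats import chi2

from . import measurements as ms
from .fitting import PathwayFit
from .parameters import PARAM_NAMES, ParameterSet
from .protocols import Protocol

__all__ = [
    "SensitivityMatrix",
    "LinearReport",
    "LinearAnalysis",
    "MCResult",
    "sensitivity_matrix",
    "scaled_singular_values",
    "sensitivity_norms",
    "perpendicular_norms",
    "error_ratios",
    "confidence_ellipse",
    "Ellipse",
    "run_monte_carlo",
]


@dataclass(frozen=True)
class SensitivityMatrix:
    """Log-log sensitivities of all normalized measurements to all parameters."""

    S: np.ndarray  # (N, p) dimensionless
    dim: int  # independent data points backing the rows
    row_index: tuple  # (protocol, genotype, observable, time_min) per row
    param_names: tuple[str, ...] = PARAM_NAMES

    def __post_init__(self):
        if self.S.shape[1] != len(self.param_names):
            raise ValueError("column count must match the parameter count")
        if self.S.shape[0] != len(self.row_index):
            raise ValueError("row index must match the row count")

    def column(self, name: str) -> np.ndarray:
        return self.S[:, self.param_names.index(name)]

    def stack(self, other: "SensitivityMatrix") -> "SensitivityMatrix":
        """Concatenate two experiments (dims add)."""
        if self.param_names != other.param_names:
            raise ValueError("parameter sets differ")
        return SensitivityMatrix(
            np.vstack([self.S, other.S]), self.dim + other.dim,
            self.row_index + other.row_index, self.param_names,
        )


def _log_normalized_values(params, protocols, rho, rtol, atol):
    vals, index = [], []
    for p in protocols:
        raw = ms.simulate_measurements(params, p, rtol=rtol, atol=atol)
        norm = ms.normalize(raw, rho)
        vals.append(np.log(norm.values_vector()))
        index.extend(norm.index())
    return np.concatenate(vals), tuple(index)


def sensitivity_matrix(
    params: ParameterSet,
    protocols: Protocol | Sequence[Protocol],
    rel_step: float = 0.01,
    rho: float = ms.RHO,
    rtol: float | None = None,
    atol: float | None = None,
) -> SensitivityMatrix:
    """Central-difference log-log sensitivity matrix at a parameter point.

    Each parameter is perturbed to θ_j·(1 + rel_step) and θ_j·(1 − rel_step)
    (default 1%), the protocols re-simulated and re-normalized, and

        s_ij = [ln y_i(θ⁺) − ln y_i(θ⁻)] / [ln(1+rel_step) − ln(1−rel_step)].
    """
    if isinstance(protocols, Protocol):
        protocols = [protocols]
    theta = params.to_array()
    if np.any(theta <= 0):
        raise ValueError("sensitivities need strictly positive parameters")
    denom = np.log1p(rel_step) - np.log1p(-rel_step)
    cols = []
    index = None
    for j, name in enumerate(PARAM_NAMES):
        col = {}
        for sign in (+1, -1):
            t = theta.copy()
            t[j] = theta[j] * (1.0 + sign * rel_step)
            try:
                ln_y, index = _log_normalized_values(
                    ParameterSet.from_array(t), protocols, rho, rtol, atol)
            except Exception as exc:
                raise RuntimeError(
                    f"simulation failed while perturbing parameter {name}"
                ) from exc
            col[sign] = ln_y
        cols.append((col[+1] - col[-1]) / denom)
    S = np.column_stack(cols)
    dim = sum(p.dim for p in protocols)
    return SensitivityMatrix(S, dim, index)


def scaled_singular_values(sm: SensitivityMatrix) -> np.ndarray:
    """Singular values of S divided by √dim, in descending order."""
    return linalg.svdvals(sm.S) / np.sqrt(sm.dim)


def sensitivity_norms(sm: SensitivityMatrix) -> np.ndarray:
    """Per-parameter ‖S_j‖ / √dim."""
    return np.linalg.norm(sm.S, axis=0) / np.sqrt(sm.dim)


def perpendicular_norms(sm: SensitivityMatrix) -> np.ndarray:
    """Per-parameter ‖S_j⊥‖ / √dim, S_j⊥ = S_j − P_{*,j} S_j.

    S_j⊥ is the residual of regressing column j on all other columns. For a
    rank-deficient matrix the dependent columns get 0 (with a warning).
    """
    S = sm.S
    n, p = S.shape
    out = np.empty(p)
    rank = np.linalg.matrix_rank(S)
    if rank < p:
        warnings.warn(
            f"sensitivity matrix is rank deficient (rank {rank} < {p}); "
            "perpendicular components of dependent columns are 0",
            stacklevel=2,
        )
    for j in range(p):
        others = np.delete(S, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, S[:, j], rcond=None)
        out[j] = np.linalg.norm(S[:, j] - others @ coef)
    # numerically dependent columns: clamp to exactly 0 below noise floor
    floor = np.linalg.norm(S) * 1e-12
    out[out < floor] = 0.0
    return out / np.sqrt(sm.dim)


def error_ratios(sm: SensitivityMatrix) -> np.ndarray:
    """R_j: parameter-estimation-error to measurement-error ratios.

    Equal to the row norms of the pseudo-inverse (SᵀS)⁻¹Sᵀ; evaluated via
    QR decomposition of S as the row norms of R_a⁻¹ (R_a = leading p×p block
    of the triangular factor), which is numerically stabler.
    """
    S = sm.S
    p = S.shape[1]
    if np.linalg.matrix_rank(S) < p:
        raise np.linalg.LinAlgError(
            "sensitivity matrix is rank deficient: the model is structurally "
            "non-identifiable for this protocol"
        )
    R = np.linalg.qr(S, mode="r")[:p, :p]
    Rinv = linalg.solve_triangular(R, np.eye(p))
    return np.linalg.norm(Rinv, axis=1)


@dataclass(frozen=True)
class Ellipse:
    """A 75% confidence ellipse in a log-parameter plane."""

    pair: tuple[str, str]
    center: np.ndarray       # ln θ of the two parameters
    semi_axes: np.ndarray    # lengths along the principal directions
    angle_rad: float         # rotation of the first axis from the x-axis
    level: float = 0.75


def confidence_ellipse(
    sm: SensitivityMatrix,
    params: ParameterSet,
    sigma_data: float,
    pair: tuple[str, str],
    level: float = 0.75,
) -> Ellipse:
    """Confidence ellipse of two parameters under the linear noise model.

    The log-parameter covariance is ln(σ_data)²·(SᵀS)⁻¹; its 2×2 marginal,
    scaled by the χ²₂ quantile of ``level``, gives the ellipse.
    """
    i, j = (sm.param_names.index(p) for p in pair)
    StS = sm.S.T @ sm.S
    cov = np.log(sigma_data) ** 2 * np.linalg.inv(StS)
    sub = cov[np.ix_([i, j], [i, j])]
    evals, evecs = np.linalg.eigh(sub)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = chi2.ppf(level, df=2)
    return Ellipse(
        pair=pair,
        center=np.log([params[pair[0]], params[pair[1]]]),
        semi_axes=np.sqrt(np.clip(evals, 0, None) * q),
        angle_rad=float(np.arctan2(evecs[1, 0], evecs[0, 0])),
        level=level,
    )


def ellipses_to_csv(ellipses: Sequence[Ellipse], path) -> None:
    """Write ellipse specs (one row each) for external plotting."""
    rows = ["param_x,param_y,center_ln_x,center_ln_y,"
            "semi_axis_major,semi_axis_minor,angle_rad,level"]
    for e in ellipses:
        rows.append(
            f"{e.pair[0]},{e.pair[1]},{e.center[0]:.10g},{e.center[1]:.10g},"
            f"{e.semi_axes[0]:.10g},{e.semi_axes[1]:.10g},"
            f"{e.angle_rad:.10g},{e.level}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(rows) + "\n")


@dataclass
class LinearReport:
    """All scalar outputs of the linear identifiability analysis."""

    sensitivity: SensitivityMatrix
    scaled_singular_values: np.ndarray
    scaled_norms: np.ndarray
    scaled_perp_norms: np.ndarray
    error_ratios: np.ndarray          # raw R_j (used for sigma_linear)
    error_ratios_scaled: np.ndarray   # R_j × √dim, for cross-protocol plots
    param_names: tuple[str, ...] = PARAM_NAMES

    @property
    def dim(self) -> int:
        return self.sensitivity.dim

    def sigma_linear(self, sigma_data: float) -> np.ndarray:
        """σ_linear,j = σ_data^{R_j} per parameter."""
        return np.asarray(sigma_data) ** self.error_ratios

    @property
    def structurally_identifiable(self) -> bool:
        """All scaled singular values above 1e-3."""
        return bool(np.all(self.scaled_singular_values > 1e-3))

    def least_identifiable(self) -> str:
        """Parameter with the largest error ratio R_j."""
        return self.param_names[int(np.argmax(self.error_ratios))]

    def summary(self) -> str:
        sv = self.scaled_singular_values
        lines = [
            "Linear identifiability analysis",
            "=" * 60,
            f"measurements: {self.sensitivity.S.shape[0]}   dim: {self.dim}",
            f"scaled singular values (desc): largest {sv[0]:.4g}, "
            f"smallest {sv[-1]:.4g}",
            f"structurally identifiable (all > 1e-3): "
            f"{self.structurally_identifiable}",
            f"least identifiable parameter (max R_j): "
            f"{self.least_identifiable()}",
            "-" * 60,
            f"{'parameter':<10}{'|S_j|/√dim':>13}{'|S_j⊥|/√dim':>14}"
            f"{'R_j':>10}{'R_j·√dim':>12}",
        ]
        for k, name in enumerate(self.param_names):
            lines.append(
                f"{name:<10}{self.scaled_norms[k]:>13.4g}"
                f"{self.scaled_perp_norms[k]:>14.4g}"
                f"{self.error_ratios[k]:>10.4g}"
                f"{self.error_ratios_scaled[k]:>12.4g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "scaled_singular_values": self.scaled_singular_values.tolist(),
            "scaled_norms": dict(zip(self.param_names,
                                     self.scaled_norms.tolist())),
            "scaled_perp_norms": dict(zip(self.param_names,
                                          self.scaled_perp_norms.tolist())),
            "error_ratios": dict(zip(self.param_names,
                                     self.error_ratios.tolist())),
            "error_ratios_scaled": dict(zip(self.param_names,
                                            self.error_ratios_scaled.tolist())),
        }


class LinearAnalysis:
    """Sensitivity-matrix identifiability analysis at a parameter point."""

    def __init__(
        self,
        params: ParameterSet,
        protocols: Protocol | Sequence[Protocol],
        rel_step: float = 0.01,
        rho: float = ms.RHO,
        rtol: float | None = None,
        atol: float | None = None,
    ):
        self.params = params
        self.protocols = [protocols] if isinstance(protocols, Protocol) \
            else list(protocols)
        self.rel_step = rel_step
        self.rho = rho
        self.rtol = rtol
        self.atol = atol

    def run(self) -> LinearReport:
        sm = sensitivity_matrix(self.params, self.protocols,
                                rel_step=self.rel_step, rho=self.rho,
                                rtol=self.rtol, atol=self.atol)
        R = error_ratios(sm)
        return LinearReport(
            sensitivity=sm,
            scaled_singular_values=scaled_singular_values(sm),
            scaled_norms=sensitivity_norms(sm),
            scaled_perp_norms=perpendicular_norms(sm),
            error_ratios=R,
            error_ratios_scaled=R * np.sqrt(sm.dim),
        )


@dataclass
class MCResult:
    """Monte Carlo practical-identifiability estimates.

    ``estimates[level]`` is the k×13 matrix of refitted parameters for one
    noise level; ``sigma_carlo[level]`` the per-parameter geometric SDs.
    """

    sigma_levels: tuple[float, ...]
    estimates: dict[float, np.ndarray]
    sigma_carlo: dict[float, np.ndarray]
    seeds: dict[float, tuple[int, ...]]
    excluded: dict[float, tuple[int, ...]] = field(default_factory=dict)
    param_names: tuple[str, ...] = PARAM_NAMES

    def max_sigma_carlo(self, level: float) -> float:
        return float(np.max(self.sigma_carlo[level]))

    def summary(self) -> str:
        lines = [
            "Monte Carlo practical identifiability",
            "=" * 60,
            f"{'parameter':<10}" + "".join(
                f"σ@{lv:g}".rjust(11) for lv in self.sigma_levels),
        ]
        for k, name in enumerate(self.param_names):
            lines.append(f"{name:<10}" + "".join(
                f"{self.sigma_carlo[lv][k]:>11.4g}"
                for lv in self.sigma_levels))
        lines.append("-" * 60)
        lines.append("max_j:    " + "".join(
            f"{self.max_sigma_carlo(lv):>11.4g}" for lv in self.sigma_levels))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "sigma_levels": list(self.sigma_levels),
            "sigma_carlo": {
                str(lv): dict(zip(self.param_names, sc.tolist()))
                for lv, sc in self.sigma_carlo.items()
            },
            "estimates": {
                str(lv): est.tolist() for lv, est in self.estimates.items()
            },
            "seeds": {str(lv): list(s) for lv, s in self.seeds.items()},
            "excluded": {str(lv): list(s) for lv, s in self.excluded.items()},
        }


def _sigma_carlo(log_estimates: np.ndarray) -> np.ndarray:
    """exp of the per-parameter sample SD (ddof=1) of log estimates."""
    if log_estimates.shape[0] < 2:
        return np.ones(log_estimates.shape[1])
    return np.exp(np.std(log_estimates, axis=0, ddof=1))


def run_monte_carlo(
    params: ParameterSet,
    protocol: Protocol | Sequence[Protocol],
    sigma_levels: Sequence[float] = (1.0, 1.1, 1.2, 1.3),
    k: int = 50,
    base_seed: int = 0,
    method: str = "local",
    budget: int = 50_000,
    rho: float = ms.RHO,
    n_starts: int = 3,
    start_spread_fold: float = 3.0,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> MCResult:
    """Refit the model to k noise-perturbed measurement sets per noise level.

    The clean raw measurements are simulated once at ``params``; replicate r
    perturbs them with seed ``base_seed + r`` (shared across levels), refits
    all 13 parameters, and the spread of the k estimates gives σ_carlo,j.

    The default refit emulates a budget-limited stochastic global fit: the
    log-objective is multimodal under noise, so each replicate runs
    ``n_starts`` trust-region least-squares descents — one from ``params``,
    the rest from starts jittered by a lognormal factor of geometric SD
    ``start_spread_fold`` — and keeps the lowest J (``method="de"`` instead
    runs the full differential-evolution search per replicate, which is far
    more expensive). Replicates whose refit does not converge are excluded
    and reported. At σ_data = 1 the perturbation is the identity, so the
    (deterministic) refit is computed once and replicated.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    protocols = [protocol] if isinstance(protocol, Protocol) else list(protocol)
    raw = MeasurementUnion(params, protocols, rho)

    estimates: dict[float, np.ndarray] = {}
    sigma_carlo: dict[float, np.ndarray] = {}
    seeds: dict[float, tuple[int, ...]] = {}
    excluded: dict[float, tuple[int, ...]] = {}
    for level in sigma_levels:
        level = float(level)
        level_seeds = tuple(base_seed + r for r in range(k))
        refit_kw = dict(method=method, budget=budget,
                        n_starts=n_starts, spread=start_spread_fold,
                        rtol=rtol, atol=atol)
        if level == 1.0:
            res = _refit(raw, protocols, params, seed=base_seed, **refit_kw)
            thetas = np.tile(np.log(res.params.to_array()), (k, 1))
            bad: list[int] = [] if res.converged else list(level_seeds)
        else:
            thetas_list, bad = [], []
            for seed in level_seeds:
                noisy = ms.add_lognormal_noise(
                    raw, ms.NoiseModel(level, seed=seed))
                res = _refit(noisy, protocols, params, seed=seed, **refit_kw)
                if res.converged:
                    thetas_list.append(np.log(res.params.to_array()))
                else:
                    bad.append(seed)
            thetas = np.array(thetas_list)
        estimates[level] = np.exp(thetas)
        sigma_carlo[level] = _sigma_carlo(thetas)
        seeds[level] = level_seeds
        if bad:
            excluded[level] = tuple(bad)
            warnings.warn(
                f"{len(bad)} of {k} replicate fits at sigma_data={level} "
                "did not converge and were excluded",
                stacklevel=2,
            )
    return MCResult(
        sigma_levels=tuple(float(s) for s in sigma_levels),
        estimates=estimates,
        sigma_carlo=sigma_carlo,
        seeds=seeds,
        excluded=excluded,
    )


def MeasurementUnion(params, protocols, rho) -> ms.MeasurementSet:
    series = []
    for p in protocols:
        series.extend(ms.simulate_measurements(params, p).series)
    return ms.MeasurementSet(tuple(series), normalized=False)


def _refit(raw_set, protocols, start, seed, method, budget,
           n_starts, spread, rtol, atol):
    pf = PathwayFit(raw_set, protocols, start=start, rtol=rtol, atol=atol)
    if method != "local":
        return pf.fit(method=method, budget=budget, seed=seed)
    best = pf.fit(method="local")
    rng = np.random.default_rng(2 ** 30 + seed)  # distinct from noise streams
    for _ in range(max(0, n_starts - 1)):
        jitter = np.exp(rng.normal(0.0, np.log(spread), len(PARAM_NAMES)))
        x0 = ParameterSet.from_array(start.to_array() * jitter)
        res = pf.fit(method="local", x0=x0)
        if res.converged and res.J < best.J - 1e-12:
            best = res
    return best
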