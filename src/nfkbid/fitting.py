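"""Log-least-squares fitting of the reduced model to measurement sets.

The objective is formulated on normalized series (each scaled by its
geometric mean), so only relative changes matter, matching data reported in
arbitrary units:

    J(θ) = Σᵢ (ln yᵢ(θ) − ln yᵢ_ref)²   over all N measurements,

and the goodness of fit is summarized by the Average Multiplicative Distance

    AMD = exp( sqrt( J / N ) ),

i.e. the geometric mean factor by which model and reference disagree
(AMD = 1 for identical sets, 2 for a uniform two-fold discrepancy).

``PathwayFit`` is the model object (reference data + protocols); its
``fit()`` returns a ``PathwayFitResults`` carrying the parameter estimates,
fit diagnostics and optional linear-analysis uncertainties. Two optimizers
are available: a population-based stochastic global search over
log-transformed parameters within fold-range bounds (``method="de"``,
reproducible under a seed), and a deterministic trust-region least-squares
refinement from a starting point (``method="local"``), used when the optimum
is known to be near the start — e.g. Monte Carlo refits to perturbed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import differential_evolution, least_squares

from . import measurements as ms
from .parameters import FITTED, PARAM_NAMES, ParameterSet
from .protocols import Protocol

__all__ = ["objective_J", "amd", "PathwayFit", "PathwayFitResults", "fit"]


def _aligned_log_values(model_set: ms.MeasurementSet,
                        reference_set: ms.MeasurementSet):
    """Log-values of both sets aligned on (protocol, genotype, observable, t)."""
    for s in (model_set, reference_set):
        if not s.normalized:
            raise ValueError("both measurement sets must be normalized")
    ref = {s.key: s for s in reference_set.series}
    mod = {s.key: s for s in model_set.series}
    missing = [k for k in ref if k not in mod] + [k for k in mod if k not in ref]
    if missing:
        raise ValueError(f"schedule mismatch; unmatched series: {sorted(missing)}")
    lm, lr = [], []
    for key, rs in ref.items():
        msr = mod[key]
        if len(msr) != len(rs) or not np.allclose(msr.times, rs.times):
            raise ValueError(
                f"schedule mismatch in series {key}: times "
                f"{msr.times.tolist()} vs {rs.times.tolist()}"
            )
        lm.append(np.log(msr.values))
        lr.append(np.log(rs.values))
    return np.concatenate(lm), np.concatenate(lr)


def objective_J(model_set: ms.MeasurementSet,
                reference_set: ms.MeasurementSet) -> float:
    """Sum of squared log-differences over all N measurements."""
    lm, lr = _aligned_log_values(model_set, reference_set)
    return float(np.sum((lm - lr) ** 2))


def amd(model_set: ms.MeasurementSet,
        reference_set: ms.MeasurementSet) -> float:
    """Average Multiplicative Distance, exp(sqrt(J/N)) ≥ 1."""
    lm, lr = _aligned_log_values(model_set, reference_set)
    return float(np.exp(np.sqrt(np.mean((lm - lr) ** 2))))


@dataclass
class PathwayFitResults:
    """Estimates and diagnostics from a :meth:`PathwayFit.fit` call."""

    model: "PathwayFit"
    params: ParameterSet
    J: float
    amd: float
    n_evaluations: int
    converged: bool
    method: str
    seed: int | None = None
    _sigma_linear_cache: dict = field(default_factory=dict, repr=False)

    @property
    def theta(self) -> np.ndarray:
        return self.params.to_array()

    def sigma_linear(self, sigma_data: float = 1.3) -> dict[str, float]:
        """Per-parameter geometric SD of the estimate from linear analysis.

        Propagates lognormal measurement noise of geometric SD ``sigma_data``
        through the sensitivity matrix at the fitted parameters:
        σ_linear,j = sigma_data ** R_j.
        """
        key = round(float(sigma_data), 12)
        if key not in self._sigma_linear_cache:
            from .identifiability import LinearAnalysis

            rep = LinearAnalysis(self.params, self.model.protocols,
                                 rho=self.model.rho).run()
            self._sigma_linear_cache[key] = dict(
                zip(PARAM_NAMES, sigma_data ** rep.error_ratios))
        return self._sigma_linear_cache[key]

    def summary(self, sigma_data: float | None = None) -> str:
        """Plain-text summary table (statsmodels style)."""
        lines = [
            "Reduced NF-κB model — log-least-squares fit",
            "=" * 46,
            f"protocols:     {', '.join(p.name for p in self.model.protocols)}",
            f"N / series / dim: {self.model.reference.N} / "
            f"{self.model.reference.n_series} / {self.model.reference.dim}",
            f"method:        {self.method}   seed: {self.seed}",
            f"evaluations:   {self.n_evaluations}   converged: {self.converged}",
            f"J:             {self.J:.6g}",
            f"AMD:           {self.amd:.6g}",
            "-" * 46,
        ]
        sig = self.sigma_linear(sigma_data) if sigma_data is not None else None
        head = f"{'parameter':<10}{'estimate':>14}"
        if sig is not None:
            head += f"{'sigma_linear':>14}"
        lines.append(head)
        for name in PARAM_NAMES:
            row = f"{name:<10}{self.params[name]:>14.6g}"
            if sig is not None:
                row += f"{sig[name]:>14.4g}"
            lines.append(row)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "J": self.J,
            "AMD": self.amd,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "method": self.method,
            "seed": self.seed,
        }


class PathwayFit:
    """Fit the reduced model's 13 parameters to a reference measurement set.

    Parameters
    ----------
    reference : MeasurementSet
        Reference data (raw sets are normalized on construction). Series are
        matched to protocols by the series' protocol name.
    protocols : Protocol or sequence of Protocol
        The stimulation protocols that generated the reference data.
    start : ParameterSet
        Center of the search box and starting point of local refinement.
    bounds_fold : float
        Half-width of the search box in fold change: each parameter is
        searched within [start/fold, start·fold] (in log space).
    """

    def __init__(
        self,
        reference: ms.MeasurementSet,
        protocols: Protocol | Sequence[Protocol],
        start: ParameterSet = FITTED,
        bounds_fold: float = 100.0,
        rho: float = ms.RHO,
        rtol: float | None = None,
        atol: float | None = None,
    ):
        if isinstance(protocols, Protocol):
            protocols = [protocols]
        self.protocols = list(protocols)
        if not self.protocols:
            raise ValueError("at least one protocol is required")
        if bounds_fold <= 1:
            raise ValueError("bounds_fold must exceed 1")
        self.start = start
        self.bounds_fold = float(bounds_fold)
        self.rho = rho
        self.rtol = rtol
        self.atol = atol
        self.reference = reference if reference.normalized \
            else ms.normalize(reference, rho)
        self._by_name = {p.name: p for p in self.protocols}
        ref_names = {s.protocol for s in self.reference.series}
        unknown = ref_names - set(self._by_name)
        if unknown:
            raise ValueError(
                f"reference series name protocols {sorted(unknown)} "
                f"not among {sorted(self._by_name)}"
            )
        self._ref_log = None  # lazy, aligned with model ordering
        self._n_eval = 0

    # -- model evaluation -------------------------------------------------
    def _model_set(self, params: ParameterSet) -> ms.MeasurementSet:
        ref_keys = {s.key for s in self.reference.series}
        series = []
        for p in self.protocols:
            genotypes = tuple(
                g for g in p.schedule.genotypes()
                if any(k[0] == p.name and k[1] == g for k in ref_keys)
            )
            mset = ms.simulate_measurements(
                params, p, genotypes=genotypes, rtol=self.rtol, atol=self.atol)
            series.extend(s for s in mset.series if s.key in ref_keys)
        return ms.normalize(MeasurementSetView(series), self.rho)

    def residuals(self, params: ParameterSet) -> np.ndarray:
        """ln(model) − ln(reference) per measurement; J = ‖residuals‖²."""
        self._n_eval += 1
        lm, lr = _aligned_log_values(self._model_set(params), self.reference)
        return lm - lr

    def objective(self, params: ParameterSet) -> float:
        r = self.residuals(params)
        return float(r @ r)

    # -- optimizers -------------------------------------------------------
    def fit(
        self,
        method: str = "de",
        seed: int | None = None,
        budget: int = 200_000,
        popsize: int = 15,
        tol: float = 1e-6,
        x0: ParameterSet | None = None,
    ) -> PathwayFitResults:
        """Minimize J over the 13 log-transformed parameters.

        ``method="de"`` runs differential evolution (population
        popsize × 13, log-uniform within the bounds, followed by a local
        polish); ``method="local"`` runs trust-region least squares from
        ``x0`` (default: ``start``; the bounds stay centered on ``start``).
        ``budget`` caps the number of model evaluations for the global
        search.
        """
        xc = np.log(self.start.to_array())
        lb = xc - np.log(self.bounds_fold)
        ub = xc + np.log(self.bounds_fold)
        x0 = xc if x0 is None else np.clip(np.log(x0.to_array()), lb, ub)
        self._n_eval = 0

        def obj(x):
            return self.objective(ParameterSet.from_array(np.exp(x)))

        if method == "de":
            n = len(PARAM_NAMES)
            maxiter = max(1, int(budget // (popsize * n)) - 1)
            res = differential_evolution(
                obj, bounds=list(zip(lb, ub)), seed=seed,
                popsize=popsize, maxiter=maxiter, tol=tol,
                init="sobol", polish=True, updating="deferred",
            )
            x, success = res.x, bool(res.success) or res.fun <= tol
        elif method == "local":
            def resid(x):
                return self.residuals(ParameterSet.from_array(np.exp(x)))

            res = least_squares(resid, x0, method="trf", bounds=(lb, ub),
                                xtol=1e-10, ftol=1e-10, gtol=1e-10)
            x, success = res.x, res.status > 0
        else:
            raise ValueError(f"unknown method {method!r}")

        params = ParameterSet.from_array(np.exp(x))
        J = self.objective(params)
        return PathwayFitResults(
            model=self,
            params=params,
            J=J,
            amd=float(np.exp(np.sqrt(J / self.reference.N))),
            n_evaluations=self._n_eval,
            converged=success,
            method=method,
            seed=seed,
        )


def MeasurementSetView(series) -> ms.MeasurementSet:
    """Raw measurement set from a list of series (helper)."""
    return ms.MeasurementSet(tuple(series), normalized=False)


def fit(
    reference_set: ms.MeasurementSet,
    protocols: Protocol | Sequence[Protocol],
    start: ParameterSet = FITTED,
    bounds_fold: float = 100.0,
    seed: int | None = None,
    method: str = "de",
    budget: int = 200_000,
) -> PathwayFitResults:
    """Functional one-shot wrapper around :class:`PathwayFit`."""
    return PathwayFit(reference_set, protocols, start=start,
                      bounds_fold=bounds_fold).fit(
        method=method, seed=seed, budget=budget)
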