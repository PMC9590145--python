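"""Maximum-likelihood fitting of the transition model to panel data.

`TransitionModel` wraps a :class:`~mslt.panel.PanelDataset` and exposes
``fit()`` returning a :class:`TransitionModelResults` carrying the point
estimates, their asymptotic covariance (inverse observed information via a
numerical Hessian), convergence diagnostics and a ``summary()`` table.
Life-table quantities hang off the results object (``.life_table()``).

Transitions of which no observation pair exists in the data are not
identifiable from it; their parameters are held at the initial values,
excluded from the optimisation, flagged in the convergence block and given
NaN standard errors.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools import numdiff

from .likelihood import PairData
from .panel import PanelDataset
from .params import DEFAULT_AGE_CENTER, PARAM_NAMES, TransitionParameters
from .states import TRANSITION_LABELS, HealthState

__all__ = ["TransitionModel", "TransitionModelResults", "profile_check"]

#: Default initial parameter vector: death intercepts -4, disability and
#: recovery intercepts -5 (plausible monthly logits), all slopes 0.
DEFAULT_INIT = TransitionParameters(
    intercepts=np.array([-5.0, -4.0, -5.0, -4.0]), slopes=np.zeros(4)
)

# which transition each vector entry belongs to: (a_12, b_12, a_13, ...)
_PARAM_TRANSITION = np.repeat(np.arange(4), 2)


class TransitionModel:
    """Multinomial-logit illness-death transition model for panel data.

    Parameters
    ----------
    dataset
        Analysis-ready panel data.  Every record must open with a living
        state at month 0.
    age_center
        Age (years) at which linear predictors are centred.
    """

    def __init__(
        self, dataset: PanelDataset, age_center: float = DEFAULT_AGE_CENTER
    ):
        bad = [
            r.participant_id
            for r in dataset
            if not r.observations
            or r.observations[0][0] != 0
            or r.observations[0][1] == HealthState.DEAD
        ]
        if bad:
            raise ValueError(
                "records without a living baseline observation at month 0: "
                + ", ".join(map(str, bad[:5]))
                + ("..." if len(bad) > 5 else "")
            )
        self.dataset = dataset
        self.age_center = float(age_center)
        self.pairs = PairData.from_dataset(dataset)
        if self.pairs.n_pairs == 0:
            raise ValueError("dataset has no observed transition pairs")

    # ------------------------------------------------------------------

    def _params_from_vector(self, vec: np.ndarray) -> TransitionParameters:
        return TransitionParameters.from_vector(vec, age_center=self.age_center)

    def loglike(self, params: TransitionParameters) -> float:
        return self.pairs.log_likelihood(params)

    def loglike_vector(self, vec: np.ndarray) -> float:
        return self.pairs.log_likelihood(self._params_from_vector(vec))

    def identifiable_transitions(self) -> np.ndarray:
        """Boolean mask over the four transitions with observed support."""
        c = self.pairs.pair_counts
        return np.array(
            [
                c.get((1, 2), 0) > 0,
                c.get((1, 3), 0) > 0,
                c.get((2, 1), 0) > 0,
                c.get((2, 3), 0) > 0,
            ]
        )

    def fit(
        self,
        init: Optional[TransitionParameters] = None,
        estimate_slopes: bool = True,
        maxiter: int = 500,
        gtol: float = 1e-5,
    ) -> "TransitionModelResults":
        """Maximise the panel likelihood by quasi-Newton (BFGS) iteration.

        Gradients are central finite differences; the covariance is the
        inverse negative numerical Hessian at the optimum.  Convergence
        status is reported honestly — a failed line search or hitting
        ``maxiter`` is surfaced, not masked.
        """
        if init is None:
            init = DEFAULT_INIT
        x_full = init.to_vector().copy()
        ident = self.identifiable_transitions()
        free = ident[_PARAM_TRANSITION].copy()
        if not estimate_slopes:
            free[1::2] = False
        if not free.any():
            raise ValueError("no identifiable parameters to estimate")

        # optimise the mean log-likelihood per transition pair: keeps the
        # gradient tolerance meaningful regardless of dataset size
        scale = float(self.pairs.n_pairs)

        def neg(free_vec: np.ndarray) -> float:
            x = x_full.copy()
            x[free] = free_vec
            ll = self.loglike_vector(x)
            return math.inf if ll == -math.inf else -ll / scale

        def grad(free_vec: np.ndarray) -> np.ndarray:
            return numdiff.approx_fprime(free_vec, neg, centered=True)

        res = optimize.minimize(
            neg,
            x_full[free],
            jac=grad,
            method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        x_hat = x_full.copy()
        x_hat[free] = res.x
        llf = self.loglike_vector(x_hat)
        gnorm = float(np.max(np.abs(grad(res.x))))

        hess_neg = numdiff.approx_hess(res.x, neg) * scale
        hess_neg = 0.5 * (hess_neg + hess_neg.T)
        singular = False
        try:
            cov_free = np.linalg.inv(hess_neg)
        except np.linalg.LinAlgError:
            cov_free = np.linalg.pinv(hess_neg)
            singular = True
        cov_free = 0.5 * (cov_free + cov_free.T)

        k = len(x_full)
        cov = np.full((k, k), np.nan)
        ix = np.ix_(free, free)
        cov[ix] = cov_free

        non_ident = [
            lab for lab, ok in zip(TRANSITION_LABELS, ident) if not ok
        ]
        convergence = {
            "status": res.message,
            "converged": (bool(res.success) or gnorm < gtol) and not singular,
            "iterations": int(res.nit),
            "gradient_norm": gnorm,
            "singular_hessian": singular,
            "non_identifiable": non_ident,
        }
        return TransitionModelResults(
            model=self,
            params_vector=x_hat,
            free_mask=free,
            cov_params_full=cov,
            cov_free=cov_free,
            hess_neg_free=hess_neg,
            llf=llf,
            convergence=convergence,
        )


@dataclasses.dataclass
class TransitionModelResults:
    """Estimates, covariance and diagnostics from :meth:`TransitionModel.fit`."""

    model: TransitionModel
    params_vector: np.ndarray  # length 8, pinned entries at their init values
    free_mask: np.ndarray  # bool, which entries were estimated
    cov_params_full: np.ndarray  # 8x8, NaN on pinned rows/cols
    cov_free: np.ndarray
    hess_neg_free: np.ndarray  # negative-loglik Hessian over free params
    llf: float
    convergence: dict

    @property
    def params(self) -> TransitionParameters:
        return TransitionParameters.from_vector(
            self.params_vector, age_center=self.model.age_center
        )

    @property
    def cov_params(self) -> np.ndarray:
        return self.cov_params_full

    @property
    def bse(self) -> np.ndarray:
        se = np.full(len(self.params_vector), np.nan)
        diag = np.diag(self.cov_free)
        se[self.free_mask] = np.sqrt(np.clip(diag, 0.0, None))
        return se

    @property
    def n_records(self) -> int:
        return len(self.model.dataset)

    @property
    def n_transition_pairs(self) -> int:
        return self.model.pairs.n_pairs

    def summary(self) -> str:
        df = pd.DataFrame(
            {
                "estimate": self.params_vector,
                "std err": self.bse,
                "estimated": self.free_mask,
            },
            index=list(PARAM_NAMES),
        )
        lines = [
            "Illness-death transition model (multinomial logit, monthly chain)",
            f"records: {self.n_records}   transition pairs: {self.n_transition_pairs}",
            f"log-likelihood: {self.llf:.4f}   age center: {self.model.age_center}",
            f"converged: {self.convergence['converged']} "
            f"({self.convergence['iterations']} iterations, "
            f"max |grad| = {self.convergence['gradient_norm']:.2e})",
        ]
        if self.convergence["non_identifiable"]:
            lines.append(
                "non-identifiable transitions: "
                + ", ".join(self.convergence["non_identifiable"])
            )
        return "\n".join(lines) + "\n\n" + df.to_string()

    # -- life-table interface -------------------------------------------

    def life_table(
        self,
        start_age: float = 65.0,
        max_age: float = 110.0,
        initial_state: HealthState = HealthState.NONDISABLED,
        n_draws: int = 2000,
        seed: Optional[int] = None,
        step_months: float = 1.0,
    ):
        """DFLE/DLE/TLE at ``start_age`` with parametric-simulation CIs."""
        from .lifetable import confidence_intervals

        return confidence_intervals(
            self,
            start_age=start_age,
            max_age=max_age,
            initial_state=initial_state,
            n_draws=n_draws,
            seed=seed,
            step_months=step_months,
        )


def profile_check(
    fit: TransitionModelResults, se_multiple: float = 2.0
) -> pd.DataFrame:
    """Per-parameter curvature sanity report around a fitted optimum.

    Perturbs each estimated parameter by ``+-se_multiple`` standard errors
    and verifies the log-likelihood decreases; also estimates the diagonal
    curvature by a small central second difference and compares it with the
    corresponding entry of the numerical Hessian.  Flat (non-identified)
    directions are flagged.
    """
    model = fit.model
    x0 = fit.params_vector
    llf = fit.llf
    se = fit.bse
    free_idx = np.nonzero(fit.free_mask)[0]
    hess_diag = {j: fit.hess_neg_free[i, i] for i, j in enumerate(free_idx)}
    rows = []
    for j, name in enumerate(PARAM_NAMES):
        if not fit.free_mask[j]:
            rows.append(
                dict(parameter=name, estimated=False, flat=True,
                     decreases=None, curvature_fd=np.nan,
                     curvature_hessian=np.nan)
            )
            continue
        s = se[j]
        flat = not np.isfinite(s) or s <= 0 or s > 1e3
        decreases = None
        if not flat:
            lls = []
            for sign in (+1, -1):
                x = x0.copy()
                x[j] += sign * se_multiple * s
                lls.append(model.loglike_vector(x))
            decreases = bool(all(ll < llf for ll in lls))
        # small-step central second difference for the diagonal curvature
        d = 1e-4 * max(1.0, abs(x0[j]))
        xp, xm = x0.copy(), x0.copy()
        xp[j] += d
        xm[j] -= d
        curv = -(model.loglike_vector(xp) - 2 * llf + model.loglike_vector(xm)) / d**2
        rows.append(
            dict(
                parameter=name,
                estimated=True,
                flat=flat,
                decreases=decreases,
                curvature_fd=curv,
                curvature_hessian=hess_diag[j],
            )
        )
    return pd.DataFrame(rows)
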