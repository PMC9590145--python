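"""Multinomial-logit one-step transition probabilities with linear age.

For each living origin state i the destination of one monthly step follows a
multinomial logit with the retention outcome (staying in i) as reference::

    eta_ij = a_ij + b_ij * (age - age_center)          j != i
    p_ij   = exp(eta_ij) / (1 + sum_k exp(eta_ik))
    p_ii   = 1           / (1 + sum_k exp(eta_ik))

Death is absorbing: its row of every step matrix is (0, 0, 1).  Probabilities
over longer intervals are ordered products of monthly matrices with age
advancing one step at a time.  All softmax evaluations go through
log-sum-exp so extreme ages/parameters cannot overflow.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional

import numpy as np

from .states import TRANSITION_LABELS, TRANSITIONS, HealthState

__all__ = [
    "TransitionParameters",
    "step_matrix",
    "step_probabilities",
    "interval_matrix",
    "read_parameters",
    "write_parameters",
]

#: Default age at which linear predictors are centred (years).  Centring in
#: the middle of the observed age range keeps intercepts interpretable as
#: logits of monthly probabilities at a realistic age.
DEFAULT_AGE_CENTER = 80.0

# parameter vector ordering: (a, b) per transition in TRANSITIONS order
PARAM_NAMES: tuple[str, ...] = tuple(
    f"{kind}_{lab}" for lab in TRANSITION_LABELS for kind in ("intercept", "slope")
)


@dataclasses.dataclass
class TransitionParameters:
    """Intercepts and age slopes of the four transitions.

    ``intercepts`` and ``slopes`` are arrays of length 4 in the order
    1->2, 1->3, 2->1, 2->3 (log-odds; slopes per year of age).  Optional
    named covariate slopes (one array of 4 per covariate) support external
    adjustment; they are off unless supplied.
    """

    intercepts: np.ndarray
    slopes: np.ndarray
    age_center: float = DEFAULT_AGE_CENTER
    covariate_slopes: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.slopes = np.asarray(self.slopes, dtype=float)
        if self.intercepts.shape != (4,) or self.slopes.shape != (4,):
            raise ValueError("intercepts and slopes must each have length 4")
        if not (np.isfinite(self.intercepts).all() and np.isfinite(self.slopes).all()):
            raise ValueError("transition parameters must be finite")

    # -- vector interface (fixed ordering, needed for Hessians/covariances) --

    def to_vector(self) -> np.ndarray:
        """Interleaved (intercept, slope) per transition; length 8."""
        return np.column_stack([self.intercepts, self.slopes]).ravel()

    @classmethod
    def from_vector(
        cls, vec: np.ndarray, age_center: float = DEFAULT_AGE_CENTER
    ) -> "TransitionParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (8,):
            raise ValueError("parameter vector must have length 8")
        pairs = vec.reshape(4, 2)
        return cls(intercepts=pairs[:, 0], slopes=pairs[:, 1], age_center=age_center)

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES

    def linear_predictors(
        self, age, covariates: Optional[Mapping[str, float]] = None
    ) -> np.ndarray:
        """eta for the four transitions at the given age(s); shape (..., 4)."""
        age = np.asarray(age, dtype=float)
        eta = self.intercepts + np.multiply.outer(age - self.age_center, self.slopes)
        if covariates:
            for name, value in covariates.items():
                if name not in self.covariate_slopes:
                    raise KeyError(f"no slope for covariate {name!r}")
                eta = eta + value * np.asarray(self.covariate_slopes[name], float)
        return eta

    def shifted(self, delta: Mapping[str, float]) -> "TransitionParameters":
        """Copy with named vector entries shifted (e.g. {'intercept_1->3': 0.2})."""
        vec = self.to_vector()
        for name, d in delta.items():
            vec[PARAM_NAMES.index(name)] += d
        out = TransitionParameters.from_vector(vec, age_center=self.age_center)
        out.covariate_slopes = {k: np.array(v) for k, v in self.covariate_slopes.items()}
        return out


def _rows_from_eta(eta: np.ndarray) -> np.ndarray:
    """Stack of 3x3 row-stochastic matrices from eta of shape (..., 4).

    eta columns: 1->2, 1->3, 2->1, 2->3.  Uses log-sum-exp per origin row.
    """
    eta = np.asarray(eta, dtype=float)
    if np.isnan(eta).any():
        raise ValueError("NaN in linear predictors")
    out = np.zeros(eta.shape[:-1] + (3, 3), dtype=float)
    # origin NONDISABLED: destinations (stay, 2, 3) <- logits (0, eta12, eta13)
    # origin DISABLED:    destinations (1, stay, 3) <- logits (eta21, 0, eta23)
    z1 = np.stack(
        [np.zeros(eta.shape[:-1]), eta[..., 0], eta[..., 1]], axis=-1
    )
    z2 = np.stack(
        [eta[..., 2], np.zeros(eta.shape[:-1]), eta[..., 3]], axis=-1
    )
    for origin, z in ((0, z1), (1, z2)):
        lse = np.logaddexp.reduce(z, axis=-1, keepdims=True)
        out[..., origin, :] = np.exp(z - lse)
    out[..., 2, 2] = 1.0  # dead is absorbing
    return out


def step_matrix(
    params: TransitionParameters,
    age: float,
    covariates: Optional[Mapping[str, float]] = None,
) -> np.ndarray:
    """One-step (monthly) 3x3 transition matrix at the given age."""
    return _rows_from_eta(params.linear_predictors(age, covariates))


# alias matching the operation name used throughout the docs
step_probabilities = step_matrix


def interval_matrix(
    params: TransitionParameters,
    start_age: float,
    n_steps: int,
    covariates: Optional[Mapping[str, float]] = None,
    step_months: float = 1.0,
) -> np.ndarray:
    """Transition matrix over ``n_steps`` steps starting at ``start_age``.

    Ordered left-to-right product M(a) M(a+h) ... with h = step_months/12
    years; the Chapman-Kolmogorov identity holds exactly by construction.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    h = step_months / 12.0
    out = np.eye(3)
    for k in range(int(n_steps)):
        out = out @ step_matrix(params, start_age + k * h, covariates)
    return out


# ---------------------------------------------------------------------------
# flat key-value parameter files


def write_parameters(params: TransitionParameters, path) -> None:
    """Write parameters as flat ``name = value`` text at full precision."""
    lines = [f"age_center = {float(params.age_center)!r}"]
    vec = params.to_vector()
    for name, v in zip(PARAM_NAMES, vec):
        lines.append(f"{name} = {float(v)!r}")
    for cov, sl in params.covariate_slopes.items():
        for lab, v in zip(TRANSITION_LABELS, np.asarray(sl, float)):
            lines.append(f"cov:{cov}:{lab} = {float(v)!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_parameters(path) -> TransitionParameters:
    values: dict[str, float] = {}
    cov: dict[str, dict[str, float]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key.startswith("cov:"):
                _, name, lab = key.split(":")
                cov.setdefault(name, {})[lab] = float(raw)
            else:
                values[key] = float(raw)
    vec = np.array([values[name] for name in PARAM_NAMES])
    params = TransitionParameters.from_vector(
        vec, age_center=values.get("age_center", DEFAULT_AGE_CENTER)
    )
    params.covariate_slopes = {
        name: np.array([labs[lab] for lab in TRANSITION_LABELS])
        for name, labs in cov.items()
    }
    return params
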