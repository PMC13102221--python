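"""Four-peak cumulative occurrence curve for adult flight activity.

The seasonal cumulative occurrence proportion f(x) of *Grapholita molesta*
adults as a function of thermal time x (cumulative degree-days, CDD) is a
mixture of four monotone components, one per flight peak:

    f(x) = a1 / (1 + (x/b1)^g1)                      (log-logistic, g1 < 0)
         + sum_{k=2..4} a_k / (1 + exp(-z_k))        (logistic)

with component medians mu_1 = b1 and mu_k = b1 + db1 + ... + db_{k-1}: the
b's locate the 50%-occurrence thermal time of each peak, the a's its share
of the season's catch (a1+a2+a3+a4 = 1) and the g's its steepness.

Two readings of the logistic steepness are supported.  Under the ``"scale"``
parameterization z_k = (x - mu_k) / g_k (g in DD); under ``"rate"``
z_k = g_k * (x - mu_k) (g in 1/DD).  The published steepness estimates
(~0.06) produce near-instantaneous steps when read as scales but smooth
~70 DD transitions when read as rates, so ``"rate"`` is the default.  Every
median- or share-derived quantity is identical under either reading.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence, Tuple, Union

import numpy as np
import yaml

from .errors import ConstraintViolationError, InvalidInputError

__all__ = [
    "OccurrenceParams",
    "TABLE1_PARAMS",
    "TABLE1_SEM",
    "evaluate",
    "density",
    "peak_cdd",
    "alpha4_completion",
    "peak_shares",
    "load_params",
    "save_params",
]

_EXP_CLAMP = 700.0  # |z| beyond this leaves the logistic at 0/1 to machine precision

_FREE_NAMES = (
    "alpha1", "alpha2", "alpha3",
    "beta1", "dbeta1", "dbeta2", "dbeta3",
    "gamma1", "gamma2", "gamma3", "gamma4",
)


@dataclass(frozen=True)
class OccurrenceParams:
    """The twelve parameters of the four-peak occurrence curve.

    ``alpha`` are the four mixing proportions (sum to 1), ``beta1`` the 50%
    CDD of the first peak, ``dbeta`` the three inter-peak spacings in DD and
    ``gamma`` the four steepness parameters (gamma1 < 0 is the log-logistic
    exponent of the first peak; gamma2..4 are positive logistic scales or
    rates depending on ``parameterization``).
    """

    alpha: Tuple[float, float, float, float]
    beta1: float
    dbeta: Tuple[float, float, float]
    gamma: Tuple[float, float, float, float]
    parameterization: str = "rate"

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.shape != (4,):
            raise InvalidInputError("alpha must hold exactly four proportions")
        if np.any(a < 0):
            raise ConstraintViolationError("mixing proportions must be >= 0")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ConstraintViolationError(
                f"mixing proportions must sum to 1 (got {a.sum():.12f})"
            )
        if not self.beta1 > 0:
            raise ConstraintViolationError("beta1 must be positive")
        if len(self.dbeta) != 3 or any(d <= 0 for d in self.dbeta):
            raise ConstraintViolationError("all three dbeta spacings must be positive")
        g = self.gamma
        if len(g) != 4:
            raise InvalidInputError("gamma must hold exactly four values")
        if not g[0] < 0:
            raise ConstraintViolationError("gamma1 must be negative (decaying log-logistic)")
        if any(gk <= 0 for gk in g[1:]):
            raise ConstraintViolationError("gamma2..gamma4 must be positive")
        if self.parameterization not in ("scale", "rate"):
            raise InvalidInputError("parameterization must be 'scale' or 'rate'")

    @property
    def peak_cdds(self) -> Tuple[float, float, float, float]:
        """50%-occurrence CDD of each peak: cumulative sums of beta1, dbeta."""
        b = self.beta1
        return (b, b + self.dbeta[0], b + sum(self.dbeta[:2]), b + sum(self.dbeta))

    @property
    def free(self) -> np.ndarray:
        """The 11 free parameters (alpha4 completed from the others)."""
        return np.array(
            [*self.alpha[:3], self.beta1, *self.dbeta, *self.gamma], dtype=float
        )

    @classmethod
    def from_free(cls, free: Sequence[float], parameterization: str = "rate") -> "OccurrenceParams":
        v = np.asarray(free, dtype=float)
        if v.shape != (11,):
            raise InvalidInputError("expected 11 free parameters")
        a4 = alpha4_completion(v[0], v[1], v[2])
        return cls(
            alpha=(v[0], v[1], v[2], a4),
            beta1=v[3],
            dbeta=(v[4], v[5], v[6]),
            gamma=(v[7], v[8], v[9], v[10]),
            parameterization=parameterization,
        )

    def with_parameterization(self, mode: str) -> "OccurrenceParams":
        return replace(self, parameterization=mode)


#: Published parameter estimates of the fitted Korean apple-orchard model.
TABLE1_PARAMS = OccurrenceParams(
    alpha=(0.2751, 0.3501, 0.1724, 0.2024),
    beta1=172.23,
    dbeta=(464.08, 575.33, 604.38),
    gamma=(-7.6149, 0.0586, 0.0904, 0.0604),
    parameterization="rate",
)

#: Asymptotic standard errors reported alongside the estimates (alpha4 was
#: completed, not estimated, hence carries no SEM).
TABLE1_SEM = {
    "alpha1": 0.0243, "alpha2": 0.4270, "alpha3": 0.6155,
    "beta1": 4.0759, "dbeta1": 1414.63, "dbeta2": 960.47, "dbeta3": 936.29,
    "gamma1": 1.3911, "gamma2": 0.0312, "gamma3": 0.1663, "gamma4": 0.0379,
}


def _terms(x: np.ndarray, p: OccurrenceParams) -> np.ndarray:
    """Stack of the four component values at x, shape (4, ...)."""
    a = np.asarray(p.alpha)
    mu = np.asarray(p.peak_cdds)
    out = np.empty((4,) + x.shape, dtype=float)
    # first peak: log-logistic with negative exponent; limit 0 at the origin
    with np.errstate(divide="ignore", over="ignore"):
        xpos = np.where(x > 0, x, 1.0)  # placeholder; masked to the limit below
        u = np.where(x > 0, np.power(xpos / p.beta1, p.gamma[0]), np.inf)
    out[0] = a[0] / (1.0 + u)
    for k in (1, 2, 3):
        if p.parameterization == "scale":
            z = (x - mu[k]) / p.gamma[k]
        else:
            z = p.gamma[k] * (x - mu[k])
        z = np.clip(z, -_EXP_CLAMP, _EXP_CLAMP)
        out[k] = a[k] / (1.0 + np.exp(-z))
    return out


def evaluate(x: Union[float, np.ndarray], p: OccurrenceParams) -> Union[float, np.ndarray]:
    """Cumulative occurrence proportion f(x) at thermal time x (DD).

    Defined at x = 0 through the analytic limit (0), so curves can be drawn
    from the origin.  Nondecreasing in x; approaches 1 as x grows.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise InvalidInputError("thermal time x must be finite and >= 0")
    val = _terms(arr, p).sum(axis=0)
    if val.ndim == 0:
        return float(val)
    return val


def density(x: Union[float, np.ndarray], p: OccurrenceParams) -> Union[float, np.ndarray]:
    """Analytical derivative of :func:`evaluate` (occurrence per DD); >= 0."""
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise InvalidInputError("density requires x > 0")
    a = np.asarray(p.alpha)
    mu = np.asarray(p.peak_cdds)
    with np.errstate(over="ignore"):
        u = np.power(arr / p.beta1, p.gamma[0])
        d = -a[0] * p.gamma[0] * u / (arr * (1.0 + u) ** 2)
        for k in (1, 2, 3):
            if p.parameterization == "scale":
                z, slope = (arr - mu[k]) / p.gamma[k], 1.0 / p.gamma[k]
            else:
                z, slope = p.gamma[k] * (arr - mu[k]), p.gamma[k]
            s = 1.0 / (1.0 + np.exp(-np.clip(z, -_EXP_CLAMP, _EXP_CLAMP)))
            d = d + a[k] * slope * s * (1.0 - s)
    if d.ndim == 0:
        return float(d)
    return d


def peak_cdd(p: OccurrenceParams, k: int) -> float:
    """50%-occurrence CDD of peak ``k`` (1-4): beta1 plus the spacings before it."""
    if k not in (1, 2, 3, 4):
        raise InvalidInputError(f"peak index must be 1..4, got {k}")
    return p.peak_cdds[k - 1]


def alpha4_completion(a1: float, a2: float, a3: float) -> float:
    """Fourth mixing proportion from the unit-sum constraint: 1 - a1 - a2 - a3."""
    for a in (a1, a2, a3):
        if not (np.isfinite(a) and a >= 0):
            raise InvalidInputError("proportions must be finite and >= 0")
    s = a1 + a2 + a3
    if s > 1 + 1e-12:
        raise ConstraintViolationError(f"a1+a2+a3 = {s} exceeds 1")
    return max(1.0 - s, 0.0)


def peak_shares(p: OccurrenceParams) -> Tuple[int, int, int, int]:
    """Each peak's share of the season's catch, rounded to whole percent."""
    return tuple(int(np.rint(100.0 * a)) for a in p.alpha)  # type: ignore[return-value]


# --- parameter file round-tripping (flat key-value YAML) --------------------

def save_params(p: OccurrenceParams, path) -> None:
    doc = {
        "alpha1": float(p.alpha[0]), "alpha2": float(p.alpha[1]),
        "alpha3": float(p.alpha[2]), "alpha4": float(p.alpha[3]),
        "beta1": float(p.beta1),
        "dbeta1": float(p.dbeta[0]), "dbeta2": float(p.dbeta[1]), "dbeta3": float(p.dbeta[2]),
        "gamma1": float(p.gamma[0]), "gamma2": float(p.gamma[1]),
        "gamma3": float(p.gamma[2]), "gamma4": float(p.gamma[3]),
        "parameterization": p.parameterization,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_params(path) -> OccurrenceParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return OccurrenceParams(
        alpha=(doc["alpha1"], doc["alpha2"], doc["alpha3"], doc["alpha4"]),
        beta1=doc["beta1"],
        dbeta=(doc["dbeta1"], doc["dbeta2"], doc["dbeta3"]),
        gamma=(doc["gamma1"], doc["gamma2"], doc["gamma3"], doc["gamma4"]),
        parameterization=doc.get("parameterization", "rate"),
    )


def load_bundled_params() -> OccurrenceParams:
    """The published parameter set, read from the bundled YAML file."""
    ref = resources.files("gmolesta").joinpath("data/table1_params.yaml")
    with resources.as_file(ref) as path:
        return load_params(path)
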