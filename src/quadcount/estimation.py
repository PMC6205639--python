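"""Population-size estimation and the parameter-selection protocol.

The estimator is Horvitz–Thompson: under a uniform-random grid offset every
particle is captured with probability exactly ``f = t^2/T^2``, so

    N_hat = (T/t)^2 * Q = Q / f

is unbiased for the population size ``N``, where ``Q`` is the total count
over the quadrats.  The protocol layer translates the observed sample
richness — ``Q`` and the number ``n`` of nonempty quadrats — into an
expected coefficient-of-error band and, when a band is targeted, into
concrete advice: too few particles means increase the sampling fraction
``f``; too few nonempty quadrats means increase the initial quadrat count
``n0``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

from .geometry import GridParams

__all__ = [
    "CEBand",
    "Advice",
    "BAND_THRESHOLDS",
    "estimate_size",
    "ce_band",
    "advise",
    "suggest_initial_f",
    "suggest_initial_params",
    "EstimateResult",
    "CrowdedQuadratsWarning",
]


class CEBand(enum.Enum):
    """Qualitative coefficient-of-error band, from tightest to loosest."""

    APPROX_5 = "~5%"
    WITHIN_10 = "<~10%"
    WITHIN_15 = "<~15%"
    INSUFFICIENT = "insufficient-sample"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Advice(enum.Enum):
    """How to adjust the grid to reach a target band."""

    NONE = "none"
    INCREASE_F = "increase-f"
    INCREASE_N0 = "increase-n0"
    BOTH = "increase-f-and-n0"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: (min Q, min n, band), tightest first.  These operationalize the advisory
#: thresholds "Q >~ 50 & n >~ 20 => CE <~ 15%", "Q >~ 100 & n >~ 30 =>
#: CE <~ 10%", "Q ~ 200 & n ~ 50 => CE ~ 5%" as hard cutoffs; callers may
#: supply their own table.
BAND_THRESHOLDS: tuple[tuple[int, int, CEBand], ...] = (
    (200, 50, CEBand.APPROX_5),
    (100, 30, CEBand.WITHIN_10),
    (50, 20, CEBand.WITHIN_15),
)

#: Mean particles per nonempty quadrat beyond which counting by eye gets
#: error-prone and a smaller f is advisable.
MAX_MEAN_PER_QUADRAT = 5.0


class CrowdedQuadratsWarning(UserWarning):
    """Mean count per nonempty quadrat exceeds the comfortable manual limit."""


def estimate_size(Q: float, params: GridParams) -> float:
    """Horvitz–Thompson size estimate ``(T/t)^2 * Q`` (equivalently ``Q/f``)."""
    if Q < 0:
        raise ValueError(f"sample count must be nonnegative, got {Q}")
    return (params.T / params.t) ** 2 * Q


def _validate_sample(Q: int, n: int) -> None:
    if Q < 0 or n < 0:
        raise ValueError(f"Q and n must be nonnegative, got Q={Q}, n={n}")
    if n > 0 and Q < n:
        raise ValueError(
            f"inconsistent sample: Q={Q} particles cannot occupy n={n} nonempty quadrats"
        )


def ce_band(
    Q: int,
    n: int,
    thresholds: tuple[tuple[int, int, CEBand], ...] = BAND_THRESHOLDS,
) -> CEBand:
    """Tightest expected-CE band whose (Q, n) thresholds are both met."""
    _validate_sample(Q, n)
    for q_min, n_min, band in thresholds:
        if Q >= q_min and n >= n_min:
            return band
    return CEBand.INSUFFICIENT


def advise(
    Q: int,
    n: int,
    target: CEBand = CEBand.WITHIN_10,
    thresholds: tuple[tuple[int, int, CEBand], ...] = BAND_THRESHOLDS,
) -> Advice:
    """Adjustment needed to reach ``target``: raise f if Q is short, n0 if n is.

    Returns :class:`Advice.NONE` exactly when the achieved band is at least
    as tight as the target.
    """
    _validate_sample(Q, n)
    if target is CEBand.INSUFFICIENT:
        return Advice.NONE
    q_min, n_min = next((q, m) for q, m, band in thresholds if band is target)
    low_q, low_n = Q < q_min, n < n_min
    if low_q and low_n:
        return Advice.BOTH
    if low_q:
        return Advice.INCREASE_F
    if low_n:
        return Advice.INCREASE_N0
    return Advice.NONE


#: Suggested starting sampling fraction by order of magnitude of N.
_F_BY_MAGNITUDE = {
    "<=1e3": 0.1,
    "1e3-1e4": 0.04,
    ">=1e4": 0.01,
    "unknown": 0.04,
}

#: Tentative initial quadrat count when nothing is known about the pattern.
DEFAULT_N0 = 100.0


def suggest_initial_f(n_magnitude: str = "unknown") -> float:
    """Starting sampling fraction for a rough order of magnitude of N.

    ``"<=1e3"`` -> 0.1 (for very small populations sampling barely helps,
    since Q approaches N); ``"1e3-1e4"`` -> 0.04; ``">=1e4"`` -> 0.01;
    ``"unknown"`` -> the tentative default 0.04.
    """
    try:
        return _F_BY_MAGNITUDE[n_magnitude]
    except KeyError:
        raise ValueError(
            f"unknown magnitude class {n_magnitude!r}; expected one of {sorted(_F_BY_MAGNITUDE)}"
        ) from None


def suggest_initial_params(n_magnitude: str = "unknown") -> tuple[float, float]:
    """Starting ``(f, n0)`` pair; n0 = 100 regardless of magnitude class."""
    return suggest_initial_f(n_magnitude), DEFAULT_N0


@dataclass(frozen=True)
class EstimateResult:
    """One estimate with its sample diagnostics and protocol reading."""

    N_hat: float
    Q: int
    n: int
    params: GridParams
    f: float
    n0: float
    band: CEBand
    advice: Advice

    def to_dict(self) -> dict:
        return {
            "N_hat": self.N_hat,
            "Q": self.Q,
            "n": self.n,
            "t": self.params.t,
            "T": self.params.T,
            "theta": self.params.theta,
            "f": self.f,
            "n0": self.n0,
            "band": self.band.value,
            "advice": self.advice.value,
        }


def summarize_sample(
    Q: int,
    n: int,
    params: GridParams,
    n0: float,
    target: CEBand = CEBand.WITHIN_10,
) -> EstimateResult:
    """Bundle estimate, CE band and advice for one quadrat sample.

    Warns (:class:`CrowdedQuadratsWarning`) when the mean count per nonempty
    quadrat exceeds 5, the practical limit for reliable manual counting.
    """
    _validate_sample(Q, n)
    if n > 0 and Q / n > MAX_MEAN_PER_QUADRAT:
        warnings.warn(
            f"mean count per nonempty quadrat is {Q / n:.1f} (> {MAX_MEAN_PER_QUADRAT:g}); "
            "consider a smaller sampling fraction f",
            CrowdedQuadratsWarning,
            stacklevel=2,
        )
    return EstimateResult(
        N_hat=estimate_size(Q, params),
        Q=Q,
        n=n,
        params=params,
        f=params.f,
        n0=n0,
        band=ce_band(Q, n),
        advice=advise(Q, n, target),
    )
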