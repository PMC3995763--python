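"""Parameter and boundary-value containers for the lifetime learning model.

The model tracks two states over a finite lifetime ``[0, T_max]``: energy
``E`` and knowledge ``L``.  Energy is harvested at a rate that saturates in
knowledge (Michaelis-Menten form with half-saturation ``k_L``), is spent on
living (``m``) and on learning (the control ``u``); knowledge is gained in
proportion to the learning investment (efficiency ``alpha``) and decays at
rate ``m_L``.

``ModelParams`` holds the six biological/environmental constants with their
published sweep ranges; ``BoundaryConstraints`` holds the optimisation-side
values (initial state, survival floor, control bounds).  Values outside the
published ranges are accepted with a warning, never rejected, so that users
can probe beyond them deliberately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace as _dc_replace

__all__ = [
    "ModelParams",
    "BoundaryConstraints",
    "PARAM_SWEEP_RANGES",
    "SWEEPABLE_PARAMS",
]

#: Published ranges of the model constants (min, max).  ``m`` has a single
#: published value, encoded as a degenerate range.
PARAM_SWEEP_RANGES: dict[str, tuple[float, float]] = {
    "f_max": (0.5, 10.0),
    "k_L": (0.001, 10.0),
    "m": (0.02, 0.02),
    "alpha": (0.5, 10.0),
    "m_L": (0.01, 1.0),
    "T_max": (5.0, 100.0),
}

#: Parameters that may be swept; ``m`` is fixed (single published value).
SWEEPABLE_PARAMS = ("T_max", "m_L", "k_L", "alpha")


@dataclass(frozen=True)
class ModelParams:
    """The six model constants.

    Parameters
    ----------
    f_max : float
        Maximal energy intake rate (E/t) at saturating knowledge.
    k_L : float
        Half-saturation knowledge level (L); proxies spatial heterogeneity.
    m : float
        Energy maintenance cost rate (E/t).
    alpha : float
        Knowledge gained per unit energy invested in learning (L/E).
    m_L : float
        Knowledge decay ("forgetting") rate (1/t); proxies temporal
        unpredictability.
    T_max : float
        Life duration (t).

    Defaults reproduce the worked baseline example (f_max=1, k_L=1, m=0.02,
    alpha=1, m_L=0.08, T_max=20).
    """

    f_max: float = 1.0
    k_L: float = 1.0
    m: float = 0.02
    alpha: float = 1.0
    m_L: float = 0.08
    T_max: float = 20.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = float(getattr(self, f.name))
            object.__setattr__(self, f.name, v)
            if not math.isfinite(v) or v <= 0.0:
                raise ValueError(
                    f"ModelParams.{f.name} must be strictly positive and "
                    f"finite, got {v!r}"
                )
        for name, (lo, hi) in PARAM_SWEEP_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                warnings.warn(
                    f"ModelParams.{name}={v:g} is outside the published "
                    f"range [{lo:g}, {hi:g}]; proceeding anyway",
                    UserWarning,
                    stacklevel=3,
                )

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with some fields replaced."""
        return _dc_replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class BoundaryConstraints:
    """Initial state, survival floor and control bounds.

    ``E0 > E_min`` is required: the subject must start alive with some
    spendable reserve.  The effective control ceiling is
    ``min(u_max, f_max)`` -- learning expenditure per unit time can exceed
    neither the declared bound nor the maximal energy acquisition rate.
    """

    E0: float = 5.5
    L0: float = 0.0
    E_min: float = 5.0
    L_min: float = 0.0
    u_min: float = 0.0
    u_max: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = float(getattr(self, f.name))
            object.__setattr__(self, f.name, v)
            if not math.isfinite(v):
                raise ValueError(f"BoundaryConstraints.{f.name} must be finite")
        if not self.E0 > self.E_min:
            raise ValueError(
                f"initial energy E0={self.E0:g} must exceed the survival "
                f"floor E_min={self.E_min:g}"
            )
        if self.L0 < self.L_min:
            raise ValueError(
                f"initial knowledge L0={self.L0:g} is below L_min={self.L_min:g}"
            )
        if self.u_min < 0.0:
            raise ValueError("u_min must be non-negative")
        if not self.u_max > self.u_min:
            raise ValueError("u_max must exceed u_min")

    def control_ceiling(self, params: ModelParams) -> float:
        """Effective upper bound on the learning investment rate."""
        return min(self.u_max, params.f_max)

    def replace(self, **changes: float) -> "BoundaryConstraints":
        return _dc_replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
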