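"""Library of bifurcating dynamical models.

Each :class:`ModelSpec` is a stochastic differential equation

    dX/dt = f(X, p) + g(X) * xi(t)

whose control parameter ``p`` is either ramped linearly through a bifurcation
point ``p_crit`` (transition models) or held fixed below it (no-transition
models).  The default library spans the four local bifurcations that exhibit
critical slowing down:

* fold (saddle-node)            -> catastrophic transitions (C.T.)
* transcritical / pitchfork /
  supercritical Hopf            -> smooth transitions (S.T.)
* fixed sub-critical parameters -> no transition (N.T.)

Fold models are included in both orientations: collapse of a high-density
upper branch (grazed and harvested logistic) and of a low-density lower
branch (normal form), since generalisation failures concentrate on the
lone low-density model when it is held out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["ModelSpec", "model_library", "LABELS", "CT", "ST", "NT"]

CT, ST, NT = "C.T.", "S.T.", "N.T."
LABELS = (CT, ST, NT)

#: bifurcation types that give a catastrophic (discontinuous) transition
CATASTROPHIC_TYPES = frozenset({"fold"})
#: bifurcation types that give a smooth (continuous) transition
SMOOTH_TYPES = frozenset({"transcritical", "pitchfork", "hopf"})


@dataclass(frozen=True)
class ModelSpec:
    """One stochastic model with its forcing protocol.

    ``drift(x, p)`` and ``diffusion(x)`` must be vectorised over leading axes;
    for 2-D models (``state_dim == 2``) ``x`` carries the component axis last
    and the recorded series is ``x[..., record_component]``.
    """

    name: str
    drift: Callable[[np.ndarray, np.ndarray], np.ndarray]
    diffusion: Callable[[np.ndarray], np.ndarray]
    p_start: float
    p_end: float
    bifurcation_type: str  # fold | transcritical | pitchfork | hopf | none
    p_crit: float | None
    x0_sampler: Callable[[np.random.Generator, int], np.ndarray]
    state_dim: int = 1
    record_component: int = 0
    clip_zero: bool = False  # density-like state clipped at 0

    def __post_init__(self) -> None:
        known = CATASTROPHIC_TYPES | SMOOTH_TYPES | {"none"}
        if self.bifurcation_type not in known:
            raise ValueError(f"unknown bifurcation_type {self.bifurcation_type!r}")
        if self.bifurcation_type == "none":
            if self.p_crit is not None and self._ramp_reaches(self.p_crit):
                raise ValueError(f"{self.name}: no-transition ramp reaches p_crit")
        else:
            if self.p_crit is None:
                raise ValueError(f"{self.name}: transition model needs p_crit")
            lo, hi = sorted((self.p_start, self.p_end))
            if not (lo < self.p_crit < hi):
                raise ValueError(
                    f"{self.name}: p_crit {self.p_crit} not strictly inside ramp "
                    f"[{self.p_start}, {self.p_end}]"
                )
        if self.state_dim not in (1, 2):
            raise ValueError("state_dim must be 1 or 2")

    def _ramp_reaches(self, p: float) -> bool:
        lo, hi = sorted((self.p_start, self.p_end))
        return lo <= p <= hi

    @property
    def transition_label(self) -> str:
        if self.bifurcation_type in CATASTROPHIC_TYPES:
            return CT
        if self.bifurcation_type in SMOOTH_TYPES:
            return ST
        return NT

    def ramp(self, fractions: np.ndarray) -> np.ndarray:
        """Control parameter at the given fractions of elapsed forcing time."""
        return self.p_start + (self.p_end - self.p_start) * np.asarray(fractions)

    def crossing_fraction(self) -> float | None:
        """Fraction of the ramp at which p crosses p_crit (None if never)."""
        if self.p_crit is None or self.p_end == self.p_start:
            return None
        frac = (self.p_crit - self.p_start) / (self.p_end - self.p_start)
        return float(frac) if 0.0 <= frac <= 1.0 else None

    def with_ramp(self, p_start: float, p_end: float) -> "ModelSpec":
        from dataclasses import replace

        return replace(self, p_start=p_start, p_end=p_end)


# ---------------------------------------------------------------------------
# canonical model forms


def _normal_sampler(loc: float | Sequence[float], scale: float):
    loc_arr = np.atleast_1d(np.asarray(loc, dtype=float))

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        out = loc_arr + scale * rng.standard_normal((n, loc_arr.size))
        return out[:, 0] if loc_arr.size == 1 else out

    return sample


def _grazing_p_crit(r: float, K: float, h: float) -> float:
    """Fold point of the grazed logistic: the largest grazing rate that still
    admits an upper-branch equilibrium, from the tangency of
    p(x) = r (1 - x/K) (x^2 + h^2) / x."""

    def neg_p(x: float) -> float:
        return -r * (1.0 - x / K) * (x * x + h * h) / x

    res = minimize_scalar(neg_p, bounds=(K / 4, K), method="bounded")
    return float(-res.fun)


def _upper_eq_grazed(r: float, K: float, h: float, p: float) -> float:
    # largest root of r x (1 - x/K) = p x^2/(x^2+h^2)
    coeffs = [r / K, -r, p + r * h * h / K, -r * h * h]  # cubic in x
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real
    return float(real.max())


def _ramp_for(p_start: float, p_crit: float, crossing_fraction: float = 0.85) -> float:
    """p_end placing the p_crit crossing at the given ramp fraction."""
    return p_start + (p_crit - p_start) / crossing_fraction


def model_library(crossing_fraction: float = 0.85) -> list[ModelSpec]:
    """The default 10-model library (6 transition + 4 no-transition specs)."""
    r, K, h = 1.0, 10.0, 1.0
    p_fold_grazed = _grazing_p_crit(r, K, h)  # ~2.604 for (1, 10, 1)

    def grazed_drift(x, p):
        return r * x * (1.0 - x / K) - p * x * x / (x * x + h * h)

    def harvest_const_drift(x, p):
        return r * x * (1.0 - x / K) - p

    def harvest_prop_drift(x, p):
        return r * x * (1.0 - x / K) - p * x

    # Normal-form models are expressed in rescaled state units (X = S * x)
    # and, like the harvested/grazed population models, around an operating
    # level B(p) that tracks the environmental forcing: ramping p moves the
    # observed equilibrium in every forced model, as it does in ecological
    # and climate systems.  Dynamics and bifurcation structure in the
    # deviation variable are the canonical normal forms.
    S = 5.0
    B0, B1 = 5.0, -2.0  # operating level B(p) = B0 + B1 * p

    def _level(p):
        return B0 + B1 * p

    def fold_lower_drift(x, p):
        return (S * S * p - x * x) / S

    def pitchfork_drift(x, p):
        u = x - _level(p)
        return p * u - u**3 / (S * S)

    omega = 1.0

    def hopf_drift(x, p):
        # x[..., 0] = B(p) + u, x[..., 1] = v; supercritical Hopf normal form
        u, v = x[..., 0] - _level(p), x[..., 1]
        r2 = (u * u + v * v) / (S * S)
        du = p * u - omega * v - u * r2
        dv = omega * u + p * v - v * r2
        return np.stack([du, dv], axis=-1)

    def mult(scale):
        return lambda x: scale * x

    def add(scale):
        return lambda x: scale * np.ones_like(x)

    x0_grazed = _upper_eq_grazed(r, K, h, 1.0)  # upper equilibrium at p=1
    p0_hc = 0.5
    x0_hc = K / 2 * (1 + np.sqrt(1 - 4 * p0_hc / (r * K)))

    lib = [
        ModelSpec(
            name="fold_grazed",
            drift=grazed_drift,
            diffusion=mult(0.05),
            p_start=1.0,
            p_end=_ramp_for(1.0, p_fold_grazed, crossing_fraction),
            bifurcation_type="fold",
            p_crit=p_fold_grazed,
            x0_sampler=_normal_sampler(x0_grazed, 0.3),
            clip_zero=True,
        ),
        ModelSpec(
            name="fold_harvest",
            drift=harvest_const_drift,
            diffusion=mult(0.05),
            p_start=p0_hc,
            p_end=_ramp_for(p0_hc, r * K / 4, crossing_fraction),
            bifurcation_type="fold",
            p_crit=r * K / 4,
            x0_sampler=_normal_sampler(x0_hc, 0.3),
            clip_zero=True,
        ),
        ModelSpec(
            name="fold_lower",
            drift=fold_lower_drift,
            diffusion=add(0.1),
            p_start=0.6,
            p_end=_ramp_for(0.6, 0.0, crossing_fraction),
            bifurcation_type="fold",
            p_crit=0.0,
            x0_sampler=_normal_sampler(S * np.sqrt(0.6), 0.25),
            clip_zero=True,
        ),
        ModelSpec(
            name="transcritical_harvest",
            drift=harvest_prop_drift,
            diffusion=mult(0.05),
            p_start=0.15,
            p_end=_ramp_for(0.15, r, crossing_fraction),
            bifurcation_type="transcritical",
            p_crit=r,
            x0_sampler=_normal_sampler(K * (1 - 0.15 / r), 0.3),
            clip_zero=True,
        ),
        ModelSpec(
            name="pitchfork",
            drift=pitchfork_drift,
            diffusion=add(0.1),
            p_start=-0.6,
            p_end=_ramp_for(-0.6, 0.0, crossing_fraction),
            bifurcation_type="pitchfork",
            p_crit=0.0,
            x0_sampler=_normal_sampler(_level(-0.6), 0.25),
        ),
        ModelSpec(
            name="hopf",
            drift=hopf_drift,
            diffusion=add(0.1),
            p_start=-0.6,
            p_end=_ramp_for(-0.6, 0.0, crossing_fraction),
            bifurcation_type="hopf",
            p_crit=0.0,
            x0_sampler=_normal_sampler([_level(-0.6), 0.0], 0.25),
            state_dim=2,
        ),
        ModelSpec(
            name="nt_grazed",
            drift=grazed_drift,
            diffusion=mult(0.05),
            p_start=1.5,
            p_end=1.5,
            bifurcation_type="none",
            p_crit=None,
            x0_sampler=_normal_sampler(_upper_eq_grazed(r, K, h, 1.5), 0.3),
            clip_zero=True,
        ),
        ModelSpec(
            name="nt_transcritical",
            drift=harvest_prop_drift,
            diffusion=mult(0.05),
            p_start=0.4,
            p_end=0.4,
            bifurcation_type="none",
            p_crit=None,
            x0_sampler=_normal_sampler(K * (1 - 0.4 / r), 0.3),
            clip_zero=True,
        ),
        ModelSpec(
            name="nt_pitchfork",
            drift=pitchfork_drift,
            diffusion=add(0.1),
            p_start=-0.5,
            p_end=-0.5,
            bifurcation_type="none",
            p_crit=None,
            x0_sampler=_normal_sampler(_level(-0.5), 0.25),
        ),
        ModelSpec(
            name="nt_hopf",
            drift=hopf_drift,
            diffusion=add(0.1),
            p_start=-0.5,
            p_end=-0.5,
            bifurcation_type="none",
            p_crit=None,
            x0_sampler=_normal_sampler([_level(-0.5), 0.0], 0.25),
            state_dim=2,
        ),
    ]
    return lib
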