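"""Forward SANDI signal model under the spherical-mean framework.

The direction-averaged (powder-average) signal of cortical tissue is
modelled as three non-exchanging compartments:

* neurites: zero-radius sticks with axial diffusivity ``d_in``; their
  spherical mean has the closed form sqrt(pi/(4 b d)) * erf(sqrt(b d));
* somas: impermeable spheres of radius ``r_soma`` with internal
  diffusivity ``d_soma``, attenuated per the Gaussian-phase-distribution
  (GPD) approximation (Murday-Cotts series);
* extracellular space: isotropic Gaussian "ball", exp(-b d_e).

The total signal is the fraction-weighted sum, normalized to 1 at b=0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .protocol import AcquisitionProtocol

__all__ = [
    "GAMMA_MS",
    "D_SOMA",
    "SandiParams",
    "stick_sphmean_signal",
    "ball_signal",
    "sphere_gpd_signal",
    "sandi_signal",
    "spherical_mean",
    "gradient_strength",
    "sphere_bessel_roots",
]

#: gyromagnetic ratio of the proton, rad / (ms T) (= 2.6752e8 rad/s/T).
GAMMA_MS = 2.6752218744e5

#: intra-soma diffusivity, um^2/ms — free water at body temperature,
#: fixed by convention rather than fitted.
D_SOMA = 3.0

_N_ROOTS = 20
_TAIL_TOL = 1e-8


@dataclass(frozen=True)
class SandiParams:
    """Five-parameter SANDI tissue description.

    Fractions are signal fractions on the simplex; ``f_extracellular`` is
    derived as ``1 - f_neurite - f_soma``. Radii in um, diffusivities in
    um^2/ms.
    """

    f_neurite: float
    f_soma: float
    r_soma: float
    d_in: float
    d_e: float
    d_soma: float = D_SOMA

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_neurite <= 1.0 and 0.0 <= self.f_soma <= 1.0):
            raise ValueError("signal fractions must lie in [0, 1]")
        if self.f_neurite + self.f_soma > 1.0 + 1e-9:
            raise ValueError(
                f"f_neurite + f_soma = {self.f_neurite + self.f_soma:.4f} > 1"
            )
        if not (1.0 <= self.r_soma <= 12.0):
            raise ValueError(f"r_soma = {self.r_soma} um outside [1, 12]")
        for name in ("d_in", "d_e", "d_soma"):
            d = getattr(self, name)
            if not (0.0 < d <= 3.0):
                raise ValueError(f"{name} = {d} outside (0, 3] um^2/ms")

    @property
    def f_extracellular(self) -> float:
        return max(0.0, 1.0 - self.f_neurite - self.f_soma)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.f_neurite, self.f_soma, self.r_soma, self.d_in, self.d_e]
        )


# ---------------------------------------------------------------------------
# compartment signals
# ---------------------------------------------------------------------------


def stick_sphmean_signal(b, d_in):
    """Spherical-mean signal of a stick compartment.

    S(b) = sqrt(pi / (4 b d)) * erf(sqrt(b d)), the orientation average of
    exp(-b d cos^2 theta) over the sphere; S(0) = 1.
    """
    b = np.asarray(b, float)
    if np.any(b < 0):
        raise ValueError("negative b-value")
    if d_in <= 0:
        raise ValueError("d_in must be positive")
    bd = b * d_in
    out = np.ones_like(bd)
    nz = bd > 1e-12
    out[nz] = np.sqrt(np.pi / (4.0 * bd[nz])) * special.erf(np.sqrt(bd[nz]))
    return out if out.ndim else float(out)


def ball_signal(b, d_e):
    """Isotropic Gaussian compartment: exp(-b d_e)."""
    b = np.asarray(b, float)
    if np.any(b < 0):
        raise ValueError("negative b-value")
    if d_e <= 0:
        raise ValueError("d_e must be positive")
    out = np.exp(-b * d_e)
    return out if out.ndim else float(out)


def _find_sphere_roots(n: int) -> np.ndarray:
    """First ``n`` positive roots of d/dx j1(x) = 0 (j1: spherical Bessel).

    These are the eigenvalue roots of the reflecting-sphere diffusion
    problem; the first is 2.0815759778...
    """

    def j1p(x):
        return special.spherical_jn(1, x, derivative=True)

    roots = []
    # roots are separated by ~pi; bracket and bisect
    lo = 1.0
    while len(roots) < n:
        hi = lo + 0.1
        while j1p(lo) * j1p(hi) > 0:
            hi += 0.1
        r = optimize.brentq(j1p, lo, hi, xtol=1e-13, rtol=1e-15)
        roots.append(r)
        lo = r + 1.0
    return np.array(roots)


_ROOTS: np.ndarray | None = None


def sphere_bessel_roots() -> np.ndarray:
    """Cached roots of j1'(x)=0 used by the GPD series."""
    global _ROOTS
    if _ROOTS is None:
        _ROOTS = _find_sphere_roots(_N_ROOTS)
    return _ROOTS


def gradient_strength(b, delta_small, delta_big):
    """Gradient amplitude G (T/um) from b = gamma^2 G^2 delta^2 (Delta - delta/3)."""
    b = np.asarray(b, float)
    tau = delta_small**2 * (delta_big - delta_small / 3.0)
    return np.sqrt(b / (GAMMA_MS**2 * tau))


def sphere_gpd_signal(b, delta_small, delta_big, r_soma, d_soma=D_SOMA):
    """GPD attenuation of spins restricted in an impermeable sphere.

    Murday-Cotts series over the roots mu_m of j1'(x)=0, with
    a_m = mu_m / R:

        ln S = -2 g^2 G^2 * sum_m
               [2 a^2 D d - 2 + 2 e^{-a^2 D d} + 2 e^{-a^2 D D_} -
                e^{-a^2 D (D_-d)} - e^{-a^2 D (D_+d)}]
               / (D^2 a^6 (mu^2 - 2))

    with d = delta (pulse duration), D_ = Delta (separation), D = d_soma.
    Truncated at 20 roots; the magnitude of the last retained term is
    checked against a 1e-8 tail tolerance.

    S -> 1 as r_soma -> 0 (fully restricted point) and at b = 0.
    """
    b = np.asarray(b, float)
    if np.any(b < 0):
        raise ValueError("negative b-value")
    if r_soma < 0:
        raise ValueError("negative radius")
    if d_soma <= 0:
        raise ValueError("d_soma must be positive")
    if r_soma < 1e-6:
        out = np.ones_like(b)
        return out if out.ndim else float(out)

    mu = sphere_bessel_roots()  # (m,)
    a2D = (mu / r_soma) ** 2 * d_soma  # a_m^2 * D, 1/ms
    d, D_ = delta_small, delta_big
    num = (
        2.0 * a2D * d
        - 2.0
        + 2.0 * np.exp(-a2D * d)
        + 2.0 * np.exp(-a2D * D_)
        - np.exp(-a2D * (D_ - d))
        - np.exp(-a2D * (D_ + d))
    )
    a6 = (mu / r_soma) ** 6
    terms = num / (d_soma**2 * a6 * (mu**2 - 2.0))  # um^2 ms^2 per term
    total = terms.sum()
    if total > 0 and abs(terms[-1]) / total > _TAIL_TOL:
        raise RuntimeError(
            "GPD series not converged within 20 roots: last-term ratio "
            f"{abs(terms[-1]) / total:.2e} > {_TAIL_TOL:.0e} "
            f"(r_soma={r_soma}, d_soma={d_soma}, delta={d}, Delta={D_})"
        )
    G = gradient_strength(b, d, D_)
    lnS = -2.0 * GAMMA_MS**2 * G**2 * total
    out = np.exp(lnS)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# full model and plumbing
# ---------------------------------------------------------------------------


@dataclass
class SignalVector:
    """Per-shell spherical-mean signal aligned with a protocol's shells."""

    values: np.ndarray
    protocol: AcquisitionProtocol = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape[-1] != self.protocol.n_shells:
            raise ValueError(
                f"{self.values.shape[-1]} shell values for a "
                f"{self.protocol.n_shells}-shell protocol"
            )


def sandi_signal(
    protocol: AcquisitionProtocol, params: SandiParams
) -> np.ndarray:
    """Per-shell spherical-mean SANDI signal (normalized to b=0).

    Exactly linear in (f_neurite, f_soma, f_extracellular):
    S = f_n * stick + f_s * sphere + f_e * ball.
    """
    b = protocol.b_values
    stick = stick_sphmean_signal(b, params.d_in)
    sphere = sphere_gpd_signal(
        b, protocol.delta_small, protocol.delta_big, params.r_soma, params.d_soma
    )
    ball = ball_signal(b, params.d_e)
    return (
        params.f_neurite * stick
        + params.f_soma * sphere
        + params.f_extracellular * ball
    )


def spherical_mean(signals, shell_assignment, n_shells: int | None = None):
    """Arithmetic mean of per-direction signals within each shell.

    Parameters
    ----------
    signals
        Per-volume signal values, last axis = acquired volumes.
    shell_assignment
        Shell index per volume (e.g. ``protocol.shell_assignment``).
    n_shells
        Number of shells; defaults to ``max(shell_assignment)+1``.
    """
    signals = np.asarray(signals, float)
    assign = np.asarray(shell_assignment, int)
    if signals.shape[-1] != assign.size:
        raise ValueError(
            f"{signals.shape[-1]} signal values but {assign.size} shell labels"
        )
    k = int(assign.max()) + 1 if n_shells is None else n_shells
    out = np.empty(signals.shape[:-1] + (k,))
    for j in range(k):
        mask = assign == j
        if not mask.any():
            raise ValueError(f"shell {j} has no directions")
        out[..., j] = signals[..., mask].mean(axis=-1)
    return out
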