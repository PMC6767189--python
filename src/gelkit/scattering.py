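"""Powder WAXS profiles from atomic coordinates via the Debye equation.

The orientationally averaged (isotropic) Debye kernel is used:

    I(q) = sum_k f_k(q)^2 + sum_{k != j} f_k(q) f_j(q) sinc(q r_kj)

with q = 4 pi sin(theta) / lambda. The scattering variable
s = 2 sin(theta) / lambda (in 1/Angstrom) is reported alongside 2-theta.
Atomic form factors use the four-Gaussian-plus-constant Cromer-Mann
parameterization, f(s) = sum_i a_i exp(-b_i (s/2)^2) + c, so that f(0) = Z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gelkit.structure_io import Frame

#: Cromer-Mann coefficients (a1..a4, b1..b4, c), International Tables Vol. C.
CROMER_MANN: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": (
        (0.489918, 0.262003, 0.196767, 0.049879),
        (20.6593, 7.74039, 49.5519, 2.20159),
        0.001305,
    ),
    "C": (
        (2.31000, 1.02000, 1.58860, 0.865000),
        (20.8439, 10.2075, 0.568700, 51.6512),
        0.215600,
    ),
    "N": (
        (12.2126, 3.13220, 2.01250, 1.16630),
        (0.005700, 9.89330, 28.9975, 0.582600),
        -11.5290,
    ),
    "O": (
        (3.04850, 2.28680, 1.54630, 0.867000),
        (13.2771, 5.70110, 0.323900, 32.9089),
        0.250800,
    ),
    "S": (
        (6.90530, 5.20340, 1.43790, 1.58630),
        (1.46790, 22.2151, 0.253600, 56.1720),
        0.866900,
    ),
}


@dataclass(frozen=True)
class ScatteringProfile:
    """Intensity vs scattering angle at fixed X-ray wavelength.

    ``two_theta`` in degrees (strictly increasing), ``s = 2 sin(theta)/lambda``
    in 1/Angstrom, ``intensity`` in arbitrary units, ``wavelength`` in
    Angstrom.
    """

    two_theta: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    wavelength: float

    def __post_init__(self) -> None:
        if not (len(self.two_theta) == len(self.s) == len(self.intensity)):
            raise ValueError("profile grids must have equal length")
        if np.any(np.diff(self.two_theta) <= 0):
            raise ValueError("two_theta grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")


def form_factor(element: str, s) -> np.ndarray:
    """X-ray atomic form factor at scattering variable ``s = 2 sin(theta)/lambda``.

    Satisfies f(0) = Z (electron count) to within table round-off and
    decreases monotonically over the WAXS range.
    """
    if element not in CROMER_MANN:
        raise ValueError(f"no form-factor coefficients for element {element!r}")
    a, b, c = CROMER_MANN[element]
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("scattering variable s must be non-negative")
    # Cromer-Mann argument is (sin(theta)/lambda)^2 = (s/2)^2
    x = (s / 2.0) ** 2
    f = np.full_like(s, c, dtype=float)
    for ai, bi in zip(a, b):
        f += ai * np.exp(-bi * x)
    return f


def two_theta_to_s(two_theta_deg, wavelength: float) -> np.ndarray:
    """Scattering variable s = 2 sin(theta)/lambda in 1/Angstrom."""
    theta = np.deg2rad(np.asarray(two_theta_deg, dtype=float)) / 2.0
    return 2.0 * np.sin(theta) / wavelength


def debye_intensity(
    frame: Frame,
    two_theta_grid,
    wavelength: float = 1.54178,
    pair_chunk: int = 20_000,
) -> ScatteringProfile:
    """Powder Debye intensity of a frame on a 2-theta grid (degrees).

    Pair terms are weighted by sinc(q r); self terms contribute f^2. For a
    periodic box, minimum-image distances are used with a hard cutoff at
    half the shortest box edge; note the sharp truncation can introduce
    small negative termination ripples (non-periodic frames are exactly
    the powder average of |F|^2 and therefore non-negative).
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    two_theta = np.asarray(two_theta_grid, dtype=float)
    if np.any(two_theta <= 0) or np.any(two_theta >= 180):
        raise ValueError("two_theta grid must lie within (0, 180) degrees")
    if frame.n_atoms < 1:
        raise ValueError("frame must contain at least one atom")

    s = two_theta_to_s(two_theta, wavelength)
    q = 2.0 * np.pi * s  # q = 4 pi sin(theta) / lambda

    elements = np.array(frame.elements)
    unique = sorted(set(elements))
    f = {el: form_factor(el, s) for el in unique}

    # self terms
    intensity = np.zeros_like(s)
    for el in unique:
        intensity += np.count_nonzero(elements == el) * f[el] ** 2

    pos = frame.positions
    periodic = frame.box is not None and frame.box.periodic
    if periodic:
        L = np.asarray(frame.box.lengths)
        cutoff = 0.5 * L.min()

    # cross terms grouped by element pair, chunked over pairs
    n = frame.n_atoms
    if n > 1:
        iu, ju = np.triu_indices(n, k=1)
        for start in range(0, len(iu), pair_chunk):
            ii = iu[start : start + pair_chunk]
            jj = ju[start : start + pair_chunk]
            diff = pos[ii] - pos[jj]
            if periodic:
                diff -= L * np.round(diff / L)
            r = np.linalg.norm(diff, axis=1)
            if periodic:
                keep = r < cutoff
                ii, jj, r = ii[keep], jj[keep], r[keep]
            if len(r) == 0:
                continue
            fk = np.stack([f[el] for el in elements[ii]])
            fj = np.stack([f[el] for el in elements[jj]])
            # np.sinc(x) = sin(pi x)/(pi x); want sin(qr)/(qr)
            kernel = np.sinc(np.outer(r, q) / np.pi)
            intensity += 2.0 * np.sum(fk * fj * kernel, axis=0)

    return ScatteringProfile(
        two_theta=two_theta, s=s, intensity=intensity, wavelength=wavelength
    )


def main_peak(
    profile: ScatteringProfile,
    window: tuple[float, float] = (5.0, 50.0),
    smooth_width: int = 0,
) -> float:
    """Angle (2-theta, degrees) of the global intensity maximum in ``window``.

    ``smooth_width`` > 1 applies a moving-average of that many grid points
    before locating the maximum (default: no smoothing).
    """
    lo, hi = window
    mask = (profile.two_theta >= lo) & (profile.two_theta <= hi)
    if not np.any(mask):
        raise ValueError("window contains no grid points of the profile")
    y = profile.intensity.copy()
    if smooth_width and smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        y = np.convolve(y, kernel, mode="same")
    sub = np.where(mask)[0]
    return float(profile.two_theta[sub[np.argmax(y[sub])]])
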