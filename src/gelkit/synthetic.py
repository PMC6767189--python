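"""Seeded generators for every input class the pipeline consumes.

Each generator threads a single integer seed through one local
``numpy.random.Generator``; identical parameters and seed give bit-identical
output, and no global RNG state is touched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gelkit.sequence import AminoAcidSequence
from gelkit.structure_io import (
    AVOGADRO,
    Atom,
    Box,
    Frame,
    ThermoSeries,
    DEFAULT_THERMO_UNITS,
)

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_lattice(
    kind: str = "sc", a: float = 4.0, n_cells: int = 5, element: str = "C"
) -> Frame:
    """Simple-cubic or face-centred-cubic lattice in a periodic box of edge n*a."""
    if a <= 0:
        raise ValueError("lattice constant must be positive")
    if n_cells < 2:
        raise ValueError("need at least 2 cells per edge")
    if kind == "sc":
        basis = np.array([[0.0, 0.0, 0.0]])
    elif kind == "fcc":
        basis = np.array(
            [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
        )
    else:
        raise ValueError(f"unknown lattice type {kind!r}")
    cells = np.array(
        [[i, j, k] for i in range(n_cells) for j in range(n_cells) for k in range(n_cells)],
        dtype=float,
    )
    frac = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3)
    pos = frac * a
    atoms = [Atom(element, tuple(p)) for p in pos]
    box = Box((n_cells * a,) * 3, periodic=True)
    return Frame(atoms=atoms, box=box, label=f"{kind} lattice a={a}")


def make_random_box(
    n_atoms: int,
    box_length: float,
    elements: tuple[str, ...] = ("C",),
    min_dist: float = 1.0,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> Frame:
    """Rejection-sampled random coordinates with a minimum-image distance floor."""
    rng = np.random.default_rng(seed)
    L = float(box_length)
    positions: list[np.ndarray] = []
    attempts = 0
    while len(positions) < n_atoms:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"packing failed after {max_attempts} attempts "
                f"(n={n_atoms}, box={L}, min_dist={min_dist})"
            )
        candidate = rng.uniform(0.0, L, size=3)
        ok = True
        for p in positions:
            d = candidate - p
            d -= L * np.round(d / L)
            if np.linalg.norm(d) < min_dist:
                ok = False
                break
        if ok:
            positions.append(candidate)
        attempts += 1
    atoms = [
        Atom(elements[i % len(elements)], tuple(p)) for i, p in enumerate(positions)
    ]
    return Frame(atoms=atoms, box=Box((L, L, L), periodic=True), label=f"random seed={seed}")


def make_thermo_series(
    rho0: float = 1.55,
    alpha_p: float = 6.072e-4,
    t_range: tuple[float, float] = (273.0, 318.0),
    n_points: int = 46,
    sigma: float = 0.0,
    seed: int = 0,
    total_mass: float | None = None,
    delta0: float | None = None,
    delta_slope: float = 0.0,
    delta_sigma: float = 0.0,
) -> ThermoSeries:
    """Noisy exponential density series rho(T) = rho0 exp(-alpha_p T)(1 + eps).

    Temperatures are evenly spaced over ``t_range`` (the default grid,
    273..318 K with ~1 K increment, gives 46 points). When ``total_mass``
    (g/mol) is given, a consistent volume column is emitted; when ``delta0``
    (MPa^0.5) is given, a nonbonded-energy column is emitted such that the
    noiseless Hansen parameter follows delta0 + delta_slope * T.
    """
    if n_points < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    T = np.linspace(t_range[0], t_range[1], n_points)
    rho = rho0 * np.exp(-alpha_p * T)
    if sigma > 0:
        rho = rho * (1.0 + rng.normal(0.0, sigma, size=n_points))
    data = pd.DataFrame({"temperature": T, "density": rho})
    units = dict(DEFAULT_THERMO_UNITS)
    if total_mass is not None:
        data["volume"] = total_mass / (AVOGADRO * rho * 1e-24)
    if delta0 is not None:
        if "volume" not in data:
            raise ValueError("delta generation requires total_mass for volumes")
        delta = delta0 + delta_slope * T
        if delta_sigma > 0:
            delta = delta + rng.normal(0.0, delta_sigma, size=n_points)
        ced_mpa = delta**2  # MPa
        vol = data["volume"].to_numpy()
        # invert CED = E * 4184 / N_A / (V * 1e-30) / 1e6  (kcal/mol, A^3)
        data["nonbonded_energy"] = ced_mpa * 1e6 * vol * 1e-30 * AVOGADRO / 4184.0
    return ThermoSeries(data=data, units=units)


def make_bilinear_series(
    tg: float = 424.7,
    slope_lo: float = 2.0e-4,
    slope_hi: float = 6.0e-4,
    t_range: tuple[float, float] = (100.0, 600.0),
    n_points: int = 26,
    value_at_tg: float = 0.77,
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous two-segment line with a knee at ``tg`` plus optional noise."""
    if not t_range[0] < tg < t_range[1]:
        raise ValueError("tg must lie inside t_range")
    rng = np.random.default_rng(seed)
    T = np.linspace(t_range[0], t_range[1], n_points)
    y = value_at_tg + np.where(T <= tg, slope_lo * (T - tg), slope_hi * (T - tg))
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=n_points)
    return T, y


def make_cleavage_sequences(
    n: int,
    length: int,
    kr_rate: float = 0.1,
    kp_rate: float = 0.2,
    seed: int = 0,
) -> list[tuple[AminoAcidSequence, list[int]]]:
    """Random sequences with ground-truth trypsin cut sites.

    Residues are drawn so K/R appear at ``kr_rate``; a residue following a
    K/R is proline with probability ``kp_rate`` (exercising the blocking
    rule). The annotated sites are derived from the generation draws, not
    from the digestion code under test.
    """
    if not (0 <= kr_rate <= 1 and 0 <= kp_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    others = [aa for aa in _STANDARD_AA if aa not in "KRP"]
    out = []
    for si in range(n):
        residues: list[str] = []
        for i in range(length):
            prev_kr = residues and residues[-1] in "KR"
            if prev_kr and rng.random() < kp_rate:
                residues.append("P")
            elif rng.random() < kr_rate:
                residues.append("K" if rng.random() < 0.5 else "R")
            else:
                residues.append(others[rng.integers(len(others))])
        seq = AminoAcidSequence("".join(residues), id=f"synthetic-{si}")
        # ground truth from the construction rule: previous residue K/R,
        # current residue (the one on the carboxyl side) not P, not terminal
        sites = [
            i
            for i in range(length - 1)
            if residues[i] in "KR" and residues[i + 1] != "P"
        ]
        out.append((seq, sites))
    return out
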