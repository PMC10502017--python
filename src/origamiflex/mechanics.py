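"""From angle ensembles to mechanics: distributions, free energy, torque.

A dynamic origami hinge behaves as a torsional spring: the ensemble of
observed hinge angles theta samples a Boltzmann distribution
p(theta) ∝ exp(-E(theta)/kBT), so the free-energy landscape follows from
the measured angular probability distribution by Boltzmann inversion,
E(theta) = -kBT ln p(theta) + const.  The torque at angle theta is the
negative gradient of the landscape, tau = -dE/dtheta.  Energies are in
units of kBT by default; angles in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "AngleDistribution",
    "FreeEnergyLandscape",
    "angles_to_distribution",
    "boltzmann_invert",
    "torque_from_energy",
    "ks_two_sample",
    "KT_TO_KCAL_PER_MOL",
]

#: kBT at 298 K expressed in kcal/mol, for optional unit conversion.
KT_TO_KCAL_PER_MOL = 0.5924


@dataclass(frozen=True)
class AngleDistribution:
    """Binned angular probability distribution over [0, 180] degrees."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probabilities", probs)
        if edges.ndim != 1 or probs.ndim != 1 or len(probs) != len(edges) - 1:
            raise ValueError("need len(probabilities) == len(bin_edges) - 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {probs.sum()}")

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class FreeEnergyLandscape:
    """Boltzmann-inverted landscape; NaN marks bins with no observations.

    ``energy`` is shifted so its minimum over defined bins is exactly 0;
    the subtracted constant is kept in ``reference_offset`` so the input
    probabilities can be recovered (up to normalization).
    """

    bin_centers: np.ndarray
    energy: np.ndarray
    reference_offset: float
    kT: float = 1.0

    def __post_init__(self) -> None:
        centers = np.asarray(self.bin_centers, dtype=float)
        energy = np.asarray(self.energy, dtype=float)
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "energy", energy)
        if centers.shape != energy.shape:
            raise ValueError("bin_centers and energy must have the same shape")
        defined = np.isfinite(energy)
        if not defined.any():
            raise ValueError("landscape has no defined bins")
        if abs(float(np.nanmin(energy)) - 0.0) > 1e-9:
            raise ValueError("energy must be shifted so its minimum is 0")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.energy)


def angles_to_distribution(angles, bin_width: float = 5.0) -> AngleDistribution:
    """Histogram angles into an :class:`AngleDistribution`.

    Bins are right-open [e_i, e_{i+1}) except the last, which is closed at
    180 so that an exact 180-degree measurement is counted.  ``bin_width``
    must divide 180.

    Raises ValueError on an empty sample (the distribution is undefined)
    or on any angle outside [0, 180].
    """
    arr = np.asarray(angles, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot build a distribution from an empty angle list")
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 180):
        raise ValueError("all angles must be finite and in [0, 180] degrees")
    n_bins = 180.0 / bin_width
    if not (bin_width > 0) or abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin_width must divide 180, got {bin_width}")
    edges = np.linspace(0.0, 180.0, int(round(n_bins)) + 1)
    counts, _ = np.histogram(arr, bins=edges)  # last bin closed at 180
    return AngleDistribution(
        bin_edges=edges,
        probabilities=counts / arr.size,
        n_samples=int(arr.size),
    )


def boltzmann_invert(
    dist: AngleDistribution, kT: float = 1.0, pseudocount: float | None = None
) -> FreeEnergyLandscape:
    """Invert a probability distribution into a free-energy landscape.

    E_i = -kT ln(p_i) for bins with p_i > 0, then shifted so the minimum
    defined energy is 0 (the shift is recorded in ``reference_offset``).
    Empty bins are left undefined (NaN) rather than imputed; pass
    ``pseudocount`` to add that many counts to every bin first (e.g. 0.5)
    when a fully defined landscape is required.
    """
    probs = dist.probabilities.copy()
    if pseudocount is not None:
        counts = probs * dist.n_samples + pseudocount
        probs = counts / counts.sum()
    if not np.any(probs > 0):
        raise ValueError("cannot invert an all-zero distribution")
    with np.errstate(divide="ignore"):
        energy = np.where(probs > 0, -kT * np.log(np.where(probs > 0, probs, 1.0)), np.nan)
    offset = float(np.nanmin(energy))
    energy = energy - offset
    return FreeEnergyLandscape(
        bin_centers=dist.bin_centers,
        energy=energy,
        reference_offset=offset,
        kT=kT,
    )


def torque_from_energy(landscape: FreeEnergyLandscape) -> np.ndarray:
    """Torque tau = -dE/dtheta in kT/degree, per bin center.

    Finite differences are taken over each contiguous run of defined bins:
    central differences in the interior, one-sided at run boundaries.
    Bins where the energy is undefined stay NaN.  Raises ValueError when
    no run has at least two defined bins.
    """
    energy = landscape.energy
    centers = landscape.bin_centers
    torque = np.full_like(energy, np.nan)
    defined = np.isfinite(energy)
    any_run = False
    i = 0
    n = len(energy)
    while i < n:
        if not defined[i]:
            i += 1
            continue
        j = i
        while j < n and defined[j]:
            j += 1
        if j - i >= 2:
            torque[i:j] = -np.gradient(energy[i:j], centers[i:j])
            any_run = True
        i = j
    if not any_run:
        raise ValueError("need at least 2 contiguous defined bins for torque")
    return torque


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact supremum distance between the two empirical CDFs,
    evaluated by direct ECDF comparison at every observed value.  The
    p-value uses the standard asymptotic Kolmogorov distribution with
    effective sample size n_e = n_a*n_b/(n_a+n_b) — adequate for the
    sample sizes of interest here (hundreds and up).

    The null hypothesis is that both samples come from the same
    continuous distribution.
    """
    xa = np.sort(np.asarray(a, dtype=float))
    xb = np.sort(np.asarray(b, dtype=float))
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both samples must be non-empty")
    values = np.concatenate([xa, xb])
    cdf_a = np.searchsorted(xa, values, side="right") / xa.size
    cdf_b = np.searchsorted(xb, values, side="right") / xb.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    ne = xa.size * xb.size / (xa.size + xb.size)
    p = float(special.kolmogorov(math.sqrt(ne) * d))
    return d, min(1.0, p)
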