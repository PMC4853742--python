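"""Monte Carlo transverse-current distributions for single residues.

Each Monte Carlo draw poses the residue with backbone dihedrals (phi, psi)
sampled from a Ramachandran density, a uniform azimuthal rotation about the
channel axis and zero tilt, then measures the free area of the y=0
cross-section outside the hard-sphere surface inflated by each ion species'
effective radius.  The transverse current of one draw is the sum over
species of q * g_bulk * v_bulk * A_species.  Currents are histogrammed and
smoothed with a cubic spline to give an evaluable probability density, the
per-residue signature used for classification.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .constants import (
    DEFAULT_G_BULK_MOLAR,
    ION_SPECIES,
    RESIDUE_LENGTH_A,
    current_nA,
)
from .hydro import VelocityProfile
from ._kernels import HAVE_NUMBA, mc_free_areas
from .structures import AminoAcidStructure, Conformation, apply_conformation, plane_exclusion_area

__all__ = [
    "CurrentDistribution",
    "DegenerateDistributionError",
    "RamachandranDensity",
    "build_distribution",
    "extended_ramachandran_density",
    "sample_current_values",
    "sample_currents",
]


class DegenerateDistributionError(ValueError):
    """All current samples are identical; no density can be built."""


# ---------------------------------------------------------------------------
# Ramachandran density


@dataclass(frozen=True)
class RamachandranDensity:
    """Discretised probability density over backbone dihedrals (phi, psi).

    ``weights[i, j]`` is the probability mass of the bin centred at
    (phi_centers[i], psi_centers[j]); bins tile [-180, 180] in both angles.
    ``pulling_force_pN`` labels the longitudinal force the density was
    conditioned on (a strong pull confines mass to the extended region).
    """

    phi_centers: np.ndarray
    psi_centers: np.ndarray
    weights: np.ndarray
    pulling_force_pN: float = 250.0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape != (len(self.phi_centers), len(self.psi_centers)):
            raise ValueError("weights must be (n_phi, n_psi)")
        if np.any(w < 0) or not np.isfinite(w).all():
            raise ValueError("weights must be finite and non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("Ramachandran density has no mass")
        object.__setattr__(self, "weights", w / total)
        object.__setattr__(self, "phi_centers", np.asarray(self.phi_centers, float))
        object.__setattr__(self, "psi_centers", np.asarray(self.psi_centers, float))

    @property
    def bin_width_deg(self) -> float:
        return 360.0 / len(self.phi_centers)

    def sample(self, n: int, rng: np.random.Generator):
        """Draw (phi, psi) pairs: a weighted bin, jittered uniformly within it."""
        flat = self.weights.ravel()
        idx = rng.choice(flat.size, size=n, p=flat)
        i, j = np.unravel_index(idx, self.weights.shape)
        half = self.bin_width_deg / 2.0
        phi = self.phi_centers[i] + rng.uniform(-half, half, size=n)
        psi = self.psi_centers[j] + rng.uniform(-half, half, size=n)
        return phi, psi

    def to_csv(self, path_or_buf) -> None:
        header = (
            f"# pulling_force_pN={self.pulling_force_pN:g} "
            f"bin_deg={self.bin_width_deg:g}\nphi_deg,psi_deg,weight\n"
        )
        lines = [
            f"{p:.1f},{q:.1f},{self.weights[i, j]:.8e}"
            for i, p in enumerate(self.phi_centers)
            for j, q in enumerate(self.psi_centers)
            if self.weights[i, j] > 0
        ]
        text = header + "\n".join(lines) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf) -> "RamachandranDensity":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        meta = dict(re.findall(r"([\w.]+)=([^\s]+)", text.splitlines()[0]))
        bin_deg = float(meta.get("bin_deg", 10.0))
        centers = -180.0 + bin_deg / 2.0 + bin_deg * np.arange(int(round(360 / bin_deg)))
        rows = np.loadtxt(io.StringIO(text), delimiter=",", comments="#",
                          skiprows=2, ndmin=2)
        w = np.zeros((len(centers), len(centers)))
        i = np.searchsorted(centers - bin_deg / 2.0, rows[:, 0]) - 1
        j = np.searchsorted(centers - bin_deg / 2.0, rows[:, 1]) - 1
        w[i, j] = rows[:, 2]
        return cls(centers, centers, w, float(meta.get("pulling_force_pN", 250.0)))


def extended_ramachandran_density(
    pulling_force_pN: float = 250.0, bin_deg: float = 10.0
) -> RamachandranDensity:
    """Dihedral density of a chain straightened by a strong longitudinal pull.

    A two-component Gaussian mixture concentrated in the extended (beta /
    polyproline-II) basin, evaluated on the bin grid and truncated to it.
    The dominant component sits near fully extended dihedrals; the minor one
    admits the slight compression that survives the pull.
    """
    n = int(round(360.0 / bin_deg))
    centers = -180.0 + bin_deg / 2.0 + bin_deg * np.arange(n)
    phi, psi = np.meshgrid(centers, centers, indexing="ij")
    comps = (
        (0.72, -151.0, 153.0, 14.0),
        (0.28, -119.0, 133.0, 11.0),
    )
    w = np.zeros_like(phi)
    for amp, mu_phi, mu_psi, sd in comps:
        w += amp * np.exp(
            -0.5 * (((phi - mu_phi) / sd) ** 2 + ((psi - mu_psi) / sd) ** 2)
        )
    return RamachandranDensity(centers, centers, w, pulling_force_pN)


# ---------------------------------------------------------------------------
# current distribution container


class CurrentDistribution:
    """Histogram + cubic-spline probability density of transverse current (nA).

    The spline interpolates the density-normalised histogram at bin centres,
    is clipped at zero, set to zero outside the sampled support, and
    renormalised so it integrates to one.
    """

    _PDF_GRID = 4001

    def __init__(self, residue_code, bin_edges, masses, n_samples, seed,
                 samples=None):
        bin_edges = np.asarray(bin_edges, dtype=float)
        masses = np.asarray(masses, dtype=float)
        if len(bin_edges) != len(masses) + 1 or len(masses) < 2:
            raise ValueError("need len(bin_edges) == len(masses) + 1 >= 3")
        if np.any(masses < 0) or not np.isclose(masses.sum(), 1.0, atol=1e-9):
            raise ValueError("histogram masses must be non-negative and sum to 1")
        self.residue_code = residue_code
        self.bin_edges = bin_edges
        self.masses = masses
        self.n_samples = int(n_samples)
        self.seed = seed
        self.samples = None if samples is None else np.asarray(samples, float)
        self.support = (float(bin_edges[0]), float(bin_edges[-1]))

        centers = (bin_edges[:-1] + bin_edges[1:]) / 2.0
        density = masses / np.diff(bin_edges)
        self._spline = CubicSpline(centers, density, extrapolate=True)
        grid = np.linspace(self.support[0], self.support[1], self._PDF_GRID)
        vals = np.clip(self._spline(grid), 0.0, None)
        norm = np.trapezoid(vals, grid)
        if norm <= 0:
            raise ValueError("spline density has no mass")
        self._norm = float(norm)
        # grid CDF for inverse-transform sampling
        cdf = np.concatenate([[0.0], np.cumsum((vals[1:] + vals[:-1]) / 2.0
                                               * np.diff(grid))])
        self._grid = grid
        self._cdf = cdf / cdf[-1]

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        inside = (x >= self.support[0]) & (x <= self.support[1])
        vals = np.where(inside, np.clip(self._spline(x), 0.0, None) / self._norm, 0.0)
        return vals

    def logpdf(self, x) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.pdf(x))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(n)
        return np.interp(u, self._cdf, self._grid)

    def mean(self) -> float:
        vals = np.clip(self._spline(self._grid), 0.0, None) / self._norm
        return float(np.trapezoid(self._grid * vals, self._grid))

    # -- JSON round trip ---------------------------------------------------

    def to_json(self, path_or_buf=None):
        payload = {
            "residue": self.residue_code,
            "seed": self.seed,
            "n": self.n_samples,
            "bin_edges": self.bin_edges.tolist(),
            "masses": self.masses.tolist(),
        }
        if path_or_buf is None:
            return json.dumps(payload)
        if hasattr(path_or_buf, "write"):
            json.dump(payload, path_or_buf)
        else:
            with open(path_or_buf, "w") as fh:
                json.dump(payload, fh)

    @classmethod
    def from_json(cls, path_or_buf) -> "CurrentDistribution":
        if isinstance(path_or_buf, str) and path_or_buf.lstrip().startswith("{"):
            payload = json.loads(path_or_buf)
        elif hasattr(path_or_buf, "read"):
            payload = json.load(path_or_buf)
        else:
            with open(path_or_buf) as fh:
                payload = json.load(fh)
        return cls(payload["residue"], payload["bin_edges"], payload["masses"],
                   payload["n"], payload["seed"])


def build_distribution(samples, n_bins: int = 100, residue_code: str = "SYN",
                       seed=None) -> CurrentDistribution:
    """Histogram current samples and fit the spline density.

    Raises :class:`DegenerateDistributionError` when all samples coincide
    (a point mass has no representable density).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least two samples")
    lo, hi = float(samples.min()), float(samples.max())
    if hi - lo <= 1e-12 * max(1.0, abs(hi)):
        raise DegenerateDistributionError(
            f"all {samples.size} samples equal {lo:g} nA"
        )
    counts, edges = np.histogram(samples, bins=int(n_bins), range=(lo, hi))
    return CurrentDistribution(residue_code, edges, counts / counts.sum(),
                               samples.size, seed, samples=samples)


# ---------------------------------------------------------------------------
# Monte Carlo sampling


def sample_current_values(
    s: AminoAcidStructure,
    reff: dict,
    rd: RamachandranDensity,
    vp: VelocityProfile,
    n: int,
    seed: int,
    g_bulk: float = DEFAULT_G_BULK_MOLAR,
    disk_radius: float | None = None,
    z_margin: float | None = RESIDUE_LENGTH_A / 2.0,
    grid_step: float = 0.1,
) -> np.ndarray:
    """Raw Monte Carlo draws of the total transverse ionic current (nA).

    ``reff`` maps each ion species to its effective radius (A).  Both
    species share every conformation draw — one physical configuration
    produces one total current.  ``disk_radius`` defaults to R/2; the
    cross-section is clipped along z by ``z_margin`` beyond the terminal
    backbone extent (None disables the clip).  Deterministic for fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    missing = [sp for sp in ION_SPECIES if sp not in reff]
    if missing:
        raise ValueError(f"reff missing species {missing}")
    rng = np.random.default_rng(seed)
    if disk_radius is None:
        disk_radius = vp.R / 2.0
    phi, psi = rd.sample(n, rng)
    azimuth = rng.uniform(0.0, 360.0, size=n)
    if HAVE_NUMBA and s.n_atoms > 0:
        return _batch_currents(s, reff, vp, phi, psi, azimuth, g_bulk,
                               disk_radius, z_margin, grid_step)
    currents = np.empty(n)
    for k in range(n):
        posed = apply_conformation(s, Conformation(phi[k], psi[k], azimuth[k]))
        total = 0.0
        for sp in ION_SPECIES:
            area = plane_exclusion_area(posed, reff[sp], disk_radius,
                                        z_margin, grid_step)
            total += current_nA(g_bulk, vp.v_bulk, area)
        currents[k] = total
    return currents


def _wrap_degrees(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float) % 360.0
    return np.where(a > 180.0, a - 360.0, a)


def _batch_currents(s, reff, vp, phi, psi, azimuth, g_bulk, disk_radius,
                    z_margin, grid_step):
    """Compiled batch evaluation; poses and counts cells exactly like the
    apply_conformation + plane_exclusion_area route."""
    idx = {name: i for i, name in enumerate(s.atom_names)}
    i_n, i_ca, i_c = (idx.get(a, -1) for a in ("N", "CA", "C"))
    if i_ca < 0:
        i_n = i_c = -1  # no backbone: dihedrals are no-ops
    if z_margin is None:
        z_window = float(disk_radius)
    else:
        z_window = min(float(disk_radius),
                       float(s.terminal_z_extent) + float(z_margin))
    areas = mc_free_areas(
        np.ascontiguousarray(s.coords),
        np.ascontiguousarray(s.vdw_radii),
        np.asarray(s.phi_moving, dtype=np.int64),
        np.asarray(s.psi_moving, dtype=np.int64),
        i_n, i_ca, i_c,
        _wrap_degrees(_wrap_degrees(phi) - 180.0),
        _wrap_degrees(_wrap_degrees(psi) - 180.0),
        _wrap_degrees(azimuth),
        float(reff["K+"]), float(reff["Cl-"]),
        float(disk_radius), z_window, float(grid_step),
    )
    return current_nA(g_bulk, vp.v_bulk, areas[:, 0] + areas[:, 1])


def sample_currents(
    s: AminoAcidStructure,
    reff: dict,
    rd: RamachandranDensity,
    vp: VelocityProfile,
    n: int,
    seed: int,
    n_bins: int = 100,
    **kwargs,
) -> CurrentDistribution:
    """Monte Carlo current distribution for one residue (see
    :func:`sample_current_values` for the draw semantics)."""
    currents = sample_current_values(s, reff, rd, vp, n, seed, **kwargs)
    return build_distribution(currents, n_bins, s.residue_code, seed)
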