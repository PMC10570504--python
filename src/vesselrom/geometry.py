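"""Synthetic vessel geometries: reference shapes and sinusoidally perturbed phantoms.

Every geometry is a straight tube of slowly varying radius, meshed on a fixed
structured grid so that all geometries built at one resolution share node
count and ordering (a requirement of the common-base POD downstream).  The
phantom dataset perturbs each reference radius profile with a composite of two
sinusoids whose amplitude, frequency, phase and vertical offset are drawn at
random within bounds that keep the deviation small but significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceVessel",
    "PerturbationParams",
    "PerturbationBounds",
    "MeshResolution",
    "VesselGeometry",
    "default_reference_vessels",
    "perturb_radius",
    "build_mesh",
    "generate_dataset",
    "draw_perturbation",
    "perturbation_log",
]

# Default mesh resolution: 101 axial stations, 32 circumferential points,
# 4 interior radial rings -> Ns = 3232 surface nodes, Nv = 13029 volume nodes.
DEFAULT_RESOLUTION = (101, 32, 4)


@dataclass(frozen=True)
class MeshResolution:
    """Structured-tube grid resolution.

    Attributes
    ----------
    n_axial : int
        Number of axial stations (>= 3).
    n_circ : int
        Circumferential points per ring.
    n_radial : int
        Interior radial rings per station (volume nodes, wall excluded).
    """

    n_axial: int = DEFAULT_RESOLUTION[0]
    n_circ: int = DEFAULT_RESOLUTION[1]
    n_radial: int = DEFAULT_RESOLUTION[2]

    def __post_init__(self) -> None:
        if self.n_axial < 3:
            raise ValueError("need at least 3 axial stations")
        if self.n_circ < 3 or self.n_radial < 1:
            raise ValueError("n_circ >= 3 and n_radial >= 1 required")

    @property
    def n_surface(self) -> int:
        """Surface node count Ns = n_axial * n_circ."""
        return self.n_axial * self.n_circ

    @property
    def n_volume(self) -> int:
        """Volume node count Nv = n_axial * (n_radial * n_circ + 1)."""
        return self.n_axial * (self.n_radial * self.n_circ + 1)


@dataclass(frozen=True)
class ReferenceVessel:
    """A reference vessel: axial stations and baseline radius profile (mm)."""

    id: str
    length: float                 # mm
    stations: np.ndarray          # (n_axial,) mm, uniform, s[0]=0, s[-1]=length
    radius: np.ndarray            # (n_axial,) mm, > 0

    def __post_init__(self) -> None:
        s = np.asarray(self.stations, dtype=float)
        r = np.asarray(self.radius, dtype=float)
        if s.ndim != 1 or s.size < 3 or r.shape != s.shape:
            raise ValueError("stations/radius must be matching 1-D arrays, n >= 3")
        if not (s[0] == 0.0 and np.isclose(s[-1], self.length)):
            raise ValueError("stations must run from 0 to the vessel length")
        ds = np.diff(s)
        if not (np.all(ds > 0) and np.allclose(ds, ds[0])):
            raise ValueError("stations must be uniform and strictly increasing")
        if np.any(r <= 0):
            raise ValueError("baseline radius must be strictly positive")
        object.__setattr__(self, "stations", s)
        object.__setattr__(self, "radius", r)


@dataclass(frozen=True)
class PerturbationBounds:
    """Admissible ranges for the two-sinusoid perturbation parameters.

    Defaults keep the worst-case radius deviation at 2*(a_max + d_max) = 22%,
    i.e. the perturbation bracket stays above 0.5 and the radius positive.
    """

    a_max: float = 0.08       # amplitude bound (fraction of baseline radius)
    d_max: float = 0.03       # vertical-offset bound (fraction)
    f_min: float = 0.5        # cycles per vessel length
    f_max: float = 2.5

    def __post_init__(self) -> None:
        if min(self.a_max, self.d_max) < 0 or not 0 < self.f_min <= self.f_max:
            raise ValueError("invalid perturbation bounds")
        if 2.0 * (self.a_max + self.d_max) >= 0.5:
            raise ValueError("bounds allow the perturbation bracket to fall below 0.5")


@dataclass(frozen=True)
class PerturbationParams:
    """Parameters of one two-sinusoid radius perturbation.

    r(s) = r0(s) * (1 + sum_j [a_j sin(2 pi f_j s / L + phi_j) + d_j]),  j = 1, 2
    """

    a: tuple[float, float]        # amplitudes (fraction)
    f: tuple[float, float]        # frequencies (cycles per vessel length)
    phi: tuple[float, float]      # phases (rad)
    d: tuple[float, float]        # vertical offsets (fraction)
    seed: int | None = None

    def validate(self, bounds: PerturbationBounds) -> None:
        for j in range(2):
            if abs(self.a[j]) > bounds.a_max + 1e-12:
                raise ValueError(f"amplitude a{j + 1} outside |a| <= {bounds.a_max}")
            if abs(self.d[j]) > bounds.d_max + 1e-12:
                raise ValueError(f"offset d{j + 1} outside |d| <= {bounds.d_max}")
            if not bounds.f_min - 1e-12 <= self.f[j] <= bounds.f_max + 1e-12:
                raise ValueError(
                    f"frequency f{j + 1} outside [{bounds.f_min}, {bounds.f_max}]"
                )


@dataclass(frozen=True)
class VesselGeometry:
    """One meshed vessel: radius profile plus fixed-topology node coordinates.

    Node coordinates are built lazily from the radius profile; they are only
    needed by the shape-embedding stage and by mesh export, not by the solver.
    Ordering (frozen): station-major; surface = angle 0..n_circ-1 per station;
    volume = axis node first, then rings from innermost outward, each ring
    angle-ordered.  Axis of the vessel is x; coordinates in mm, right-handed.
    """

    id: str
    parent_id: str
    stations: np.ndarray          # (n_axial,) mm
    radius: np.ndarray            # (n_axial,) mm
    resolution: MeshResolution
    params: PerturbationParams | None = None

    @property
    def n_surface(self) -> int:
        return self.resolution.n_surface

    @property
    def n_volume(self) -> int:
        return self.resolution.n_volume

    @cached_property
    def surface_nodes(self) -> np.ndarray:
        """(Ns, 3) coordinates of wall nodes, mm."""
        return _surface_coords(self.stations, self.radius, self.resolution)

    @cached_property
    def volume_nodes(self) -> np.ndarray:
        """(Nv, 3) coordinates of interior nodes, mm."""
        return _volume_coords(self.stations, self.radius, self.resolution)

    @cached_property
    def surface_station_index(self) -> np.ndarray:
        """(Ns,) axial-station index of each surface node."""
        res = self.resolution
        return np.repeat(np.arange(res.n_axial), res.n_circ)

    @cached_property
    def volume_station_index(self) -> np.ndarray:
        """(Nv,) axial-station index of each volume node."""
        res = self.resolution
        return np.repeat(np.arange(res.n_axial), res.n_radial * res.n_circ + 1)

    def shape_vector(self) -> np.ndarray:
        """Centroid-centred, flattened node coordinates (length 3*(Ns+Nv))."""
        pts = np.vstack([self.surface_nodes, self.volume_nodes])
        return (pts - pts.mean(axis=0)).ravel()


# ---------------------------------------------------------------------------
# reference vessels

# Per-reference low-frequency cosine modulation (amplitude fraction, cycles
# per length, phase) making the seven parents geometrically distinct.
_REFERENCE_SHAPES = (
    ("ref1", 0.00, 0.0, 0.0),
    ("ref2", 0.06, 0.5, 0.0),
    ("ref3", 0.10, 1.0, 0.0),
    ("ref4", 0.14, 1.5, np.pi / 3),
    ("ref5", 0.18, 0.75, np.pi / 2),
    ("ref6", 0.12, 2.0, np.pi),
    ("ref7", 0.16, 1.25, 3 * np.pi / 2),
)


def default_reference_vessels(
    n_axial: int = DEFAULT_RESOLUTION[0],
    length: float = 30.0,
    base_radius: float = 1.5,
) -> list[ReferenceVessel]:
    """Seven synthetic reference vessels (straight tubes, L=30 mm, r=1.5 mm).

    Each parent's baseline radius is modulated by a fixed low-frequency cosine
    with a distinct amplitude/frequency/phase so the parents are geometrically
    distinct and the shape embedding can form per-parent clusters.
    """
    s = np.linspace(0.0, length, n_axial)
    refs = []
    for name, amp, freq, phase in _REFERENCE_SHAPES:
        r = base_radius * (1.0 + amp * np.cos(2 * np.pi * freq * s / length + phase))
        refs.append(ReferenceVessel(id=name, length=length, stations=s, radius=r))
    return refs


# ---------------------------------------------------------------------------
# operations

def perturb_radius(
    ref: ReferenceVessel,
    params: PerturbationParams,
    bounds: PerturbationBounds | None = None,
) -> np.ndarray:
    """Apply the two-sinusoid perturbation to a reference radius profile.

    Returns r(s) = r0(s) * (1 + sum_j [a_j sin(2 pi f_j s/L + phi_j) + d_j])
    evaluated on the reference stations (mm).  Raises if the parameters fall
    outside the bounds or any perturbed radius is non-positive.
    """
    params.validate(bounds or PerturbationBounds())
    s = ref.stations
    bracket = np.ones_like(s)
    for j in range(2):
        bracket += params.a[j] * np.sin(
            2 * np.pi * params.f[j] * s / ref.length + params.phi[j]
        ) + params.d[j]
    r = ref.radius * bracket
    if np.any(r <= 0):
        raise ValueError("perturbation drives the radius non-positive")
    return r


def draw_perturbation(
    rng: np.random.Generator, bounds: PerturbationBounds | None = None
) -> PerturbationParams:
    """Draw one parameter set uniformly within the bounds."""
    b = bounds or PerturbationBounds()
    a = rng.uniform(-b.a_max, b.a_max, size=2)
    f = rng.uniform(b.f_min, b.f_max, size=2)
    phi = rng.uniform(0.0, 2 * np.pi, size=2)
    d = rng.uniform(-b.d_max, b.d_max, size=2)
    return PerturbationParams(a=tuple(a), f=tuple(f), phi=tuple(phi), d=tuple(d))


def build_mesh(
    radius: np.ndarray,
    ref: ReferenceVessel,
    resolution: MeshResolution | None = None,
    mesh_id: str = "",
    params: PerturbationParams | None = None,
) -> VesselGeometry:
    """Build a fixed-topology structured tube mesh from a radius profile."""
    res = resolution or MeshResolution()
    r = np.asarray(radius, dtype=float)
    if r.shape != ref.stations.shape:
        raise ValueError("radius profile does not match the reference stations")
    if res.n_axial != ref.stations.size:
        raise ValueError("resolution n_axial does not match the reference stations")
    if np.any(r <= 0):
        raise ValueError("radius must be strictly positive")
    return VesselGeometry(
        id=mesh_id or ref.id,
        parent_id=ref.id,
        stations=ref.stations,
        radius=r,
        resolution=res,
        params=params,
    )


def _rings(n_circ: int) -> tuple[np.ndarray, np.ndarray]:
    theta = 2 * np.pi * np.arange(n_circ) / n_circ
    return np.cos(theta), np.sin(theta)


def _surface_coords(s, r, res: MeshResolution) -> np.ndarray:
    cos_t, sin_t = _rings(res.n_circ)
    out = np.empty((res.n_surface, 3))
    out[:, 0] = np.repeat(s, res.n_circ)
    out[:, 1] = np.outer(r, cos_t).ravel()
    out[:, 2] = np.outer(r, sin_t).ravel()
    return out


def _volume_coords(s, r, res: MeshResolution) -> np.ndarray:
    # interior ring radii at fractions l/(n_radial+1), l=1..n_radial: strictly
    # inside the wall, no duplication of surface nodes
    cos_t, sin_t = _rings(res.n_circ)
    fracs = np.arange(1, res.n_radial + 1) / (res.n_radial + 1)
    per_station = res.n_radial * res.n_circ + 1
    out = np.empty((res.n_volume, 3))
    for i in range(res.n_axial):
        base = i * per_station
        out[base] = (s[i], 0.0, 0.0)                       # axis node
        ring_r = r[i] * fracs
        block = out[base + 1 : base + per_station]
        block[:, 0] = s[i]
        block[:, 1] = np.outer(ring_r, cos_t).ravel()
        block[:, 2] = np.outer(ring_r, sin_t).ravel()
    return out


def generate_dataset(
    refs: list[ReferenceVessel] | None = None,
    n_perturb: int = 200,
    seed: int = 0,
    resolution: MeshResolution | None = None,
    bounds: PerturbationBounds | None = None,
) -> list[VesselGeometry]:
    """Generate the phantom dataset: each reference plus ``n_perturb`` randoms.

    Returns len(refs) * (n_perturb + 1) geometries, fully reproducible from
    the seed.  With the defaults (7 references, 200 perturbations) this is the
    1407-mesh ensemble the pipeline is designed around.
    """
    if n_perturb < 0:
        raise ValueError("n_perturb must be >= 0")
    refs = refs if refs is not None else default_reference_vessels(
        (resolution or MeshResolution()).n_axial
    )
    res = resolution or MeshResolution()
    bounds = bounds or PerturbationBounds()
    ss = np.random.SeedSequence(seed)
    geoms: list[VesselGeometry] = []
    for ref, child_ss in zip(refs, ss.spawn(len(refs))):
        geoms.append(build_mesh(ref.radius, ref, res, mesh_id=ref.id))
        rng = np.random.default_rng(child_ss)
        for k in range(n_perturb):
            params = draw_perturbation(rng, bounds)
            r = perturb_radius(ref, params, bounds)
            geoms.append(
                build_mesh(r, ref, res, mesh_id=f"{ref.id}_p{k:03d}", params=params)
            )
    return geoms


def perturbation_log(geoms: list[VesselGeometry]) -> pd.DataFrame:
    """Tabulate perturbation parameters (one row per mesh; NaN for references)."""
    rows = []
    for g in geoms:
        p = g.params
        rows.append(
            {
                "mesh_id": g.id,
                "parent_id": g.parent_id,
                "a1": p.a[0] if p else np.nan,
                "f1": p.f[0] if p else np.nan,
                "phi1": p.phi[0] if p else np.nan,
                "d1": p.d[0] if p else np.nan,
                "a2": p.a[1] if p else np.nan,
                "f2": p.f[1] if p else np.nan,
                "phi2": p.phi[1] if p else np.nan,
                "d2": p.d[1] if p else np.nan,
            }
        )
    return pd.DataFrame(rows)
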