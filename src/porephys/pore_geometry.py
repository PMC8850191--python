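"""Permeation-pathway geometry of pentameric channels.

The central computation is a HOLE-style pore profile: at each station along
the channel axis, find the largest sphere centred in the perpendicular
plane that touches no atom, where an atom of van der Waals radius r at
distance d from the sphere centre limits the sphere to radius d - r.  The
in-plane maximization uses a derivative-free Nelder-Mead search seeded from
the previous station's centre (restarted from the axis on failure), which
makes the profile deterministic for a given model and step.

On top of the profile sit the gate metrics used to describe pLGIC
conduction states: minimal gate diameters at the -2', 9' and 17' rings,
Cα pentagon perimeters, M2 helix tilt angles relative to the pore axis,
Kabsch superposition / RMSD, per-atom displacements between states, metal
coordination geometry and inter-group contact maps.

Axial convention: the pore axis direction points extracellular ->
intracellular (from the 20' ring toward -2'), while profile axial
coordinates are measured the other way up - zero at the -2' ring centroid,
increasing extracellularly - matching how channel profiles are plotted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .structure_io import AtomRecord, StructureModel

__all__ = [
    "VDW_RADII_SETS",
    "PoreAxis",
    "PoreProfile",
    "RingMetrics",
    "TiltResult",
    "SuperpositionResult",
    "CoordinationGeometry",
    "fit_pore_axis",
    "pore_profile",
    "gate_diameter",
    "ring_metrics",
    "helix_tilt",
    "mean_m2_tilt",
    "superpose",
    "kabsch",
    "displacement",
    "coordination",
    "contact_map",
]

#: Element -> van der Waals radius (Angstrom).  "hole-default" mirrors the
#: simple radius set traditionally used for channel profiling.
VDW_RADII_SETS: dict[str, dict[str, float]] = {
    "hole-default": {
        "C": 1.85, "N": 1.75, "O": 1.65, "S": 2.00, "P": 2.10, "H": 1.00,
        # bare metal ions get their ionic radius; Zn2+ (Pauling)
        "ZN": 0.74,
    },
}
DEFAULT_RADIUS = 2.00


def vdw_radius(element: str, radii_set: str = "hole-default") -> float:
    table = VDW_RADII_SETS[radii_set]
    return table.get(element.upper(), DEFAULT_RADIUS)


# ---------------------------------------------------------------------------
# axis


@dataclass(frozen=True)
class PoreAxis:
    point: np.ndarray  # a point on the axis
    direction: np.ndarray  # unit vector, extracellular -> intracellular
    axial_range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction", d)

    @property
    def up(self) -> np.ndarray:
        """Unit vector pointing extracellularly (increasing axial coord)."""
        return -self.direction

    def axial(self, x: np.ndarray, origin: np.ndarray | None = None
              ) -> np.ndarray:
        """Axial coordinate(s) of point(s), increasing extracellularly."""
        o = self.point if origin is None else np.asarray(origin, float)
        return np.dot(np.atleast_2d(x) - o, self.up).squeeze()

    def in_plane_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Right-handed orthonormal (e1, e2) with e1 x e2 = up, i.e. the
        frame seen looking down the pore from the extracellular side."""
        up = self.up
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, up)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - np.dot(ref, up) * up
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(up, e1)
        return e1, e2


def _ring_centroid(model: StructureModel, prime: int) -> np.ndarray:
    chains = model.subunit_chains()
    if not chains:
        raise KeyError("model has no annotated subunit chains")
    pts = [model.prime_ca(ch, prime).position for ch in chains]
    return np.mean(pts, axis=0)


def fit_pore_axis(
    model: StructureModel, ring_indices: list[int] | None = None
) -> PoreAxis:
    """Least-squares line through M2 ring Cα centroids.

    Uses every prime index resolvable on all five chains by default (needs
    at least two).  The direction is oriented from the highest prime ring
    (extracellular) toward the lowest (intracellular).
    """
    if not model.is_annotated:
        raise ValueError("model must be annotated (annotate_pentamer)")
    if ring_indices is None:
        lo, hi = model.prime_maps[model.subunit_chains()[0]].valid_range
        ring_indices = list(range(lo, hi + 1))
    centroids = []
    primes = []
    for p in sorted(ring_indices):
        try:
            centroids.append(_ring_centroid(model, p))
            primes.append(p)
        except KeyError:
            continue
    if len(centroids) < 2:
        raise ValueError("need >= 2 rings resolvable on all five chains")
    pts = np.array(centroids)
    mean = pts.mean(axis=0)
    _u, _s, vt = np.linalg.svd(pts - mean)
    direction = vt[0]
    # orient from high-prime (extracellular) toward low-prime centroid
    span = pts[-1] - pts[0]  # low prime -> high prime
    if np.dot(direction, span) > 0:
        direction = -direction
    proj = np.dot(pts - mean, direction)
    return PoreAxis(
        point=mean,
        direction=direction / np.linalg.norm(direction),
        axial_range=(float(proj.min()), float(proj.max())),
    )


# ---------------------------------------------------------------------------
# profile


@dataclass
class PoreProfile:
    """Axial series of maximal inscribed sphere radii."""

    stations: pd.DataFrame  # axial_coord, radius, cx, cy, cz, flagged
    step: float
    radii_set_name: str
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: PoreAxis | None = None

    def radius_at(self, axial: float) -> float:
        i = (self.stations["axial_coord"] - axial).abs().idxmin()
        return float(self.stations.loc[i, "radius"])

    def min_radius(self, lo: float | None = None, hi: float | None = None
                   ) -> float:
        df = self.stations
        if lo is not None:
            df = df[df["axial_coord"] >= lo]
        if hi is not None:
            df = df[df["axial_coord"] <= hi]
        if df.empty:
            raise ValueError("window outside profile range")
        return float(df["radius"].min())

    def to_csv(self, path: str | Path) -> None:
        self.stations.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        self.stations.to_json(path, orient="records")


def _profile_atoms(
    model: StructureModel,
    radii_set: str,
    include_het: bool,
    exclude: set[str] | None,
) -> tuple[np.ndarray, np.ndarray]:
    xyz, rad = [], []
    for a in model.atoms:
        if a.is_hetero and not include_het:
            continue
        if exclude and a.chain_id in exclude:
            continue
        xyz.append(a.position)
        rad.append(vdw_radius(a.element, radii_set))
    if not xyz:
        raise ValueError("empty atom selection for profiling")
    return np.array(xyz), np.array(rad)


def _station_radius(
    center2: np.ndarray,
    plane_point: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
    xyz: np.ndarray,
    rad: np.ndarray,
) -> float:
    c = plane_point + center2[0] * e1 + center2[1] * e2
    d = np.linalg.norm(xyz - c, axis=1) - rad
    return float(d.min())


def pore_profile(
    model: StructureModel,
    axis: PoreAxis,
    step: float = 0.25,
    radii_set: str = "hole-default",
    include_het: bool = False,
    exclude_chains: set[str] | None = None,
    z_range: tuple[float, float] | None = None,
    radius_cap: float = 10.0,
    max_offaxis: float = 5.0,
) -> PoreProfile:
    """HOLE-style maximal-sphere profile along the pore.

    At each axial station the sphere centre is optimized in the
    perpendicular plane (Nelder-Mead, seeded from the previous station and
    restarted from the axis when the search strays), and the radius is the
    clearance to the nearest atom surface.  Radii are clamped at
    ``radius_cap`` in vestibule-like regions; stations whose centre refuses
    to stay within ``max_offaxis`` of the axis are flagged rather than
    dropped.  Hetero atoms (e.g. a bound channel blocker) are excluded
    unless ``include_het``.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    xyz, rad = _profile_atoms(model, radii_set, include_het, exclude_chains)
    # origin of axial coordinates: -2' ring centroid when annotated
    try:
        origin = _ring_centroid(model, -2)
    except (KeyError, ValueError, IndexError):
        origin = axis.point
    e1, e2 = axis.in_plane_basis()
    up = axis.up
    ax_atoms = np.dot(xyz - origin, up)
    if z_range is None:
        # default: span the annotated ring range with 2 A margin
        lo, hi = float(ax_atoms.min()), float(ax_atoms.max())
        try:
            lo = float(axis.axial(_ring_centroid(model, -2), origin=origin)) - 2.0
            hi = float(axis.axial(
                _ring_centroid(model,
                               model.prime_maps[model.subunit_chains()[0]]
                               .valid_range[1]), origin=origin)) + 2.0
        except (KeyError, ValueError, IndexError):
            pass
    else:
        lo, hi = z_range
    us = np.arange(lo, hi + step / 2, step)
    max_r = rad.max()
    # projection of the axial origin onto the axis line
    axis_at_origin = axis.point + np.dot(origin - axis.point, up) * up
    rows = []
    prev_c2 = np.zeros(2)
    for u in us:
        plane_point = axis_at_origin + u * up
        slab = np.abs(ax_atoms - u) <= radius_cap + max_r + max_offaxis
        sub_xyz, sub_rad = xyz[slab], rad[slab]
        if sub_xyz.size == 0:
            rows.append((u, radius_cap, *(plane_point), True))
            prev_c2 = np.zeros(2)
            continue

        def neg(c2):
            return -_station_radius(c2, plane_point, e1, e2, sub_xyz, sub_rad)

        best = None
        for seed in (prev_c2, np.zeros(2)):
            res = optimize.minimize(
                neg, seed, method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
            )
            if best is None or res.fun < best.fun:
                best = res
            if np.linalg.norm(res.x) <= max_offaxis:
                break
        c2 = best.x
        r = -best.fun
        flagged = bool(np.linalg.norm(c2) > max_offaxis)
        if flagged:
            # keep the on-axis evaluation instead of a runaway center
            r = -neg(np.zeros(2))
            c2 = np.zeros(2)
        r = min(max(r, 0.0), radius_cap)
        center = plane_point + c2[0] * e1 + c2[1] * e2
        rows.append((u, r, *center, flagged))
        prev_c2 = c2
    df = pd.DataFrame(
        rows, columns=["axial_coord", "radius", "cx", "cy", "cz", "flagged"]
    )
    return PoreProfile(
        stations=df, step=step, radii_set_name=radii_set,
        origin=origin, axis=axis,
    )


def gate_diameter(
    profile: PoreProfile,
    model: StructureModel,
    prime_index: int,
    window: float = 2.0,
) -> float:
    """Gate diameter: twice the minimal profile radius within +/- ``window``
    of the prime ring's axial position."""
    if profile.axis is None:
        raise ValueError("profile lacks its axis; rebuild with pore_profile")
    u0 = float(profile.axis.axial(_ring_centroid(model, prime_index),
                                  origin=profile.origin))
    lo, hi = u0 - window, u0 + window
    smin = profile.stations["axial_coord"].min()
    smax = profile.stations["axial_coord"].max()
    if hi < smin or lo > smax:
        raise ValueError(
            f"window [{lo:.1f}, {hi:.1f}] outside profile range "
            f"[{smin:.1f}, {smax:.1f}]"
        )
    return 2.0 * profile.min_radius(lo, hi)


# ---------------------------------------------------------------------------
# rings & tilts


@dataclass(frozen=True)
class RingMetrics:
    prime_index: int
    chain_order: tuple[str, ...]  # azimuthal order about the axis
    perimeter: float
    min_pairwise_diameter: float
    centroid: np.ndarray


def ring_metrics(
    model: StructureModel, prime_index: int, axis: PoreAxis
) -> RingMetrics:
    """Closed-pentagon metrics of one Cα ring.

    Atoms are ordered by azimuth about the pore axis (right-handed, viewed
    from the extracellular side); the perimeter sums the five consecutive
    Cα-Cα distances of the closed polygon and is invariant to cyclic
    relabeling.  ``min_pairwise_diameter`` is the shortest distance between
    non-adjacent ring atoms (the pentagon "diagonals").
    """
    chains = model.subunit_chains()
    pts = np.array(
        [model.prime_ca(ch, prime_index).position for ch in chains]
    )
    centroid = pts.mean(axis=0)
    e1, e2 = axis.in_plane_basis()
    rel = pts - centroid
    az = np.arctan2(rel @ e2, rel @ e1)
    order = np.argsort(az)
    ordered = pts[order]
    n = len(ordered)
    perim = float(
        sum(np.linalg.norm(ordered[(i + 1) % n] - ordered[i])
            for i in range(n))
    )
    diag = min(
        np.linalg.norm(ordered[i] - ordered[j])
        for i in range(n)
        for j in range(i + 1, n)
        if (j - i) % n not in (1, n - 1)
    )
    return RingMetrics(
        prime_index=prime_index,
        chain_order=tuple(np.array(chains)[order]),
        perimeter=perim,
        min_pairwise_diameter=float(diag),
        centroid=centroid,
    )


@dataclass(frozen=True)
class TiltResult:
    per_chain: tuple[tuple[str, float], ...]
    mean_angle: float


def helix_tilt(
    model: StructureModel,
    chain_id: str,
    segment: tuple[int, int] = (0, 20),
    axis: PoreAxis | None = None,
) -> float:
    """Tilt (degrees) of one M2 helix relative to the pore axis.

    The helix axis is the principal (largest-variance) direction of the
    segment's Cα coordinates; the angle is folded into [0, 90].
    """
    if axis is None:
        raise ValueError("a PoreAxis is required")
    lo, hi = segment
    pts = []
    for p in range(lo, hi + 1):
        try:
            pts.append(model.prime_ca(chain_id, p).position)
        except KeyError:
            continue
    if len(pts) < 6:
        raise ValueError(
            f"chain {chain_id}: only {len(pts)} Cα in segment "
            f"{lo}'..{hi}'; need >= 6"
        )
    pts = np.array(pts)
    _u, _s, vt = np.linalg.svd(pts - pts.mean(axis=0))
    h = vt[0]
    cosang = abs(float(np.dot(h, axis.direction)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def mean_m2_tilt(
    model: StructureModel,
    axis: PoreAxis,
    segment: tuple[int, int] = (0, 20),
) -> TiltResult:
    """Per-chain M2 tilts and their arithmetic mean."""
    per = tuple(
        (ch, helix_tilt(model, ch, segment=segment, axis=axis))
        for ch in model.subunit_chains()
    )
    return TiltResult(
        per_chain=per,
        mean_angle=float(np.mean([t for _ch, t in per])),
    )


# ---------------------------------------------------------------------------
# superposition


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    selection: str = ""


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping points P onto Q.

    Standard Kabsch: SVD of the covariance of centred coordinates with a
    determinant correction so R is a proper rotation.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("need >= 3 paired atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-12:
        raise ValueError("degenerate (collinear) selection")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    return R, t


def _match_atoms(
    mobile: StructureModel,
    reference: StructureModel,
    selection,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Pair atoms between two models.

    ``selection`` may be "ca" (all Cα shared by chain+residue), a dict of
    :meth:`StructureModel.select` keywords, or a callable AtomRecord
    predicate; atoms are paired on (chain, residue number, atom name).
    """
    if selection == "ca" or selection is None:
        pred = lambda a: a.atom_name == "CA"  # noqa: E731
        label = "ca"
    elif isinstance(selection, dict):
        def pred(a, _kw=selection):
            return all(
                getattr(a, {"chain": "chain_id", "resnum": "residue_number",
                            "resname": "residue_name", "atom": "atom_name",
                            "element": "element"}.get(k, k)) == v
                for k, v in _kw.items()
            )
        label = repr(selection)
    elif callable(selection):
        pred = selection
        label = getattr(selection, "__name__", "callable")
    else:
        raise TypeError(f"unsupported selection {selection!r}")
    key = lambda a: (a.chain_id, a.residue_number, a.atom_name)  # noqa: E731
    mob = {key(a): a for a in mobile.atoms if pred(a)}
    ref = {key(a): a for a in reference.atoms if pred(a)}
    shared = [k for k in mob if k in ref]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} paired atoms for {label!r}")
    P = np.array([mob[k].position for k in shared])
    Q = np.array([ref[k].position for k in shared])
    return P, Q, label


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    selection="ca",
) -> SuperpositionResult:
    """Kabsch superposition of ``mobile`` onto ``reference``."""
    P, Q, label = _match_atoms(mobile, reference, selection)
    R, t = kabsch(P, Q)
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd, n_atoms=P.shape[0],
        selection=label,
    )


def displacement(
    model_a: StructureModel,
    model_b: StructureModel,
    atom_selector: dict,
    align_selection="ca",
) -> float:
    """Distance moved by one atom between two states, after aligning
    ``model_b`` onto ``model_a`` on ``align_selection``."""
    sup = superpose(model_b, model_a, selection=align_selection)
    hits_a = model_a.select(**atom_selector)
    hits_b = model_b.select(**atom_selector)
    if len(hits_a) != 1 or len(hits_b) != 1:
        raise ValueError(
            f"selector must match exactly one atom in each model "
            f"(got {len(hits_a)}/{len(hits_b)})"
        )
    moved_b = sup.rotation @ hits_b[0].position + sup.translation
    return float(np.linalg.norm(moved_b - hits_a[0].position))


# ---------------------------------------------------------------------------
# coordination & contacts


@dataclass(frozen=True)
class CoordinationGeometry:
    metal: AtomRecord
    ligand_atoms: tuple[AtomRecord, ...]
    distances: tuple[float, ...]
    inter_ligand_angles: tuple[float, ...]  # metal-centred, degrees


def coordination(
    model: StructureModel,
    metal_selector: dict,
    ligand_selector: dict,
    cutoff: float = 3.5,
) -> CoordinationGeometry:
    """Distances and metal-centred angles of a coordination shell."""
    metals = model.select(**metal_selector)
    if len(metals) != 1:
        raise ValueError(f"metal selector matched {len(metals)} atoms, need 1")
    metal = metals[0]
    ligs = [
        a for a in model.select(**ligand_selector)
        if np.linalg.norm(a.position - metal.position) <= cutoff
        and a is not metal
    ]
    ligs.sort(key=lambda a: np.linalg.norm(a.position - metal.position))
    dists = tuple(
        float(np.linalg.norm(a.position - metal.position)) for a in ligs
    )
    angles = []
    for i in range(len(ligs)):
        for j in range(i + 1, len(ligs)):
            v1 = ligs[i].position - metal.position
            v2 = ligs[j].position - metal.position
            c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angles.append(float(np.degrees(np.arccos(np.clip(c, -1, 1)))))
    return CoordinationGeometry(
        metal=metal,
        ligand_atoms=tuple(ligs),
        distances=dists,
        inter_ligand_angles=tuple(angles),
    )


def contact_map(
    model: StructureModel,
    group_a: dict,
    group_b: dict,
    cutoff: float = 4.0,
) -> list[tuple[AtomRecord, AtomRecord, float]]:
    """All cross-group atom pairs within ``cutoff``, sorted by distance."""
    aa = model.select(**group_a)
    bb = model.select(**group_b)
    if not aa or not bb:
        raise ValueError("selections must be non-empty")
    out = []
    for a in aa:
        for b in bb:
            d = float(np.linalg.norm(a.position - b.position))
            if d <= cutoff:
                out.append((a, b, d))
    out.sort(key=lambda x: x[2])
    return out
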