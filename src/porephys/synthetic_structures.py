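"""Idealized pentameric pore fixtures with analytic ground truth.

Builds an n-fold symmetric bundle of idealized M2 helices around the z
axis.  Each chain's Cα trace is laid along a straight helix axis (the
smoothed trace, one residue per 1.5 Å rise), pivoted at its 9' residue and
tilted radially by a chosen angle — the tilt lies in the plane containing
the chain's azimuth and z, so the principal-component helix axis equals the
construction axis exactly and every geometric observable has a closed form:

* pore axis: z through the origin (extracellular = +z),
* ring radius at prime p: R + (p - 9) * rise * sin(tilt),
* Cα pentagon perimeter at prime p: n * 2 * r_p * sin(pi/n),
* minimal pore radius (ca_only): min_p r_p - vdW(C).

Residues are LEU except the 17' anchor, written HIS on beta-like chains
(positions B, C, E) and SER on alpha-like chains (A, D), so the default
anchor numbering (beta3 267 / alpha1 272) applies and the fixtures exercise
the same annotation path as real depositions.  Gaussian coordinate jitter
(seeded) is applied after ground-truth capture.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .pore_geometry import vdw_radius
from .structure_io import (
    DEFAULT_ANCHORS,
    AtomRecord,
    StructureModel,
    annotate_pentamer,
)

__all__ = ["IdealPoreSpec", "build_ideal_pore", "default_chain_spec"]

ALPHA_POSITIONS = {"A", "D"}  # alpha-beta-beta-alpha-beta, clockwise


@dataclass(frozen=True)
class IdealPoreSpec:
    """Recipe for one ideal pore fixture.

    ``ring_radius`` is the Cα ring radius (Å) at the 9' pivot; ``helix_tilt``
    is the radial tilt in degrees (positive = top leans outward).
    """

    ring_radius: float = 6.84
    helix_tilt: float = 0.0  # degrees
    n_subunits: int = 5
    helix_length: int = 23  # residues, covers primes -2'..20'
    rise_per_residue: float = 1.5  # Angstrom
    residues_per_turn: float = 3.6
    atom_set: str = "ca_only"  # ca_only | ca_cb | full_backbone
    jitter_sigma: float = 0.0  # Angstrom
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subunits < 3:
            raise ValueError("n_subunits must be >= 3")
        if not 0 <= self.helix_tilt < 45:
            raise ValueError("helix_tilt must be in [0, 45) degrees")
        if self.ring_radius <= vdw_radius("C"):
            raise ValueError("ring_radius must exceed the carbon vdW radius")
        if self.atom_set not in ("ca_only", "ca_cb", "full_backbone"):
            raise ValueError(f"unknown atom_set {self.atom_set!r}")
        if self.helix_length < 8:
            raise ValueError("helix_length must cover >= 8 residues")


def default_chain_spec(n_subunits: int = 5) -> dict[str, str]:
    """Chain annotation spec matching :func:`build_ideal_pore` fixtures."""
    return {
        ch: ("alpha1" if ch in ALPHA_POSITIONS else "beta3")
        for ch in "ABCDEFGH"[:n_subunits]
    }


def build_ideal_pore(
    spec: IdealPoreSpec,
) -> tuple[StructureModel, dict]:
    """Construct the fixture and its exact ground-truth record.

    Returns ``(model, truth)`` where the (annotated) model carries
    ``spec.n_subunits`` chains and ``truth`` holds the axis, per-ring
    centroid radii (keyed by prime index), per-helix tilt and the analytic
    minimal pore radius for the ca_only atom set.  Jitter, when requested,
    perturbs coordinates only after the truth record is captured.
    """
    n = spec.n_subunits
    tilt = np.radians(spec.helix_tilt)
    rise = spec.rise_per_residue
    primes = list(range(-2, spec.helix_length - 2))
    # z of the 9' pivot so that the -2' ring sits at z = 0
    z9 = (9 - (-2)) * rise * np.cos(tilt)
    chain_ids = "ABCDEFGH"[:n]
    atoms: list[AtomRecord] = []
    ring_radii = {
        p: spec.ring_radius + (p - 9) * rise * np.sin(tilt) for p in primes
    }
    if min(ring_radii.values()) <= 0:
        raise ValueError("tilt/length combination collapses the pore")
    for k, ch in enumerate(chain_ids):
        phi = 2 * np.pi * k / n
        r_hat = np.array([np.cos(phi), np.sin(phi), 0.0])
        t_hat = np.array([-np.sin(phi), np.cos(phi), 0.0])
        d = np.sin(tilt) * r_hat + np.cos(tilt) * np.array([0.0, 0.0, 1.0])
        pivot = spec.ring_radius * r_hat + np.array([0.0, 0.0, z9])
        alpha_like = ch in ALPHA_POSITIONS
        anchor = DEFAULT_ANCHORS["alpha1" if alpha_like else "beta3"]
        for p in primes:
            ca = pivot + (p - 9) * rise * d
            if p == 17:
                resname = "SER" if alpha_like else "HIS"
            else:
                resname = "LEU"
            resnum = anchor + (p - 17)
            atoms.append(
                AtomRecord(
                    chain_id=ch, residue_number=resnum, residue_name=resname,
                    atom_name="CA", element="C", position=ca,
                )
            )
            if spec.atom_set in ("ca_cb", "full_backbone") and resname != "GLY":
                atoms.append(
                    AtomRecord(
                        chain_id=ch, residue_number=resnum,
                        residue_name=resname, atom_name="CB", element="C",
                        position=ca + 1.5 * r_hat,
                    )
                )
            if spec.atom_set == "full_backbone":
                # schematic backbone: N/C flank Cα along the helix axis,
                # O offset tangentially; not stereochemically exact
                for name, elem, off in (
                    ("N", "N", -0.5 * rise * d + 0.4 * t_hat),
                    ("C", "C", 0.5 * rise * d + 0.4 * t_hat),
                    ("O", "O", 0.7 * rise * d + 1.0 * t_hat),
                ):
                    atoms.append(
                        AtomRecord(
                            chain_id=ch, residue_number=resnum,
                            residue_name=resname, atom_name=name,
                            element=elem, position=ca + off,
                        )
                    )
    model = StructureModel(atoms, name=f"ideal_pore_t{spec.helix_tilt:g}")
    if n == 5:  # annotation is defined for pentamers
        model = annotate_pentamer(model, default_chain_spec(n))
    truth = {
        "axis_point": [0.0, 0.0, 0.0],
        "axis_up": [0.0, 0.0, 1.0],  # extracellular direction
        "ring_radius": {str(p): float(r) for p, r in ring_radii.items()},
        "ring_perimeter": {
            str(p): float(n * 2 * r * np.sin(np.pi / n))
            for p, r in ring_radii.items()
        },
        "helix_tilt": {ch: float(spec.helix_tilt) for ch in chain_ids},
        "min_pore_radius_ca_only": float(
            min(ring_radii.values()) - vdw_radius("C")
        ),
        "minus2_z": 0.0,
        "spec": asdict(spec),
    }
    if spec.jitter_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for a in model.atoms:
            a.position = a.position + rng.normal(
                0.0, spec.jitter_sigma, size=3
            )
    return model, truth


def write_fixture(
    spec: IdealPoreSpec,
    pdb_path: str | Path,
    truth_path: str | Path | None = None,
) -> tuple[StructureModel, dict]:
    """Build and write a fixture as minimal PDB plus JSON ground truth."""
    model, truth = build_ideal_pore(spec)
    model.write(pdb_path, format="pdb")
    if truth_path is not None:
        Path(truth_path).write_text(json.dumps(truth, indent=1))
    return model, truth
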