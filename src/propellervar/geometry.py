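"""Propeller axis determination and axial (Z) projection of residues.

A beta-propeller is disc-like: its symmetry axis is the direction of minimal
variance of the CA coordinate cloud.  Each residue's backbone carbonyl carbon
is projected onto that axis to give its signed position between the top
(ligand-binding) and bottom faces; unresolved residues get linearly
interpolated positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .structure import DomainStructure

__all__ = [
    "AxisMode",
    "PropellerFrame",
    "ZEntry",
    "ZProjection",
    "DegenerateAxisError",
    "compute_axis",
    "project_residues",
    "interpolate_missing",
]


class AxisMode(str, Enum):
    PRINCIPAL = "principal"   # minimal-variance direction of the CA cloud
    CRYSTAL_Z = "crystal_z"   # deposited +Z axis, as read from the file


class DegenerateAxisError(ValueError):
    """CA cloud has no well-separated minimal-variance direction."""


@dataclass(frozen=True)
class PropellerFrame:
    origin: np.ndarray          # domain CA centroid, Angstrom
    axis: np.ndarray            # unit vector, top face positive
    mode: AxisMode
    flipped: bool = False       # True if the sign was reversed by the anchor rule

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        ax = np.asarray(self.axis, float)
        n = np.linalg.norm(ax)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"axis norm {n} != 1")
        object.__setattr__(self, "axis", ax)

    def z_of(self, position: np.ndarray) -> float:
        return float((np.asarray(position, float) - self.origin) @ self.axis)


@dataclass(frozen=True)
class ZEntry:
    z: float
    status: str  # "observed" | "interpolated"


@dataclass(frozen=True)
class ZProjection:
    """Map residue number -> signed axial coordinate with provenance."""

    entries: dict[int, ZEntry]

    def z(self, residue_number: int) -> float | None:
        e = self.entries.get(residue_number)
        return None if e is None else e.z

    def values(self, numbers=None) -> np.ndarray:
        if numbers is None:
            return np.array([e.z for e in self.entries.values()])
        return np.array([self.entries[n].z for n in numbers if n in self.entries])


def compute_axis(domain: DomainStructure, mode: AxisMode | str = AxisMode.PRINCIPAL,
                 anchor_residues: set[int] | None = None,
                 flip: bool = False) -> PropellerFrame:
    """Propeller frame: origin at the CA centroid, axis through the barrel.

    ``principal`` mode takes the smallest-eigenvalue direction of the CA
    covariance; ``crystal_z`` takes the deposited +Z.  The sign is chosen so
    that the mean projection of *anchor_residues* (e.g. the tetrad aspartates,
    which sit at the top of each blade) exceeds the domain mean: top face
    positive.  ``flip`` reverses the result explicitly.
    """
    mode = AxisMode(mode)
    nums, ca = domain.coords("CA")
    if len(nums) < 10:
        raise ValueError(f"need >=10 CA atoms to define an axis, got {len(nums)}")
    origin = ca.mean(axis=0)

    if mode is AxisMode.CRYSTAL_Z:
        axis = np.array([0.0, 0.0, 1.0])
    else:
        centered = ca - origin
        cov = centered.T @ centered / len(ca)
        evals, evecs = np.linalg.eigh(cov)  # ascending
        scale = max(evals[-1], 1e-30)
        if (evals[1] - evals[0]) / scale < 1e-6:
            raise DegenerateAxisError(
                "CA cloud has a degenerate minimal-variance direction "
                "(relative eigengap < 1e-6); consider crystal_z mode"
            )
        axis = evecs[:, 0]

    flipped = False
    if anchor_residues:
        zs = {n: float((p - origin) @ axis) for n, p in zip(nums, ca)}
        anchor = [zs[n] for n in anchor_residues if n in zs]
        if anchor and np.mean(anchor) < np.mean(list(zs.values())):
            axis = -axis
            flipped = True
    if flip:
        axis = -axis
        flipped = not flipped
    return PropellerFrame(origin=origin, axis=axis / np.linalg.norm(axis),
                          mode=mode, flipped=flipped)


def project_residues(domain: DomainStructure, frame: PropellerFrame,
                     atom_name: str = "C", ca_fallback: bool = False) -> ZProjection:
    """Project the named atom of each residue onto the axis (status ``observed``).

    Residues lacking the atom are omitted here unless ``ca_fallback`` is set,
    in which case CA substitutes with a warning.
    """
    entries: dict[int, ZEntry] = {}
    for r in domain.residues:
        a = r.atom(atom_name)
        if a is None and ca_fallback:
            a = r.atom("CA")
            if a is not None:
                warnings.warn(f"residue {r.author_number}: no {atom_name} atom, using CA")
        if a is not None:
            entries[r.author_number] = ZEntry(z=frame.z_of(a.position), status="observed")
    return ZProjection(entries=entries)


def interpolate_missing(projection: ZProjection, domain: DomainStructure) -> ZProjection:
    """Fill internal gaps linearly in residue number (status ``interpolated``).

    For a missing number m with nearest observed neighbours a < m < b:
    z(m) = z(a) + (m-a)/(b-a) * (z(b)-z(a)).  Gaps touching the domain
    boundary cannot be bracketed and are left absent with a warning.
    """
    entries = dict(projection.entries)
    observed = sorted(n for n, e in entries.items() if e.status == "observed")
    if not observed:
        return ZProjection(entries=entries)
    lo, hi = observed[0], observed[-1]
    targets = [n for n in domain.missing_numbers if n not in entries]
    # residues present in the model but lacking the projection atom also get
    # interpolated positions (they are "absent" from the projection's view)
    targets += [r.author_number for r in domain.residues if r.author_number not in entries]
    for m in sorted(set(targets)):
        if not lo < m < hi:
            warnings.warn(f"residue {m}: gap touches the domain boundary, not interpolated")
            continue
        import bisect
        i = bisect.bisect_left(observed, m)
        a, b = observed[i - 1], observed[i]
        za, zb = entries[a].z, entries[b].z
        entries[m] = ZEntry(z=za + (m - a) / (b - a) * (zb - za), status="interpolated")
    return ZProjection(entries=dict(sorted(entries.items())))
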