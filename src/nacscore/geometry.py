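"""Reaction-center geometry and near-attack-conformation (NAC) classification.

During hydrogen abstraction by the P450 compound I intermediate, the
ferryl oxygen, the abstracted hydrogen and its parent carbon must adopt a
near-transition-state arrangement.  A trajectory frame counts as a NAC for
a given hydrogen when three geometric descriptors fall inside threshold
windows:

* ``d``      — distance between the reactive (ferryl) oxygen and the hydrogen,
* ``theta1`` — Fe-O-H angle, vertex at the oxygen,
* ``theta2`` — C-H-O angle, vertex at the hydrogen.

The default thresholds are ``d <= 2.7`` Angstrom (inclusive),
``100 < theta1 < 140`` degrees and ``theta2 > 140`` degrees (both strict),
derived from DFT models of the hydrogen-abstraction transition state.

All lengths are Angstrom, all angles degrees.  Coordinates are plain
3-vectors (anything :func:`numpy.asarray` accepts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidGeometryError, SelectionError

#: Canonical hydrogen-role labels for the prochiral target carbon.
PRO_R = "pro_R"
PRO_S = "pro_S"

#: Default ferryl Fe=O bond length used when synthesizing a virtual oxo atom.
DEFAULT_OXO_BOND_LENGTH = 1.62


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise InvalidGeometryError(f"expected a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise InvalidGeometryError(f"non-finite coordinate: {v}")
    return v


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame, keyed by (chain, resseq, name) across frames."""

    serial: int
    name: str
    resname: str
    chain: str
    resseq: int
    element: str
    coord: np.ndarray
    virtual: bool = False

    def __post_init__(self):
        if not self.name:
            raise ValueError("atom name must be non-empty")
        object.__setattr__(self, "coord", _as_vec(self.coord))

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.name)


@dataclass(frozen=True)
class ReactionCenter:
    """The role-tagged atoms needed to score one frame.

    ``extra_h`` carries additional candidate abstraction sites (alkylic or
    vinylic hydrogens) as ``(site_label, atom)`` pairs.  ``virtual_oxo`` is
    True iff the oxo atom was synthesized from the heme plane rather than
    read from the structure.
    """

    fe: AtomRecord
    oxo: AtomRecord
    c_target: AtomRecord
    h_pro_r: AtomRecord
    h_pro_s: AtomRecord
    extra_h: tuple = ()
    virtual_oxo: bool = False

    def hydrogen(self, label: str) -> AtomRecord:
        if label == PRO_R:
            return self.h_pro_r
        if label == PRO_S:
            return self.h_pro_s
        for site, atom in self.extra_h:
            if site == label:
                return atom
        raise SelectionError(f"unknown hydrogen label {label!r}; "
                             f"known: {self.hydrogen_labels()}")

    def hydrogen_labels(self) -> list[str]:
        return [PRO_S, PRO_R] + [site for site, _ in self.extra_h]


@dataclass(frozen=True)
class NACCriteria:
    """Threshold windows classifying a (d, theta1, theta2) triple as a NAC.

    The distance bound is inclusive, both angle windows strict, matching
    the inequality symbols of the source criteria (d <= 2.7; 100 < theta1
    < 140; theta2 > 140).
    """

    d_max: float = 2.7
    theta1_min: float = 100.0
    theta1_max: float = 140.0
    theta2_min: float = 140.0

    def __post_init__(self):
        if not self.d_max > 0:
            raise ValueError("d_max must be positive")
        if not (0 <= self.theta1_min < self.theta1_max <= 180):
            raise ValueError("need 0 <= theta1_min < theta1_max <= 180")
        if not (0 <= self.theta2_min <= 180):
            raise ValueError("need 0 <= theta2_min <= 180")


@dataclass(frozen=True)
class GeometrySample:
    """The scored descriptors of one hydrogen in one frame."""

    hydrogen_label: str
    d: float
    theta1: float
    theta2: float
    is_nac: Optional[bool] = None
    frame_index: int = 0
    replica_id: str = ""

    def __post_init__(self):
        if self.d < 0:
            raise ValueError("d must be >= 0")
        for name in ("theta1", "theta2"):
            v = getattr(self, name)
            if not (0 <= v <= 180):
                raise ValueError(f"{name}={v} outside [0, 180]")


def distance(a, b) -> float:
    """Euclidean distance between two points, in Angstrom."""
    return float(np.linalg.norm(_as_vec(a) - _as_vec(b)))


def angle(a, vertex, b) -> float:
    """Angle in degrees between rays vertex->a and vertex->b, in [0, 180].

    Uses the atan2(|u x w|, u.w) form, which is stable near 0 and 180.
    Raises :class:`InvalidGeometryError` if either ray is shorter than
    1e-6 Angstrom.
    """
    v = _as_vec(vertex)
    u = _as_vec(a) - v
    w = _as_vec(b) - v
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu <= 1e-6 or nw <= 1e-6:
        raise InvalidGeometryError(
            f"degenerate ray at vertex {v}: |u|={nu:.2e}, |w|={nw:.2e}")
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, w)),
                                       float(np.dot(u, w)))))


def heme_plane_normal(n1, n2, n3, n4, toward=None) -> np.ndarray:
    """Unit normal of the least-squares plane through the four pyrrole nitrogens.

    Orientation is flipped toward the reference point ``toward`` (normally
    an atom on the distal side, e.g. the substrate carbon); without a
    reference the normal is oriented to have a non-negative z component.
    """
    pts = np.stack([_as_vec(p) for p in (n1, n2, n3, n4)])
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    # Rank < 2 means the points are collinear (or coincident): no plane.
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise InvalidGeometryError("pyrrole nitrogens are collinear; no plane normal")
    normal = vt[2]
    if toward is not None:
        ref = _as_vec(toward) - centroid
        if abs(float(np.dot(ref, normal))) <= 1e-12:
            raise InvalidGeometryError("orientation reference lies in the heme plane")
        if float(np.dot(ref, normal)) < 0:
            normal = -normal
    elif normal[2] < 0:
        normal = -normal
    return normal / np.linalg.norm(normal)


def place_virtual_oxo(fe, normal, bond_length: float = DEFAULT_OXO_BOND_LENGTH) -> np.ndarray:
    """Coordinate of a ferryl oxygen placed along ``normal`` from the iron."""
    n = _as_vec(normal)
    norm = np.linalg.norm(n)
    if norm <= 1e-8:
        raise InvalidGeometryError("zero-length normal for virtual oxo placement")
    if bond_length <= 0:
        raise InvalidGeometryError("oxo bond length must be positive")
    return _as_vec(fe) + bond_length * (n / norm)


def evaluate_geometry(rc: ReactionCenter, hydrogen_label: str,
                      frame_index: int = 0, replica_id: str = "") -> GeometrySample:
    """Measure (d, theta1, theta2) for one hydrogen of one resolved frame.

    ``is_nac`` is left unset; apply :func:`classify_nac` to fill it.
    """
    h = rc.hydrogen(hydrogen_label).coord
    o = rc.oxo.coord
    return GeometrySample(
        hydrogen_label=hydrogen_label,
        d=distance(o, h),
        theta1=angle(rc.fe.coord, o, h),
        theta2=angle(rc.c_target.coord, h, o),
        frame_index=frame_index,
        replica_id=replica_id,
    )


def classify_nac(sample: GeometrySample, criteria: NACCriteria = NACCriteria()) -> GeometrySample:
    """Return a copy of ``sample`` with ``is_nac`` filled in from ``criteria``."""
    is_nac = (sample.d <= criteria.d_max
              and criteria.theta1_min < sample.theta1 < criteria.theta1_max
              and sample.theta2 > criteria.theta2_min)
    return replace(sample, is_nac=is_nac)


def check_distance_constraint(a, b, max_d: float) -> bool:
    """True iff distance(a, b) < max_d (strict), the design-stage Fe-C filter."""
    if max_d <= 0:
        raise ValueError("max_d must be positive")
    return distance(a, b) < max_d
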