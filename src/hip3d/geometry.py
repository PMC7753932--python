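"""Anatomical frame conventions and shared hip-joint geometry.

Every module in the package uses one fixed anatomical frame:

    +x  lateral (toward the imaged hip)
    +y  anterior
    +z  superior

All angles are defined in this frame.  The acetabular opening axis ``n``
(the outward normal of the acetabular opening plane, pointing away from
the joint, i.e. laterally for a normal hip) is constructed from the two
clinical orientation angles as

    n = ( sin(incl) * cos(av),  sin(av),  -cos(incl) * cos(av) )

so that inclination is the coronal-plane tilt of the opening away from
the inferior direction toward lateral, ``incl = atan2(n_x, -n_z)``, and
anteversion is the elevation toward anterior, ``av = asin(n_y)``.
A cup with zero inclination and zero anteversion opens straight
inferiorly (n = -z); a cup with 90 deg inclination opens straight
laterally (n = +x).
"""

from __future__ import annotations

import numpy as np

#: Tag stored on every grid object; checked at pipeline entry points.
ANATOMICAL_FRAME = "x-lateral,y-anterior,z-superior"


def cup_opening_axis(inclination_deg: float, anteversion_deg: float) -> np.ndarray:
    """Unit outward normal of the acetabular opening plane.

    Parameters
    ----------
    inclination_deg : float
        Coronal tilt of the opening from inferior toward lateral, degrees.
    anteversion_deg : float
        Elevation of the opening axis toward anterior, degrees.
    """
    i = np.deg2rad(inclination_deg)
    a = np.deg2rad(anteversion_deg)
    n = np.array([np.sin(i) * np.cos(a), np.sin(a), -np.cos(i) * np.cos(a)])
    return n / np.linalg.norm(n)


def cup_angles_from_axis(n: np.ndarray) -> tuple[float, float]:
    """Invert :func:`cup_opening_axis`: (inclination_deg, anteversion_deg).

    Raises
    ------
    ValueError
        If the opening points purely anterior/posterior (|n_y| = 1), where
        inclination is undefined.
    """
    n = np.asarray(n, dtype=float)
    n = n / np.linalg.norm(n)
    ny = np.clip(n[1], -1.0, 1.0)
    if abs(abs(ny) - 1.0) < 1e-12:
        raise ValueError("opening axis purely anterior/posterior: inclination undefined")
    anteversion = np.degrees(np.arcsin(ny))
    inclination = np.degrees(np.arctan2(n[0], -n[2]))
    return float(inclination), float(anteversion)


def cup_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed in-plane basis (e1, e2) for the opening plane of ``n``.

    e1 is the projection of anterior (+y) into the plane, so the azimuth
    ``atan2(u.e2, u.e1)`` is zero for the most anterior point of the rim.
    Falls back to the projection of +z when n is (anti)parallel to +y.
    """
    n = np.asarray(n, dtype=float)
    ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, n) * n
    if np.linalg.norm(e1) < 1e-8:
        ref = np.array([0.0, 0.0, 1.0])
        e1 = ref - np.dot(ref, n) * n
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(t) * k + (1.0 - np.cos(t)) * (k @ k)


def euler_xyz_matrix(rx_deg: float, ry_deg: float, rz_deg: float) -> np.ndarray:
    """Extrinsic x-then-y-then-z rotation, R = Rz @ Ry @ Rx."""
    rx = rotation_matrix([1, 0, 0], rx_deg)
    ry = rotation_matrix([0, 1, 0], ry_deg)
    rz = rotation_matrix([0, 0, 1], rz_deg)
    return rz @ ry @ rx


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit directions (n, 3), Fibonacci lattice."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def wrap_deg(a):
    """Wrap angle(s) to (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def in_cup_sector(u: np.ndarray, n: np.ndarray, half_angle_deg: float,
                  deficiency_deg: float = 0.0,
                  deficiency_center_deg: float = 0.0) -> np.ndarray:
    """Membership of unit directions ``u`` (N,3) in the cup's angular support.

    A direction belongs to the cup cap iff its polar angle from the deep
    axis (-n) is at most ``half_angle_deg`` and its azimuth is outside the
    removed rim-deficiency sector (centered at ``deficiency_center_deg``,
    azimuth 0 = anterior).
    """
    u = np.atleast_2d(u)
    e1, e2 = cup_basis(n)
    cosp = u @ (-n)
    ok = cosp >= np.cos(np.deg2rad(half_angle_deg))
    if deficiency_deg > 0:
        az = np.degrees(np.arctan2(u @ e2, u @ e1))
        removed = np.abs(wrap_deg(az - deficiency_center_deg)) <= deficiency_deg / 2.0
        ok &= ~removed
    return ok
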