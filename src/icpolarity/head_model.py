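"""Spherical volume-conductor head model and idealized 10-10 electrode geometry.

The head is modelled as a single homogeneous conducting sphere (default radius
85 mm, conductivity 0.33 S/m).  The surface potential of an eccentric current
dipole is evaluated with the classical Legendre-series expansion truncated at
``n_terms`` terms; at the origin the series collapses to the closed form
``V = 3 (p . r_hat) / (4 pi sigma R^2)``.

Electrode positions follow the idealized spherical 10-10 layout: the vertex at
Cz, the outer 10% ring at 72 degrees of inclination (Fpz, T7/T8, Oz, ...), the
midline at 18-degree steps, and every intermediate row on the circle through
its two ring endpoints and its midline electrode, subdivided at equal arc
angles.  This is the construction underlying the published 10-10 tables, so the
montage is reproducible bit-exactly from code alone.

Coordinates: +x right, +y anterior, +z superior, millimetres, origin at the
sphere centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Electrode",
    "HeadModel",
    "Dipole",
    "MONTAGE_62",
    "make_montage",
    "standard_62_montage",
    "load_electrodes",
    "save_electrodes",
    "electrode_array",
    "dipole_potential",
    "leadfield",
    "leadfield_batch",
]

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class Electrode:
    """A named scalp electrode at a fixed position (mm) on the sphere surface."""

    label: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class HeadModel:
    """Homogeneous single-sphere conductor.

    Parameters
    ----------
    radius_mm : outer (scalp) radius in millimetres.
    conductivity_sm : homogeneous conductivity in S/m.
    n_terms : truncation order of the Legendre series.  The truncation error
        scales like ``(|r0|/R)**n_terms``; the default 60 gives machine-level
        accuracy for eccentricities up to ~0.7 R and <1e-4 relative up to
        0.85 R, which covers the cortical shell used throughout.
    """

    radius_mm: float = 85.0
    conductivity_sm: float = 0.33
    n_terms: int = 60

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("radius_mm must be positive")
        if not self.conductivity_sm > 0:
            raise ValueError("conductivity_sm must be positive")
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")


@dataclass(frozen=True)
class Dipole:
    """Equivalent current dipole: position (mm, inside the sphere) and moment (nA*m)."""

    position_mm: np.ndarray
    moment_nam: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position_mm, dtype=float).reshape(3)
        mom = np.asarray(self.moment_nam, dtype=float).reshape(3)
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(mom))):
            raise ValueError("dipole position and moment must be finite")
        object.__setattr__(self, "position_mm", pos)
        object.__setattr__(self, "moment_nam", mom)


# ---------------------------------------------------------------------------
# Idealized 10-10 montage
# ---------------------------------------------------------------------------

# Outer 10% ring: inclination 72 deg from the vertex, azimuth measured from +x
# (right ear) towards +y (nasion), 18-degree steps.
_RING = [
    ("T8", 0.0), ("FT8", 18.0), ("F8", 36.0), ("AF8", 54.0), ("Fp2", 72.0),
    ("Fpz", 90.0), ("Fp1", 108.0), ("AF7", 126.0), ("F7", 144.0),
    ("FT7", 162.0), ("T7", 180.0), ("TP7", 198.0), ("P7", 216.0),
    ("PO7", 234.0), ("O1", 252.0), ("Oz", 270.0), ("O2", 288.0),
    ("PO8", 306.0), ("P8", 324.0), ("TP8", 342.0),
]

# Midline: (label, inclination from vertex, azimuth 90=front / 270=back).
_MIDLINE = [
    ("AFz", 54.0, 90.0), ("Fz", 36.0, 90.0), ("FCz", 18.0, 90.0),
    ("Cz", 0.0, 90.0), ("CPz", 18.0, 270.0), ("Pz", 36.0, 270.0),
    ("POz", 54.0, 270.0),
]

# Rows interpolated on the circle through (left ring endpoint, midline
# electrode, right ring endpoint); labels ordered left -> right.
_ROWS = {
    "C": (["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"], "Cz"),
    "F": (["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"], "Fz"),
    "FC": (["FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"], "FCz"),
    "CP": (["TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8"], "CPz"),
    "P": (["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"], "Pz"),
    "AF": (["AF7", "AF3", "AFz", "AF4", "AF8"], "AFz"),
    "PO": (["PO7", "PO3", "POz", "PO4", "PO8"], "POz"),
}

# Below the outer ring (inclination 90 deg), same azimuths as PO7/PO8.
_LOWER = [("PO9", 90.0, 234.0), ("PO10", 90.0, 306.0)]

#: The 62-channel montage of the reference resting-state database (initial
#: reference FCz included as an ordinary scalp site after reference recovery).
MONTAGE_62 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "CP5", "CP1", "CP2", "CP6", "AFz", "P7",
    "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10", "AF7", "AF3",
    "AF4", "AF8", "F5", "F1", "F2", "F6", "FT7", "FC3", "FC4", "FT8", "C5",
    "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8", "P5", "P1", "P2",
    "P6", "PO7", "PO3", "POz", "PO4", "PO8", "FCz",
)


def _unit(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    si = math.sin(inclination_deg * _DEG)
    return np.array(
        [
            si * math.cos(azimuth_deg * _DEG),
            si * math.sin(azimuth_deg * _DEG),
            math.cos(inclination_deg * _DEG),
        ]
    )


def _arc_points(p_left: np.ndarray, p_mid: np.ndarray, p_right: np.ndarray,
                fractions: np.ndarray) -> np.ndarray:
    """Points at given arc fractions on the spherical circle through three points."""
    n = np.cross(p_right - p_left, p_mid - p_left)
    n = n / np.linalg.norm(n)
    d = float(p_left @ n)
    centre = d * n
    u = p_left - centre
    rho = np.linalg.norm(u)
    u = u / rho
    w = np.cross(n, u)
    if (p_mid - centre) @ w < 0:  # orient the arc to pass through the midpoint
        w = -w
    a_right = math.atan2(float((p_right - centre) @ w), float((p_right - centre) @ u))
    if a_right <= 0:
        a_right += 2.0 * math.pi
    ang = fractions * a_right
    return centre + rho * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * w)


def _build_unit_positions() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    for label, az in _RING:
        pos[label] = _unit(72.0, az)
    for label, incl, az in _MIDLINE:
        pos[label] = _unit(incl, az)
    for label, incl, az in _LOWER:
        pos[label] = _unit(incl, az)
    for labels, mid in _ROWS.values():
        left, right = pos[labels[0]], pos[labels[-1]]
        fracs = np.linspace(0.0, 1.0, len(labels))
        pts = _arc_points(left, pos[mid], right, fracs)
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        for lab, p in zip(labels, pts):
            pos[lab] = p
    return pos


_UNIT_POSITIONS = _build_unit_positions()
_CANONICAL = {k.lower(): k for k in _UNIT_POSITIONS}


def make_montage(labels, radius_mm: float = 85.0) -> list[Electrode]:
    """Electrodes at idealized 10-10 positions scaled to ``radius_mm``.

    Labels are matched case-insensitively against the supported 10-10 set;
    duplicates and unknown labels raise ``ValueError``.
    """
    seen: set[str] = set()
    out: list[Electrode] = []
    for label in labels:
        key = str(label).lower()
        if key not in _CANONICAL:
            raise ValueError(f"unknown 10-10 electrode label: {label!r}")
        canon = _CANONICAL[key]
        if canon in seen:
            raise ValueError(f"duplicate electrode label: {label!r}")
        seen.add(canon)
        out.append(Electrode(canon, radius_mm * _UNIT_POSITIONS[canon]))
    return out


def standard_62_montage(radius_mm: float = 85.0) -> list[Electrode]:
    """The canonical 62-channel montage used throughout the analyses."""
    return make_montage(MONTAGE_62, radius_mm)


def electrode_array(electrodes) -> np.ndarray:
    """Stack electrode positions into an (n, 3) array (mm)."""
    return np.stack([e.position for e in electrodes])


def save_electrodes(path, electrodes) -> None:
    """Write a tab-separated electrode file: label, x_mm, y_mm, z_mm."""
    lines = ["label\tx_mm\ty_mm\tz_mm"]
    for e in electrodes:
        x, y, z = e.position
        lines.append(f"{e.label}\t{x:.12g}\t{y:.12g}\t{z:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_electrodes(path) -> list[Electrode]:
    """Read a tab-separated electrode file written by :func:`save_electrodes`."""
    text = Path(path).read_text().strip().splitlines()
    out = []
    for line in text[1:]:
        label, x, y, z = line.split("\t")
        out.append(Electrode(label, np.array([float(x), float(y), float(z)])))
    return out


def packaged_62_montage() -> list[Electrode]:
    """The 62-channel montage fixture shipped with the package (radius 85 mm)."""
    with resources.as_file(resources.files("icpolarity.data") / "montage_62.tsv") as p:
        return load_electrodes(p)


# ---------------------------------------------------------------------------
# Forward solution
# ---------------------------------------------------------------------------

def leadfield_batch(positions_mm: np.ndarray, electrodes, head_model: HeadModel,
                    average_reference: bool = False) -> np.ndarray:
    """Leadfields for a batch of dipole positions.

    Returns an array of shape ``(n_positions, n_electrodes, 3)`` in volts per
    nA*m of moment along each Cartesian axis.
    """
    hm = head_model
    r0 = np.atleast_2d(np.asarray(positions_mm, dtype=float)) * 1e-3  # m
    R = hm.radius_mm * 1e-3
    b = np.linalg.norm(r0, axis=1)
    if np.any(b >= R):
        raise ValueError("dipole position outside the conducting sphere (|r0| >= R)")
    epos = electrode_array(electrodes) * 1e-3
    er = np.linalg.norm(epos, axis=1)
    e_hat = epos / er[:, None]

    # Radial unit vector of each dipole; arbitrary (z) at the origin, where the
    # combination below is independent of the choice.
    safe_b = np.where(b > 0, b, 1.0)
    r0_hat = np.where((b > 0)[:, None], r0 / safe_b[:, None], [0.0, 0.0, 1.0])
    f = b / R  # eccentricity
    x = r0_hat @ e_hat.T  # (k, n) cos(gamma)

    # Accumulate A = sum c_n f^(n-1) n P_n(x), B = sum c_n f^(n-1) P_n'(x)
    # with c_n = (2n+1)/n; recurrences for P_n and P_n'.
    p_prev = np.ones_like(x)       # P_0
    p_cur = x.copy()               # P_1
    pd_prev = np.zeros_like(x)     # P_0'
    pd_cur = np.ones_like(x)       # P_1'
    fpow = np.ones_like(f)         # f^(n-1), n = 1  (0**0 -> 1)
    a_sum = 3.0 * fpow[:, None] * p_cur
    b_sum = 3.0 * fpow[:, None] * pd_cur
    for n in range(2, hm.n_terms + 1):
        p_next = ((2 * n - 1) * x * p_cur - (n - 1) * p_prev) / n
        pd_next = pd_prev + (2 * n - 1) * p_cur
        fpow = fpow * f
        c = (2 * n + 1) / n
        a_sum += c * n * fpow[:, None] * p_next
        b_sum += c * fpow[:, None] * pd_next
        p_prev, p_cur = p_cur, p_next
        pd_prev, pd_cur = pd_cur, pd_next

    scale = 1e-9 / (4.0 * math.pi * hm.conductivity_sm * R * R)  # V per nA*m
    # L[k, e, j] = scale * (pr_j A + (e_hat[e, j] - pr_j x) B), pr_j = r0_hat[k, j]
    lf = scale * (
        r0_hat[:, None, :] * a_sum[:, :, None]
        + (e_hat[None, :, :] - r0_hat[:, None, :] * x[:, :, None]) * b_sum[:, :, None]
    )
    if average_reference:
        lf = lf - lf.mean(axis=1, keepdims=True)
    return lf


def leadfield(position_mm, electrodes, head_model: HeadModel,
              average_reference: bool = False) -> np.ndarray:
    """(n_electrodes, 3) leadfield at one dipole position, volts per nA*m."""
    return leadfield_batch(np.asarray(position_mm, dtype=float)[None, :],
                           electrodes, head_model, average_reference)[0]


def dipole_potential(dipole: Dipole, electrodes, head_model: HeadModel,
                     average_reference: bool = False) -> np.ndarray:
    """Surface potential (volts) of a dipole at each electrode.

    Linear in the moment; at the origin it equals the central closed form
    ``3 (p . r_hat) / (4 pi sigma R^2)``.
    """
    lf = leadfield(dipole.position_mm, electrodes, head_model, average_reference)
    return lf @ dipole.moment_nam
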