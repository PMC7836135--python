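"""Idealized spherical 10-20 montage for 32 scalp channels plus mastoids.

Electrode positions are generated on the unit sphere from the nominal 10-20
construction rather than loaded from a vendor file: midline and circumferential
sites sit at their textbook azimuths on the 90-degree inclination ring,
intermediate sites are great-circle midpoints of their flanking named sites,
and the inferior ring (FT9/FT10, PO9/PO10, mastoids) sits below the equator.
Real caps deviate from a sphere; only the relative geometry matters here, since
it drives the spherical-spline Laplacian and topographic export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "make_montage", "SCALP_LABELS", "MASTOID_LABELS"]

#: 32 scalp channels of the extended 10-20 layout used for analysis.
SCALP_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT9", "FC5", "FC1", "FC2", "FC6", "FT10",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)

#: Mastoid reference channels recorded alongside the scalp set.
MASTOID_LABELS: tuple[str, ...] = ("M1", "M2")


def _sph(incl_deg: float, az_deg: float) -> np.ndarray:
    """Unit vector from inclination (angle from vertex Cz) and azimuth.

    Azimuth is measured counterclockwise from the right ear (+x); the front of
    the head is +y (azimuth 90), the back is azimuth 270.
    """
    incl = np.deg2rad(incl_deg)
    az = np.deg2rad(az_deg)
    return np.array(
        [np.sin(incl) * np.cos(az), np.sin(incl) * np.sin(az), np.cos(incl)]
    )


def _slerp(a: np.ndarray, b: np.ndarray, t: float = 0.5) -> np.ndarray:
    """Point at fraction ``t`` along the great-circle arc from ``a`` to ``b``."""
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-12:
        return a.copy()
    return (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / np.sin(omega)


def _ideal_positions() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    # Vertex and midline (front azimuth 90, back 270).
    pos["Cz"] = _sph(0, 0)
    pos["Fz"] = _sph(45, 90)
    pos["Pz"] = _sph(45, 270)
    pos["Oz"] = _sph(90, 270)
    # Circumferential ring: 10-20 spacing in 18-degree (5%) steps.
    pos["Fp1"] = _sph(90, 108)
    pos["Fp2"] = _sph(90, 72)
    pos["F7"] = _sph(90, 144)
    pos["F8"] = _sph(90, 36)
    pos["T7"] = _sph(90, 180)
    pos["T8"] = _sph(90, 0)
    pos["P7"] = _sph(90, 216)
    pos["P8"] = _sph(90, 324)
    pos["O1"] = _sph(90, 252)
    pos["O2"] = _sph(90, 288)
    # Coronal arc through the vertex.
    pos["C3"] = _sph(45, 180)
    pos["C4"] = _sph(45, 0)
    # Intermediate sites: great-circle midpoints of flanking named sites.
    pos["F3"] = _slerp(pos["Fz"], pos["F7"])
    pos["F4"] = _slerp(pos["Fz"], pos["F8"])
    pos["P3"] = _slerp(pos["Pz"], pos["P7"])
    pos["P4"] = _slerp(pos["Pz"], pos["P8"])
    pos["FC1"] = _slerp(pos["Fz"], pos["C3"])
    pos["FC2"] = _slerp(pos["Fz"], pos["C4"])
    pos["FC5"] = _slerp(pos["F7"], pos["C3"])
    pos["FC6"] = _slerp(pos["F8"], pos["C4"])
    pos["CP1"] = _slerp(pos["Pz"], pos["C3"])
    pos["CP2"] = _slerp(pos["Pz"], pos["C4"])
    pos["CP5"] = _slerp(pos["P7"], pos["C3"])
    pos["CP6"] = _slerp(pos["P8"], pos["C4"])
    # Inferior ring, 18 degrees below the equator.
    pos["FT9"] = _sph(108, 162)
    pos["FT10"] = _sph(108, 18)
    pos["PO9"] = _sph(108, 234)
    pos["PO10"] = _sph(108, 306)
    # Mastoids behind/below the ears.
    pos["M1"] = _sph(115, 200)
    pos["M2"] = _sph(115, 340)
    return pos


@dataclass(frozen=True)
class Montage:
    """Scalp electrode layout on the unit sphere.

    Parameters
    ----------
    labels
        Ordered channel names (the analysis set; mastoids excluded).
    positions
        ``(n, 3)`` unit vectors, one row per label.
    a_priori_channel
        The hypothesis-bearing channel reported without FDR adjustment
        (``Oz`` over primary visual cortex by default).
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    a_priori_channel: str = "Oz"
    mastoid_positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("electrode positions must lie on the unit sphere")
        if self.a_priori_channel not in self.labels:
            raise ValueError(f"a priori channel {self.a_priori_channel!r} not in montage")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def cosine_distances(self) -> np.ndarray:
        """Matrix of cos(angular distance) between all electrode pairs."""
        return np.clip(self.positions @ self.positions.T, -1.0, 1.0)

    def angular_distance_from(self, label: str) -> np.ndarray:
        """Angular distance (radians) of every channel from ``label``."""
        ref = self.positions[self.index(label)]
        return np.arccos(np.clip(self.positions @ ref, -1.0, 1.0))


def make_montage(a_priori_channel: str = "Oz") -> Montage:
    """Build the idealized 32-channel 10-20 montage."""
    pos = _ideal_positions()
    positions = np.stack([pos[lab] for lab in SCALP_LABELS])
    mastoids = {lab: pos[lab] for lab in MASTOID_LABELS}
    return Montage(
        labels=SCALP_LABELS,
        positions=positions,
        a_priori_channel=a_priori_channel,
        mastoid_positions=mastoids,
    )
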