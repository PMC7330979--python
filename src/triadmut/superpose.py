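"""Rigid-body least-squares superposition (Kabsch) and triad-pair RMSD.

RMSD is the usual root-mean-square deviation over an established one-to-one
atom correspondence,

    RMSD = sqrt( (1/N) * sum_i |delta_i|^2 ),

minimized over all proper rotations and translations.  A sign-corrected SVD
solution (det = +1 enforced) guards against mirror-image superpositions,
which are chemically invalid.

Triad pairs are compared over a fixed 24-atom main-chain correspondence:
residues (n-1, n, n+1, n'-1, n', n'+1), atoms (N, CA, C, O) within each.
Because the two residues of an interaction are unordered, both the direct
and the swapped pairing of the target pair onto the template are evaluated
and the minimum-RMSD pairing is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError

PAIRING_DIRECT = "direct"
PAIRING_SWAPPED = "swapped"


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation (proper rotation, det = +1)."""
    rotation: np.ndarray    # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)


def _check_conditioning(coords: np.ndarray, label: str) -> None:
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] == 0.0 or s[1] / s[0] < 1e-8:
        raise DegenerateGeometryError(
            f"{label} point set is collinear/degenerate; rotation is underdetermined")


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray):
    """Optimal rigid superposition of ``moving`` onto ``fixed``.

    Returns ``(RigidTransform, rmsd)`` where the transform maps moving
    coordinates into the fixed frame and the RMSD is the global minimum
    over all proper rigid motions.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise DegenerateGeometryError("coordinate sets must both be N x 3")
    n = moving.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 points, got {n}")
    _check_conditioning(moving, "moving")
    _check_conditioning(fixed, "fixed")

    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = fc - rot @ mc
    tf = RigidTransform(rotation=rot, translation=trans)
    delta = tf.apply(moving) - fixed
    rmsd = float(np.sqrt((delta ** 2).sum() / n))
    return tf, rmsd


def _swap_blocks(coords24: np.ndarray) -> np.ndarray:
    """Exchange the two 12-atom triad blocks of a 24-atom correspondence."""
    return np.vstack([coords24[12:], coords24[:12]])


def triad_rmsd(target, template):
    """Minimum main-chain RMSD between two triad pairs.

    Both pairings of the target pair onto the template pair (n, n') are
    evaluated.  Returns ``(rmsd, transform, pairing)`` where the transform
    maps *template* coordinates into the target frame under the winning
    pairing (``"direct"``: target first site corresponds to template n;
    ``"swapped"``: target first site corresponds to template n').
    """
    tgt = target.backbone_coords
    tpl = template.backbone_coords
    tf_d, r_d = kabsch_superpose(tpl, tgt)
    tf_s, r_s = kabsch_superpose(tpl, _swap_blocks(tgt))
    if r_s < r_d:
        # template n block lands on the target's second site
        return r_s, tf_s, PAIRING_SWAPPED
    return r_d, tf_d, PAIRING_DIRECT
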