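"""Kabsch superposition and RMSD."""

from __future__ import annotations

import numpy as np

from ..errors import PepmpcError


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal least-squares rotation/translation of ``mobile`` onto
    ``target``.  Returns (rotation matrix, translation) such that
    ``mobile @ R.T + t`` superposes onto ``target``."""
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise PepmpcError("coordinate sets must share shape (n, 3)")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def rmsd(frame_A, frame_B, superpose: bool = False) -> float:
    """Root-mean-square deviation between two equal-size bead sets.

    With ``superpose=True`` the optimal rigid transform (Kabsch) is
    applied to ``frame_A`` first.  Units follow the inputs.
    """
    A = np.asarray(frame_A, float)
    B = np.asarray(frame_B, float)
    if A.shape != B.shape:
        raise PepmpcError("bead counts must match")
    if superpose:
        R, t = kabsch(A, B)
        A = A @ R.T + t
    d = A - B
    return float(np.sqrt(np.einsum("ij,ij->", d, d) / A.shape[0]))
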