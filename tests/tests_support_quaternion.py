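"""Independent quaternion-eigenvalue RMSD oracle (Horn's method)."""

import math

import numpy as np


def quaternion_rmsd(A, B):
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    S = A.T @ B
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = float(np.linalg.eigvalsh(K).max())
    e0 = float((A**2).sum() + (B**2).sum())
    return math.sqrt(max(0.0, (e0 - 2.0 * lam) / A.shape[0]))
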