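"""Native-contact (Go-style) analysis on C-alpha beads."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ..errors import PepmpcError
from ..units import NM_PER_A


@dataclass
class NativeContactMap:
    """Native C-alpha contact pairs and per-frame fraction Q.

    ``pairs`` holds 1-based residue index tuples (i < j); ``q`` is the
    per-frame fraction of native pairs within ``tolerance * cutoff``.
    """

    reference_frame: int
    pairs: list
    cutoff: float          # A
    seq_sep: int
    tolerance: float
    q: np.ndarray


def native_contact_map(reference, traj_frames, cutoff: float = 6.5,
                       seq_sep: int = 3, tolerance: float = 1.2,
                       reference_frame: int = 0) -> NativeContactMap:
    """Build a native contact map from a reference conformation.

    ``reference`` is the (n_res, 3) C-alpha coordinate array (nm) of the
    native structure; ``traj_frames`` an (n_frames, n_res, 3) array with
    the same topology.  Native pairs are residue pairs with
    ``|i - j| >= seq_sep`` and reference distance <= ``cutoff`` (A);
    Q(frame) counts the fraction within ``tolerance * cutoff``.
    """
    if seq_sep < 1:
        raise PepmpcError("seq_sep must be >= 1")
    ref = np.asarray(reference, float)
    frames = np.asarray(traj_frames, float)
    if frames.ndim == 2:
        frames = frames[None, ...]
    if ref.shape[0] != frames.shape[1]:
        raise PepmpcError("reference and trajectory topologies differ")
    n = ref.shape[0]
    cutoff_nm = cutoff * NM_PER_A
    dref = squareform(pdist(ref))
    ii, jj = np.triu_indices(n, k=seq_sep)
    native = dref[ii, jj] <= cutoff_nm
    pairs = [(int(i) + 1, int(j) + 1)
             for i, j in zip(ii[native], jj[native])]
    if pairs:
        pi = ii[native]
        pj = jj[native]
        d = np.linalg.norm(frames[:, pi, :] - frames[:, pj, :], axis=-1)
        q = (d <= tolerance * cutoff_nm).mean(axis=1)
    else:
        q = np.zeros(frames.shape[0])
    return NativeContactMap(reference_frame=reference_frame, pairs=pairs,
                            cutoff=cutoff, seq_sep=seq_sep,
                            tolerance=tolerance, q=q)
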