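"""Group-wise landmark similarity.

Combines the short-range feature G (normalized geodesic distance) and the
long-range feature P (normalized, histogram-equalized hop counts) across
subjects into a single distance

    D = alpha * G + (1 - alpha) * P,   alpha in [0, 1] (default 0.5),

with G the subject mean of G_n / max(G_n) and P the subject mean of
histEq(P_n / max(P_n)).  Hop counts concentrate on a few small integers, so
they are histogram-equalized (empirical-CDF mapped) per subject to spread
them over (0, 1] before averaging.  The affinity graph fed to the spectral
clustering is the Gaussian kernel W(delta) = exp(-D^2 / (2 delta^2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GroupFeature", "histogram_equalize", "group_features", "affinity"]


@dataclass
class GroupFeature:
    """Averaged, normalized landmark features and their combination."""

    G: np.ndarray
    P: np.ndarray
    D: np.ndarray
    alpha: float
    n_subjects: int

    @property
    def consistency_matrix(self) -> np.ndarray:
        """The balanced combination 0.5*G + 0.5*P used as a consistency measure."""
        return 0.5 * self.G + 0.5 * self.P


def histogram_equalize(values: np.ndarray) -> np.ndarray:
    """Empirical-CDF mapping of a collection of numbers onto (0, 1].

    Each value x maps to F(x) = #{y <= x} / m over the input collection;
    the map is order-preserving and ties map equal.  A point mass maps to 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("histogram_equalize requires a nonempty collection")
    flat = v.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_v = flat[order]
    # rank of the last occurrence of each value = #{y <= x}
    counts = np.searchsorted(sorted_v, flat, side="right")
    return (counts / flat.size).reshape(v.shape)


def group_features(G_list, P_list, alpha: float = 0.5) -> GroupFeature:
    """Average the per-subject features into the combined group distance.

    ``G_list`` holds per-subject geodesic matrices (mm), ``P_list`` the hop
    matrices.  Each G_n is scaled by its own max; each P_n is scaled by its
    max and histogram-equalized over the off-diagonal entries.  Diagonals are
    forced to zero throughout.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if len(G_list) == 0 or len(P_list) == 0:
        raise ValueError("at least one subject is required")
    if len(G_list) != len(P_list):
        raise ValueError("G and P subject counts differ")
    L = np.asarray(G_list[0]).shape[0]
    off = ~np.eye(L, dtype=bool)

    G_acc = np.zeros((L, L))
    P_acc = np.zeros((L, L))
    for G_n, P_n in zip(G_list, P_list):
        G_n = np.asarray(G_n, dtype=float)
        P_n = np.asarray(P_n, dtype=float)
        if G_n.shape != (L, L) or P_n.shape != (L, L):
            raise ValueError("all subjects must share the same landmark count and order")
        g_max = G_n.max()
        if g_max <= 0:
            raise ValueError("degenerate subject: all-zero geodesic matrix")
        G_acc += G_n / g_max
        p_max = P_n.max()
        Pn_norm = P_n / p_max if p_max > 0 else P_n.astype(float)
        eq = np.zeros_like(Pn_norm)
        eq[off] = histogram_equalize(Pn_norm[off])
        P_acc += eq
    N = len(G_list)
    G = G_acc / N
    P = P_acc / N
    np.fill_diagonal(G, 0.0)
    np.fill_diagonal(P, 0.0)
    D = alpha * G + (1.0 - alpha) * P
    return GroupFeature(G=G, P=P, D=D, alpha=float(alpha), n_subjects=N)


def affinity(D: np.ndarray, delta: float, kernel_denominator: str = "2dd") -> np.ndarray:
    """Gaussian affinity W(delta) of the combined distance.

    ``kernel_denominator`` selects exp(-D^2/(2 delta^2)) (``"2dd"``, the
    standard Gaussian, default) or exp(-D^2/delta^2) (``"dd"``); both readings
    of the kernel are monotone reparameterizations of one another.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    D = np.asarray(D, dtype=float)
    denom = 2.0 * delta**2 if kernel_denominator == "2dd" else delta**2
    if kernel_denominator not in ("2dd", "dd"):
        raise ValueError("kernel_denominator must be '2dd' or 'dd'")
    W = np.exp(-(D**2) / denom)
    np.fill_diagonal(W, 1.0)
    return W
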