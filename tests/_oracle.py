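"""Brute-force oracles used to validate the MCMC sampler on tiny instances.

Everything here is deliberately independent of the sampler implementation:
likelihoods are assembled from explicit loops over grid cells, inclusion
configurations, and record allocations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from gensmr.geometry import StateSpace


def tiny_posterior_N(
    state_space: StateSpace,
    cam_coords: np.ndarray,
    E_R: np.ndarray,  # (J_R,) exposure occasions per camera (augmented row)
    live_coords: np.ndarray | None,
    E_M: np.ndarray | None,  # (J_M,) marking exposure per live trap
    marked_y_mark: np.ndarray | None,  # (J_M,) marking counts of the one marked ind.
    marked_y_res: np.ndarray | None,  # (J_R,) resight counts of the marked ind.
    records: list[int],  # camera index per unmarked record (distinct occasions)
    n_aug: int,
    lam0_m: float,
    lam0_r: float,
    sigma_d: float,
    psi: float,
    grid: int = 15,
) -> np.ndarray:
    """Exact posterior P(N = k) by enumeration.

    The activity-center integral over the rectangular state space is
    approximated by a midpoint rule on a ``grid x grid`` lattice — the same
    approximation for every configuration, so the normalized posterior is
    exact up to quadrature error.  Records are single detections at distinct
    (camera, occasion) cells, so occasion-level factorials reduce to
    ``1/y!`` per owned multiset computed explicitly below.

    Returns an array p of length ``n_marked + n_aug + 1`` with p[k] = P(N=k).
    """
    xs = np.linspace(state_space.xmin, state_space.xmax, 2 * grid + 1)[1::2]
    ys = np.linspace(state_space.ymin, state_space.ymax, 2 * grid + 1)[1::2]
    cells = np.array([(x, y) for x in xs for y in ys])

    def rates(coords, lam0):
        d2 = ((cells[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        return lam0 * np.exp(-d2 / (2.0 * sigma_d**2))

    lamR = rates(cam_coords, lam0_r)  # (G, J_R)
    hM = rates(live_coords, lam0_m) if live_coords is not None else None

    n_marked = 1 if marked_y_res is not None else 0

    def marked_integral() -> float:
        if n_marked == 0:
            return 1.0
        ll = np.zeros(cells.shape[0])
        # binomial marking for the marked individual
        if hM is not None:
            p_mat = -np.expm1(-hM)
            for j in range(hM.shape[1]):
                y, n = marked_y_mark[j], E_M[j]
                ll += (
                    np.log(math.comb(int(n), int(y)))
                    + y * np.log(np.maximum(p_mat[:, j], 1e-300))
                    - (n - y) * hM[:, j]
                )
        for j in range(lamR.shape[1]):
            mu = E_R[j] * lamR[:, j]
            y = marked_y_res[j]
            ll += y * np.log(np.maximum(mu, 1e-300)) - mu - math.lgamma(y + 1)
        return float(np.exp(ll).mean())

    # augmented rows are exchangeable: the grid-averaged likelihood depends
    # only on the multiset of owned records (here: the owned camera list)
    def aug_integral(owned: tuple[int, ...]) -> float:
        ll = -(E_R[None, :] * lamR).sum(axis=1)  # zero-count likelihood
        if hM is not None:
            ll = ll - (E_M[None, :] * hM).sum(axis=1)
        for j in owned:
            ll = ll + np.log(np.maximum(lamR[:, j], 1e-300))
        return float(np.exp(ll).mean())

    g_cache: dict[tuple[int, ...], float] = {}

    def g(owned: tuple[int, ...]) -> float:
        key = tuple(sorted(owned))
        if key not in g_cache:
            g_cache[key] = aug_integral(key)
        return g_cache[key]

    G_marked = marked_integral()
    R = len(records)
    p_n = np.zeros(n_marked + n_aug + 1)
    for z in itertools.product((0, 1), repeat=n_aug):
        nz = sum(z)
        included = [i for i, zi in enumerate(z) if zi]
        w_z = psi**nz * (1 - psi) ** (n_aug - nz)
        if R > 0 and nz == 0:
            continue  # records need an owner
        total = 0.0
        for alloc in itertools.product(included, repeat=R) if R else [()]:
            prod = 1.0
            for i in included:
                owned = tuple(records[r] for r in range(R) if alloc[r] == i)
                prod *= g(owned)
            total += prod
        p_n[n_marked + nz] += w_z * total * G_marked
    return p_n / p_n.sum()


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    n = max(len(p), len(q))
    p = np.pad(np.asarray(p, float), (0, n - len(p)))
    q = np.pad(np.asarray(q, float), (0, n - len(q)))
    return 0.5 * float(np.abs(p - q).sum())
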