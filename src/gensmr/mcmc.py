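"""Metropolis-within-Gibbs sampling for spatial mark-resight models.

One sampler covers the whole model family: generalized SMR (marking process
modeled) and conventional SMR, with or without telemetry, one-time activity
center transiency, the sex partial-identity constraint, and sex-specific
detection parameters.  A null spatial capture-recapture fit (all identities
known) is the degenerate case with no identity-free records and no marking
process; :func:`fit_null_scr` wraps it.

Update blocks per sweep:

1. detection parameters — random-walk Metropolis on the log scale (baseline
   rates use an exact multiplicative shortcut: scaling ``lam0`` scales every
   rate, so the likelihood delta needs only per-row totals),
2. transiency scale ``sigma_t`` — log random-walk, plus a joint rescaling
   move that carries the resighting centers of data-free individuals along
   with ``sigma_t`` (a deterministic-map proposal with the exact Jacobian;
   this is what keeps the notoriously slow-mixing transiency scale moving),
3. activity centers — per-individual bivariate random walks, vectorized
   across individuals (the likelihood factorizes over individuals given the
   parameters); excluded individuals are redrawn from their prior,
4. latent identity allocation — per-record reassignment among eligible
   individuals (included, unmarked-and-alive at the record's occasion,
   sex-compatible), accepted by the Poisson likelihood ratio,
5. sexes of individuals without a directly observed sex — Gibbs,
6. ``p_sex`` and inclusion (``z``/``psi``) — conjugate Gibbs.

Distance and rate matrices are cached and updated incrementally; with
``audit`` on, every retained draw re-derives them from scratch and checks
the latent-state invariants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .data import SMRData
from .geometry import StateSpace, TrapArray, build_exposure, make_state_space
from .model import ModelSpec, Parameters
from .simulate import truncated_normal_rect

__all__ = ["MCMCConfig", "Chains", "run_mcmc", "fit_null_scr"]

_LOG_2PI = float(np.log(2.0 * np.pi))
_TINY = 1e-300


@dataclass
class MCMCConfig:
    """Run-length, proposal, and prior-bound settings.

    Flat priors: ``lam0 ~ U(0, lam0_max)``, ``sigma_d ~ U(0, sigma_d_max)``,
    ``sigma_t ~ U(0, sigma_t_max)``, ``psi, p_sex ~ Beta(1, 1)``.  Proposal
    scales adapt during burn-in (targeting ~30-35% acceptance) and are then
    frozen.  ``fix_detection``/``fix_psi`` freeze those parameters at their
    initial values (used for validation against enumeration oracles).
    """

    n_iter: int = 20000
    burn_in: int = 2000
    thin: int = 5
    seed: int = 0
    A: Optional[int] = None  # overrides ModelSpec.A when set
    buffer_km: float = 25.0
    prop_s_km: Optional[float] = None  # default: sigma_d initial value
    prop_log_rate: float = 0.35
    prop_log_sigma: float = 0.15
    prop_log_sigma_t: float = 0.3
    adapt: bool = True
    audit: bool = False
    fix_detection: bool = False
    fix_psi: bool = False
    init: Optional[Parameters] = None
    lam0_max: float = 10.0
    sigma_d_max: float = 50.0
    sigma_t_max: float = 100.0
    joint_sigma_t_move: bool = True
    track_latent: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def replace(self, **kwargs) -> "MCMCConfig":
        return MCMCConfig(**{**self.__dict__, **kwargs})


@dataclass
class Chains:
    """Retained posterior draws plus run metadata.

    ``draws`` maps parameter names to 1-D arrays of equal length; ``D`` is
    density per 100 km^2 (``100 * N / area`` exactly, every draw), ``n_um``
    the number of distinct individuals owning at least one unmarked record.
    """

    draws: dict[str, np.ndarray]
    area: float
    acceptance: dict[str, float]
    seed: int
    latent: Optional[dict[str, np.ndarray]] = None

    def __getitem__(self, key: str) -> np.ndarray:
        return self.draws[key]

    def __contains__(self, key: str) -> bool:
        return key in self.draws

    @property
    def n_draws(self) -> int:
        return len(next(iter(self.draws.values())))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws)


class _Sampler:
    def __init__(
        self,
        data: SMRData,
        spec: ModelSpec,
        config: MCMCConfig,
        state_space: StateSpace | None = None,
    ) -> None:
        self.data = data
        self.spec = spec
        self.config = config
        self.rng = np.random.default_rng(config.seed)

        self.use_marking = bool(spec.generalized and data.live is not None)
        if spec.generalized and data.live is None and data.y_mark is not None:
            raise ValueError("generalized model requires a live-trap array")
        self.single = not spec.use_transience

        if state_space is not None:
            self.ss = state_space
        elif self.use_marking:
            self.ss = make_state_space([data.live, data.cameras], config.buffer_km)
        else:
            self.ss = make_state_space(data.cameras, config.buffer_km)
        self._lo = np.array([self.ss.xmin, self.ss.ymin])
        self._hi = np.array([self.ss.xmax, self.ss.ymax])

        self.A = int(config.A or spec.A)
        self.n_M = data.n_marked
        rec = data.unmarked
        self.R = len(rec)
        if self.A < self.n_M + self.R:
            raise ValueError(
                f"augmentation size A={self.A} below n_marked + n_records "
                f"= {self.n_M + self.R}"
            )

        self.XR = data.cameras.coords
        self.ER = data.exposure.expand_E_R(self.A)
        self.yR_known = np.zeros((self.A, data.cameras.n_traps))
        self.yR_known[: self.n_M] = data.y_resight_marked_summed()
        self._yk_rows, self._yk_cols = np.nonzero(self.yR_known)
        self._yk_vals = self.yR_known[self._yk_rows, self._yk_cols]
        if self.use_marking:
            self.XM = data.live.coords
            self.EM = data.exposure.expand_E_M(self.A)
            self.yM = np.zeros((self.A, data.live.n_traps))
            self.yM[: self.n_M] = data.y_mark if data.y_mark is not None else 0
            self.yM_nz = np.nonzero(self.yM)
        else:
            self.XM = self.EM = self.yM = self.yM_nz = None

        # unmarked records and their (trap, occasion) cells
        self.rec_trap = rec["trap"].to_numpy(dtype=int) if self.R else np.empty(0, int)
        self.rec_occ = rec["occasion"].to_numpy(dtype=int) if self.R else np.empty(0, int)
        if spec.use_sex_constraint and self.R:
            self.rec_sex = rec["obs_sex"].to_numpy(dtype=int)
        else:
            self.rec_sex = -np.ones(self.R, dtype=int)
        cell_key = self.rec_trap * 10000 + self.rec_occ
        _, self.cell_of = np.unique(cell_key, return_inverse=True)
        self.n_cells = int(self.cell_of.max()) + 1 if self.R else 0

        # eligibility by mark-status phase: marked rows only while their code
        # is 0 (not yet marked); augmented rows always (alive by construction)
        self.phase_ok = np.ones((self.A, self.R), dtype=bool)
        if self.R and self.n_M:
            m = data.exposure.m
            self.phase_ok[: self.n_M] = m[:, self.rec_occ - 1] == 0

        # telemetry sufficient statistics per row
        self.tel_n = np.zeros(self.A)
        self.tel_sx = np.zeros(self.A)
        self.tel_sy = np.zeros(self.A)
        self.tel_ss = np.zeros(self.A)
        if spec.use_telemetry:
            for i, locs in enumerate(data.telemetry):
                locs = np.atleast_2d(locs)
                if locs.size == 0:
                    continue
                xy = locs[:, 1:3]
                self.tel_n[i] = xy.shape[0]
                self.tel_sx[i] = xy[:, 0].sum()
                self.tel_sy[i] = xy[:, 1].sum()
                self.tel_ss[i] = float((xy**2).sum())
        self.has_tel = self.tel_n > 0

        self._init_state()
        self._refresh_rates()
        self._init_proposals()
        self.acc = {k: [0, 0] for k in ("lam0_m", "lam0_r", "sigma_d", "sigma_t",
                                        "sigma_t_joint", "s_M", "s_R", "alloc")}

    # ------------------------------------------------------------------ init

    def _init_state(self) -> None:
        rng, A, n_M = self.rng, self.A, self.n_M
        cfg, data = self.config, self.data

        init = cfg.init
        if init is not None:
            self.lam0m = float(init.lam0_m)
            self.lam0r = init.lam0_r_pair.copy()
            self.sigd = init.sigma_d_pair.copy()
            self.sigt = float(init.sigma_t) if not self.single else 0.0
            self.psi = float(init.psi)
            self.p_sex = float(init.p_sex)
        else:
            sig0 = self._telemetry_sd()
            if sig0 is None:
                ext = min(self.ss.xmax - self.ss.xmin, self.ss.ymax - self.ss.ymin)
                sig0 = 0.08 * ext
            self.lam0m = 0.01
            self.lam0r = np.array([0.05, 0.05])
            self.sigd = np.array([sig0, sig0])
            self.sigt = max(sig0, 1.0)
            self.psi = float(np.clip(2.0 * (n_M + self.R) / A, 0.1, 0.9))
            self.p_sex = 0.5
        if self.single:
            self.sigt = 0.0

        # activity centers: observed individuals start at the centroid of
        # their detections/telemetry, augmented rows uniform
        self.sM = rng.uniform(self._lo, self._hi, size=(A, 2))
        for i in range(n_M):
            pts = []
            if self.use_marking and self.yM[i].sum() > 0:
                w = self.yM[i]
                pts.append((self.XM * w[:, None]).sum(0) / w.sum())
            if self.has_tel[i]:
                pts.append(np.array([self.tel_sx[i], self.tel_sy[i]]) / self.tel_n[i])
            if self.yR_known[i].sum() > 0:
                w = self.yR_known[i]
                pts.append((self.XR * w[:, None]).sum(0) / w.sum())
            if pts:
                self.sM[i] = np.mean(pts, axis=0)
        self.sM = np.clip(self.sM, self._lo, self._hi)
        if self.single:
            self.sR = self.sM  # same object: one center per individual
        else:
            self.sR = self.sM.copy()
            for i in range(n_M):
                if self.has_tel[i]:
                    self.sR[i] = np.array([self.tel_sx[i], self.tel_sy[i]]) / self.tel_n[i]
            self.sR = np.clip(self.sR, self._lo, self._hi)

        # sexes, allocation, inclusion
        self.sex = (rng.random(A) < 0.5).astype(int)
        self.sex[:n_M] = data.marked_sex
        self.alloc = np.arange(n_M, n_M + self.R)
        self.owned_n = np.zeros(A, dtype=int)
        self.owned_f = np.zeros(A, dtype=int)
        self.owned_m = np.zeros(A, dtype=int)
        self.y_cell = np.zeros((A, self.n_cells), dtype=int)
        self.yR_alloc = np.zeros_like(self.yR_known)
        for r in range(self.R):
            i = self.alloc[r]
            if self.rec_sex[r] >= 0:
                self.sex[i] = self.rec_sex[r]
            self._attach(r, i)
        self.z = rng.random(A) < self.psi
        self.z[:n_M] = True
        self.z[self.owned_n > 0] = True

    def _telemetry_sd(self) -> float | None:
        """Pooled per-axis sd of telemetry about per-individual means."""
        num, dof = 0.0, 0.0
        for i in np.flatnonzero(self.tel_n > 1):
            n = self.tel_n[i]
            num += self.tel_ss[i] - (self.tel_sx[i] ** 2 + self.tel_sy[i] ** 2) / n
            dof += 2.0 * (n - 1.0)
        if dof < 4:
            return None
        return float(np.sqrt(max(num / dof, 1e-6)))

    def _init_proposals(self) -> None:
        cfg = self.config
        self.s_scale = float(cfg.prop_s_km or max(self.sigd[0], 0.5))
        self.scale_lam = cfg.prop_log_rate
        self.scale_sig = cfg.prop_log_sigma
        self.scale_sigt = cfg.prop_log_sigma_t

    # ------------------------------------------------------- rate caches

    def _sig_row(self, sigd=None) -> np.ndarray:
        return (self.sigd if sigd is None else sigd)[self.sex]

    def _lamR_from(self, d2, lam0r=None, sigd=None) -> np.ndarray:
        lam0 = (self.lam0r if lam0r is None else lam0r)[self.sex]
        sig = self._sig_row(sigd)
        return lam0[:, None] * np.exp(-d2 / (2.0 * sig**2)[:, None])

    def _hM_from(self, d2, lam0m=None, sigd=None) -> np.ndarray:
        lam0 = self.lam0m if lam0m is None else lam0m
        sig = self._sig_row(sigd)
        return lam0 * np.exp(-d2 / (2.0 * sig**2)[:, None])

    @staticmethod
    def _d2(s: np.ndarray, x: np.ndarray) -> np.ndarray:
        diff = s[:, None, :] - x[None, :, :]
        return np.einsum("ijk,ijk->ij", diff, diff)

    def _refresh_rates(self, rows: np.ndarray | None = None) -> None:
        """(Re)build cached distance and rate matrices, fully or row-wise."""
        if rows is None:
            self.d2R = self._d2(self.sR, self.XR)
            self.lamR = self._lamR_from(self.d2R)
            if self.use_marking:
                self.d2M = self._d2(self.sM, self.XM)
                self.hM = self._hM_from(self.d2M)
            else:
                self.d2M = self.hM = None
            return
        idx = np.flatnonzero(rows) if rows.dtype == bool else np.asarray(rows)
        self.d2R[idx] = self._d2(self.sR[idx], self.XR)
        self.lamR[idx] = self._lam_sub(self.d2R[idx], idx)
        if self.use_marking:
            self.d2M[idx] = self._d2(self.sM[idx], self.XM)
            self.hM[idx] = self._h_sub(self.d2M[idx], idx)

    # ------------------------------------------------------- bookkeeping

    def _attach(self, r: int, i: int) -> None:
        self.alloc[r] = i
        self.owned_n[i] += 1
        if self.rec_sex[r] == 1:
            self.owned_f[i] += 1
        elif self.rec_sex[r] == 0:
            self.owned_m[i] += 1
        self.y_cell[i, self.cell_of[r]] += 1
        self.yR_alloc[i, self.rec_trap[r]] += 1

    def _detach(self, r: int) -> None:
        i = self.alloc[r]
        self.owned_n[i] -= 1
        if self.rec_sex[r] == 1:
            self.owned_f[i] -= 1
        elif self.rec_sex[r] == 0:
            self.owned_m[i] -= 1
        self.y_cell[i, self.cell_of[r]] -= 1
        self.yR_alloc[i, self.rec_trap[r]] -= 1

    # ------------------------------------------------------- likelihood rows

    def _ll_res_rows(self, lamR: np.ndarray) -> np.ndarray:
        # counts are sparse: handle y * log(lam) through the known-count
        # index lists and the current record allocation
        out = -(self.ER * lamR).sum(axis=1)
        if self._yk_rows.size:
            lg = np.log(np.maximum(lamR[self._yk_rows, self._yk_cols], _TINY))
            np.add.at(out, self._yk_rows, self._yk_vals * lg)
        if self.R:
            lg = np.log(np.maximum(lamR[self.alloc, self.rec_trap], _TINY))
            np.add.at(out, self.alloc, lg)
        return out

    def _ll_res_sub(self, lamR_sub: np.ndarray, idx: np.ndarray) -> np.ndarray:
        """Resighting log-likelihood restricted to the rows ``idx``;
        ``lamR_sub`` is the (len(idx), J_R) rate block for those rows.

        Every row holding counts (marked, or owning records) has z = 1 by
        invariant, so when ``idx`` covers the included rows the count terms
        always land inside the block.
        """
        out = -(self.ER[idx] * lamR_sub).sum(axis=1)
        pos = self._pos_of(idx)
        if self._yk_rows.size:
            p = pos[self._yk_rows]
            keep = p >= 0
            if keep.any():
                lg = np.log(np.maximum(lamR_sub[p[keep], self._yk_cols[keep]], _TINY))
                np.add.at(out, p[keep], self._yk_vals[keep] * lg)
        if self.R:
            p = pos[self.alloc]
            keep = p >= 0
            if keep.any():
                lg = np.log(np.maximum(lamR_sub[p[keep], self.rec_trap[keep]], _TINY))
                np.add.at(out, p[keep], lg)
        return out

    def _pos_of(self, idx: np.ndarray) -> np.ndarray:
        pos = np.full(self.A, -1)
        pos[idx] = np.arange(idx.size)
        return pos

    def _ll_mark_rows(self, hM: np.ndarray | None) -> np.ndarray:
        if hM is None:
            return np.zeros(self.A)
        out = -((self.EM - self.yM) * hM).sum(axis=1)
        ii, jj = self.yM_nz
        if ii.size:
            p = -np.expm1(-hM[ii, jj])
            np.add.at(out, ii, self.yM[ii, jj] * np.log(np.maximum(p, _TINY)))
        return out

    def _ll_mark_sub(self, hM_sub: np.ndarray, idx: np.ndarray) -> np.ndarray:
        out = -((self.EM - self.yM)[idx] * hM_sub).sum(axis=1)
        ii, jj = self.yM_nz
        if ii.size:
            pos = self._pos_of(idx)
            p_row = pos[ii]
            keep = p_row >= 0
            if keep.any():
                p = -np.expm1(-hM_sub[p_row[keep], jj[keep]])
                np.add.at(
                    out, p_row[keep],
                    self.yM[ii[keep], jj[keep]] * np.log(np.maximum(p, _TINY)),
                )
        return out

    def _ll_tel_sub(self, s_sub: np.ndarray, idx: np.ndarray, sigd=None) -> np.ndarray:
        out = np.zeros(idx.size)
        if not self.spec.use_telemetry:
            return out
        m = self.tel_n[idx] > 0
        if not m.any():
            return out
        sig = self._sig_row(sigd)[idx]
        q = (
            self.tel_ss[idx]
            - 2.0 * (s_sub[:, 0] * self.tel_sx[idx] + s_sub[:, 1] * self.tel_sy[idx])
            + self.tel_n[idx] * (s_sub[:, 0] ** 2 + s_sub[:, 1] ** 2)
        )
        vals = -self.tel_n[idx] * (_LOG_2PI + 2.0 * np.log(sig)) - q / (2.0 * sig**2)
        out[m] = vals[m]
        return out

    def _ll_trans_sub(self, sR_sub, sM_sub, sigt) -> np.ndarray:
        resid2 = ((sR_sub - sM_sub) ** 2).sum(axis=1)
        lk = -(_LOG_2PI + 2.0 * np.log(sigt)) - resid2 / (2.0 * sigt**2)
        px = ndtr((self.ss.xmax - sM_sub[:, 0]) / sigt) - ndtr(
            (self.ss.xmin - sM_sub[:, 0]) / sigt
        )
        py = ndtr((self.ss.ymax - sM_sub[:, 1]) / sigt) - ndtr(
            (self.ss.ymin - sM_sub[:, 1]) / sigt
        )
        inside = self.ss.contains(sR_sub)
        return np.where(inside, lk - np.log(np.maximum(px * py, _TINY)), -np.inf)

    def _ll_tel_rows(self, s: np.ndarray, sigd=None) -> np.ndarray:
        out = np.zeros(self.A)
        if not self.spec.use_telemetry or not self.has_tel.any():
            return out
        sig = self._sig_row(sigd)
        q = (
            self.tel_ss
            - 2.0 * (s[:, 0] * self.tel_sx + s[:, 1] * self.tel_sy)
            + self.tel_n * (s[:, 0] ** 2 + s[:, 1] ** 2)
        )
        vals = -self.tel_n * (_LOG_2PI + 2.0 * np.log(sig)) - q / (2.0 * sig**2)
        out[self.has_tel] = vals[self.has_tel]
        return out

    def _ll_trans_rows(self, sR=None, sM=None, sigt=None) -> np.ndarray:
        sR = self.sR if sR is None else sR
        sM = self.sM if sM is None else sM
        sigt = self.sigt if sigt is None else sigt
        resid2 = ((sR - sM) ** 2).sum(axis=1)
        lk = -(_LOG_2PI + 2.0 * np.log(sigt)) - resid2 / (2.0 * sigt**2)
        px = ndtr((self.ss.xmax - sM[:, 0]) / sigt) - ndtr((self.ss.xmin - sM[:, 0]) / sigt)
        py = ndtr((self.ss.ymax - sM[:, 1]) / sigt) - ndtr((self.ss.ymin - sM[:, 1]) / sigt)
        inside = self.ss.contains(sR)
        return np.where(inside, lk - np.log(np.maximum(px * py, _TINY)), -np.inf)

    def log_posterior(self) -> float:
        """Total log joint density of the current state (debug/test hook).

        Omits constants no update depends on (record factorials and the
        uniform activity-center prior), which cancel in every comparison this
        is used for.
        """
        z = self.z
        total = float(self._ll_res_rows(self.lamR)[z].sum())
        if self.use_marking:
            total += float(self._ll_mark_rows(self.hM)[z].sum())
        total += float(self._ll_tel_rows(self.sR)[z].sum())
        if not self.single:
            total += float(self._ll_trans_rows().sum())
        n1 = int(z.sum())
        total += n1 * np.log(self.psi) + (self.A - n1) * np.log1p(-self.psi)
        nf = int((self.sex == 1).sum())
        total += nf * np.log(self.p_sex) + (self.A - nf) * np.log1p(-self.p_sex)
        return total

    # ------------------------------------------------------------- updates

    def _propose_log(self, cur: float, hi: float, scale: float) -> float | None:
        prop = cur * np.exp(scale * self.rng.standard_normal())
        return prop if 0.0 < prop < hi else None

    def _update_detection(self) -> None:
        rng, z = self.rng, self.z
        groups = ((0, 1),) if not self.spec.sex_specific_detection else ((0,), (1,))

        if self.use_marking:
            # lam0_m: hazard scales multiplicatively, h' = c * h
            self.acc["lam0_m"][1] += 1
            prop = self._propose_log(self.lam0m, self.config.lam0_max, self.scale_lam)
            if prop is not None:
                c = prop / self.lam0m
                d = -(c - 1.0) * float(
                    (((self.EM - self.yM) * self.hM)[z]).sum()
                )
                ii, jj = self.yM_nz
                keep = z[ii]
                h = self.hM[ii[keep], jj[keep]]
                d += float(
                    (self.yM[ii[keep], jj[keep]]
                     * (np.log(-np.expm1(-c * h)) - np.log(-np.expm1(-h)))).sum()
                )
                if np.log(rng.random()) < d + np.log(c):
                    self.lam0m = prop
                    self.hM *= c
                    self.acc["lam0_m"][0] += 1

        yR_rowsum = (self.yR_known + self.yR_alloc).sum(axis=1)
        for g in groups:
            # lam0_r: every rate of the affected rows scales by c, so
            # delta = sum(y) log c - (c - 1) sum(E lam)
            self.acc["lam0_r"][1] += 1
            prop = self._propose_log(self.lam0r[g[0]], self.config.lam0_max, self.scale_lam)
            if prop is None:
                continue
            c = prop / self.lam0r[g[0]]
            sex_rows = np.isin(self.sex, g)
            rows = z & sex_rows
            d = float(yR_rowsum[rows].sum()) * np.log(c) - (c - 1.0) * float(
                (self.ER[rows] * self.lamR[rows]).sum()
            )
            if np.log(rng.random()) < d + np.log(c):
                self.lam0r[list(g)] = prop
                self.lamR[sex_rows] *= c
                self.acc["lam0_r"][0] += 1

        for g in groups:
            self.acc["sigma_d"][1] += 1
            prop = self._propose_log(self.sigd[g[0]], self.config.sigma_d_max, self.scale_sig)
            if prop is None:
                continue
            trial = self.sigd.copy()
            trial[list(g)] = prop
            sex_rows = np.isin(self.sex, g)
            idx = np.flatnonzero(z & sex_rows)
            lamR_new = self._lam_sub(self.d2R[idx], idx, sigd=trial)
            d = float(
                (self._ll_res_sub(lamR_new, idx) - self._ll_res_sub(self.lamR[idx], idx)).sum()
            )
            d += float(
                (self._ll_tel_sub(self.sR[idx], idx, sigd=trial)
                 - self._ll_tel_sub(self.sR[idx], idx)).sum()
            )
            if self.use_marking:
                hM_new = self._h_sub(self.d2M[idx], idx, sigd=trial)
                d += float(
                    (self._ll_mark_sub(hM_new, idx) - self._ll_mark_sub(self.hM[idx], idx)).sum()
                )
            if np.log(rng.random()) < d + np.log(prop / self.sigd[g[0]]):
                self.sigd[list(g)] = prop
                rows2 = np.flatnonzero(sex_rows)
                self.lamR[rows2] = self._lam_sub(self.d2R[rows2], rows2)
                if self.use_marking:
                    self.hM[rows2] = self._h_sub(self.d2M[rows2], rows2)
                self.acc["sigma_d"][0] += 1

    def _update_sigma_t(self) -> None:
        rng = self.rng
        self.acc["sigma_t"][1] += 1
        prop = self._propose_log(self.sigt, self.config.sigma_t_max, self.scale_sigt)
        if prop is not None:
            d = float(
                (self._ll_trans_rows(sigt=prop) - self._ll_trans_rows()).sum()
            )
            if np.log(rng.random()) < d + np.log(prop / self.sigt):
                self.sigt = prop
                self.acc["sigma_t"][0] += 1

        if not self.config.joint_sigma_t_move:
            return
        # joint move: rescale the resighting centers of rows with no data
        # binding s_R, together with sigma_t (deterministic-map proposal;
        # Jacobian c^(2 n_moved))
        self.acc["sigma_t_joint"][1] += 1
        prop = self._propose_log(self.sigt, self.config.sigma_t_max, self.scale_sigt)
        if prop is None:
            return
        free = (~self.has_tel) & ((self.yR_known + self.yR_alloc).sum(axis=1) == 0)
        c = prop / self.sigt
        sR_new = self.sR.copy()
        sR_new[free] = self.sM[free] + c * (self.sR[free] - self.sM[free])
        n_free = int(free.sum())
        d = (
            float((self._ll_trans_rows(sR=sR_new, sigt=prop) - self._ll_trans_rows()).sum())
            + 2.0 * n_free * np.log(c)
            + np.log(c)
        )
        # included data-free rows still carry the zero-detection likelihood
        moved_z = free & self.z
        if moved_z.any() and np.isfinite(d):
            d2_new = self._d2(sR_new[moved_z], self.XR)
            sig = self._sig_row()[moved_z]
            lam0 = self.lam0r[self.sex[moved_z]]
            lam_new = lam0[:, None] * np.exp(-d2_new / (2.0 * sig**2)[:, None])
            d += float(
                -(self.ER[moved_z] * lam_new).sum()
                + (self.ER[moved_z] * self.lamR[moved_z]).sum()
            )
        if np.isfinite(d) and np.log(rng.random()) < d:
            self.sigt = prop
            self.sR[free] = sR_new[free]
            self._refresh_rates(rows=free)
            self.acc["sigma_t_joint"][0] += 1

    def _lam_sub(self, d2_sub: np.ndarray, idx: np.ndarray, sigd=None) -> np.ndarray:
        lam0 = self.lam0r[self.sex[idx]]
        sig = self._sig_row(sigd)[idx]
        return lam0[:, None] * np.exp(-d2_sub / (2.0 * sig**2)[:, None])

    def _h_sub(self, d2_sub: np.ndarray, idx: np.ndarray, sigd=None) -> np.ndarray:
        sig = self._sig_row(sigd)[idx]
        return self.lam0m * np.exp(-d2_sub / (2.0 * sig**2)[:, None])

    def _update_centers(self) -> None:
        """Random-walk updates of the included rows' centers; excluded rows
        are redrawn from their prior (every row holding data is included, so
        the likelihood only ever involves the included block)."""
        rng, z = self.rng, self.z
        z0 = ~z
        idx = np.flatnonzero(z)

        if self.single:
            if z0.any():
                self.sM[z0] = rng.uniform(self._lo, self._hi, size=(int(z0.sum()), 2))
                self._refresh_rates(rows=z0)
            prop = self.sM[idx] + self.s_scale * rng.standard_normal((idx.size, 2))
            inside = self.ss.contains(prop)
            d2R_new = self._d2(prop, self.XR)
            lamR_new = self._lam_sub(d2R_new, idx)
            dll = (
                self._ll_res_sub(lamR_new, idx)
                - self._ll_res_sub(self.lamR[idx], idx)
                + self._ll_tel_sub(prop, idx)
                - self._ll_tel_sub(self.sM[idx], idx)
            )
            if self.use_marking:
                d2M_new = self._d2(prop, self.XM)
                hM_new = self._h_sub(d2M_new, idx)
                dll += self._ll_mark_sub(hM_new, idx) - self._ll_mark_sub(
                    self.hM[idx], idx
                )
            acc = inside & (np.log(rng.random(idx.size)) < dll)
            rows = idx[acc]
            self.sM[rows] = prop[acc]
            self.d2R[rows] = d2R_new[acc]
            self.lamR[rows] = lamR_new[acc]
            if self.use_marking:
                self.d2M[rows] = d2M_new[acc]
                self.hM[rows] = hM_new[acc]
            self.acc["s_M"][0] += int(acc.sum())
            self.acc["s_M"][1] += idx.size
            return

        if z0.any():
            self.sM[z0] = rng.uniform(self._lo, self._hi, size=(int(z0.sum()), 2))
            self.sR[z0] = truncated_normal_rect(self.sM[z0], self.sigt, self.ss, rng)
            self._refresh_rates(rows=z0)

        # marking-period centers: marking likelihood + transience kernel
        prop = self.sM[idx] + self.s_scale * rng.standard_normal((idx.size, 2))
        inside = self.ss.contains(prop)
        dll = self._ll_trans_sub(self.sR[idx], prop, self.sigt) - self._ll_trans_sub(
            self.sR[idx], self.sM[idx], self.sigt
        )
        if self.use_marking:
            d2M_new = self._d2(prop, self.XM)
            hM_new = self._h_sub(d2M_new, idx)
            dll += self._ll_mark_sub(hM_new, idx) - self._ll_mark_sub(self.hM[idx], idx)
        acc = inside & (np.log(rng.random(idx.size)) < dll)
        rows = idx[acc]
        self.sM[rows] = prop[acc]
        if self.use_marking:
            self.d2M[rows] = d2M_new[acc]
            self.hM[rows] = hM_new[acc]
        self.acc["s_M"][0] += int(acc.sum())
        self.acc["s_M"][1] += idx.size

        # resighting-period centers: resighting + telemetry + transience
        prop = self.sR[idx] + self.s_scale * rng.standard_normal((idx.size, 2))
        inside = self.ss.contains(prop)
        d2R_new = self._d2(prop, self.XR)
        lamR_new = self._lam_sub(d2R_new, idx)
        dll = (
            self._ll_res_sub(lamR_new, idx)
            - self._ll_res_sub(self.lamR[idx], idx)
            + self._ll_tel_sub(prop, idx)
            - self._ll_tel_sub(self.sR[idx], idx)
            + self._ll_trans_sub(prop, self.sM[idx], self.sigt)
            - self._ll_trans_sub(self.sR[idx], self.sM[idx], self.sigt)
        )
        acc = inside & (np.log(rng.random(idx.size)) < dll)
        rows = idx[acc]
        self.sR[rows] = prop[acc]
        self.d2R[rows] = d2R_new[acc]
        self.lamR[rows] = lamR_new[acc]
        self.acc["s_R"][0] += int(acc.sum())
        self.acc["s_R"][1] += idx.size

    def _update_alloc(self) -> None:
        """Reassign each unmarked record to an eligible owner.

        Candidates are proposed with probability proportional to their
        Poisson rate at the record's camera (rates and eligibility are fixed
        within the loop, so the proposal is a valid independence kernel).
        The Hastings ratio then reduces to ``y_a / (y_b + 1)`` at the
        record's (camera, occasion) cell, which keeps merge moves — several
        records joining one plausible owner — at high acceptance; uniform
        proposals mix the owner partition far too slowly.
        """
        if self.R == 0:
            return
        rng = self.rng
        lam_rec = self.lamR[:, self.rec_trap]  # (A, R); rates fixed in loop
        for r in rng.permutation(self.R):
            self.acc["alloc"][1] += 1
            a = self.alloc[r]
            elig = self.z & self.phase_ok[:, r]
            if self.rec_sex[r] >= 0:
                elig &= self.sex == self.rec_sex[r]
            cand = np.flatnonzero(elig)
            if cand.size <= 1:
                continue
            w = lam_rec[cand, r]
            total = w.sum()
            if total <= 0.0:
                b = int(cand[rng.integers(cand.size)])
                log_q = 0.0  # uniform fallback, symmetric
            else:
                pick = min(
                    int(np.searchsorted(np.cumsum(w), rng.random() * total)),
                    cand.size - 1,
                )
                b = int(cand[pick])
                # q(b) prop lam_b  =>  q(a)/q(b) = lam_a/lam_b
                log_q = np.log(max(lam_rec[a, r], _TINY)) - np.log(
                    max(lam_rec[b, r], _TINY)
                )
            if b == a:
                continue
            c = self.cell_of[r]
            log_ratio = (
                np.log(max(lam_rec[b, r], _TINY))
                - np.log(max(lam_rec[a, r], _TINY))
                + np.log(self.y_cell[a, c])
                - np.log(self.y_cell[b, c] + 1.0)
                + log_q
            )
            if np.log(rng.random()) < log_ratio:
                self._detach(r)
                self._attach(r, b)
                self.acc["alloc"][0] += 1

    def _update_sex(self) -> None:
        rng = self.rng
        free = np.ones(self.A, dtype=bool)
        free[: self.n_M] = False  # marked sexes observed
        if not free.any():
            return
        forced_f = free & (self.owned_f > 0)
        forced_m = free & (self.owned_m > 0)
        changed = (forced_f & (self.sex == 0)) | (forced_m & (self.sex == 1))
        self.sex[forced_f] = 1
        self.sex[forced_m] = 0
        open_rows = free & ~forced_f & ~forced_m
        if not self.spec.sex_specific_detection:
            if open_rows.any():
                self.sex[open_rows] = rng.random(int(open_rows.sum())) < self.p_sex
            return
        # sex-specific detection: the count history (including all-zero) and
        # marking zero-history depend on sex through (lam0_r, sigma_d)
        if open_rows.any():
            lam_f = self.lam0r[1] * np.exp(-self.d2R / (2.0 * self.sigd[1] ** 2))
            lam_m = self.lam0r[0] * np.exp(-self.d2R / (2.0 * self.sigd[0] ** 2))
            yR = self.yR_known + self.yR_alloc
            with np.errstate(divide="ignore", invalid="ignore"):
                ll_f = (np.where(yR > 0, yR * np.log(np.maximum(lam_f, _TINY)), 0.0)
                        - self.ER * lam_f).sum(axis=1)
                ll_m = (np.where(yR > 0, yR * np.log(np.maximum(lam_m, _TINY)), 0.0)
                        - self.ER * lam_m).sum(axis=1)
            if self.use_marking:
                h_f = self.lam0m * np.exp(-self.d2M / (2.0 * self.sigd[1] ** 2))
                h_m = self.lam0m * np.exp(-self.d2M / (2.0 * self.sigd[0] ** 2))
                ll_f += -((self.EM - self.yM) * h_f).sum(axis=1)
                ll_m += -((self.EM - self.yM) * h_m).sum(axis=1)
            rows = np.flatnonzero(open_rows & self.z)
            logit = np.log(self.p_sex) - np.log1p(-self.p_sex) + ll_f[rows] - ll_m[rows]
            new = (rng.random(rows.size) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
            changed[rows] |= new != self.sex[rows]
            self.sex[rows] = new
            off = np.flatnonzero(open_rows & ~self.z)
            new_off = (rng.random(off.size) < self.p_sex).astype(int)
            changed[off] |= new_off != self.sex[off]
            self.sex[off] = new_off
        if changed.any():
            self._refresh_rates(rows=changed)

    def _update_inclusion(self) -> None:
        rng = self.rng
        free = np.ones(self.A, dtype=bool)
        free[: self.n_M] = False
        free &= self.owned_n == 0
        if free.any():
            expo = (self.ER * self.lamR).sum(axis=1)
            if self.use_marking:
                expo = expo + ((self.EM - self.yM) * self.hM).sum(axis=1)
            l0 = np.exp(-expo[free])
            p1 = self.psi * l0 / (self.psi * l0 + (1.0 - self.psi))
            self.z[free] = rng.random(int(free.sum())) < p1
        self.z[: self.n_M] = True
        self.z[self.owned_n > 0] = True
        if not self.config.fix_psi:
            n1 = int(self.z.sum())
            self.psi = rng.beta(1 + n1, 1 + self.A - n1)
            nf = int((self.sex[self.z] == 1).sum())
            self.p_sex = rng.beta(1 + nf, 1 + n1 - nf)

    # ------------------------------------------------------------- driver

    def _adapt(self) -> None:
        def tune(scale, key, lo, hi, target=0.32):
            a, n = self.acc[key]
            if n == 0:
                return scale
            return float(np.clip(scale * np.exp(1.2 * (a / n - target)), lo, hi))

        ext = max(self.ss.xmax - self.ss.xmin, self.ss.ymax - self.ss.ymin)
        self.s_scale = tune(self.s_scale, "s_M", 1e-3, ext)
        self.scale_lam = tune(self.scale_lam, "lam0_r", 0.01, 3.0)
        self.scale_sig = tune(self.scale_sig, "sigma_d", 0.01, 3.0)
        if not self.single:
            self.scale_sigt = tune(self.scale_sigt, "sigma_t", 0.01, 3.0)
        for k in self.acc:
            self.acc[k] = [0, 0]

    def _audit(self) -> None:
        assert np.array_equal(
            np.bincount(self.cell_of, minlength=self.n_cells),
            self.y_cell.sum(axis=0),
        ), "allocation conservation violated"
        assert self.z[self.alloc].all(), "record allocated to an excluded individual"
        assert self.z[: self.n_M].all(), "marked individual excluded"
        for r in range(self.R):
            i = self.alloc[r]
            assert self.phase_ok[i, r], "record allocated against mark-status matrix"
            if self.rec_sex[r] >= 0:
                assert self.sex[i] == self.rec_sex[r], "sex-exclusion violated"
        owners_f = set(np.flatnonzero(self.owned_f > 0))
        owners_m = set(np.flatnonzero(self.owned_m > 0))
        assert not (owners_f & owners_m), "individual owns both-sex records"
        # cache integrity
        assert np.allclose(self.lamR, self._lamR_from(self._d2(self.sR, self.XR))), (
            "stale resighting-rate cache"
        )
        if self.use_marking:
            assert np.allclose(self.hM, self._hM_from(self._d2(self.sM, self.XM))), (
                "stale marking-hazard cache"
            )

    def sweep(self) -> None:
        if not self.config.fix_detection:
            self._update_detection()
            if not self.single:
                self._update_sigma_t()
        self._update_centers()
        self._update_alloc()
        self._update_sex()
        self._update_inclusion()

    def run(self) -> Chains:
        cfg = self.config
        n_ret = (cfg.n_iter - cfg.burn_in + cfg.thin - 1) // cfg.thin
        keys = ["lam0_r", "sigma_d", "psi", "p_sex", "N", "D", "n_um"]
        if self.use_marking:
            keys.insert(0, "lam0_m")
        if self.spec.sex_specific_detection:
            keys += ["lam0_r_f", "sigma_d_f"]
        if not self.single:
            keys.insert(keys.index("psi"), "sigma_t")
        draws = {k: np.empty(n_ret) for k in keys}
        latent = (
            {"alloc": np.empty((n_ret, self.R), dtype=np.int32),
             "z": np.empty((n_ret, self.A), dtype=bool),
             "sex": np.empty((n_ret, self.A), dtype=np.int8)}
            if cfg.track_latent
            else None
        )

        idx = 0
        for it in range(cfg.n_iter):
            self.sweep()
            if cfg.adapt and 0 < it < cfg.burn_in and it % 50 == 0:
                self._adapt()
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                if cfg.audit:
                    self._audit()
                N = int(self.z.sum())
                draws["N"][idx] = N
                draws["D"][idx] = 100.0 * N / self.ss.area
                draws["n_um"][idx] = int((self.owned_n > 0).sum())
                if self.use_marking:
                    draws["lam0_m"][idx] = self.lam0m
                draws["lam0_r"][idx] = self.lam0r[0]
                draws["sigma_d"][idx] = self.sigd[0]
                if self.spec.sex_specific_detection:
                    draws["lam0_r_f"][idx] = self.lam0r[1]
                    draws["sigma_d_f"][idx] = self.sigd[1]
                if not self.single:
                    draws["sigma_t"][idx] = self.sigt
                draws["psi"][idx] = self.psi
                draws["p_sex"][idx] = self.p_sex
                if latent is not None:
                    latent["alloc"][idx] = self.alloc
                    latent["z"][idx] = self.z
                    latent["sex"][idx] = self.sex
                idx += 1

        for k in draws:
            draws[k] = draws[k][:idx]
        if latent is not None:
            latent = {k: v[:idx] for k, v in latent.items()}
        if np.any(draws["N"] > 0.95 * self.A):
            warnings.warn(
                "data augmentation nearly saturated: some draws have "
                "N > 0.95 * A; increase A",
                RuntimeWarning,
            )
        acceptance = {k: (a / n if n else np.nan) for k, (a, n) in self.acc.items()}
        return Chains(
            draws=draws,
            area=self.ss.area,
            acceptance=acceptance,
            seed=cfg.seed,
            latent=latent,
        )


def run_mcmc(
    data: SMRData,
    spec: ModelSpec,
    config: MCMCConfig | None = None,
    state_space: StateSpace | None = None,
) -> Chains:
    """Sample the posterior of a spatial mark-resight model.

    The state space defaults to the detector bounding box buffered by
    ``config.buffer_km``: live-traps and cameras combined for generalized
    models, cameras only for conventional ones.
    """
    config = config or MCMCConfig()
    return _Sampler(data, spec, config, state_space).run()


def fit_null_scr(
    counts: np.ndarray,
    cameras: TrapArray,
    config: MCMCConfig | None = None,
    state_space: StateSpace | None = None,
) -> Chains:
    """Fit a null spatial capture-recapture model (all identities known).

    ``counts`` is ``(n, J)`` occasion-summed or ``(n, J, K)`` occasion-level
    Poisson detection counts for the ``n`` detected individuals.  This is the
    sampler the design-evaluation harness runs per replicate.
    """
    counts = np.asarray(counts, dtype=int)
    J, K = cameras.n_traps, cameras.n_occasions
    if counts.ndim == 2:
        occ = np.zeros((counts.shape[0], J, K), dtype=int)
        occ[:, :, 0] = counts
        counts = occ
    n = counts.shape[0]
    config = config or MCMCConfig()
    spec = ModelSpec(
        generalized=False,
        use_telemetry=False,
        use_transience=False,
        use_sex_constraint=False,
        A=int(config.A or 200),
    )
    data = SMRData(
        cameras=cameras,
        exposure=build_exposure(None, cameras, n),
        y_resight_marked=counts,
        marked_sex=np.zeros(n, dtype=int),
        unmarked=pd.DataFrame(columns=["trap", "occasion", "obs_sex"]),
    )
    return run_mcmc(data, spec, config, state_space)
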