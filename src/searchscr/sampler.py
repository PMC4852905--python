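"""Metropolis-Hastings-within-Gibbs sampler for the augmented SECR model.

One sweep updates, in order: the detection parameters (one-at-a-time Gaussian
random walks on transformed scales), the activity centres (local uniform
proposals over suitable pixels), the inclusion indicators z (Gibbs), the
latent sexes and psi_sex (Gibbs), and psi (conjugate Beta). Conjugate steps
run last so that the derived N_super recorded each iteration is consistent
with the states it is computed from.

The per-individual Bernoulli likelihood factorizes so the all-zero part
collapses over occasions: with hazard mu_ijk = a_i * w_ij * E_jk^beta_eff
and w_ij = exp(-f(d_ij)),

    sum_k active log(1 - pi_ijk) = -a_i * sum_j w_ij * C_j,
    C_j = sum_{k: E_jk > 0} E_jk^beta_eff,

leaving only the (few) detection cells with an extra log(pi) - log(1-pi)
term. The sampler keeps the log-distance matrix, the kernel matrix w and its
effort-weighted row sums cached per chain, recomputing only the rows a
proposal touches, so each sweep costs a handful of M x J array passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .effort import EffortGrid
from .encounters import EncounterData
from .grids import StateSpace, TrapGrid
from .model import KERNEL_FORM, AugmentedState, ModelParams, ModelVariant

__all__ = ["SamplerConfig", "PosteriorDraws", "SECRSampler", "run_chains",
           "gibbs_update_psi"]

logger = logging.getLogger(__name__)

PARAM_NAMES = ["lam0", "beta_eff", "beta_sex", "sigma_f", "sigma_m",
               "theta", "psi", "psi_sex"]

_DEFAULT_SCALES = {
    "lam0": 0.25,      # random walk on ln(lam0)
    "beta_eff": 0.05,
    "beta_sex": 0.3,
    "sigma_f": 0.15,   # random walk on ln(sigma)
    "sigma_m": 0.15,
    "theta": 0.5,      # random walk on logit-rescaled theta
}


@dataclass
class SamplerConfig:
    iterations: int = 11_000
    burn_in: int = 1_000
    thin: int = 2
    chains: int = 8
    seed: int = 0
    proposal_scales: dict = field(default_factory=lambda: dict(_DEFAULT_SCALES))
    window_halfwidth: int = 10  # activity-centre proposal window, in pixels
    adapt: bool = True
    adapt_interval: int = 50
    store_traces: bool = True
    # update switches (for oracle tests that hold parts of the model fixed)
    update_detection_params: bool = True
    update_activity_centres: bool = True
    update_z: bool = True
    update_sex: bool = True
    update_psi: bool = True

    def validate(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorDraws:
    """Per-chain retained draws plus derived abundance and density."""

    params: dict  # name -> (chains, T) array
    nsuper: np.ndarray  # (chains, T)
    density: np.ndarray  # (chains, T), per 100 km^2 of suitable habitat
    traces: dict | None  # {"s", "z", "sex"} -> (chains, T, M) arrays
    acceptance: list  # per chain: name -> post-burn-in acceptance rate
    config: SamplerConfig
    variant: ModelVariant
    suitable_area: float
    m_total: int
    n_detected: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.nsuper.shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return self.nsuper.shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated, for one parameter or 'nsuper'/'density'."""
        if name == "nsuper":
            return self.nsuper.ravel()
        if name == "density":
            return self.density.ravel()
        return self.params[name].ravel()

    def per_chain(self, name: str) -> np.ndarray:
        if name == "nsuper":
            return self.nsuper
        if name == "density":
            return self.density
        return self.params[name]


def gibbs_update_psi(z: np.ndarray, m_total: int, rng: np.random.Generator) -> float:
    """Conjugate draw psi ~ Beta(1 + sum z, 1 + M - sum z)."""
    nz = int(np.sum(z))
    return float(rng.beta(1 + nz, 1 + m_total - nz))


class SECRSampler:
    """Holds the precomputed survey geometry and runs MCMC chains."""

    def __init__(
        self,
        enc: EncounterData,
        effort: EffortGrid,
        space: StateSpace,
        traps: TrapGrid,
        variant: ModelVariant,
        config: SamplerConfig,
        m_total: int,
    ):
        config.validate()
        if m_total <= enc.n_individuals:
            raise ValueError("augmented size M must exceed the detected count n")
        self.enc = enc
        self.effort = effort
        self.space = space
        self.traps = traps
        self.variant = variant
        self.config = config
        self.M = m_total
        self.n = enc.n_individuals

        # suitable-pixel geometry
        self.pix = space.suitable_xy  # (G, 2)
        self.G = self.pix.shape[0]
        idx = space.suitable_indices
        self.pix_iy = idx // space.nx
        self.pix_ix = idx % space.nx
        suit2d = space.suitable.reshape(space.ny, space.nx)
        self.sindex2d = np.full((space.ny, space.nx), -1, dtype=np.int64)
        self.sindex2d[self.pix_iy, self.pix_ix] = np.arange(self.G)
        # 2-D prefix sums for O(1) suitable-pixel counts in a window
        self._psum = np.zeros((space.ny + 1, space.nx + 1), dtype=np.int64)
        self._psum[1:, 1:] = np.cumsum(np.cumsum(suit2d, axis=0), axis=1)

        self.tx = traps.x
        self.ty = traps.y
        self.J = traps.n_traps

        # prior upper bound for the movement scales: the state-space diagonal.
        # Without it sigma for a sex with no included individuals has a flat
        # likelihood and the random walk can drift without bound.
        self.sigma_max = float(np.hypot(space.nx * space.side,
                                        space.ny * space.side))

        # active effort cells, flattened
        act = effort.active
        self.act_j, self.act_k = np.nonzero(act)
        self.lnE_act = np.log(effort.effort[self.act_j, self.act_k])
        self._c_cache: tuple[float, np.ndarray] | None = None

        # detection cells, flattened
        self.i_det, self.j_det, self.k_det = np.nonzero(enc.y)
        e_det = effort.effort[self.j_det, self.k_det]
        if np.any(e_det <= 0):
            raise ValueError(
                "detections present in cells with zero effort; apply the "
                "effort floor in build_encounter_array first"
            )
        self.lnE_det = np.log(e_det)
        self.txy_det = np.column_stack([self.tx[self.j_det], self.ty[self.j_det]])
        self.y_tot = np.zeros(self.M)
        self.y_tot[: self.n] = enc.individual_totals

    # ------------------------------------------------------------------ #
    # likelihood machinery

    def _effort_sum(self, beta_eff: float) -> np.ndarray:
        """C_j = sum over active occasions of EFFORT_jk^beta_eff."""
        if self._c_cache is not None and self._c_cache[0] == beta_eff:
            return self._c_cache[1]
        C = np.bincount(self.act_j, weights=np.exp(beta_eff * self.lnE_act),
                        minlength=self.J)
        self._c_cache = (beta_eff, C)
        return C

    def _lnD_rows(self, s_idx: np.ndarray) -> np.ndarray:
        """Log Euclidean distance (km) from pixels ``s_idx`` to every trap."""
        pxy = self.pix[s_idx]
        d = np.hypot(pxy[:, 0, None] - self.tx[None, :],
                     pxy[:, 1, None] - self.ty[None, :])
        with np.errstate(divide="ignore"):
            return np.log(d)

    @staticmethod
    def _kernel_w(lnD, sigma, theta):
        """w = exp(-f) with f = (d/sigma)^(2*theta), from log distances."""
        sig = np.asarray(sigma, dtype=float)
        if sig.ndim:
            sig = sig[:, None]
        return np.exp(-np.exp(2.0 * theta * (lnD - np.log(sig))))

    @staticmethod
    def _lnw_cells(lnD_cells, sigma_cells, theta):
        """ln w = -f at individual detection cells (flat arrays)."""
        return -np.exp(2.0 * theta * (lnD_cells - np.log(sigma_cells)))

    def _ll_parts(self, params: ModelParams, wC, lnw_det, sex):
        """(loglik_i, hazard_i) from cached kernel summaries.

        ``wC`` is the per-individual effort-weighted kernel sum
        sum_j w_ij C_j; ``lnw_det`` is ln(w) at each detection cell.
        """
        sexf = np.asarray(sex, dtype=float)
        a = params.lam0 * np.exp(params.beta_sex * sexf)
        haz = a * wC
        ll = -haz
        if self.i_det.size:
            ln_mu = (np.log(params.lam0)
                     + params.beta_eff * self.lnE_det
                     + params.beta_sex * sexf[self.i_det]
                     + lnw_det)
            mu = np.exp(ln_mu)
            with np.errstate(divide="ignore"):
                term = np.log(-np.expm1(-mu)) + mu
            ll[: self.n] += np.bincount(self.i_det, weights=term,
                                        minlength=self.n)[: self.n]
        return ll, haz

    def individual_logliks(self, params: ModelParams, s, sex):
        """(loglik_i, hazard_i), length M, ignoring z (self-contained path)."""
        lnD = self._lnD_rows(np.asarray(s))
        w = self._kernel_w(lnD, params.sigma_for(sex), params.theta)
        wC = w @ self._effort_sum(params.beta_eff)
        lnw_det = self._lnw_cells(
            lnD[self.i_det, self.j_det],
            np.asarray(params.sigma_for(sex), dtype=float)[self.i_det],
            params.theta,
        ) if self.i_det.size else np.empty(0)
        return self._ll_parts(params, wC, lnw_det, sex)

    def _refresh_cache(self, state):
        """Recompute every cached quantity from (params, s, sex)."""
        p = state["params"]
        state["lnD"] = self._lnD_rows(state["s"])
        state["w"] = self._kernel_w(state["lnD"], p.sigma_for(state["sex"]),
                                    p.theta)
        state["wC"] = state["w"] @ self._effort_sum(p.beta_eff)
        state["lnD_det"] = state["lnD"][self.i_det, self.j_det]
        sig_det = np.asarray(p.sigma_for(state["sex"]), dtype=float)[self.i_det]
        state["lnw_det"] = (self._lnw_cells(state["lnD_det"], sig_det, p.theta)
                            if self.i_det.size else np.empty(0))
        state["ll"], state["haz"] = self._ll_parts(
            p, state["wC"], state["lnw_det"], state["sex"])

    # ------------------------------------------------------------------ #
    # initialization

    def _init_state(self, rng: np.random.Generator) -> dict:
        enc = self.enc
        total_eff = max(self.effort.total_km, 1e-6)
        lam0 = max(enc.n_detections / total_eff, 1e-5)

        # per-individual centroid of detection trap locations
        cen = np.zeros((self.n, 2))
        for i in range(self.n):
            m = self.i_det == i
            cen[i] = self.txy_det[m].mean(axis=0)
        # sigma init: per-sex mean maximum distance moved / 2, floored
        sig_init = {0: 0.5, 1: 0.5}
        for code in (0, 1):
            maxima = []
            for i in np.flatnonzero(enc.sex == code):
                pts = self.txy_det[self.i_det == i]
                if len(pts) >= 2:
                    dd = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                                  pts[:, None, 1] - pts[None, :, 1])
                    maxima.append(dd.max())
                else:
                    maxima.append(0.0)
            if maxima:
                sig_init[code] = max(float(np.mean(maxima)) / 2.0, 0.5)

        psi = float(np.clip(self.n / self.M, 0.05, 0.9))
        psi_sex = float(np.clip(enc.sex.mean(), 0.05, 0.95)) if self.n else 0.5
        params = ModelParams(
            lam0=lam0, beta_eff=0.0, beta_sex=0.0,
            sigma_f=sig_init[0], sigma_m=sig_init[1],
            theta=self.variant.theta_fixed_value if self.variant.fix_theta else 0.75,
            psi=psi, psi_sex=psi_sex,
        )
        params = self.variant.constrain(params)

        # detected individuals start at the nearest suitable pixel to their
        # sighting centroid; augmented ones uniform over suitable pixels
        s = np.empty(self.M, dtype=np.int64)
        for i in range(self.n):
            d2 = (self.pix[:, 0] - cen[i, 0]) ** 2 + (self.pix[:, 1] - cen[i, 1]) ** 2
            s[i] = int(np.argmin(d2))
        s[self.n:] = rng.integers(0, self.G, size=self.M - self.n)

        sex = np.empty(self.M, dtype=np.int8)
        sex[: self.n] = enc.sex
        sex[self.n:] = rng.random(self.M - self.n) < params.psi_sex

        z = np.zeros(self.M, dtype=np.int8)
        z[: self.n] = 1
        z[self.n:] = rng.random(self.M - self.n) < params.psi

        state = {"params": params, "s": s, "sex": sex, "z": z}
        self._refresh_cache(state)
        return state

    # ------------------------------------------------------------------ #
    # update steps

    def _free_coords(self) -> list[str]:
        names = ["lam0", "beta_eff", "sigma_f", "sigma_m"]
        if not self.variant.fix_beta_sex:
            names.insert(2, "beta_sex")
        if not self.variant.fix_theta:
            names.append("theta")
        return names

    @staticmethod
    def _theta_to_t(theta: float) -> float:
        u = (theta - 0.5) / 0.5
        u = min(max(u, 1e-12), 1 - 1e-12)
        return float(np.log(u / (1 - u)))

    @staticmethod
    def _t_to_theta(t: float) -> float:
        return 0.5 + 0.5 / (1.0 + np.exp(-t))

    def _propose_coord(self, params: ModelParams, name: str, scale: float,
                       rng) -> tuple[ModelParams, float]:
        """Random-walk proposal on the coordinate's transformed scale;
        returns (proposal, log prior-plus-Jacobian increment)."""
        prop = params.copy()
        log_extra = 0.0
        if name == "lam0":  # flat prior on ln(lam0): RW there needs nothing
            prop.lam0 = params.lam0 * np.exp(scale * rng.standard_normal())
        elif name in ("sigma_f", "sigma_m"):
            old = getattr(params, name)
            new = old * np.exp(scale * rng.standard_normal())
            setattr(prop, name, new)
            if new > self.sigma_max:  # Uniform(0, state-space diagonal) prior
                log_extra = -np.inf
            else:
                # flat prior on sigma itself + log-scale proposal Jacobian
                log_extra = np.log(new) - np.log(old)
        elif name == "theta":
            t_old = self._theta_to_t(params.theta)
            t_new = t_old + scale * rng.standard_normal()
            prop.theta = self._t_to_theta(t_new)
            # flat prior on theta; Jacobian of the logit rescaling
            e_old = 1.0 / (1.0 + np.exp(-t_old))
            e_new = 1.0 / (1.0 + np.exp(-t_new))
            log_extra = (np.log(e_new) + np.log(1 - e_new)
                         - np.log(e_old) - np.log(1 - e_old))
        else:  # beta_eff, beta_sex: flat prior, plain random walk
            setattr(prop, name, getattr(params, name) + scale * rng.standard_normal())
        return prop, log_extra

    def mh_update_detection_params(self, state, rng, scales, acc):
        """One-at-a-time random-walk updates of the free detection parameters,
        recomputing only the kernel rows each proposal touches."""
        z1 = state["z"] == 1
        sex = state["sex"]
        for name in self._free_coords():
            params = state["params"]
            prop, log_extra = self._propose_coord(params, name, scales[name], rng)

            w_rows = rows = None
            if name in ("lam0", "beta_sex"):
                wC_new, lnw_det_new = state["wC"], state["lnw_det"]
            elif name == "beta_eff":
                wC_new = state["w"] @ self._effort_sum(prop.beta_eff)
                lnw_det_new = state["lnw_det"]
            elif name in ("sigma_f", "sigma_m"):
                code = 0 if name == "sigma_f" else 1
                rows = np.flatnonzero(sex == code)
                sig = getattr(prop, name)
                w_rows = self._kernel_w(state["lnD"][rows], sig, prop.theta)
                wC_new = state["wC"].copy()
                wC_new[rows] = w_rows @ self._effort_sum(prop.beta_eff)
                lnw_det_new = state["lnw_det"].copy()
                dm = sex[self.i_det] == code
                if dm.any():
                    lnw_det_new[dm] = self._lnw_cells(
                        state["lnD_det"][dm], sig, prop.theta)
            else:  # theta: every row changes
                rows = np.arange(self.M)
                w_rows = self._kernel_w(state["lnD"], prop.sigma_for(sex),
                                        prop.theta)
                wC_new = w_rows @ self._effort_sum(prop.beta_eff)
                sig_det = np.asarray(prop.sigma_for(sex), dtype=float)[self.i_det]
                lnw_det_new = self._lnw_cells(state["lnD_det"], sig_det,
                                              prop.theta)

            ll_new, haz_new = self._ll_parts(prop, wC_new, lnw_det_new, sex)
            delta = float((ll_new[z1] - state["ll"][z1]).sum()) + log_extra
            acc[name][1] += 1
            if np.log(rng.random()) < delta:
                state["params"] = prop
                state["ll"], state["haz"] = ll_new, haz_new
                state["wC"], state["lnw_det"] = wC_new, lnw_det_new
                if w_rows is not None:
                    state["w"][rows] = w_rows
                acc[name][0] += 1
            elif name == "beta_eff":
                # repoint the C cache at the retained value
                self._effort_sum(params.beta_eff)

    def _window_counts(self, iy, ix, h):
        ny, nx = self.space.ny, self.space.nx
        r0 = np.maximum(iy - h, 0)
        r1 = np.minimum(iy + h, ny - 1)
        c0 = np.maximum(ix - h, 0)
        c1 = np.minimum(ix + h, nx - 1)
        P = self._psum
        cnt = (P[r1 + 1, c1 + 1] - P[r0, c1 + 1] - P[r1 + 1, c0] + P[r0, c0])
        return r0, r1, c0, c1, cnt

    def mh_update_activity_centre(self, state, rng, h, acc):
        """Propose a uniform suitable pixel in a (2h+1)^2 window around each
        current centre; accept by likelihood ratio times the window-count
        ratio (the uniform activity-centre prior cancels)."""
        p = state["params"]
        s = state["s"]
        iy, ix = self.pix_iy[s], self.pix_ix[s]
        r0, r1, c0, c1, n_cur = self._window_counts(iy, ix, h)

        # rejection-sample a suitable cell per individual (vectorized rounds)
        cand = np.full(self.M, -1, dtype=np.int64)
        pending = np.arange(self.M)
        for _ in range(50):
            if pending.size == 0:
                break
            rr = rng.integers(r0[pending], r1[pending] + 1)
            cc = rng.integers(c0[pending], c1[pending] + 1)
            g = self.sindex2d[rr, cc]
            ok = g >= 0
            cand[pending[ok]] = g[ok]
            pending = pending[~ok]
        has = cand >= 0  # unresolved windows (no suitable pixel found) stay put

        s_prop = np.where(has, cand, s)
        _, _, _, _, n_prop = self._window_counts(self.pix_iy[s_prop],
                                                 self.pix_ix[s_prop], h)
        lnD_new = self._lnD_rows(s_prop)
        w_new = self._kernel_w(lnD_new, p.sigma_for(state["sex"]), p.theta)
        wC_new = w_new @ self._effort_sum(p.beta_eff)
        lnD_det_new = lnD_new[self.i_det, self.j_det]
        sig_det = np.asarray(p.sigma_for(state["sex"]), dtype=float)[self.i_det]
        lnw_det_new = (self._lnw_cells(lnD_det_new, sig_det, p.theta)
                       if self.i_det.size else np.empty(0))
        ll_new, haz_new = self._ll_parts(p, wC_new, lnw_det_new, state["sex"])

        z1 = state["z"] == 1
        logratio = np.where(z1, ll_new - state["ll"], 0.0) + np.log(n_cur / n_prop)
        accept = has & (np.log(rng.random(self.M)) < logratio)

        state["s"][accept] = s_prop[accept]
        state["lnD"][accept] = lnD_new[accept]
        state["w"][accept] = w_new[accept]
        state["wC"][accept] = wC_new[accept]
        state["ll"][accept] = ll_new[accept]
        state["haz"][accept] = haz_new[accept]
        if self.i_det.size:
            dm = accept[self.i_det]
            state["lnD_det"][dm] = lnD_det_new[dm]
            state["lnw_det"][dm] = lnw_det_new[dm]
        acc["s"][0] += int(accept.sum())
        acc["s"][1] += self.M

    def gibbs_update_z(self, state, rng):
        """Full-conditional draw of the inclusion indicators for augmented
        individuals: Pr(z=1 | .) = psi*q / (psi*q + 1 - psi), q = Pr(all-zero
        history)."""
        psi = state["params"].psi
        q = np.exp(-state["haz"][self.n:])
        p1 = psi * q / (psi * q + (1 - psi))
        state["z"][self.n:] = rng.random(self.M - self.n) < p1

    def update_sex(self, state, rng):
        """Draw latent sexes for augmented individuals and Gibbs-update
        psi_sex from the sex tally among included (z = 1) individuals."""
        params = state["params"]
        if self.M > self.n:
            aug = np.arange(self.n, self.M)
            lnD_aug = state["lnD"][aug]
            C = self._effort_sum(params.beta_eff)
            w_f = self._kernel_w(lnD_aug, params.sigma_f, params.theta)
            w_m = self._kernel_w(lnD_aug, params.sigma_m, params.theta)
            haz_f = params.lam0 * (w_f @ C)
            haz_m = params.lam0 * np.exp(params.beta_sex) * (w_m @ C)
            # log-odds form avoids underflow when both hazards are large
            logit = (np.log(params.psi_sex) - np.log1p(-params.psi_sex)
                     + haz_f - haz_m)
            p_cond = 1.0 / (1.0 + np.exp(-logit))
            p_male = np.where(state["z"][aug] == 1, p_cond, params.psi_sex)
            new_sex = (rng.random(aug.size) < p_male).astype(np.int8)
            flipped = new_sex != state["sex"][aug]
            state["sex"][aug] = new_sex
            if flipped.any():
                male = new_sex == 1
                new_haz = np.where(male, haz_m, haz_f)
                rows = aug[flipped]
                state["w"][rows] = np.where(male[flipped, None],
                                            w_m[flipped], w_f[flipped])
                a_m = params.lam0 * np.exp(params.beta_sex)
                new_wC = np.where(male, haz_m / a_m, haz_f / params.lam0)
                state["wC"][rows] = new_wC[flipped]
                state["haz"][rows] = new_haz[flipped]
                state["ll"][rows] = -new_haz[flipped]  # no detections there

        z1 = state["z"] == 1
        males = int((state["sex"][z1] == 1).sum())
        females = int(z1.sum()) - males
        state["params"].psi_sex = float(rng.beta(1 + males, 1 + females))

    # ------------------------------------------------------------------ #
    # chain driver

    def run_chain(self, rng: np.random.Generator):
        cfg = self.config
        state = None
        for _ in range(20):
            state = self._init_state(rng)
            if np.isfinite(state["ll"][state["z"] == 1].sum()):
                break
        else:
            raise RuntimeError("could not find a finite-likelihood initial state")

        scales = dict(cfg.proposal_scales)
        for k, v in _DEFAULT_SCALES.items():
            scales.setdefault(k, v)
        h = cfg.window_halfwidth
        acc = {name: [0, 0] for name in self._free_coords()}
        acc["s"] = [0, 0]
        acc_post = {name: [0, 0] for name in acc}

        T = cfg.n_retained
        out = {name: np.empty(T) for name in PARAM_NAMES}
        nsuper = np.empty(T, dtype=np.int64)
        traces = None
        if cfg.store_traces:
            traces = {
                "s": np.empty((T, self.M), dtype=np.int32),
                "z": np.empty((T, self.M), dtype=np.int8),
                "sex": np.empty((T, self.M), dtype=np.int8),
            }

        t = 0
        for it in range(cfg.iterations):
            in_burn = it < cfg.burn_in
            rec = acc if in_burn or not cfg.adapt else acc_post
            if cfg.update_detection_params:
                self.mh_update_detection_params(state, rng, scales, rec)
            if cfg.update_activity_centres:
                self.mh_update_activity_centre(state, rng, h, rec)
            if cfg.update_z:
                self.gibbs_update_z(state, rng)
            if cfg.update_sex:
                self.update_sex(state, rng)
            if cfg.update_psi:
                state["params"].psi = gibbs_update_psi(state["z"], self.M, rng)

            # proposal adaptation, burn-in only (retained draws keep detailed balance)
            if cfg.adapt and in_burn and (it + 1) % cfg.adapt_interval == 0:
                batch = (it + 1) // cfg.adapt_interval
                damp = min(1.0, 2.0 / np.sqrt(batch))
                for name in self._free_coords():
                    a, nprop = acc[name]
                    if nprop:
                        scales[name] *= np.exp(damp * (a / nprop - 0.35))
                    acc[name] = [0, 0]
                a, nprop = acc["s"]
                if nprop:
                    rate = a / nprop
                    if rate < 0.2:
                        h = max(1, h - 1)
                    elif rate > 0.6:
                        h = min(h + 1, max(self.space.nx, self.space.ny))
                acc["s"] = [0, 0]

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                p = state["params"]
                for name in PARAM_NAMES:
                    out[name][t] = getattr(p, name)
                nsuper[t] = int(state["z"].sum())
                if traces is not None:
                    traces["s"][t] = state["s"]
                    traces["z"][t] = state["z"]
                    traces["sex"][t] = state["sex"]
                t += 1

        rates = {}
        source = acc_post if cfg.adapt else acc
        for name, (a, nprop) in source.items():
            rates[name] = a / nprop if nprop else float("nan")
        return out, nsuper, traces, rates

    def run(self) -> PosteriorDraws:
        cfg = self.config
        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
        T = cfg.n_retained
        params = {name: np.empty((cfg.chains, T)) for name in PARAM_NAMES}
        nsuper = np.empty((cfg.chains, T), dtype=np.int64)
        traces = None
        if cfg.store_traces:
            traces = {
                "s": np.empty((cfg.chains, T, self.M), dtype=np.int32),
                "z": np.empty((cfg.chains, T, self.M), dtype=np.int8),
                "sex": np.empty((cfg.chains, T, self.M), dtype=np.int8),
            }
        acc_all = []
        for c, ss in enumerate(seeds):
            rng = np.random.default_rng(ss)
            out, ns, tr, rates = self.run_chain(rng)
            for name in PARAM_NAMES:
                params[name][c] = out[name]
            nsuper[c] = ns
            if traces is not None:
                for key in traces:
                    traces[key][c] = tr[key]
            acc_all.append(rates)
            logger.info("chain %d/%d done (mean N_super %.1f)",
                        c + 1, cfg.chains, ns.mean())

        area = self.space.suitable_area
        density = 100.0 * nsuper / area
        psi_mean = params["psi"].mean()
        if not (0.2 < psi_mean < 0.8):
            logger.warning(
                "posterior mean psi = %.3f lies outside (0.2, 0.8); consider "
                "changing the augmented size M for reliable estimation", psi_mean
            )
        return PosteriorDraws(
            params=params, nsuper=nsuper, density=density, traces=traces,
            acceptance=acc_all, config=cfg, variant=self.variant,
            suitable_area=area, m_total=self.M, n_detected=self.n,
            metadata={"kernel": KERNEL_FORM,
                      "psi_posterior_mean": float(psi_mean)},
        )


def run_chains(
    enc: EncounterData,
    effort: EffortGrid,
    space: StateSpace,
    traps: TrapGrid,
    variant: ModelVariant,
    config: SamplerConfig,
    m_total: int,
) -> PosteriorDraws:
    """Fit one model variant: run ``config.chains`` independent MCMC chains
    (seeds derived deterministically from ``config.seed``) and collect the
    retained draws with derived N_super and density."""
    sampler = SECRSampler(enc, effort, space, traps, variant, config, m_total)
    return sampler.run()
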