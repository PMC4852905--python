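"""Convergence diagnostics, model adequacy, posterior summaries, density map.

* Gelman-Rubin potential scale reduction factor (PSRF) in its classic
  between/within-chain form; a fit is called converged at max PSRF < 1.2.
* Posterior predictive (Bayesian) p-value with a Freeman-Tukey discrepancy on
  per-individual encounter totals, T = sum_i (sqrt(y_i.) - sqrt(e_i.))^2;
  values in (0.15, 0.85) are taken as adequate.
* Table-style posterior means and standard deviations, pooled over chains.
* The expected pixel-specific density surface (animals per km^2 per pixel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .effort import EffortGrid
from .encounters import EncounterData
from .grids import StateSpace, TrapGrid
from .model import ModelParams, ModelVariant, sex_ratio
from .sampler import PosteriorDraws

__all__ = [
    "gelman_rubin",
    "max_psrf",
    "bayesian_pvalue",
    "summarize_posterior",
    "density_surface",
    "DiagnosticsReport",
]

PSRF_THRESHOLD = 1.2
PVALUE_BOUNDS = (0.15, 0.85)


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor.

    ``chains`` is (n_chains, L). With within-chain variance W (mean of the
    per-chain sample variances) and between-chain variance B (L times the
    variance of the chain means),

        PSRF = sqrt( ((L-1)/L * W + B/L) / W ).

    The estimator is floored at 1.0: finite-sample noise can push it slightly
    below 1, which carries no information beyond "mixing as well as
    expected". Returns 1.0 by convention when every draw is identical.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("gelman_rubin needs >= 2 chains of equal length")
    m, L = chains.shape
    if L < 2:
        raise ValueError("chains must contain >= 2 draws")
    W = chains.var(axis=1, ddof=1).mean()
    B = L * chains.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0
    return float(max(1.0, np.sqrt(((L - 1) / L * W + B / L) / W)))


def max_psrf(draws: PosteriorDraws) -> tuple[float, dict]:
    """Maximum PSRF over the free parameters plus N_super."""
    names = draws.variant.free_parameters + ["nsuper"]
    vals = {name: gelman_rubin(draws.per_chain(name)) for name in names}
    return max(vals.values()), vals


def _draw_params(draws: PosteriorDraws, c: int, t: int) -> ModelParams:
    return ModelParams(**{name: float(draws.params[name][c, t])
                          for name in draws.params})


def bayesian_pvalue(
    draws: PosteriorDraws,
    enc: EncounterData,
    effort: EffortGrid,
    space: StateSpace,
    traps: TrapGrid,
    rng: np.random.Generator,
    max_draws: int = 200,
) -> float:
    """Posterior predictive check on individual encounter totals.

    For each retained draw the Freeman-Tukey discrepancy is computed for the
    observed totals (augmented individuals count 0) and for a replicate data
    set simulated from the same draw; the p-value is the proportion of draws
    with T_rep >= T_obs.
    """
    if draws.traces is None:
        raise ValueError(
            "bayesian_pvalue needs stored latent-state traces; re-run the "
            "sampler with store_traces=True"
        )
    pix = space.suitable_xy
    tx, ty = traps.x, traps.y
    act_j, act_k = np.nonzero(effort.active)
    lnE = np.log(effort.effort[act_j, act_k])
    y_tot = np.zeros(draws.m_total)
    y_tot[: enc.n_individuals] = enc.individual_totals
    sqrt_y = np.sqrt(y_tot)

    C, T = draws.nsuper.shape
    flat = [(c, t) for c in range(C) for t in range(T)]
    if len(flat) > max_draws:
        pick = rng.choice(len(flat), size=max_draws, replace=False)
        flat = [flat[i] for i in pick]

    n_ge = 0
    for c, t in flat:
        p = _draw_params(draws, c, t)
        z = draws.traces["z"][c, t]
        inc = np.flatnonzero(z == 1)
        s = draws.traces["s"][c, t][inc]
        sx = draws.traces["sex"][c, t][inc].astype(float)
        pxy = pix[s]
        D = np.hypot(pxy[:, 0, None] - tx[None, :], pxy[:, 1, None] - ty[None, :])
        sig = np.where(sx == 1, p.sigma_m, p.sigma_f)[:, None]
        w = np.exp(-((D / sig) ** (2.0 * p.theta)))
        a = p.lam0 * np.exp(p.beta_sex * sx)
        mu = a[:, None] * w[:, act_j] * np.exp(p.beta_eff * lnE)[None, :]
        pi = -np.expm1(-mu)
        e = pi.sum(axis=1)
        t_obs = float(((sqrt_y[inc] - np.sqrt(e)) ** 2).sum())
        y_rep = (rng.random(pi.shape) < pi).sum(axis=1)
        t_rep = float(((np.sqrt(y_rep) - np.sqrt(e)) ** 2).sum())
        n_ge += t_rep >= t_obs
    return n_ge / len(flat)


def summarize_posterior(draws: PosteriorDraws, variant: ModelVariant | None = None
                        ) -> pd.DataFrame:
    """Pooled posterior mean and SD for the free parameters and the derived
    quantities (N_super, density D, females-per-male sex ratio)."""
    variant = variant or draws.variant
    rows = []
    for name in variant.free_parameters:
        x = draws.pooled(name)
        rows.append((name, x.mean(), x.std(ddof=1)))
    ns = draws.pooled("nsuper")
    rows.append(("nsuper", ns.mean(), ns.std(ddof=1)))
    d = draws.pooled("density")
    rows.append(("density", d.mean(), d.std(ddof=1)))
    psx = draws.pooled("psi_sex")
    sr = (1.0 - psx) / psx
    rows.append(("sex_ratio", sr.mean(), sr.std(ddof=1)))
    return pd.DataFrame(rows, columns=["parameter", "mean", "sd"]).set_index("parameter")


def density_surface(draws: PosteriorDraws, space: StateSpace) -> np.ndarray:
    """Expected animals per km^2 per state-space pixel.

    Per pixel g: the posterior mean of the number of included activity
    centres at g, divided by the pixel area. Returns a length-n_pixels array
    (zeros off the suitable support) laid out like ``space.x``/``space.y``;
    export with ``space.to_ascii_grid(surface)``.
    """
    if draws.traces is None:
        raise ValueError(
            "density_surface needs stored activity-centre traces; re-run the "
            "sampler with store_traces=True"
        )
    s = draws.traces["s"]
    z = draws.traces["z"]
    n_draws = s.shape[0] * s.shape[1]
    counts = np.bincount(s[z == 1].ravel(), minlength=space.n_suitable)
    per_pixel = counts / n_draws
    surface = np.zeros(space.n_pixels)
    surface[space.suitable_indices] = per_pixel / space.pixel_area
    return surface


@dataclass
class DiagnosticsReport:
    """Convergence + adequacy verdicts and the posterior summary table."""

    psrf: dict
    max_psrf: float
    bayes_pvalue: float | None
    summary: pd.DataFrame
    n_retained: int
    variant_label: str
    metadata: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.max_psrf < PSRF_THRESHOLD

    @property
    def adequate(self) -> bool | None:
        if self.bayes_pvalue is None:
            return None
        lo, hi = PVALUE_BOUNDS
        return lo < self.bayes_pvalue < hi

    def to_dict(self) -> dict:
        return {
            "variant": self.variant_label,
            "n_retained": self.n_retained,
            "psrf": {k: float(v) for k, v in self.psrf.items()},
            "max_psrf": float(self.max_psrf),
            "converged": bool(self.converged),
            "bayes_pvalue": None if self.bayes_pvalue is None else float(self.bayes_pvalue),
            "adequate": self.adequate,
            "posterior": {
                name: {"mean": float(r["mean"]), "sd": float(r["sd"])}
                for name, r in self.summary.iterrows()
            },
            "metadata": self.metadata,
        }

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def diagnose(
    draws: PosteriorDraws,
    enc: EncounterData | None = None,
    effort: EffortGrid | None = None,
    space: StateSpace | None = None,
    traps: TrapGrid | None = None,
    rng: np.random.Generator | None = None,
) -> DiagnosticsReport:
    """Convenience wrapper assembling the full report for one fitted model."""
    mx, per = max_psrf(draws)
    pval = None
    if enc is not None and effort is not None and space is not None and traps is not None:
        pval = bayesian_pvalue(draws, enc, effort, space, traps,
                               rng or np.random.default_rng(0))
    return DiagnosticsReport(
        psrf=per,
        max_psrf=mx,
        bayes_pvalue=pval,
        summary=summarize_posterior(draws),
        n_retained=draws.n_chains * draws.n_draws_per_chain,
        variant_label=draws.variant.label,
        metadata=dict(draws.metadata),
    )
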