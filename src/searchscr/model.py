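"""The sex-specific search-encounter SECR probability model.

Detection of individual *i* in trap pixel *j* on occasion *k* is Bernoulli
with a complementary log-log linear predictor:

    cloglog(pi_ijk) = log(lam0) + beta_eff * log(EFFORT_jk)
                      + beta_sex * SEX_i - f(d_ij; theta, sigma_sex)

with the distance-decay term

    f(d) = (d / sigma)^(2 * theta),

so exp(-f) is Gaussian (half-normal) in d at theta = 1 and negative
exponential at theta = 0.5; sigma keeps units of km for every theta. This
parameterization of f is a package choice — the two printed limit shapes pin
it only up to a rescaling of sigma — and is recorded in output metadata.

Population size is handled by data augmentation: the detected n individuals
are padded with n_z all-zero histories to a superpopulation cap M, each with
an inclusion indicator z_i ~ Bernoulli(psi), so that
N_super | M, psi ~ Binomial(M, psi). Sexes are Bernoulli(psi_sex)
(female = 0, male = 1) and activity centres are uniform over suitable pixels.

Priors (expressed over the sampling coordinates): flat on ln(lam0) and on the
betas; flat on sigma up to an upper bound the sampler sets at the state-space
diagonal (without a bound, sigma for a sex with no included individuals has a
flat likelihood and an improper posterior); Uniform(0.5, 1) on theta;
Beta(1, 1) on psi and psi_sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .effort import EffortGrid
from .encounters import EncounterData

__all__ = [
    "ModelParams",
    "ModelVariant",
    "AugmentedState",
    "detection_kernel",
    "encounter_prob",
    "complete_data_loglik",
    "log_prior",
    "sex_ratio",
    "density_from_nsuper",
    "KERNEL_FORM",
]

#: recorded in run metadata so fits are comparable across kernel conventions
KERNEL_FORM = "f(d) = (d/sigma)^(2*theta); exp(-f) Gaussian at theta=1, exponential at theta=0.5"

THETA_FIXED_DEFAULT = 0.75


@dataclass
class ModelParams:
    """All top-level parameters of the detection and augmentation model."""

    lam0: float  # basal encounter rate at d=0, 1 km effort
    beta_eff: float  # effect per unit log-km effort
    beta_sex: float  # male minus female cloglog offset
    sigma_f: float  # km, female movement/detection-decline scale
    sigma_m: float  # km, male scale
    theta: float  # detection shape in [0.5, 1]
    psi: float  # augmentation inclusion probability
    psi_sex: float  # proportion male

    def validate(self) -> None:
        if self.lam0 <= 0:
            raise ValueError("lam0 must be positive")
        if self.sigma_f <= 0 or self.sigma_m <= 0:
            raise ValueError("sigma must be positive")
        if not (0.5 <= self.theta <= 1.0):
            raise ValueError("theta must lie in [0.5, 1]")
        if not (0 < self.psi < 1) or not (0 < self.psi_sex < 1):
            raise ValueError("psi and psi_sex must lie in (0, 1)")

    def sigma_for(self, sex):
        """sigma_F for sex 0, sigma_M for sex 1 (vectorized)."""
        return np.where(np.asarray(sex) == 1, self.sigma_m, self.sigma_f)

    def copy(self) -> "ModelParams":
        return replace(self)


@dataclass(frozen=True)
class ModelVariant:
    """One of the four candidate models.

    1: beta_sex free, theta free      2: beta_sex = 0, theta free
    3: beta_sex = 0, theta fixed      4: beta_sex free, theta fixed

    sigma stays sex-specific in every variant (it is a movement parameter,
    not only a detection one).
    """

    number: int
    theta_fixed_value: float = THETA_FIXED_DEFAULT

    def __post_init__(self):
        if self.number not in (1, 2, 3, 4):
            raise ValueError("model variant must be 1, 2, 3 or 4")

    @property
    def fix_beta_sex(self) -> bool:
        return self.number in (2, 3)

    @property
    def fix_theta(self) -> bool:
        return self.number in (3, 4)

    @property
    def label(self) -> str:
        bs = "beta_sex=0(fixed)" if self.fix_beta_sex else "beta_sex"
        th = f"theta={self.theta_fixed_value}(fixed)" if self.fix_theta else "theta(.)"
        return f"Model {self.number} [{bs}, {th}]"

    @property
    def free_parameters(self) -> list[str]:
        names = ["lam0", "beta_eff", "sigma_f", "sigma_m", "psi", "psi_sex"]
        if not self.fix_beta_sex:
            names.insert(2, "beta_sex")
        if not self.fix_theta:
            names.insert(names.index("psi"), "theta")
        return names

    def constrain(self, params: ModelParams) -> ModelParams:
        """Return params with this variant's fixed values imposed."""
        p = params.copy()
        if self.fix_beta_sex:
            p.beta_sex = 0.0
        if self.fix_theta:
            p.theta = self.theta_fixed_value
        return p


@dataclass
class AugmentedState:
    """Latent state of the data-augmented population.

    ``s`` indexes into the *suitable* pixels of the state space (the
    activity-centre support). Detected individuals occupy rows 0..n-1 and are
    pinned at z = 1 with their observed sex.
    """

    z: np.ndarray  # (M,) 0/1 inclusion
    sex: np.ndarray  # (M,) 0/1
    s: np.ndarray  # (M,) suitable-pixel index
    n_detected: int

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.int8)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        self.s = np.asarray(self.s, dtype=np.int64)
        if not (self.z.size == self.sex.size == self.s.size):
            raise ValueError("z, sex, s must share length M")
        if self.n_detected > self.z.size:
            raise ValueError("n_detected exceeds M")
        if not np.all(self.z[: self.n_detected] == 1):
            raise ValueError("detected individuals must have z = 1")

    @property
    def m_total(self) -> int:
        return self.z.size

    @property
    def n_super(self) -> int:
        return int(self.z.sum())


def detection_kernel(d, sigma, theta):
    """Distance-decay exponent f(d) = (d/sigma)^(2*theta) (dimensionless)."""
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    if np.any(np.asarray(theta) < 0.5) or np.any(np.asarray(theta) > 1.0):
        raise ValueError("theta must lie in [0.5, 1]")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    return (d / sigma) ** (2.0 * np.asarray(theta, dtype=float))


def encounter_prob(params: ModelParams, sex, d, effort):
    """Per-cell detection probability pi (0 where the trap is inactive)."""
    params.validate()
    d = np.asarray(d, dtype=float)
    effort = np.asarray(effort, dtype=float)
    if np.any(effort < 0):
        raise ValueError("effort must be non-negative")
    sigma = params.sigma_for(sex)
    with np.errstate(divide="ignore"):
        eta = (
            np.log(params.lam0)
            + params.beta_eff * np.log(np.where(effort > 0, effort, 1.0))
            + params.beta_sex * np.asarray(sex)
            - detection_kernel(d, sigma, params.theta)
        )
    pi = -np.expm1(-np.exp(eta))
    pi = np.where(effort > 0, pi, 0.0)
    return pi if pi.ndim else float(pi)


def complete_data_loglik(
    params: ModelParams,
    state: AugmentedState,
    enc: EncounterData,
    effort: EffortGrid,
    distmat: np.ndarray,
) -> float:
    """Bernoulli log-likelihood of the detection data given the latent state.

    Sums y*log(pi) + (1-y)*log(1-pi) over individuals with z = 1 and active
    (trap, occasion) cells; z = 0 individuals contribute nothing. ``distmat``
    is (n_suitable_pixels, J) and ``state.s`` indexes its rows. Detected
    individuals (rows 0..n-1 of ``enc.y``) must have z = 1; augmented ones
    have all-zero histories.
    """
    params.validate()
    n = enc.n_individuals
    if state.n_detected != n:
        raise ValueError("state.n_detected does not match encounter data")
    active = effort.active
    if np.any(enc.y & ~active[None, :, :]):
        raise ValueError(
            "detection at an inactive trap-occasion; apply the effort floor "
            "when building the encounter array"
        )

    E = effort.effort
    logE = np.zeros_like(E)
    np.log(E, out=logE, where=active)

    total = 0.0
    for i in np.flatnonzero(state.z == 1):
        sig = float(params.sigma_for(state.sex[i]))
        f = detection_kernel(distmat[state.s[i]], sig, params.theta)  # (J,)
        eta = (
            np.log(params.lam0)
            + params.beta_eff * logE
            + params.beta_sex * float(state.sex[i])
            - f[:, None]
        )
        mu = np.exp(eta)
        yi = enc.y[i] if i < n else np.zeros_like(active)
        # log(1-pi) = -mu; log(pi) = log(1 - exp(-mu))
        total += float(-(mu[active & ~yi]).sum())
        if yi.any():
            mu1 = mu[yi]
            total += float(np.log(-np.expm1(-mu1)).sum())
    return total


def log_prior(params: ModelParams, variant: ModelVariant) -> float:
    """Joint log prior density over the sampling coordinates, up to a constant.

    Flat on ln(lam0), beta_eff, beta_sex; flat on sigma over [0, inf);
    Uniform(0.5, 1) on theta; Beta(1, 1) on psi and psi_sex. Parameters the
    variant fixes contribute 0. Returns -inf outside a support.
    """
    if params.lam0 <= 0 or params.sigma_f <= 0 or params.sigma_m <= 0:
        return -np.inf
    if not (0 < params.psi < 1) or not (0 < params.psi_sex < 1):
        return -np.inf
    if not variant.fix_theta and not (0.5 <= params.theta <= 1.0):
        return -np.inf
    return 0.0


def sex_ratio(psi_sex: float) -> float:
    """Females per male, (1 - psi_sex) / psi_sex."""
    if not (0 < psi_sex < 1):
        raise ValueError("psi_sex must lie strictly in (0, 1)")
    return (1.0 - psi_sex) / psi_sex


def density_from_nsuper(n_super, suitable_area: float):
    """Individuals per 100 km^2 of suitable habitat."""
    if suitable_area <= 0:
        raise ValueError("suitable_area must be positive")
    return 100.0 * np.asarray(n_super, dtype=float) / suitable_area
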