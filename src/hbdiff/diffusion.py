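"""Variance-preserving denoising-diffusion machinery.

Per-step signal/noise coefficients satisfy ``alpha_t**2 + sigma_t**2 == 1``
exactly; coordinates are noised inside the zero center-of-mass subspace so
the Gaussian latents are compatible with translation symmetry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LatentState",
    "NoiseSchedule",
    "as_rng",
    "build_noise_schedule",
    "denoise_step",
    "forward_diffuse",
    "posterior_params",
    "predict_clean",
    "project_zero_com",
    "sample_com_free_noise",
    "simplified_loss",
    "vlb_terms",
]


def as_rng(rng) -> np.random.Generator:
    """Accept a seed or a Generator; return a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class NoiseSchedule:
    """Discrete schedule over steps t = 0..T.

    ``alpha[t]`` is the marginal signal coefficient (alpha_0 ~ 1 down to
    alpha_T ~ 0), ``sigma[t] = sqrt(1 - alpha[t]**2)`` the marginal noise
    scale, ``beta[t]`` the per-step noise variance increment and
    ``snr[t] = alpha[t]**2 / sigma[t]**2``.
    """

    T: int
    alpha: np.ndarray
    sigma: np.ndarray
    beta: np.ndarray
    kind: str = "polynomial"
    precision: float = 1e-4

    snr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.alpha.shape != (self.T + 1,):
            raise ValueError("alpha must have T+1 entries")
        if np.any(np.abs(self.alpha**2 + self.sigma**2 - 1.0) > 1e-12):
            raise AssertionError("schedule is not variance preserving")
        if np.any(np.diff(self.alpha) >= 0):
            raise AssertionError("alpha must be strictly decreasing")
        self.snr = self.alpha**2 / self.sigma**2
        if np.any(np.diff(self.snr) >= 0):
            raise AssertionError("SNR must be strictly decreasing")

    def to_json(self) -> str:
        return json.dumps(
            {
                "T": self.T,
                "kind": self.kind,
                "precision": self.precision,
                "alpha": self.alpha.tolist(),
                "sigma": self.sigma.tolist(),
                "beta": self.beta.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NoiseSchedule":
        d = json.loads(text)
        return cls(
            T=d["T"],
            alpha=np.array(d["alpha"]),
            sigma=np.array(d["sigma"]),
            beta=np.array(d["beta"]),
            kind=d.get("kind", "polynomial"),
            precision=d.get("precision", 1e-4),
        )


def build_noise_schedule(
    T: int, kind: str = "polynomial", precision: float = 1e-4
) -> NoiseSchedule:
    """Construct a variance-preserving schedule.

    ``polynomial`` interpolates alpha_t^2 = (1 - (t/T)^2)^2 (clipped for
    monotonicity and squeezed by ``precision`` away from exact 0/1);
    ``cosine`` uses the squared-cosine profile.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0 < precision < 0.1):
        raise ValueError("precision must lie in (0, 0.1)")
    t = np.arange(T + 1, dtype=float) / T
    if kind == "polynomial":
        alphas2 = (1.0 - t**2) ** 2
    elif kind == "cosine":
        s = 0.008
        alphas2 = np.cos((t + s) / (1 + s) * np.pi / 2) ** 2
        alphas2 = alphas2 / alphas2[0]
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    # clip per-step decay so alpha never collapses too fast
    ratios = np.clip(alphas2[1:] / np.maximum(alphas2[:-1], 1e-12), 0.001, 1.0)
    alphas2 = np.concatenate([[alphas2[0]], alphas2[0] * np.cumprod(ratios)])
    # squeeze into [precision, 1 - precision] so endpoints are near 1 and 0
    alphas2 = precision + (1.0 - 2.0 * precision) * alphas2
    alpha = np.sqrt(alphas2)
    sigma = np.sqrt(1.0 - alphas2)
    beta = np.empty(T + 1)
    beta[0] = 0.0
    beta[1:] = 1.0 - alphas2[1:] / alphas2[:-1]
    return NoiseSchedule(T=T, alpha=alpha, sigma=sigma, beta=beta, kind=kind, precision=precision)


@dataclass
class LatentState:
    """Noised ligand state at step t: coordinates z_x and features z_h."""

    z_x: np.ndarray
    z_h: np.ndarray
    t: int


def project_zero_com(coords: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Subtract the mean position of the masked subset from that subset.

    Nodes outside the mask are untouched.  Idempotent and translation
    invariant on the masked subset.
    """
    coords = np.array(coords, dtype=float)
    if mask is None:
        mask = np.ones(len(coords), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no nodes")
    coords[mask] = coords[mask] - coords[mask].mean(axis=0)
    return coords


def sample_com_free_noise(shape: tuple[int, int], rng) -> np.ndarray:
    """Standard normal noise projected onto the zero center-of-mass subspace."""
    rng = as_rng(rng)
    eps = rng.standard_normal(shape)
    return eps - eps.mean(axis=0)


def forward_diffuse(
    x_coords: np.ndarray,
    x_feats: np.ndarray,
    t: int,
    schedule: NoiseSchedule,
    rng,
    com_free: bool = True,
) -> tuple[LatentState, tuple[np.ndarray, np.ndarray]]:
    """Closed-form forward noising ``z_t = alpha_t x + sigma_t eps``.

    By default coordinate noise lives in the zero-CoM subspace of the
    noised nodes (the translation-symmetric, unconditioned setting);
    ``com_free=False`` draws unconstrained noise, which is what the
    pocket-conditioned pipeline uses since fixed conditions break
    translation symmetry.  Feature noise is always unconstrained.  Only
    the ligand is ever diffused — pocket and particles are conditions
    and are never passed through here.
    """
    if not (1 <= t <= schedule.T):
        raise ValueError(f"t={t} outside [1, {schedule.T}]")
    rng = as_rng(rng)
    x_coords = np.asarray(x_coords, dtype=float)
    x_feats = np.asarray(x_feats, dtype=float)
    if com_free:
        eps_x = sample_com_free_noise(x_coords.shape, rng)
    else:
        eps_x = rng.standard_normal(x_coords.shape)
    eps_h = rng.standard_normal(x_feats.shape)
    a, s = schedule.alpha[t], schedule.sigma[t]
    z = LatentState(z_x=a * x_coords + s * eps_x, z_h=a * x_feats + s * eps_h, t=t)
    return z, (eps_x, eps_h)


def posterior_params(
    z_t: np.ndarray, x: np.ndarray, s: int, t: int, schedule: NoiseSchedule
) -> tuple[np.ndarray, float]:
    """Mean and scale of the true denoising transition q(z_s | z_t, x).

    With alpha_{t|s} = alpha_t/alpha_s and sigma_{t|s}^2 = sigma_t^2 -
    alpha_{t|s}^2 sigma_s^2, the posterior is Normal(mu, sigma^2) with
    mu = (alpha_{t|s} sigma_s^2 z_t + alpha_s sigma_{t|s}^2 x) / sigma_t^2
    and sigma = sigma_{t|s} sigma_s / sigma_t.
    """
    if not (0 <= s < t <= schedule.T):
        raise ValueError(f"need 0 <= s < t <= T, got s={s}, t={t}")
    a_t, a_s = schedule.alpha[t], schedule.alpha[s]
    s_t2, s_s2 = schedule.sigma[t] ** 2, schedule.sigma[s] ** 2
    a_ts = a_t / a_s
    s_ts2 = s_t2 - a_ts**2 * s_s2
    mu = (a_ts * s_s2 / s_t2) * np.asarray(z_t) + (a_s * s_ts2 / s_t2) * np.asarray(x)
    sigma = float(np.sqrt(max(s_ts2, 0.0)) * np.sqrt(s_s2) / np.sqrt(s_t2))
    return mu, sigma


def predict_clean(
    z_t: np.ndarray, eps_hat: np.ndarray, t: int, schedule: NoiseSchedule
) -> np.ndarray:
    """Invert the forward closed form: x_hat = (z_t - sigma_t eps_hat)/alpha_t."""
    a_t = schedule.alpha[t]
    if abs(a_t) < 1e-12:
        raise ZeroDivisionError("alpha_t is zero; clean-data prediction undefined")
    return (np.asarray(z_t) - schedule.sigma[t] * np.asarray(eps_hat)) / a_t


def denoise_step(
    z_x: np.ndarray,
    z_h: np.ndarray,
    eps_x_hat: np.ndarray,
    eps_h_hat: np.ndarray,
    s: int,
    t: int,
    schedule: NoiseSchedule,
    rng=None,
    noise_scale: float = 1.0,
    com_free: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """One reverse transition z_t -> z_s using predicted noise.

    The clean state is estimated via :func:`predict_clean`, then a sample
    is drawn from the posterior; coordinate noise is drawn in the
    zero-CoM subspace unless ``com_free=False`` (conditioned setting).
    ``rng=None`` (or ``noise_scale=0``) gives the deterministic mean,
    the convention used for the final t=1 -> 0 step.
    """
    x_hat = predict_clean(z_x, eps_x_hat, t, schedule)
    h_hat = predict_clean(z_h, eps_h_hat, t, schedule)
    mu_x, sig = posterior_params(z_x, x_hat, s, t, schedule)
    mu_h, _ = posterior_params(z_h, h_hat, s, t, schedule)
    if rng is None or noise_scale == 0.0 or sig == 0.0:
        return mu_x, mu_h
    rng = as_rng(rng)
    if com_free:
        nx = sample_com_free_noise(mu_x.shape, rng)
    else:
        nx = rng.standard_normal(mu_x.shape)
    nh = rng.standard_normal(mu_h.shape)
    return mu_x + noise_scale * sig * nx, mu_h + noise_scale * sig * nh


def _flatten(parts) -> np.ndarray:
    if isinstance(parts, (tuple, list)):
        return np.concatenate([np.asarray(p, dtype=float).ravel() for p in parts])
    return np.asarray(parts, dtype=float).ravel()


def simplified_loss(eps, eps_hat) -> float:
    """Training objective: half the mean squared error over all components.

    Accepts single arrays or (coordinate, feature) tuples; the mean runs
    over every scalar component jointly.
    """
    e = _flatten(eps)
    eh = _flatten(eps_hat)
    if e.shape != eh.shape:
        raise ValueError("noise shape mismatch")
    return float(0.5 * np.mean((e - eh) ** 2))


def vlb_terms(
    x_coords: np.ndarray,
    x_feats: np.ndarray,
    model,
    schedule: NoiseSchedule,
    rng,
) -> tuple[float, list[float], float]:
    """Diagnostic variational-bound terms (L_0, [L_1..L_T-ish], L_T).

    L_T is the KL between the terminal forward marginal and the standard
    normal prior; each diffusion term is the SNR-ratio-weighted squared
    noise-prediction error 0.5 (SNR(s)/SNR(t) - 1) ||eps - eps_hat||^2
    with a single Monte-Carlo noise draw.  ``model`` maps
    ``(z_x, z_h, t)`` to ``(eps_x_hat, eps_h_hat)``.  Training uses
    :func:`simplified_loss`; these terms are for inspection only.
    """
    rng = as_rng(rng)
    x_all = _flatten((x_coords, x_feats))
    a_T, s_T2 = schedule.alpha[schedule.T], schedule.sigma[schedule.T] ** 2
    # KL(N(a_T x, s_T^2) || N(0, 1)) summed over dimensions
    l_T = float(0.5 * np.sum(s_T2 + a_T**2 * x_all**2 - 1.0 - np.log(s_T2)))
    l_ts: list[float] = []
    for t in range(1, schedule.T + 1):
        z, (eps_x, eps_h) = forward_diffuse(x_coords, x_feats, t, schedule, rng)
        eps_x_hat, eps_h_hat = model(z.z_x, z.z_h, t)
        err2 = float(
            np.sum((_flatten((eps_x, eps_h)) - _flatten((eps_x_hat, eps_h_hat))) ** 2)
        )
        w = schedule.snr[t - 1] / schedule.snr[t] - 1.0
        l_ts.append(0.5 * w * err2)
    # reconstruction term with the t=1 latent mapped back through the model
    z1, _ = forward_diffuse(x_coords, x_feats, 1, schedule, rng)
    ex, eh = model(z1.z_x, z1.z_h, 1)
    xc = predict_clean(z1.z_x, ex, 1, schedule)
    xh = predict_clean(z1.z_h, eh, 1, schedule)
    scale2 = (schedule.sigma[1] / schedule.alpha[1]) ** 2
    resid2 = float(np.sum((_flatten((xc, xh)) - x_all) ** 2))
    d = x_all.size
    l_0 = float(0.5 * (d * np.log(2 * np.pi * scale2) + resid2 / scale2))
    return l_0, l_ts, l_T
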