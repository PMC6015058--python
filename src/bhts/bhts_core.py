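"""Two-channel hierarchical Dirichlet process Gaussian mixture for
multi-plate screens, with a truncated stick-breaking blocked Gibbs sampler.

Each compound readout is modeled as a draw from either an "active" or an
"inactive" mixture channel.  Within a channel, every plate carries a local
truncated DP over H clusters; local clusters point at K global Gaussian
atoms shared across plates, so plates selectively share components.  The
sampler alternates conjugate conditional updates and reports, per compound
well, the posterior probability of being active.

Channels are indexed 0 (inactive) and 1 (active) throughout; identifiability
is anchored only through the prior means ``mu10 > mu00``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateDataError, DomainError, ValidationError
from .plate_io import ScreenDataset

__all__ = [
    "BhtsHyperparameters",
    "MCMCState",
    "PosteriorSummary",
    "auto_hyperparameters",
    "stick_weights",
    "mixture_density",
    "init_state",
    "gibbs_step",
    "run_sampler",
    "nig_posterior",
    "sample_readouts_from_state",
]

_STICK_EPS = 1e-12
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class BhtsHyperparameters:
    """Prior constants and truncation levels for the two-HDP mixture.

    ``mu10``/``mu00`` anchor the active/inactive channel means; ``a``/``b``
    are the shared inverse-gamma shape/scale for kernel variances; ``H`` and
    ``K`` are the local and global stick-breaking truncations.
    """

    mu10: float
    mu00: float
    a: float
    b: float
    a_pi: float = 1.0
    b_pi: float = 1.0
    a_alpha: float = 1.0
    b_alpha: float = 1.0
    a_tau: float = 1.0
    b_tau: float = 1.0
    H: int = 10
    K: int = 20

    def validate(self) -> None:
        for name in ("a_pi", "b_pi", "a_alpha", "b_alpha", "a_tau", "b_tau", "a", "b"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"hyperparameter {name} must be positive")
        if not self.mu10 > self.mu00:
            raise ValidationError(
                f"mu10 ({self.mu10}) must exceed mu00 ({self.mu00})"
            )
        if self.H < 2:
            raise ValidationError("local truncation H must be >= 2")
        if self.K < self.H:
            raise ValidationError("global truncation K must be >= H")


def auto_hyperparameters(
    dataset: ScreenDataset,
    inv_gamma_var: float = 1e-4,
    **overrides,
) -> BhtsHyperparameters:
    """Derive ``{mu00, mu10, a, b}`` from the compound data.

    With ``mu`` the compound mean and ``v`` the compound sample variance:
    ``mu00 = 0.5 mu``, ``mu10 = 3 mu00``, ``a = v^2/inv_gamma_var + 2`` and
    ``b = v^3/inv_gamma_var + v`` — so the inverse-gamma variance prior has
    mean ``v`` and variance ``inv_gamma_var``.  Keyword overrides replace
    any derived or default field.
    """
    z = dataset.compound_readouts()
    if z.size < 2:
        raise DegenerateDataError("need at least 2 compound wells")
    mu = float(z.mean())
    v = float(z.var(ddof=1))
    if v == 0.0:
        raise DegenerateDataError("compound readouts have zero variance")
    if mu <= 0.0:
        raise DegenerateDataError(
            "compound mean is non-positive; the automatic rule would give "
            "mu10 <= mu00 — supply mu00/mu10 explicitly"
        )
    mu00 = 0.5 * mu
    mu10 = 3.0 * mu00
    a = v * v / inv_gamma_var + 2.0
    b = v ** 3 / inv_gamma_var + v
    hyper = BhtsHyperparameters(mu10=mu10, mu00=mu00, a=a, b=b)
    if overrides:
        hyper = replace(hyper, **overrides)
    hyper.validate()
    return hyper


def stick_weights(sticks: np.ndarray, axis: int = -1) -> np.ndarray:
    """Weights from finite stick-breaking: ``w_l = v_l * prod_{j<l}(1-v_j)``.

    The final stick must be 1 (truncation closure) so the weights sum to 1.
    """
    v = np.asarray(sticks, dtype=float)
    if np.any(v < 0.0) or np.any(v > 1.0):
        raise DomainError("stick variables must lie in [0, 1]")
    one_minus = 1.0 - v
    cum = np.cumprod(one_minus, axis=axis)
    shifted = np.roll(cum, 1, axis=axis)
    idx = [slice(None)] * v.ndim
    idx[axis] = 0
    shifted[tuple(idx)] = 1.0
    return v * shifted


@dataclass
class MCMCState:
    """One configuration of the Gibbs sampler.

    Array shapes: ``b``/``local_labels`` are ``(N,)`` over compound wells in
    canonical order; ``local_sticks``/``local_to_global`` are ``(M, 2, H)``;
    ``global_sticks``/``atom_means``/``atom_vars`` are ``(2, K)``;
    ``alpha``/``tau`` are ``(2,)``, indexed by channel (0 inactive, 1 active).
    """

    pi: float
    b: np.ndarray
    local_labels: np.ndarray
    local_to_global: np.ndarray
    local_sticks: np.ndarray
    global_sticks: np.ndarray
    atom_means: np.ndarray
    atom_vars: np.ndarray
    alpha: np.ndarray
    tau: np.ndarray

    @property
    def alpha0(self) -> float:
        return float(self.alpha[0])

    @property
    def alpha1(self) -> float:
        return float(self.alpha[1])

    @property
    def tau0(self) -> float:
        return float(self.tau[0])

    @property
    def tau1(self) -> float:
        return float(self.tau[1])

    def local_weights(self) -> np.ndarray:
        """(M, 2, H) plate-level mixture weights."""
        return stick_weights(self.local_sticks, axis=-1)

    def global_weights(self) -> np.ndarray:
        """(2, K) global atom weights."""
        return stick_weights(self.global_sticks, axis=-1)


@dataclass
class PosteriorSummary:
    """Posterior hit probabilities and scalar traces from one MCMC run."""

    hit_prob: np.ndarray
    traces: dict
    n_kept: int


def mixture_density(z, state: MCMCState, plate: int) -> np.ndarray:
    """Two-channel mixture density of readout(s) ``z`` on a given plate."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    lam = state.local_weights()[plate]  # (2, H)
    dens = np.zeros((2, z.size))
    for c in (0, 1):
        k = state.local_to_global[plate, c]  # (H,)
        mu = state.atom_means[c, k]
        var = state.atom_vars[c, k]
        norm = np.exp(
            -0.5 * (z[None, :] - mu[:, None]) ** 2 / var[:, None]
        ) / np.sqrt(2.0 * np.pi * var[:, None])
        dens[c] = lam[c] @ norm
    out = state.pi * dens[1] + (1.0 - state.pi) * dens[0]
    return out if out.size > 1 else float(out[0])


def _draw_sticks(rng, size_without_last, concentration):
    """Beta(1, concentration) sticks with the final stick forced to 1."""
    v = rng.beta(1.0, concentration, size=size_without_last)
    v = np.clip(v, _STICK_EPS, 1.0 - _STICK_EPS)
    pad_shape = list(v.shape)
    pad_shape[-1] = 1
    return np.concatenate([v, np.ones(pad_shape)], axis=-1)


def init_state(dataset: ScreenDataset, hyper: BhtsHyperparameters, seed: int) -> MCMCState:
    """Deterministic (seeded) initial configuration.

    Activity indicators start from thresholding at the compound mean; if
    that leaves either channel empty, the top 1% (at least one well) is
    forced active and the rest inactive.
    """
    hyper.validate()
    rng = np.random.default_rng(seed)
    z = dataset.compound_readouts()
    M, N, H, K = dataset.M, z.size, hyper.H, hyper.K

    b = (z > z.mean()).astype(np.int64)
    if b.sum() == 0 or b.sum() == N:
        n_top = max(1, N // 100)
        b = np.zeros(N, dtype=np.int64)
        b[np.argsort(z)[-n_top:]] = 1

    local_labels = rng.integers(0, H, size=N)
    local_to_global = rng.integers(0, K, size=(M, 2, H))
    alpha_mean = hyper.a_alpha / hyper.b_alpha
    tau_mean = hyper.a_tau / hyper.b_tau
    local_sticks = _draw_sticks(rng, (M, 2, H - 1), alpha_mean)
    global_sticks = _draw_sticks(rng, (2, K - 1), tau_mean)
    atom_vars = 1.0 / rng.gamma(hyper.a, 1.0 / hyper.b, size=(2, K))
    mu0 = np.array([hyper.mu00, hyper.mu10])
    atom_means = rng.normal(mu0[:, None], np.sqrt(atom_vars))
    return MCMCState(
        pi=hyper.a_pi / (hyper.a_pi + hyper.b_pi),
        b=b,
        local_labels=local_labels,
        local_to_global=local_to_global,
        local_sticks=local_sticks,
        global_sticks=global_sticks,
        atom_means=atom_means,
        atom_vars=atom_vars,
        alpha=np.array([alpha_mean, alpha_mean]),
        tau=np.array([tau_mean, tau_mean]),
    )


def nig_posterior(n, s1, s2, mu0, a, b, kappa0: float = 1.0):
    """Normal-inverse-gamma posterior parameters given sufficient statistics.

    ``n``, ``s1``, ``s2`` are the count, sum and sum of squares of the
    assigned observations (arrays broadcast elementwise).  Returns
    ``(mu_n, kappa_n, a_n, b_n)``; with ``n = 0`` the prior is returned.
    """
    n = np.asarray(n, dtype=float)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    kappa_n = kappa0 + n
    mu_n = (kappa0 * mu0 + s1) / kappa_n
    a_n = a + 0.5 * n
    nz = n > 0
    zbar = np.where(nz, s1 / np.maximum(n, 1.0), 0.0)
    ss = np.where(nz, s2 - n * zbar ** 2, 0.0)
    ss = np.maximum(ss, 0.0)  # guard tiny negative round-off
    b_n = b + 0.5 * ss + np.where(nz, kappa0 * n * (zbar - mu0) ** 2 / (2.0 * kappa_n), 0.0)
    return mu_n, kappa_n, a_n, b_n


def _well_log_densities(z, pidx, state):
    """(N, 2, H) log of (local weight x normal kernel) per well.

    Only the quadratic term is evaluated per well; the weight/normalizer
    coefficients are shared per (plate, channel, cluster).
    """
    lam = state.local_weights()  # (M, 2, H)
    mu_loc = np.take_along_axis(
        state.atom_means[None, :, :], state.local_to_global, axis=2
    )  # (M, 2, H)
    var_loc = np.take_along_axis(
        state.atom_vars[None, :, :], state.local_to_global, axis=2
    )
    const = np.log(lam) - 0.5 * (_LOG2PI + np.log(var_loc))  # (M, 2, H)
    prec = 0.5 / var_loc
    diff = z[:, None, None] - mu_loc[pidx]
    return const[pidx] - diff * diff * prec[pidx]


def gibbs_step(
    state: MCMCState,
    dataset: ScreenDataset,
    hyper: BhtsHyperparameters,
    rng: np.random.Generator,
) -> MCMCState:
    """One full Gibbs sweep in fixed order.

    Order: activity indicators, local labels, local-to-global maps, local
    sticks, global sticks, atoms, pi, concentrations.  Components with no
    assigned data are refreshed from their priors (the conjugate updates
    reduce to the priors at zero counts).  The generator is consumed in a
    data-independent order, so runs are reproducible bit-for-bit.
    """
    z = dataset.compound_readouts()
    pidx = dataset.compound_plate_index()
    M, N, H, K = dataset.M, z.size, hyper.H, hyper.K

    # (1) activity indicators
    logd = _well_log_densities(z, pidx, state)  # (N, 2, H)
    flat = logd.reshape(N, 2 * H)
    shift = flat.max(axis=1, keepdims=True)
    e = np.exp(flat - shift)  # shared by steps (1) and (2)
    f0 = e[:, :H].sum(axis=1)
    f1 = e[:, H:].sum(axis=1)
    num = state.pi * f1
    p1 = num / (num + (1.0 - state.pi) * f0)
    b = (rng.random(N) < p1).astype(np.int64)

    # (2) local labels within the sampled channel
    probs = np.where(b[:, None] == 1, e[:, H:], e[:, :H])
    cs = np.cumsum(probs, axis=1)
    u = rng.random(N) * cs[:, -1]
    local_labels = (cs < u[:, None]).sum(axis=1)

    # (3) local-to-global maps, via per-cluster sufficient statistics
    G = M * 2 * H
    g = (pidx * 2 + b) * H + local_labels
    cnt = np.bincount(g, minlength=G).reshape(M, 2, H)
    s1 = np.bincount(g, weights=z, minlength=G).reshape(M, 2, H)
    s2 = np.bincount(g, weights=z * z, minlength=G).reshape(M, 2, H)
    mu_a = state.atom_means[None, :, None, :]  # (1, 2, 1, K)
    var_a = state.atom_vars[None, :, None, :]
    ll = (
        -0.5 * cnt[..., None] * (_LOG2PI + np.log(var_a))
        - (s2[..., None] - 2.0 * mu_a * s1[..., None] + cnt[..., None] * mu_a ** 2)
        / (2.0 * var_a)
    )
    lam_g = stick_weights(state.global_sticks, axis=-1)  # (2, K)
    logp = np.log(lam_g)[None, :, None, :] + ll
    gumbel = rng.gumbel(size=(M, 2, H, K))
    local_to_global = np.argmax(logp + gumbel, axis=-1)

    # (4a) local sticks: Beta(1 + n_mh, alpha_c + sum_{l>h} n_ml)
    tail = cnt[..., ::-1].cumsum(axis=-1)[..., ::-1] - cnt
    alpha_c = state.alpha[None, :, None]
    v_loc = rng.beta(
        1.0 + cnt[..., : H - 1], alpha_c + tail[..., : H - 1]
    )
    v_loc = np.clip(v_loc, _STICK_EPS, 1.0 - _STICK_EPS)
    local_sticks = np.concatenate([v_loc, np.ones((M, 2, 1))], axis=-1)

    # (4b) global sticks from local-cluster occupancy of atoms
    gcnt = np.zeros((2, K), dtype=float)
    for c in (0, 1):
        gcnt[c] = np.bincount(local_to_global[:, c, :].ravel(), minlength=K)
    gtail = gcnt[:, ::-1].cumsum(axis=1)[:, ::-1] - gcnt
    v_glob = rng.beta(
        1.0 + gcnt[:, : K - 1], state.tau[:, None] + gtail[:, : K - 1]
    )
    v_glob = np.clip(v_glob, _STICK_EPS, 1.0 - _STICK_EPS)
    global_sticks = np.concatenate([v_glob, np.ones((2, 1))], axis=-1)

    # (5) atoms: normal-inverse-gamma conjugate update per (channel, atom)
    atom_of_well = local_to_global[pidx, b, local_labels]
    ak = b * K + atom_of_well
    a_cnt = np.bincount(ak, minlength=2 * K).reshape(2, K)
    a_s1 = np.bincount(ak, weights=z, minlength=2 * K).reshape(2, K)
    a_s2 = np.bincount(ak, weights=z * z, minlength=2 * K).reshape(2, K)
    mu0 = np.array([hyper.mu00, hyper.mu10])[:, None]
    mu_n, kappa_n, a_n, b_n = nig_posterior(a_cnt, a_s1, a_s2, mu0, hyper.a, hyper.b)
    atom_vars = 1.0 / rng.gamma(a_n, 1.0 / b_n)
    atom_means = rng.normal(mu_n, np.sqrt(atom_vars / kappa_n))

    # (6) mixing proportion
    n1 = int(b.sum())
    pi = float(rng.beta(hyper.a_pi + n1, hyper.b_pi + N - n1))
    pi = min(max(pi, 1e-12), 1.0 - 1e-12)

    # (7) concentrations from their gamma conditionals
    log1m_loc = np.log1p(-local_sticks[..., : H - 1])  # (M, 2, H-1)
    rate_a = hyper.b_alpha - log1m_loc.sum(axis=(0, 2))  # per channel
    alpha = rng.gamma(hyper.a_alpha + M * (H - 1), 1.0 / rate_a)
    log1m_glob = np.log1p(-global_sticks[:, : K - 1])
    rate_t = hyper.b_tau - log1m_glob.sum(axis=1)
    tau = rng.gamma(hyper.a_tau + (K - 1), 1.0 / rate_t)

    return MCMCState(
        pi=pi,
        b=b,
        local_labels=local_labels,
        local_to_global=local_to_global,
        local_sticks=local_sticks,
        global_sticks=global_sticks,
        atom_means=atom_means,
        atom_vars=atom_vars,
        alpha=alpha,
        tau=tau,
    )


def run_sampler(
    dataset: ScreenDataset,
    hyper: BhtsHyperparameters,
    n_iter: int = 7000,
    burn_in: int = 2000,
    thin: int = 5,
    seed: int = 0,
) -> PosteriorSummary:
    """Run the blocked Gibbs sampler and summarize the posterior.

    ``hit_prob[i]`` is the fraction of kept iterations in which compound
    well ``i`` was assigned to the active channel.  Traces record, per kept
    iteration: ``pi``, both concentrations per level, and the
    global-weight-averaged atom mean of each channel.
    """
    hyper.validate()
    if not (n_iter > burn_in >= 0):
        raise ValidationError("need n_iter > burn_in >= 0")
    if thin < 1:
        raise ValidationError("thin must be >= 1")
    state = init_state(dataset, hyper, seed)
    rng = np.random.default_rng([seed, 0xB1175])
    N = dataset.n_compound_wells
    hit_counts = np.zeros(N)
    trace_names = ("pi", "alpha0", "alpha1", "tau0", "tau1", "mu_inactive", "mu_active")
    traces = {name: [] for name in trace_names}
    n_kept = 0
    for it in range(1, n_iter + 1):
        state = gibbs_step(state, dataset, hyper, rng)
        if it > burn_in and (it - burn_in - 1) % thin == 0:
            n_kept += 1
            hit_counts += state.b
            w = state.global_weights()
            traces["pi"].append(state.pi)
            traces["alpha0"].append(state.alpha0)
            traces["alpha1"].append(state.alpha1)
            traces["tau0"].append(state.tau0)
            traces["tau1"].append(state.tau1)
            traces["mu_inactive"].append(float((w[0] * state.atom_means[0]).sum()))
            traces["mu_active"].append(float((w[1] * state.atom_means[1]).sum()))
    traces = {k: np.asarray(v) for k, v in traces.items()}
    return PosteriorSummary(hit_prob=hit_counts / n_kept, traces=traces, n_kept=n_kept)


def sample_readouts_from_state(
    state: MCMCState, dataset: ScreenDataset, rng: np.random.Generator
):
    """Draw readouts (and activity indicators) from the model given a state.

    Used for generating data from the model itself (parameter-recovery and
    prior/posterior consistency checks).  Returns ``(z, b)`` flat over the
    compound wells of ``dataset``.
    """
    pidx = dataset.compound_plate_index()
    N = pidx.size
    b = (rng.random(N) < state.pi).astype(np.int64)
    lam = state.local_weights()  # (M, 2, H)
    probs = lam[pidx, b, :]  # (N, H)
    cs = np.cumsum(probs, axis=1)
    u = rng.random(N) * cs[:, -1]
    h = (cs < u[:, None]).sum(axis=1)
    k = state.local_to_global[pidx, b, h]
    mu = state.atom_means[b, k]
    sd = np.sqrt(state.atom_vars[b, k])
    z = rng.normal(mu, sd)
    return z, b
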