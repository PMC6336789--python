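"""Variational Bayesian inference for hidden Markov models with full
multivariate-Gaussian emissions (VBEM-MGHMM).

Each hidden state k emits an observation vector (here: spot signal and
local background, which are correlated and have non-zero means) from a
full-covariance Gaussian.  Conjugate priors are placed on everything:
Dirichlet on the initial distribution and on each transition-matrix row,
Normal–Wishart on each state's mean and precision.  The variational
posterior factorizes over the state path and the parameters, and evidence
maximization alternates

* **E-step** — forward–backward under the *expected* log transition
  probabilities and log emission densities (digamma/log-det expectations),
  numerically scaled per frame;
* **M-step** — closed-form conjugate updates of the Dirichlet and
  Normal–Wishart hyperparameters from the expected sufficient statistics.

The evidence lower bound (ELBO) is the scaled forward normalizer minus the
KL divergences of all parameter posteriors from their priors; it is exact
for this factorization and provably nondecreasing over iterations.  Model
order is selected by fitting each candidate K and taking the largest ELBO
(ties broken toward fewer states): the bound penalizes extra parameters
automatically, so no external criterion is needed.  Because the bound
weighs data against priors, small datasets are biased toward the prior
(under-selection) while very large datasets can over-select — the per-K
ELBO table is retained for that diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.special import digamma, gammaln

_LOG2 = np.log(2.0)
_LOG2PI = np.log(2.0 * np.pi)


class VBEMError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Priors and posterior containers
# ---------------------------------------------------------------------------

@dataclass
class MGHMMPriors:
    """Conjugate hyperparameters shared by all states.

    ``m`` is the prior emission mean (photons; typically the mean signal
    and background of one identified binding event); ``kappa`` scales the
    mean's precision; ``nu`` is the Wishart degrees of freedom and
    ``W_sqrt`` sets the scale so that the prior expected emission
    *variance* per dimension is ``W_sqrt**2`` (the Wishart scale matrix is
    ``W0 = I / (nu * W_sqrt**2)``, giving ``E[Lambda] = I / W_sqrt**2``).
    ``kappa = nu = W_sqrt = 10`` are the packaged model-order-selection
    defaults.  Dirichlet concentrations default to 1 (symmetric,
    uninformative).
    """

    m: np.ndarray = field(default_factory=lambda: np.array([300.0, 50.0]))
    kappa: float = 10.0
    nu: float = 10.0
    W_sqrt: float | np.ndarray = 10.0
    dirichlet_init: float = 1.0
    dirichlet_trans: float = 1.0

    def __post_init__(self) -> None:
        self.m = np.atleast_1d(np.asarray(self.m, dtype=float))
        d = self.m.size
        if self.kappa <= 0:
            raise VBEMError("kappa must be positive")
        if self.nu <= d - 1:
            raise VBEMError("nu must exceed dimension - 1")
        if np.any(np.atleast_1d(self.W_sqrt) <= 0):
            raise VBEMError("W_sqrt must be positive")
        if self.dirichlet_init <= 0 or self.dirichlet_trans <= 0:
            raise VBEMError("Dirichlet concentrations must be positive")

    @property
    def dim(self) -> int:
        return self.m.size

    def W0(self) -> np.ndarray:
        w = np.broadcast_to(np.atleast_1d(np.asarray(self.W_sqrt, dtype=float)),
                            (self.dim,))
        return np.diag(1.0 / (self.nu * w**2))

    def to_dict(self) -> dict:
        return {"m": self.m.tolist(), "kappa": self.kappa, "nu": self.nu,
                "W_sqrt": (np.asarray(self.W_sqrt).tolist()
                           if np.ndim(self.W_sqrt) else float(self.W_sqrt)),
                "dirichlet_init": self.dirichlet_init,
                "dirichlet_trans": self.dirichlet_trans}

    @classmethod
    def from_dict(cls, d: dict) -> "MGHMMPriors":
        return cls(m=np.asarray(d["m"], dtype=float), kappa=float(d["kappa"]),
                   nu=float(d["nu"]),
                   W_sqrt=np.asarray(d["W_sqrt"], dtype=float)
                   if np.ndim(d["W_sqrt"]) else float(d["W_sqrt"]),
                   dirichlet_init=float(d.get("dirichlet_init", 1.0)),
                   dirichlet_trans=float(d.get("dirichlet_trans", 1.0)))


@dataclass
class MGHMMPosterior:
    """Fitted variational posterior for one model order K."""

    K: int
    priors: MGHMMPriors
    alpha_init: np.ndarray          # Dirichlet, (K,)
    alpha_trans: np.ndarray         # Dirichlet, (K, K)
    m: np.ndarray                   # Normal-Wishart means, (K, D)
    kappa: np.ndarray               # (K,)
    nu: np.ndarray                  # (K,)
    W: np.ndarray                   # Wishart scales, (K, D, D)
    elbo_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False
    order: np.ndarray | None = None  # state relabelling by ascending signal

    @property
    def elbo(self) -> float:
        return float(self.elbo_trace[-1]) if len(self.elbo_trace) else -np.inf

    def expected_means(self) -> np.ndarray:
        """Posterior emission means, in occupancy order if available."""
        means = self.m
        return means[self.order] if self.order is not None else means

    def expected_covariances(self) -> np.ndarray:
        covs = np.stack([np.linalg.inv(self.W[k]) / (self.nu[k] - self.priors.dim - 1)
                         if self.nu[k] > self.priors.dim + 1
                         else np.linalg.inv(self.W[k]) / self.nu[k]
                         for k in range(self.K)])
        return covs[self.order] if self.order is not None else covs

    def expected_transition(self) -> np.ndarray:
        """Posterior-mean transition matrix, occupancy-ordered."""
        a = self.alpha_trans / self.alpha_trans.sum(axis=1, keepdims=True)
        if self.order is not None:
            a = a[np.ix_(self.order, self.order)]
        return a

    def expected_initial(self) -> np.ndarray:
        p = self.alpha_init / self.alpha_init.sum()
        return p[self.order] if self.order is not None else p

    def occupancy(self) -> np.ndarray:
        """Expected long-run fraction of time per state (stationary law)."""
        a = self.expected_transition()
        vals, vecs = np.linalg.eig(a.T)
        pi = np.abs(np.real(vecs[:, np.argmin(np.abs(vals - 1.0))]))
        return pi / pi.sum()


# ---------------------------------------------------------------------------
# Internal helpers
# ---------------------------------------------------------------------------

def _as_trace_list(observations) -> list[np.ndarray]:
    if isinstance(observations, np.ndarray):
        if observations.ndim == 3:
            return [observations[i] for i in range(observations.shape[0])]
        if observations.ndim == 2:
            return [observations]
        return [np.atleast_2d(observations).T]
    out = []
    for tr in observations:
        tr = np.asarray(tr, dtype=float)
        if tr.ndim == 1:
            tr = tr[:, None]
        out.append(tr)
    return out


def _group_by_length(traces: list[np.ndarray]) -> list[tuple[np.ndarray, np.ndarray]]:
    """Batch traces of equal length into (indices, (n, T, D)) groups."""
    by_len: dict[int, list[int]] = {}
    for i, tr in enumerate(traces):
        by_len.setdefault(len(tr), []).append(i)
    groups = []
    for length, idx in sorted(by_len.items()):
        batch = np.stack([traces[i] for i in idx])
        groups.append((np.array(idx), batch))
    return groups


def _expected_log_gauss(batch: np.ndarray, m: np.ndarray, kappa: np.ndarray,
                        nu: np.ndarray, W: np.ndarray) -> np.ndarray:
    """E_q[log N(x | mu_k, Lambda_k^{-1})] for every frame and state.

    ``batch`` is (n, T, D); returns (n, T, K).
    """
    n, T, D = batch.shape
    K = m.shape[0]
    ds = np.arange(D)
    logdet_tilde = (digamma((nu[:, None] - ds[None, :]) / 2.0).sum(axis=1)
                    + D * _LOG2
                    + np.array([np.linalg.slogdet(W[k])[1] for k in range(K)]))
    diff = batch[:, :, None, :] - m[None, None, :, :]          # (n,T,K,D)
    quad = np.einsum("ntkd,kde,ntke->ntk", diff, W, diff)
    return 0.5 * (logdet_tilde[None, None, :] - D / kappa[None, None, :]
                  - nu[None, None, :] * quad - D * _LOG2PI)


def _forward_backward_batch(log_emis: np.ndarray, log_pi: np.ndarray,
                            log_trans: np.ndarray):
    """Scaled forward-backward for a batch of equal-length traces.

    ``log_emis`` is (n, T, K) expected log emissions; ``log_pi`` (K,) and
    ``log_trans`` (K, K) expected log initial/transition terms.  Returns
    (gamma (n,T,K), xi_sum (K,K), gamma0_sum (K,), logZ scalar).
    """
    n, T, K = log_emis.shape
    shift = log_emis.max(axis=2, keepdims=True)
    emis = np.exp(log_emis - shift)                            # (n,T,K)
    A = np.exp(log_trans)
    pi = np.exp(log_pi)

    alpha = np.empty((n, T, K))
    c = np.empty((n, T))
    a = pi[None, :] * emis[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * emis[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / np.clip(c[:, t, None], 1e-300, None)

    beta = np.ones((n, K))
    gamma = np.empty((n, T, K))
    gamma[:, T - 1] = alpha[:, T - 1]
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        be = beta * emis[:, t + 1]                             # (n,K)
        xi = alpha[:, t, :, None] * A[None, :, :] * be[:, None, :]
        xi /= np.clip(xi.sum(axis=(1, 2), keepdims=True), 1e-300, None)
        xi_sum += xi.sum(axis=0)
        beta = (be @ A.T) / np.clip(c[:, t + 1, None], 1e-300, None)
        g = alpha[:, t] * beta
        gamma[:, t] = g / np.clip(g.sum(axis=1, keepdims=True), 1e-300, None)

    log_z = float(np.log(np.clip(c, 1e-300, None)).sum() + shift.sum())
    return gamma, xi_sum, gamma[:, 0].sum(axis=0), log_z


def _kl_dirichlet(aq: np.ndarray, ap: np.ndarray) -> float:
    aq = np.asarray(aq, dtype=float)
    ap = np.asarray(ap, dtype=float)
    sq = aq.sum()
    return float(gammaln(sq) - gammaln(aq).sum()
                 - gammaln(ap.sum()) + gammaln(ap).sum()
                 + ((aq - ap) * (digamma(aq) - digamma(sq))).sum())


def _log_wishart_b(W: np.ndarray, nu: float) -> float:
    D = W.shape[0]
    ds = np.arange(D)
    return float(-(nu / 2.0) * np.linalg.slogdet(W)[1]
                 - (nu * D / 2.0) * _LOG2 - (D * (D - 1) / 4.0) * np.log(np.pi)
                 - gammaln((nu - ds) / 2.0).sum())


def _kl_normal_wishart(mq, kq, nuq, Wq, m0, k0, nu0, W0) -> float:
    D = len(mq)
    ds = np.arange(D)
    elogdet = (digamma((nuq - ds) / 2.0).sum() + D * _LOG2
               + np.linalg.slogdet(Wq)[1])
    diff = mq - m0
    kl_normal = 0.5 * (D * np.log(kq / k0) + D * (k0 / kq - 1.0)
                       + k0 * nuq * diff @ Wq @ diff)
    kl_wishart = (_log_wishart_b(Wq, nuq) - _log_wishart_b(W0, nu0)
                  + ((nuq - nu0) / 2.0) * elogdet
                  - 0.5 * nuq * D
                  + 0.5 * nuq * np.trace(np.linalg.inv(W0) @ Wq))
    return float(kl_normal + kl_wishart)


def _init_responsibilities(data: np.ndarray, K: int, rng: np.random.Generator,
                           perturb: float) -> np.ndarray:
    """Soft one-hot responsibilities from seeded k-means, optionally jittered."""
    n = data.shape[0]
    if K == 1:
        return np.ones((n, 1))
    _, labels = kmeans2(data, K, minit="++",
                        seed=int(rng.integers(2**31 - 1)))
    resp = np.full((n, K), 0.05 / max(K - 1, 1))
    resp[np.arange(n), labels] = 0.95
    if perturb > 0:
        resp = resp + perturb * rng.random((n, K))
    return resp / resp.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# VBEM core
# ---------------------------------------------------------------------------

def vbem_fit(observations, K: int, priors: MGHMMPriors | None = None,
             restarts: int = 3, seed: int = 0, max_iter: int = 500,
             tol: float = 1e-8,
             init_posterior: MGHMMPosterior | None = None) -> MGHMMPosterior:
    """Fit the K-state MGHMM by variational Bayesian evidence maximization.

    ``observations`` is an ``(n_traces, T, D)`` array, a list of
    ``(T_i, D)`` arrays, or a single trace.  The best of ``restarts``
    seeded k-means(+jitter) initializations is returned; iteration stops
    when the relative ELBO change drops below ``tol``.  Passing
    ``init_posterior`` warm-starts a single run from an earlier fit (used
    by bootstrap refits).

    The returned posterior's ``elbo_trace`` is checked nondecreasing; a
    decrease beyond numerical tolerance raises, since it would indicate a
    broken update.
    """
    traces = _as_trace_list(observations)
    if not traces or any(len(t) == 0 for t in traces):
        raise VBEMError("observations must be nonempty traces")
    if K < 1:
        raise VBEMError("K must be >= 1")
    D = traces[0].shape[1]
    if priors is None:
        priors = MGHMMPriors(m=np.zeros(D))
    if priors.dim != D:
        raise VBEMError("prior mean dimension mismatch")
    groups = _group_by_length(traces)
    pooled = np.concatenate(traces, axis=0)
    n_points = pooled.shape[0]
    rng = np.random.default_rng(seed)

    W0 = priors.W0()
    W0_inv = np.linalg.inv(W0)
    prior_ai = np.full(K, priors.dirichlet_init)
    prior_at = np.full((K, K), priors.dirichlet_trans)

    def m_step_from_stats(Nk, xbar, Sk, gamma0, xi_sum):
        kappa_q = priors.kappa + Nk
        nu_q = priors.nu + Nk
        m_q = (priors.kappa * priors.m[None, :] + Nk[:, None] * xbar) \
            / kappa_q[:, None]
        W_q = np.empty((K, D, D))
        for k in range(K):
            diff = (xbar[k] - priors.m)[:, None]
            W_inv = W0_inv + Nk[k] * Sk[k] \
                + (priors.kappa * Nk[k] / (priors.kappa + Nk[k])) * (diff @ diff.T)
            W_inv = 0.5 * (W_inv + W_inv.T)
            try:
                W_q[k] = np.linalg.inv(W_inv)
            except np.linalg.LinAlgError as exc:
                raise VBEMError("non-positive-definite scale update") from exc
        return (prior_ai + gamma0, prior_at + xi_sum, m_q, kappa_q, nu_q, W_q)

    def e_step(post):
        log_pi = digamma(post[0]) - digamma(post[0].sum())
        log_trans = digamma(post[1]) - digamma(post[1].sum(axis=1))[:, None]
        Nk = np.zeros(K)
        xsum = np.zeros((K, D))
        ssum = np.zeros((K, D, D))
        xi_sum = np.zeros((K, K))
        gamma0 = np.zeros(K)
        log_z = 0.0
        for _, batch in groups:
            le = _expected_log_gauss(batch, post[2], post[3], post[4], post[5])
            gamma, xi, g0, lz = _forward_backward_batch(le, log_pi, log_trans)
            log_z += lz
            xi_sum += xi
            gamma0 += g0
            flat_g = gamma.reshape(-1, K)
            flat_x = batch.reshape(-1, D)
            Nk += flat_g.sum(axis=0)
            xsum += flat_g.T @ flat_x
            ssum += np.einsum("nk,nd,ne->kde", flat_g, flat_x, flat_x)
        Nk_safe = np.clip(Nk, 1e-10, None)
        xbar = xsum / Nk_safe[:, None]
        Sk = ssum / Nk_safe[:, None, None] \
            - np.einsum("kd,ke->kde", xbar, xbar)
        return Nk, xbar, Sk, gamma0, xi_sum, log_z

    def elbo_of(post, log_z):
        kl = _kl_dirichlet(post[0], prior_ai)
        for i in range(K):
            kl += _kl_dirichlet(post[1][i], prior_at[i])
        for k in range(K):
            kl += _kl_normal_wishart(post[2][k], post[3][k], post[4][k],
                                     post[5][k], priors.m, priors.kappa,
                                     priors.nu, W0)
        return log_z - kl

    def run(start_post):
        elbos = []
        post = start_post
        for _ in range(max_iter):
            Nk, xbar, Sk, gamma0, xi_sum, log_z = e_step(post)
            elbo = elbo_of(post, log_z)
            if elbos and elbo < elbos[-1] - 1e-6 * max(1.0, abs(elbos[-1])):
                raise VBEMError("ELBO decreased: broken variational update")
            done = bool(elbos) and \
                abs(elbo - elbos[-1]) <= tol * max(1.0, abs(elbo))
            elbos.append(elbo)
            post = m_step_from_stats(Nk, xbar, Sk, gamma0, xi_sum)
            if done:
                break
        return post, np.array(elbos)

    candidates = []
    failures = []
    if init_posterior is not None:
        starts = [(init_posterior.alpha_init, init_posterior.alpha_trans,
                   init_posterior.m, init_posterior.kappa,
                   init_posterior.nu, init_posterior.W)]
    else:
        starts = []
        for r in range(max(restarts, 1)):
            resp = _init_responsibilities(pooled, K, rng,
                                          perturb=0.0 if r == 0 else 0.3)
            Nk = resp.sum(axis=0)
            Nk_safe = np.clip(Nk, 1e-10, None)
            xbar = resp.T @ pooled / Nk_safe[:, None]
            Sk = (np.einsum("nk,nd,ne->kde", resp, pooled, pooled)
                  / Nk_safe[:, None, None]
                  - np.einsum("kd,ke->kde", xbar, xbar))
            # transition counts from hard labels of the init responsibilities
            labels = resp.argmax(axis=1)
            xi0 = np.zeros((K, K))
            np.add.at(xi0, (labels[:-1], labels[1:]), 1.0)
            g0 = resp[0]
            starts.append(m_step_from_stats(Nk, xbar, Sk, g0, xi0))
    for start in starts:
        try:
            post, elbos = run(start)
            candidates.append((post, elbos))
        except (VBEMError, np.linalg.LinAlgError) as exc:
            failures.append(str(exc))
    if not candidates:
        raise VBEMError("all restarts failed: " + "; ".join(failures))
    post, elbos = max(candidates, key=lambda c: c[1][-1])
    order = np.argsort(post[2][:, 0])       # ascending signal mean
    result = MGHMMPosterior(
        K=K, priors=priors, alpha_init=post[0], alpha_trans=post[1],
        m=post[2], kappa=post[3], nu=post[4], W=post[5],
        elbo_trace=elbos, converged=len(elbos) < max_iter, order=order)
    result.n_points = n_points
    return result


def select_order(observations, K_range, priors: MGHMMPriors | None = None,
                 restarts: int = 3, seed: int = 0, max_iter: int = 500,
                 ) -> tuple[int, dict[int, MGHMMPosterior]]:
    """Fit every candidate order and select the K with the largest ELBO.

    Ties (ELBO plateaus within 1e-6 relative) break toward smaller K
    (parsimony).  Failed fits are excluded from the argmax but reported in
    the returned table as ``None``.
    """
    ks = sorted(set(int(k) for k in K_range))
    if not ks:
        raise VBEMError("K_range must be nonempty")
    table: dict[int, MGHMMPosterior | None] = {}
    best_k, best_elbo = None, -np.inf
    for k in ks:
        try:
            post = vbem_fit(observations, k, priors, restarts=restarts,
                            seed=seed + k, max_iter=max_iter)
        except VBEMError:
            table[k] = None
            continue
        table[k] = post
        if best_k is None or \
                post.elbo > best_elbo + 1e-6 * max(1.0, abs(best_elbo)):
            best_k, best_elbo = k, post.elbo
    if best_k is None:
        raise VBEMError("every model order failed to fit")
    return best_k, table


def decode_states(posterior: MGHMMPosterior, observations) -> list[np.ndarray]:
    """Viterbi state sequences under the posterior-expected parameters.

    States are relabelled by ascending signal mean, so label k reads as
    "k bound complexes" (S_0 ... S_K-1).  Returns one integer array per
    trace, in the input order.
    """
    traces = _as_trace_list(observations)
    log_pi = digamma(posterior.alpha_init) - digamma(posterior.alpha_init.sum())
    log_trans = digamma(posterior.alpha_trans) \
        - digamma(posterior.alpha_trans.sum(axis=1))[:, None]
    order = posterior.order if posterior.order is not None \
        else np.arange(posterior.K)
    relabel = np.empty(posterior.K, dtype=int)
    relabel[order] = np.arange(posterior.K)

    out: list[np.ndarray | None] = [None] * len(traces)
    for idx, batch in _group_by_length(traces):
        le = _expected_log_gauss(batch, posterior.m, posterior.kappa,
                                 posterior.nu, posterior.W)
        n, T, K = le.shape
        delta = log_pi[None, :] + le[:, 0]
        back = np.zeros((n, T, K), dtype=np.int64)
        for t in range(1, T):
            cand = delta[:, :, None] + log_trans[None, :, :]
            back[:, t] = cand.argmax(axis=1)
            delta = cand.max(axis=1) + le[:, t]
        states = np.empty((n, T), dtype=np.int64)
        states[:, T - 1] = delta.argmax(axis=1)
        for t in range(T - 2, -1, -1):
            states[:, t] = back[np.arange(n), t + 1, states[:, t + 1]]
        for j, i in enumerate(idx):
            out[i] = relabel[states[j]]
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Occupancy-level kinetics
# ---------------------------------------------------------------------------

def occupancy_rates(labels, frame_interval_s: float = 0.1,
                    concentration_M: float | None = None,
                    n_boot: int = 200, seed: int = 0) -> dict:
    """Per-occupancy-level association/dissociation rates and their ratios.

    ``labels`` is a list/array of per-frame occupancy sequences (integers,
    k = number of bound complexes).  The rate out of level k upward is the
    count of k->k+1 transitions divided by the total time spent at level
    k; downward likewise.  Reports the ratios
    ``kon_ratio = rate(1->2) / rate(0->1)`` and
    ``koff_ratio = rate(2->1) / rate(1->0)`` with bootstrap-over-traces
    SDs, for comparison with the independent-identical-sites expectations
    0.5 and 2.  Never-visited levels yield NaN ratios rather than errors.
    """
    seqs = [np.asarray(s, dtype=int) for s in
            (labels if not isinstance(labels, np.ndarray) or labels.ndim > 1
             else [labels])]
    K = max(int(s.max()) for s in seqs) + 1

    def counts_of(subset):
        up = np.zeros(K)
        down = np.zeros(K)
        time_at = np.zeros(K)
        for s in subset:
            src, dst = s[:-1], s[1:]
            np.add.at(time_at, src, frame_interval_s)
            np.add.at(up, src[dst == src + 1], 1.0)
            np.add.at(down, src[dst == src - 1], 1.0)
        return up, down, time_at

    def ratios_of(subset):
        up, down, time_at = counts_of(subset)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate_up = np.where(time_at > 0, up / time_at, np.nan)
            rate_down = np.where(time_at > 0, down / time_at, np.nan)
        kon_ratio = rate_up[1] / rate_up[0] if K > 2 and rate_up[0] > 0 else np.nan
        koff_ratio = rate_down[2] / rate_down[1] \
            if K > 2 and rate_down[1] > 0 else np.nan
        return rate_up, rate_down, kon_ratio, koff_ratio

    rate_up, rate_down, kon_ratio, koff_ratio = ratios_of(seqs)
    rng = np.random.default_rng(seed)
    boot_on = np.full(n_boot, np.nan)
    boot_off = np.full(n_boot, np.nan)
    for b in range(n_boot):
        idx = rng.integers(len(seqs), size=len(seqs))
        _, _, r_on, r_off = ratios_of([seqs[i] for i in idx])
        boot_on[b], boot_off[b] = r_on, r_off
    def _sd(arr):
        vals = arr[np.isfinite(arr)]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan

    out = {
        "rate_up_per_s": rate_up, "rate_down_per_s": rate_down,
        "kon_ratio": float(kon_ratio), "koff_ratio": float(koff_ratio),
        "kon_ratio_se": _sd(boot_on),
        "koff_ratio_se": _sd(boot_off),
        "independent_sites_expectation": {"kon_ratio": 0.5, "koff_ratio": 2.0},
    }
    if concentration_M:
        out["kon_per_level_M_s"] = rate_up / concentration_M
    return out


def precision_analysis(observations, K: int, priors: MGHMMPriors,
                       n_replicates: int = 10, fraction: float = 0.9,
                       seed: int = 0, restarts: int = 2) -> dict:
    """Reproducibility of the fitted kinetics across 90%-of-traces subsamples.

    Fits the full dataset once, then refits ``n_replicates`` subsamples of
    ``fraction`` of the traces drawn without replacement (warm-started from
    the full fit) and reports the elementwise SD across replicates of the
    posterior-mean transition matrix, of the stationary occupancy, and of
    the state signal means.
    """
    traces = _as_trace_list(observations)
    n = len(traces)
    full = vbem_fit(traces, K, priors, restarts=restarts, seed=seed)
    rng = np.random.default_rng(seed)
    m = max(1, int(round(fraction * n)))
    trans, occ, means = [], [], []
    for _ in range(n_replicates):
        idx = rng.choice(n, size=m, replace=False)
        post = vbem_fit([traces[i] for i in idx], K, priors, seed=seed,
                        init_posterior=full)
        trans.append(post.expected_transition())
        occ.append(post.occupancy())
        means.append(post.expected_means())
    return {
        "full": full,
        "transition_sd": np.std(np.stack(trans), axis=0, ddof=1),
        "occupancy_sd": np.std(np.stack(occ), axis=0, ddof=1),
        "mean_sd": np.std(np.stack(means), axis=0, ddof=1),
        "n_points": sum(len(t) for t in traces),
    }


def estimate_priors_from_traces(traces, events=None,
                                kappa: float = 10.0, nu: float = 10.0,
                                W_sqrt: float = 10.0) -> MGHMMPriors:
    """Priors for model-order selection from identified single binding events.

    ``m`` is the pooled mean (signal, background) over the frames of the
    supplied single-binding events; the spread hyperparameters default to
    the packaged value 10.  ``traces`` is the per-frame fit table
    (columns ``site_id, frame, I_gf, bg_est``); ``events`` the event table
    restricted to clean single events.
    """
    import pandas as pd

    if isinstance(traces, pd.DataFrame):
        if events is None or len(events) == 0:
            raise VBEMError(
                "no single-binding events supplied: set priors manually")
        frames = []
        for _, ev in events.iterrows():
            sel = traces[(traces["site_id"] == ev["site_id"])
                         & (traces["frame"] >= ev["start_frame"])
                         & (traces["frame"] <= ev["end_frame"])]
            frames.append(sel[["I_gf", "bg_est"]].to_numpy(dtype=float))
        if not frames:
            raise VBEMError("events matched no trace frames")
        pooled = np.concatenate(frames, axis=0)
        m = pooled.mean(axis=0)
    else:
        m = np.mean(np.atleast_2d(np.asarray(traces, dtype=float)), axis=0)
    return MGHMMPriors(m=m, kappa=kappa, nu=nu, W_sqrt=W_sqrt)
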