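"""Bilinear dynamic causal models of the 4-ROI network.

Model: dx/dt = (A(theta) + u_mod B(theta)) x + C(theta) u_drive, observed as
y = g .* x + noise with per-ROI gains g (the sign/scale of minimum-norm ROI
series is arbitrary).  The diagonal of A is a fixed self-decay (-1/s), not a
free parameter.  Inversion is a variational-Laplace scheme: Gauss-Newton
updates with Levenberg damping on the posterior mode, a closed-form Gaussian
posterior covariance, and a fixed-point update of the observation-noise
precision under a Gamma prior.  The returned free energy is the evidence
lower bound used for model comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from . import _integrator
from .errors import InvalidConfigError, ShapeError

NODES = ("PMC", "SMA", "M1", "DLPFC")
NODE_INDEX = {lb: i for i, lb in enumerate(NODES)}


@dataclass
class DCMSpec:
    """Masks and priors defining one model's free parameters."""

    a_mask: np.ndarray  # (4,4) binary, row=target col=source, diag ignored
    b_mask: np.ndarray  # (4,4) binary
    c_mask: np.ndarray  # (4,) binary, exactly one entry (PMC or SMA)
    nodes: tuple[str, ...] = NODES
    self_decay: float = -1.0
    a_prior_sd: float = 0.25  # N(0, 1/16)
    # wider than the A prior: tight B shrinkage biases nested-model selection
    # toward supersets (extra edges compensate the shrunk shared couplings)
    b_prior_sd: float = 0.5
    c_prior_sd: float = 1.0
    gain_prior_mean: float = 1.0
    gain_prior_sd: float = 0.25
    noise_shape: float = 2.0  # Gamma(shape, rate) prior on noise precision
    noise_rate: float = 1.0
    name: str = ""

    def __post_init__(self):
        self.a_mask = np.asarray(self.a_mask, bool)
        self.b_mask = np.asarray(self.b_mask, bool)
        self.c_mask = np.asarray(self.c_mask, bool)
        if self.a_mask.shape != (4, 4) or self.b_mask.shape != (4, 4):
            raise ShapeError("a_mask and b_mask must be 4x4")
        m1 = self.nodes.index("M1")
        dlpfc = self.nodes.index("DLPFC")
        for M, nm in ((self.a_mask, "a_mask"), (self.b_mask, "b_mask")):
            if M[m1, dlpfc] or M[dlpfc, m1]:
                raise ShapeError(f"{nm} must exclude DLPFC<->M1 couplings")
        if np.any(np.diag(self.b_mask)):
            raise ShapeError("self-modulation is not a free parameter here")
        if self.c_mask.sum() != 1 or not (
            self.c_mask[self.nodes.index("PMC")] or self.c_mask[self.nodes.index("SMA")]
        ):
            raise ShapeError("c_mask needs exactly one entry, at PMC or SMA")

    # -- parameter vector layout: A entries, B entries, C entry, 4 gains -----

    @property
    def _a_idx(self):
        m = self.a_mask.copy()
        np.fill_diagonal(m, False)
        return np.nonzero(m)

    @property
    def _b_idx(self):
        return np.nonzero(self.b_mask)

    @property
    def n_params(self) -> int:
        return len(self._a_idx[0]) + len(self._b_idx[0]) + 1 + 4

    @property
    def param_names(self) -> list[str]:
        names = [f"A:{self.nodes[i]}<-{self.nodes[j]}" for i, j in zip(*self._a_idx)]
        names += [f"B:{self.nodes[i]}<-{self.nodes[j]}" for i, j in zip(*self._b_idx)]
        names.append(f"C:{self.nodes[int(np.argmax(self.c_mask))]}")
        names += [f"gain:{n}" for n in self.nodes]
        return names

    def prior_mean(self) -> np.ndarray:
        mu = np.zeros(self.n_params)
        mu[-4:] = self.gain_prior_mean
        return mu

    def prior_variances(self) -> np.ndarray:
        na, nb = len(self._a_idx[0]), len(self._b_idx[0])
        v = np.empty(self.n_params)
        v[:na] = self.a_prior_sd**2
        v[na : na + nb] = self.b_prior_sd**2
        v[na + nb] = self.c_prior_sd**2
        v[-4:] = self.gain_prior_sd**2
        return v

    def unpack(self, theta: np.ndarray):
        """theta -> (A, B, C, gains) with the fixed self-decay on A's diagonal."""
        theta = np.asarray(theta, float)
        if theta.shape != (self.n_params,):
            raise ShapeError(f"theta must have length {self.n_params}")
        na, nb = len(self._a_idx[0]), len(self._b_idx[0])
        A = np.diag(np.full(4, self.self_decay))
        A[self._a_idx] = theta[:na]
        B = np.zeros((4, 4))
        B[self._b_idx] = theta[na : na + nb]
        C = np.zeros(4)
        C[np.argmax(self.c_mask)] = theta[na + nb]
        gains = theta[-4:]
        return A, B, C, gains

    def pack(self, A, B, C, gains=None) -> np.ndarray:
        theta = np.concatenate(
            [
                np.asarray(A, float)[self._a_idx],
                np.asarray(B, float)[self._b_idx],
                [np.asarray(C, float)[np.argmax(self.c_mask)]],
                np.ones(4) if gains is None else np.asarray(gains, float),
            ]
        )
        return theta

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "nodes": list(self.nodes),
                "a_mask": self.a_mask.astype(int).tolist(),
                "b_mask": self.b_mask.astype(int).tolist(),
                "c_mask": self.c_mask.astype(int).tolist(),
                "self_decay": self.self_decay,
                "priors": {
                    "a_sd": self.a_prior_sd,
                    "b_sd": self.b_prior_sd,
                    "c_sd": self.c_prior_sd,
                    "gain_mean": self.gain_prior_mean,
                    "gain_sd": self.gain_prior_sd,
                    "noise_shape": self.noise_shape,
                    "noise_rate": self.noise_rate,
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DCMSpec":
        d = json.loads(text)
        p = d["priors"]
        return cls(
            a_mask=np.array(d["a_mask"]),
            b_mask=np.array(d["b_mask"]),
            c_mask=np.array(d["c_mask"]),
            nodes=tuple(d["nodes"]),
            self_decay=d["self_decay"],
            a_prior_sd=p["a_sd"],
            b_prior_sd=p["b_sd"],
            c_prior_sd=p["c_sd"],
            gain_prior_mean=p["gain_mean"],
            gain_prior_sd=p["gain_sd"],
            noise_shape=p["noise_shape"],
            noise_rate=p["noise_rate"],
            name=d.get("name", ""),
        )


@dataclass
class DCMFit:
    posterior_mean: np.ndarray
    posterior_cov: np.ndarray
    free_energy: float
    predicted: np.ndarray
    iterations: int
    converged: bool
    noise_precision: float
    param_names: list = field(default_factory=list)

    def posterior_b_matrix(self, spec: DCMSpec) -> np.ndarray:
        _, B, _, _ = spec.unpack(self.posterior_mean)
        return B

    def credible_interval(self, i: int, level: float = 0.95):
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        sd = float(np.sqrt(self.posterior_cov[i, i]))
        m = float(self.posterior_mean[i])
        return m - z * sd, m + z * sd


def integrate(spec: DCMSpec, theta, inputs: dict, dt: float, method: str = "zoh"):
    """Predicted ROI series (4, n) for parameter vector theta."""
    if dt <= 0:
        raise InvalidConfigError("dt must be positive")
    A, B, C, gains = spec.unpack(theta)
    x = _integrator.trajectory(
        A, [B], C, inputs["drive"], [inputs["mod"]], dt, method=method
    )
    return gains[:, None] * x


def _integrate_batch(spec: DCMSpec, thetas: np.ndarray, inputs: dict, dt: float):
    P = thetas.shape[0]
    A_b = np.empty((P, 4, 4))
    B_b = np.empty((P, 1, 4, 4))
    C_b = np.empty((P, 4))
    gains = np.empty((P, 4))
    for p in range(P):
        A, B, C, g = spec.unpack(thetas[p])
        A_b[p], B_b[p, 0], C_b[p], gains[p] = A, B, C, g
    u_m = np.asarray(inputs["mod"], float)[None, :]
    x = _integrator.trajectory_batch(A_b, B_b, C_b, inputs["drive"], u_m, dt)
    return gains[:, :, None] * x


# ---------------------------------------------------------------------------
# variational Laplace
# ---------------------------------------------------------------------------

def free_energy(
    residual: np.ndarray,
    jacobian: np.ndarray,
    posterior_cov: np.ndarray,
    posterior_mean: np.ndarray,
    prior_mean: np.ndarray,
    prior_cov: np.ndarray,
    noise: dict,
) -> float:
    """Evidence lower bound for a Gaussian-likelihood model.

    F = E_q[log p(y|theta)] - KL(q(theta) || p(theta)) - KL(q(lambda) || p(lambda))

    ``noise``: either {"precision": lam} for fixed known precision, or
    {"shape": a, "rate": b, "prior_shape": a0, "prior_rate": b0} for a Gamma
    posterior over the precision.
    """
    r = np.ravel(residual)
    N = r.size
    J, S = jacobian, posterior_cov
    dm = posterior_mean - prior_mean
    P = len(posterior_mean)

    if "precision" in noise:
        e_lam, e_loglam, kl_lam = noise["precision"], np.log(noise["precision"]), 0.0
    else:
        a, b = noise["shape"], noise["rate"]
        a0, b0 = noise["prior_shape"], noise["prior_rate"]
        e_lam = a / b
        e_loglam = digamma(a) - np.log(b)
        kl_lam = (
            (a - a0) * digamma(a)
            - gammaln(a)
            + gammaln(a0)
            + a0 * (np.log(b) - np.log(b0))
            + a * (b0 - b) / b
        )

    trJSJ = float(np.sum((J @ S) * J)) if S.size else 0.0
    exp_ll = -0.5 * e_lam * (r @ r + trJSJ) + 0.5 * N * (e_loglam - np.log(2 * np.pi))

    if S.size and np.any(np.diag(S) > 0):
        prior_cov = np.atleast_2d(prior_cov)
        if prior_cov.shape[0] != P:
            prior_cov = np.diag(np.broadcast_to(np.diag(prior_cov), (P,)))
        P0 = np.linalg.inv(prior_cov)
        sign0, logdet0 = np.linalg.slogdet(prior_cov)
        signS, logdetS = np.linalg.slogdet(S)
        kl_theta = 0.5 * (
            np.trace(P0 @ S) + dm @ P0 @ dm - P + logdet0 - logdetS
        )
    else:
        kl_theta = 0.0  # delta prior: q pinned to the prior mean
    return float(exp_ll - kl_theta - kl_lam)


def _jitter_inv(H: np.ndarray) -> np.ndarray:
    """Inverse via jittered Cholesky, keeping the result symmetric PD."""
    jitter = 0.0
    scale = np.mean(np.diag(H)) or 1.0
    for _ in range(12):
        try:
            L = np.linalg.cholesky(H + jitter * np.eye(H.shape[0]))
            Linv = np.linalg.inv(L)
            return Linv.T @ Linv
        except np.linalg.LinAlgError:
            jitter = max(2 * jitter, 1e-12 * scale)
    raise np.linalg.LinAlgError("could not stabilize the posterior Hessian")


def variational_laplace(
    h,
    y: np.ndarray,
    prior_mean: np.ndarray,
    prior_var: np.ndarray,
    noise_precision: float | None = None,
    noise_shape: float = 2.0,
    noise_rate: float = 1.0,
    max_iter: int = 64,
    tol: float = 1e-2,
    h_batch=None,
    fd_eps: float = 1e-4,
):
    """Gauss-Newton variational Laplace for y = h(theta) + Gaussian noise.

    ``prior_var`` is the diagonal of the prior covariance.  When
    ``noise_precision`` is given the noise is treated as known; otherwise the
    precision carries a Gamma(noise_shape, noise_rate) prior and is updated by
    fixed point.  ``h_batch`` (thetas (P, K) -> (P, ...)) accelerates the
    finite-difference Jacobian.  Returns a dict with the posterior, free
    energy and diagnostics.
    """
    y = np.ravel(np.asarray(y, float))
    mu0 = np.asarray(prior_mean, float).copy()
    v0 = np.asarray(prior_var, float)
    K = mu0.size
    N = y.size

    if np.all(v0 == 0):  # delta prior: nothing to estimate
        r = y - np.ravel(h(mu0))
        lam = noise_precision if noise_precision is not None else noise_shape / noise_rate
        F = free_energy(
            r, np.zeros((N, K)), np.zeros((K, K)), mu0, mu0, np.diag(v0), {"precision": lam}
        )
        return {
            "posterior_mean": mu0,
            "posterior_cov": np.zeros((K, K)),
            "free_energy": F,
            "iterations": 0,
            "converged": True,
            "noise_precision": lam,
            "residual": r,
        }

    P0 = np.diag(1.0 / v0)
    fixed_noise = noise_precision is not None
    lam = noise_precision if fixed_noise else noise_shape / noise_rate
    a = noise_shape + N / 2.0

    def hv(theta):
        return np.ravel(h(theta))

    def jac(theta, pred):
        eps = fd_eps * np.maximum(1.0, np.abs(theta))
        if h_batch is not None:
            thetas = theta[None, :] + np.diag(eps)
            preds = h_batch(thetas).reshape(K, -1)
            return (preds - pred[None, :]).T / eps[None, :]
        J = np.empty((N, K))
        for i in range(K):
            tp = theta.copy()
            tp[i] += eps[i]
            J[:, i] = (hv(tp) - pred) / eps[i]
        return J

    def logjoint(theta, pred):
        r = y - pred
        if not np.all(np.isfinite(r)):
            return -np.inf, r
        dm = theta - mu0
        return -0.5 * lam * (r @ r) - 0.5 * dm @ P0 @ dm, r

    m = mu0.copy()
    pred = hv(m)
    L, r = logjoint(m, pred)
    nu = 1e-4
    J = jac(m, pred)
    converged = False
    fails = 0
    it = 0
    for it in range(1, max_iter + 1):
        H = lam * (J.T @ J) + P0
        g = lam * (J.T @ r) - P0 @ (m - mu0)
        accepted = False
        for _ in range(16):
            try:
                step = np.linalg.solve(H + nu * np.mean(np.diag(H)) * np.eye(K), g)
            except np.linalg.LinAlgError:
                nu *= 8
                continue
            m_new = m + step
            pred_new = hv(m_new)
            L_new, r_new = logjoint(m_new, pred_new)
            if np.isfinite(L_new) and L_new >= L:
                dL = L_new - L
                m, pred, r, L = m_new, pred_new, r_new, L_new
                nu = max(nu / 4, 1e-8)
                accepted = True
                break
            nu *= 8
        if not accepted:
            fails += 1
            if fails >= 8:
                break
            continue
        fails = 0
        J = jac(m, pred)
        if not fixed_noise:
            S = _jitter_inv(lam * (J.T @ J) + P0)
            b = noise_rate + 0.5 * (r @ r + float(np.sum((J @ S) * J)))
            lam = a / b
            L, _ = logjoint(m, pred)  # lambda changed; refresh the objective
        if accepted and dL < tol:
            converged = True
            break

    S = _jitter_inv(lam * (J.T @ J) + P0)
    if fixed_noise:
        noise = {"precision": lam}
    else:
        b = noise_rate + 0.5 * (r @ r + float(np.sum((J @ S) * J)))
        noise = {
            "shape": a,
            "rate": b,
            "prior_shape": noise_shape,
            "prior_rate": noise_rate,
        }
    F = free_energy(r, J, S, m, mu0, np.diag(v0), noise)
    return {
        "posterior_mean": m,
        "posterior_cov": S,
        "free_energy": F,
        "iterations": it,
        "converged": converged,
        "noise_precision": float(lam),
        "residual": r,
    }


def invert(
    spec: DCMSpec,
    roi_data: np.ndarray,
    inputs: dict,
    dt: float,
    max_iter: int = 64,
    tol: float = 1e-2,
) -> DCMFit:
    """Fit one DCM to (4, n) ROI data; returns posteriors and free energy."""
    roi_data = np.asarray(roi_data, float)
    if not np.all(np.isfinite(roi_data)):
        raise InvalidConfigError("ROI data must be finite")
    n = roi_data.shape[1]
    if len(inputs["drive"]) != n or len(inputs["mod"]) != n:
        raise ShapeError("inputs must be aligned to the data grid")

    res = variational_laplace(
        h=lambda th: integrate(spec, th, inputs, dt),
        y=roi_data,
        prior_mean=spec.prior_mean(),
        prior_var=spec.prior_variances(),
        noise_shape=spec.noise_shape,
        noise_rate=spec.noise_rate,
        max_iter=max_iter,
        tol=tol,
        h_batch=lambda ths: _integrate_batch(spec, ths, inputs, dt),
    )
    return DCMFit(
        posterior_mean=res["posterior_mean"],
        posterior_cov=res["posterior_cov"],
        free_energy=res["free_energy"],
        predicted=integrate(spec, res["posterior_mean"], inputs, dt),
        iterations=res["iterations"],
        converged=res["converged"],
        noise_precision=res["noise_precision"],
        param_names=spec.param_names,
    )
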