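"""Adaptive Metropolis-within-Gibbs engines.

One sweep updates, in order: the latent log relative risks ``z = log(mu)``
(elementwise, conditionally independent given the linear predictor), the
space-time interaction ``theta`` (elementwise), the unstructured spatial
effect ``v`` (per region), the ICAR field ``u`` (vectorized over graph
color classes — no two same-color regions are neighbours, so simultaneous
elementwise accept/reject is exact), the temporal random walk ``lambda``
(even/odd periods), optional regression coefficients ``beta`` (joint
random-walk), and the five scale parameters (log-scale random walk with a
Jacobian, hard rejection outside the uniform prior's support).

Two families of extra moves fight the weak identification built into the
hierarchy.  *Group scaling* moves rescale a random-effect block together
with its scale parameter, walking along the (effect, scale) ridge.
*Transfer* moves shift level between blocks whose sum is all the
likelihood sees (temporal trend vs region effects, region effects vs the
interaction rows, structured vs unstructured spatial effects); they leave
the linear predictor untouched and are decided by the prior terms alone.
The scale/ridge moves are cheap relative to the field updates and are
repeated within each sweep.

Per-block step sizes adapt toward a 0.44 acceptance rate during burn-in via
a Robbins-Monro recursion and are frozen afterwards, keeping the retained
chain a valid Markov chain.  After every ``u`` update the field is
re-centered to mean zero (the conventional handling of the intrinsic
prior's flat direction).

The same engine serves the quantile model (asymmetric-Laplace error at a
fixed level ``tau``) and the mean-regression comparator (Gaussian error);
a separate engine handles the threshold-quantile detection model in which
the per-unit level ``tau_it`` is itself unknown with a flat Beta(1, 1)
prior.
"""

from __future__ import annotations

import numpy as np

TARGET_ACC = 0.44
BETA_PRIOR_SD = 1000.0
RIDGE_REPEATS = 3


def _rho(r, tau):
    """Check loss, elementwise; ``tau`` may be scalar or array."""
    return r * (tau - (r < 0.0))


def _gamma(it):
    return min(0.25, (it + 1.0) ** -0.6)


def _adapt(log_step, accepted, it, adapting):
    """Vector Robbins-Monro step-size adaptation (in place)."""
    if adapting:
        log_step += _gamma(it) * (accepted - TARGET_ACC)


class _HierChain:
    """One chain of the hierarchical model (quantile or mean variant)."""

    def __init__(self, y, e, X, graph_pre, error, tau, sd_upper, rng):
        self.y = y
        self.e = e
        self.X = X  # (n, T, p) or None
        self.error = error  # "al" | "gaussian"
        self.tau = tau
        self.upper = sd_upper
        self.rng = rng
        self.edges, self.deg, self.A, self.colors, self.t_colors = graph_pre
        self.n, self.T = y.shape
        self.N = self.n * self.T
        p = 0 if X is None else X.shape[2]
        self.p = p

        # overdispersed start
        self.z = np.log((y + 0.5) / e) + rng.normal(0, 0.3, size=y.shape)
        self.u = rng.normal(0, 0.5, self.n)
        self.u -= self.u.mean()
        self.v = rng.normal(0, 0.5, self.n)
        self.lam = rng.normal(0, 0.5, self.T)
        self.theta = rng.normal(0, 0.3, size=y.shape)
        self.beta = rng.normal(0, 0.1, p)
        init_scales = rng.uniform(0.3, 2.0, 5)
        (self.s_u, self.s_v, self.s_lam, self.s_th, self.s_eps) = init_scales

        # adaptive log step sizes
        self.ls_z = np.log(1.0 / np.sqrt(y + 2.0))
        self.ls_th = np.full(y.shape, np.log(0.5))
        self.ls_v = np.full(self.n, np.log(0.5))
        self.ls_u = np.full(self.n, np.log(0.5))
        self.ls_lam = np.full(self.T, np.log(0.5))
        self.ls_beta = np.log(0.1)
        self.ls_scales = np.full(5, np.log(0.3))
        self.ls_group = np.full(5, np.log(0.3))
        self.ls_tr_lv = np.log(0.3)
        self.ls_tr_vth = np.full(self.n, np.log(0.3))
        self.ls_tr_lth = np.full(self.T, np.log(0.3))
        self.ls_tr_uv = np.full(self.n, np.log(0.3))

        self._refresh_eta()

    # ------------------------------------------------------------------
    def _refresh_eta(self):
        eta = self.u[:, None] + self.v[:, None] + self.lam[None, :] + self.theta
        if self.p:
            eta = eta + self.X @ self.beta
        self.eta = eta
        self.r = self.z - eta

    def _err(self, r):
        """Elementwise error log-density kernel (scale normalizer excluded)."""
        if self.error == "al":
            return -_rho(r, self.tau) / self.s_eps
        return -0.5 * r * r / (self.s_eps * self.s_eps)

    def _adapt_scalar(self, attr, acc, it, adapting):
        if adapting:
            setattr(
                self, attr, getattr(self, attr) + _gamma(it) * (float(acc) - TARGET_ACC)
            )

    # ------------------------------------------------------------------
    def _update_z(self, it, adapting):
        rng = self.rng
        zp = self.z + np.exp(self.ls_z) * rng.standard_normal(self.z.shape)
        d = (
            self.y * (zp - self.z)
            - self.e * (np.exp(zp) - np.exp(self.z))
            + self._err(zp - self.eta)
            - self._err(self.r)
        )
        acc = np.log(rng.uniform(size=d.shape)) < d
        self.z = np.where(acc, zp, self.z)
        self.r = self.z - self.eta
        _adapt(self.ls_z, acc, it, adapting)

    def _update_theta(self, it, adapting):
        rng = self.rng
        tp = self.theta + np.exp(self.ls_th) * rng.standard_normal(self.theta.shape)
        dth = tp - self.theta
        d = (
            self._err(self.r - dth)
            - self._err(self.r)
            - (tp * tp - self.theta * self.theta) / (2.0 * self.s_th * self.s_th)
        )
        acc = np.log(rng.uniform(size=d.shape)) < d
        dth = np.where(acc, dth, 0.0)
        self.theta = self.theta + dth
        self.eta += dth
        self.r -= dth
        _adapt(self.ls_th, acc, it, adapting)

    def _update_v(self, it, adapting):
        rng = self.rng
        dv = np.exp(self.ls_v) * rng.standard_normal(self.n)
        vp = self.v + dv
        d_like = (self._err(self.r - dv[:, None]) - self._err(self.r)).sum(axis=1)
        d = d_like - (vp * vp - self.v * self.v) / (2.0 * self.s_v * self.s_v)
        acc = np.log(rng.uniform(size=self.n)) < d
        dv = np.where(acc, dv, 0.0)
        self.v = self.v + dv
        self.eta += dv[:, None]
        self.r -= dv[:, None]
        _adapt(self.ls_v, acc, it, adapting)

    def _update_u(self, it, adapting):
        rng = self.rng
        su2 = self.s_u * self.s_u
        for cls in self.colors:
            du_c = np.exp(self.ls_u[cls]) * rng.standard_normal(len(cls))
            up_c = self.u[cls] + du_c
            du = np.zeros(self.n)
            du[cls] = du_c
            nbr_sum = self.A @ self.u
            # pairwise-difference ICAR: local change for independent sites
            d_prior = -(
                self.deg[cls] * (up_c**2 - self.u[cls] ** 2)
                - 2.0 * nbr_sum[cls] * du_c
            ) / (2.0 * su2)
            d_like = (self._err(self.r - du[:, None]) - self._err(self.r)).sum(axis=1)
            acc = np.log(rng.uniform(size=len(cls))) < d_like[cls] + d_prior
            du[cls] = np.where(acc, du[cls], 0.0)
            self.u = self.u + du
            self.eta += du[:, None]
            self.r -= du[:, None]
            _adapt(self.ls_u[cls], acc, it, adapting)
        # sum-to-zero centering of the intrinsic field
        m = self.u.mean()
        if m != 0.0:
            self.u -= m
            self.eta -= m
            self.r += m

    def _lam_prior_delta(self, cls, lam_new_c):
        """RW1 prior change when lam[cls] -> lam_new_c (independent sites)."""
        lam = self.lam
        out = np.empty(len(cls))
        for k, t in enumerate(cls):
            new, old = lam_new_c[k], lam[t]
            prev = lam[t - 1] if t > 0 else 0.0  # zero-mean anchor at t=1
            out[k] = (new - prev) ** 2 - (old - prev) ** 2
            if t + 1 < self.T:
                nxt = lam[t + 1]
                out[k] += (nxt - new) ** 2 - (nxt - old) ** 2
        return -out / (2.0 * self.s_lam * self.s_lam)

    def _update_lam(self, it, adapting):
        rng = self.rng
        for cls in self.t_colors:
            dl_c = np.exp(self.ls_lam[cls]) * rng.standard_normal(len(cls))
            dl = np.zeros(self.T)
            dl[cls] = dl_c
            d_prior = self._lam_prior_delta(cls, self.lam[cls] + dl_c)
            d_like = (self._err(self.r - dl[None, :]) - self._err(self.r)).sum(axis=0)
            acc = np.log(rng.uniform(size=len(cls))) < d_like[cls] + d_prior
            dl[cls] = np.where(acc, dl[cls], 0.0)
            self.lam = self.lam + dl
            self.eta += dl[None, :]
            self.r -= dl[None, :]
            _adapt(self.ls_lam[cls], acc, it, adapting)

    def _update_beta(self, it, adapting):
        rng = self.rng
        bp = self.beta + np.exp(self.ls_beta) * rng.standard_normal(self.p)
        d_eta = self.X @ (bp - self.beta)
        d = (self._err(self.r - d_eta) - self._err(self.r)).sum() - (
            bp @ bp - self.beta @ self.beta
        ) / (2.0 * BETA_PRIOR_SD**2)
        acc = np.log(rng.uniform()) < d
        if acc:
            self.beta = bp
            self.eta += d_eta
            self.r -= d_eta
        self._adapt_scalar("ls_beta", acc, it, adapting)

    # ------------------------------------------------------------------
    def _update_scales(self, it, adapting):
        """Exact Gibbs draws for the five scales under Unif(0, upper) priors.

        A Gaussian block with k free terms and sum of squares SS has
        conditional p(s) proportional to s^-k exp(-SS/(2 s^2)) on (0, upper):
        the precision 1/s^2 is Gamma((k-1)/2, rate SS/2) truncated to
        1/s^2 > upper^-2.  The AL scale with check-loss sum S has
        p(s) proportional to s^-N exp(-S/s): 1/s is Gamma(N-1, rate S)
        truncated likewise.  Degenerate cases (k < 2 or zero sums, e.g. a
        single-region graph) fall back to a random-walk step.
        """
        n, T, N = self.n, self.T, self.N
        ea, eb = self.edges[:, 0], self.edges[:, 1]
        du = self.u[ea] - self.u[eb] if len(ea) else np.zeros(0)
        lam_prev = np.concatenate(([0.0], self.lam[:-1]))
        dlam = self.lam - lam_prev
        self.s_u = self._gibbs_gaussian_scale(self.n - 1, float(du @ du), self.s_u, 0, it, adapting)
        self.s_v = self._gibbs_gaussian_scale(n, float(self.v @ self.v), self.s_v, 1, it, adapting)
        self.s_lam = self._gibbs_gaussian_scale(T, float(dlam @ dlam), self.s_lam, 2, it, adapting)
        self.s_th = self._gibbs_gaussian_scale(
            N, float((self.theta * self.theta).sum()), self.s_th, 3, it, adapting
        )
        if self.error == "al":
            s_rho = float(_rho(self.r, self.tau).sum())
            self.s_eps = self._gibbs_al_scale(N, s_rho, self.s_eps, 4, it, adapting)
        else:
            self.s_eps = self._gibbs_gaussian_scale(
                N, float((self.r * self.r).sum()), self.s_eps, 4, it, adapting
            )

    def _gibbs_gaussian_scale(self, k, ss, current, slot, it, adapting):
        if k >= 2 and ss > 0.0:
            shape, rate = (k - 1) / 2.0, ss / 2.0
            lo = self.upper**-2
            for _ in range(64):
                phi = self.rng.gamma(shape) / rate
                if phi > lo:
                    return float(phi**-0.5)
        return self._rw_scale(
            current, lambda s: -k * np.log(s) - ss / (2 * s * s), slot, it, adapting
        )

    def _gibbs_al_scale(self, N, s_rho, current, slot, it, adapting):
        if N >= 2 and s_rho > 0.0:
            shape = N - 1
            lo = 1.0 / self.upper
            for _ in range(64):
                x = self.rng.gamma(shape) / s_rho
                if x > lo:
                    return float(1.0 / x)
        return self._rw_scale(
            current, lambda s: -N * np.log(s) - s_rho / s, slot, it, adapting
        )

    def _rw_scale(self, s, logp, slot, it, adapting):
        """Fallback log-scale random walk with Jacobian."""
        sp = s * np.exp(np.exp(self.ls_scales[slot]) * self.rng.standard_normal())
        acc = False
        if sp < self.upper:
            d = logp(sp) - logp(s) + (np.log(sp) - np.log(s))
            acc = np.log(self.rng.uniform()) < d
        if adapting:
            self.ls_scales[slot] += _gamma(it) * (float(acc) - TARGET_ACC)
        return float(sp) if acc else float(s)

    def _group_scale_moves(self, it, adapting):
        """Jointly rescale a random-effect block and its scale parameter.

        (x, s) -> (g*x, g*s) with log-normal g: the Gaussian/ICAR prior
        changes by -k_prior*log(g), the Jacobian contributes
        (size(x)+1)*log(g), and the likelihood sees the shifted predictor.
        """
        rng = self.rng
        blocks = (
            ("theta", "s_th", self.N, 0),
            ("v", "s_v", self.n, 1),
            ("u", "s_u", self.n - 1, 2),
            ("lam", "s_lam", self.T, 3),
        )
        gs = np.exp(np.exp(self.ls_group[:4]) * rng.standard_normal(4))
        logu = np.log(rng.uniform(size=4))
        for name, sname, k_prior, slot in blocks:
            g = gs[slot]
            x = getattr(self, name)
            s = getattr(self, sname)
            acc = False
            if g * s < self.upper:
                if name == "theta":
                    d_eta = (g - 1.0) * x
                elif name == "lam":
                    d_eta = (g - 1.0) * x[None, :]
                else:
                    d_eta = (g - 1.0) * x[:, None]
                d_like = (self._err(self.r - d_eta) - self._err(self.r)).sum()
                d = d_like + (x.size + 1 - k_prior) * np.log(g)
                acc = logu[slot] < d
            if acc:
                setattr(self, name, g * x)
                setattr(self, sname, g * s)
                self.eta += d_eta
                self.r -= d_eta
            if adapting:
                self.ls_group[slot] += _gamma(it) * (float(acc) - TARGET_ACC)
        self._residual_exchange_move(it, adapting)

    def _residual_exchange_move(self, it, adapting):
        """Trade noise between the interaction field and the error term.

        With z fixed, scale the residual field r -> a*r (compensated by
        theta -> theta + (1-a)*r) and the error scale s_eps -> a*s_eps.
        The error kernel (AL or Gaussian) is invariant under this map; its
        scale normalizer and the Jacobian a^(N+1) leave a single +log(a)
        term, so acceptance is decided by the theta prior alone.  This
        walks the sigma_eps <-> sigma_theta ridge directly and rescues
        chains from the degenerate corner where one of the two scales
        collapses to zero.
        """
        rng = self.rng
        a = float(np.exp(np.exp(self.ls_group[4]) * rng.standard_normal()))
        acc = False
        if self.s_eps * a < self.upper:
            d_th = (1.0 - a) * self.r
            tp = self.theta + d_th
            d = (
                -((tp * tp).sum() - (self.theta * self.theta).sum())
                / (2.0 * self.s_th * self.s_th)
                + np.log(a)
            )
            acc = np.log(rng.uniform()) < d
        if acc:
            self.theta = tp
            self.s_eps *= a
            self.eta += d_th
            self.r -= d_th
        if adapting:
            self.ls_group[4] += _gamma(it) * (float(acc) - TARGET_ACC)

    def _transfer_moves(self, it, adapting):
        """Redistribute level between confounded blocks at fixed likelihood.

        The linear predictor is invariant to moving a constant between the
        temporal trend and the region effects, or between a region (time)
        effect and the matching row (column) of the interaction; only the
        Gaussian/ICAR prior terms decide these splits, so the moves are
        cheap and dramatically improve mixing of the scale parameters.
        """
        rng = self.rng
        sv2 = self.s_v * self.s_v
        sth2 = self.s_th * self.s_th
        sl2 = self.s_lam * self.s_lam

        # (1) scalar: lam += c, v -= c; only the lambda_1 anchor term moves
        c = np.exp(self.ls_tr_lv) * rng.standard_normal()
        d = -(2.0 * self.lam[0] * c + c * c) / (2.0 * sl2) - (
            -2.0 * c * self.v.sum() + self.n * c * c
        ) / (2.0 * sv2)
        acc = np.log(rng.uniform()) < d
        if acc:
            self.lam = self.lam + c
            self.v = self.v - c
        self._adapt_scalar("ls_tr_lv", acc, it, adapting)

        # (2) per region: v_i += c_i, theta_i. -= c_i
        #     sum_t [(th-c)^2 - th^2] = T c^2 - 2 c rowsum(theta)
        cv = np.exp(self.ls_tr_vth) * rng.standard_normal(self.n)
        row = self.theta.sum(axis=1)
        d = -(2.0 * self.v * cv + cv * cv) / (2.0 * sv2) - (
            self.T * cv * cv - 2.0 * cv * row
        ) / (2.0 * sth2)
        acc = np.log(rng.uniform(size=self.n)) < d
        cv = np.where(acc, cv, 0.0)
        self.v = self.v + cv
        self.theta = self.theta - cv[:, None]
        _adapt(self.ls_tr_vth, acc, it, adapting)

        # (3) per time (parity classes; RW1 couples neighbours):
        #     lam_t += d_t, theta_.t -= d_t
        col = self.theta.sum(axis=0)
        for cls in self.t_colors:
            ct = np.exp(self.ls_tr_lth[cls]) * rng.standard_normal(len(cls))
            d_prior = self._lam_prior_delta(cls, self.lam[cls] + ct)
            d_th = -(self.n * ct * ct - 2.0 * ct * col[cls]) / (2.0 * sth2)
            acc = np.log(rng.uniform(size=len(cls))) < d_prior + d_th
            ct = np.where(acc, ct, 0.0)
            self.lam[cls] += ct
            self.theta[:, cls] -= ct[None, :]
            col[cls] -= self.n * ct  # keep the cached column sums current
            _adapt(self.ls_tr_lth[cls], acc, it, adapting)

        # (4) per region (graph color classes): u_i += c_i, v_i -= c_i
        su2 = self.s_u * self.s_u
        for cls in self.colors:
            cu = np.exp(self.ls_tr_uv[cls]) * rng.standard_normal(len(cls))
            nbr_sum = self.A @ self.u
            d_icar = -(
                self.deg[cls] * (2.0 * self.u[cls] * cu + cu * cu)
                - 2.0 * nbr_sum[cls] * cu
            ) / (2.0 * su2)
            d_v = -(-2.0 * self.v[cls] * cu + cu * cu) / (2.0 * sv2)
            acc = np.log(rng.uniform(size=len(cls))) < d_icar + d_v
            cu = np.where(acc, cu, 0.0)
            self.u[cls] += cu
            self.v[cls] -= cu
            _adapt(self.ls_tr_uv[cls], acc, it, adapting)
        # keep u centered without touching the likelihood: shift the mean
        # into v (the predictor sees only u + v)
        m = self.u.mean()
        if m != 0.0:
            self.u -= m
            self.v += m

    # ------------------------------------------------------------------
    def sweep(self, it, adapting):
        self._update_z(it, adapting)
        self._update_theta(it, adapting)
        self._update_v(it, adapting)
        self._update_u(it, adapting)
        self._update_lam(it, adapting)
        if self.p:
            self._update_beta(it, adapting)
        # the scale/ridge moves are cheap relative to the field updates;
        # repeating them speeds mixing of the variance components
        for _ in range(RIDGE_REPEATS):
            self._update_scales(it, adapting)
            self._group_scale_moves(it, adapting)
            self._transfer_moves(it, adapting)


def graph_precompute(graph):
    edges = graph.edges()
    A = graph.adjacency_matrix()
    deg = A.sum(axis=1)
    colors = graph.coloring()
    return edges, deg, A, colors


def time_coloring(T):
    even = np.arange(0, T, 2)
    odd = np.arange(1, T, 2)
    return [c for c in (even, odd) if len(c)]


def run_hier_chain(y, e, X, graph, error, tau, sd_upper, iterations, burn_in, thin, seed):
    """Run one chain; returns dict of retained draws."""
    edges, deg, A, colors = graph_precompute(graph)
    T = y.shape[1]
    pre = (edges, deg, A, colors, time_coloring(T))
    rng = np.random.default_rng(seed)
    chain = _HierChain(y, e, X, pre, error, tau, sd_upper, rng)
    n_keep = (iterations - burn_in) // thin
    p = chain.p
    store = {
        "z": np.empty((n_keep,) + y.shape),
        "eta": np.empty((n_keep,) + y.shape),
        "theta": np.empty((n_keep,) + y.shape),
        "u": np.empty((n_keep, y.shape[0])),
        "v": np.empty((n_keep, y.shape[0])),
        "lam": np.empty((n_keep, T)),
        "sigma_u": np.empty(n_keep),
        "sigma_v": np.empty(n_keep),
        "sigma_lam": np.empty(n_keep),
        "sigma_theta": np.empty(n_keep),
        "sigma_eps": np.empty(n_keep),
    }
    if p:
        store["beta"] = np.empty((n_keep, p))
    k = 0
    for it in range(iterations):
        chain.sweep(it, adapting=it < burn_in)
        if it >= burn_in and (it - burn_in) % thin == 0:
            store["z"][k] = chain.z
            store["eta"][k] = chain.eta
            store["theta"][k] = chain.theta
            store["u"][k] = chain.u
            store["v"][k] = chain.v
            store["lam"][k] = chain.lam
            store["sigma_u"][k] = chain.s_u
            store["sigma_v"][k] = chain.s_v
            store["sigma_lam"][k] = chain.s_lam
            store["sigma_theta"][k] = chain.s_th
            store["sigma_eps"][k] = chain.s_eps
            if p:
                store["beta"][k] = chain.beta
            k += 1
    return store


# ----------------------------------------------------------------------
# threshold-quantile detection model: log(c) = log(mu_it) + eps with
# eps ~ AL(0, tau_it, sigma), tau_it ~ Beta(1, 1)
# ----------------------------------------------------------------------
def run_detection_chain(
    y, e, log_c, sd_upper, iterations, burn_in, thin, seed, fix_sigma=None
):
    rng = np.random.default_rng(seed)
    n, T = y.shape
    N = n * T
    z = np.log((y + 0.5) / e) + rng.normal(0, 0.3, size=y.shape)
    q = rng.normal(0, 0.5, size=y.shape)  # logit of tau_it
    s_eps = float(fix_sigma) if fix_sigma is not None else rng.uniform(0.3, 2.0)
    ls_z = np.log(1.0 / np.sqrt(y + 2.0))
    ls_q = np.full(y.shape, np.log(1.0))
    ls_s = np.log(0.3)

    n_keep = (iterations - burn_in) // thin
    store = {
        "z": np.empty((n_keep,) + y.shape),
        "tau": np.empty((n_keep,) + y.shape),
        "sigma_eps": np.empty(n_keep),
    }
    k = 0
    for it in range(iterations):
        adapting = it < burn_in
        tau = 1.0 / (1.0 + np.exp(-q))
        r = log_c - z
        # latent log risk
        zp = z + np.exp(ls_z) * rng.standard_normal(z.shape)
        rp = log_c - zp
        d = (
            y * (zp - z)
            - e * (np.exp(zp) - np.exp(z))
            - (_rho(rp, tau) - _rho(r, tau)) / s_eps
        )
        acc = np.log(rng.uniform(size=d.shape)) < d
        z = np.where(acc, zp, z)
        r = log_c - z
        _adapt(ls_z, acc, it, adapting)
        # per-unit quantile level on the logit scale; the flat Beta(1,1)
        # prior contributes only the Jacobian tau(1-tau)
        qp = q + np.exp(ls_q) * rng.standard_normal(q.shape)
        taup = 1.0 / (1.0 + np.exp(-qp))
        d = (
            2.0 * (np.log(taup * (1.0 - taup)) - np.log(tau * (1.0 - tau)))
            - (_rho(r, taup) - _rho(r, tau)) / s_eps
        )
        acc = np.log(rng.uniform(size=d.shape)) < d
        q = np.where(acc, qp, q)
        tau = 1.0 / (1.0 + np.exp(-q))
        _adapt(ls_q, acc, it, adapting)
        # shared AL scale: p(s) ~ s^-N exp(-sum(rho)/s) on (0, upper);
        # exact Gibbs via 1/s ~ Gamma(N-1, rate sum(rho)), truncated
        if fix_sigma is None:
            s_rho = float(_rho(r, tau).sum())
            if s_rho > 0.0:
                for _ in range(64):
                    x = rng.gamma(N - 1) / s_rho
                    if x > 1.0 / sd_upper:
                        s_eps = float(1.0 / x)
                        break
            else:  # degenerate: flat-ish conditional, random-walk fallback
                sp = s_eps * np.exp(np.exp(ls_s) * rng.standard_normal())
                if sp < sd_upper and np.log(rng.uniform()) < -(N - 1) * (
                    np.log(sp) - np.log(s_eps)
                ):
                    s_eps = float(sp)
        if it >= burn_in and (it - burn_in) % thin == 0:
            store["z"][k] = z
            store["tau"][k] = tau
            store["sigma_eps"][k] = s_eps
            k += 1
    return store
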