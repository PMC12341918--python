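"""REML engine for Gaussian mixed models with longitudinal residuals.

The engine fits models of the form::

    y = X theta + sum_k Z_k g_k + e,   g_k ~ N(0, sigma_k^2 G_k),
    e ~ N(0, blockdiag_plants R[cycles observed by the plant])

where ``R`` is an unstructured positive-definite covariance between crop
cycles of the same plant, each random term carries an arbitrary supplied
covariance structure ``G_k`` (identity if omitted) and variance parameters
may be shared between terms by name.

Each ``G_k`` is eigen-factored once as ``G_k = L_k L_k^T`` (PSD structures,
including singular ones, are handled by dropping null directions), so the
working random design is ``Z_k L_k`` with iid scaled effects.  Levels with
no observations still receive BLUPs through their covariance with observed
levels, which is what one-step prediction of unobserved crosses relies on.

Random effects whose levels are confined to a single plant (the within-cross
hybrid deviation of a once-planted hybrid) can be *absorbed* into the
per-plant residual covariance (``R + sigma_H^2 J``), which removes thousands
of mixed-model-equation rows while leaving the likelihood unchanged;
cross-specific hybrid variances are absorbed the same way with one variance
parameter per cross group.

Estimation maximises the REML log-likelihood with a projected quasi-Newton
method (L-BFGS-B) on analytic gradients, with monotone EM steps available
for warm starts and as a fallback; variances are kept non-negative by bound
projection and flagged when pinned at the boundary, and ``R`` is
parameterised by its Cholesky factor so it stays positive definite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import optimize, stats

log = logging.getLogger(__name__)

VAR_FLOOR = 1e-10  # relative floor (times var(y)) for variance components
CONV_LL_TOL = 1e-8
CONV_PAR_TOL = 1e-6
MAX_ITER = 200


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the optimisation trajectory."""

    def __init__(self, message: str, trajectory: list[float] | None = None):
        super().__init__(message)
        self.trajectory = trajectory or []


@dataclass
class RandomTerm:
    """One random term: per-observation level index and covariance structure.

    ``z`` holds the level index of each observation (-1 for observations the
    term does not apply to, e.g. control plants in GCA terms).  ``G`` is the
    covariance structure over all ``levels`` (identity when None), and
    ``variance`` names the variance parameter (shared across terms carrying
    the same name).
    """

    name: str
    levels: list
    z: np.ndarray
    G: np.ndarray | None = None
    variance: str | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=int)
        if self.variance is None:
            self.variance = f"sigma2_{self.name}"
        if self.z.max(initial=-1) >= len(self.levels):
            raise ValueError(f"term {self.name}: level index out of range")
        if self.G is not None and self.G.shape != (len(self.levels),) * 2:
            raise ValueError(f"term {self.name}: G does not match levels")


@dataclass
class AbsorbedTerm:
    """Plant-exclusive iid random effect folded into the residual blocks.

    ``group`` labels each observation with its variance group (None/NaN for
    observations without the effect); every plant must carry a single group.
    ``variance_of`` optionally maps group label -> variance parameter name
    (default ``sigma2_{name}`` when there is a single group, else
    ``sigma2_{name}[{group}]``).
    """

    name: str
    group: np.ndarray
    variance_of: dict | None = None


@dataclass
class ModelFit:
    """Converged REML fit: parameters, BLUEs, BLUPs and diagnostics."""

    loglik: float
    neg2_reml: float
    variances: dict[str, float]
    R: np.ndarray
    beta: np.ndarray
    beta_se: np.ndarray
    x_names: list[str]
    blups: dict[str, "pd.Series"]
    absorbed_blups: "pd.Series | None"
    n_obs: int
    n_params: int
    converged: bool
    n_iter: int
    grad_norm: float
    boundary: dict[str, bool]
    method: str
    model: "MixedModel" = field(repr=False, default=None)

    @property
    def fixed_effects(self) -> "pd.Series":
        import pandas as pd

        return pd.Series(self.beta, index=self.x_names)


# --------------------------------------------------------------------------


def _factor_psd(G: np.ndarray, name: str, tol: float = 1e-10) -> np.ndarray:
    """Return L with G = L L^T, dropping null eigen-directions."""
    w, U = np.linalg.eigh((G + G.T) / 2.0)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError(f"covariance structure of term {name!r} is not PSD")
    keep = w > tol * max(1.0, w.max())
    return U[:, keep] * np.sqrt(w[keep])


class MixedModel:
    """A mixed model bound to one observation vector and design.

    Parameters
    ----------
    y, X : observation vector (n,) and fixed-effect design (n, p).
    plant : (n,) array of plant identifiers (groups repeated measures).
    cycle : (n,) array of 1-based crop-cycle indices in {1, .., n_cycles}.
    random : explicit random terms.
    absorbed : optional plant-exclusive iid term (see AbsorbedTerm).
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        plant: np.ndarray,
        cycle: np.ndarray,
        random: Sequence[RandomTerm] = (),
        absorbed: AbsorbedTerm | None = None,
        n_cycles: int = 3,
        x_names: Sequence[str] | None = None,
    ) -> None:
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = y.size
        if X.shape[0] != n:
            raise ValueError("X and y disagree on the number of observations")
        cycle = np.asarray(cycle, dtype=int)
        if cycle.min() < 1 or cycle.max() > n_cycles:
            raise ValueError(f"cycle indices must be in 1..{n_cycles}")
        self.n_cycles = n_cycles
        self.x_names = list(x_names) if x_names is not None else [
            f"x{j}" for j in range(X.shape[1])
        ]

        # rank check with aliased-column naming
        _, Rq, piv = sla.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(Rq))
        bad = diag < 1e-8 * max(1.0, diag.max())
        if bad.any():
            aliased = [self.x_names[piv[j]] for j in np.where(bad)[0]]
            raise ValueError(f"fixed-effect design is rank deficient; aliased "
                             f"columns: {aliased}")

        plant_labels, plant_idx = np.unique(np.asarray(plant), return_inverse=True)
        order = np.lexsort((cycle, plant_idx))
        self.order = order
        self.y = y[order]
        self.X = X[order]
        self.plant_idx = plant_idx[order]
        self.cycle0 = cycle[order] - 1
        self.plant_labels = plant_labels
        self.n_plants = len(plant_labels)
        self.n, self.p = self.X.shape

        key = self.plant_idx * n_cycles + self.cycle0
        if len(np.unique(key)) != n:
            raise ValueError("duplicate (plant, cycle) observation")

        # obs row per (plant, cycle); -1 when unobserved
        self.omat = -np.ones((self.n_plants, n_cycles), dtype=int)
        self.omat[self.plant_idx, self.cycle0] = np.arange(n)

        # absorbed term: per-plant variance-group index (-1 = none)
        self.absorbed = absorbed
        self.abs_group_of_plant = np.full(self.n_plants, -1, dtype=int)
        self.abs_group_params: list[str] = []
        self.abs_group_labels: list = []
        if absorbed is not None:
            raw = np.asarray(absorbed.group, dtype=object)[order]
            has = np.array([g is not None and g == g for g in raw])
            labels = sorted({g for g in raw[has]}, key=str)
            lab_idx = {g: i for i, g in enumerate(labels)}
            per_plant = {}
            for i in range(n):
                pl = self.plant_idx[i]
                g = lab_idx[raw[i]] if has[i] else -1
                if pl in per_plant and per_plant[pl] != g:
                    raise ValueError(
                        f"absorbed term {absorbed.name!r}: plant "
                        f"{plant_labels[pl]!r} carries several groups"
                    )
                per_plant[pl] = g
            for pl, g in per_plant.items():
                self.abs_group_of_plant[pl] = g
            vmap = absorbed.variance_of or {}
            for g in labels:
                if g in vmap:
                    self.abs_group_params.append(vmap[g])
                elif len(labels) == 1:
                    self.abs_group_params.append(f"sigma2_{absorbed.name}")
                else:
                    self.abs_group_params.append(f"sigma2_{absorbed.name}[{g}]")
            self.abs_group_labels = labels

        # plant groups sharing (cycle pattern, absorbed group)
        groups: dict[tuple, list[int]] = {}
        for pl in range(self.n_plants):
            pat = tuple(np.where(self.omat[pl] >= 0)[0])
            groups.setdefault((pat, self.abs_group_of_plant[pl]), []).append(pl)
        self.groups = []
        for (pat, g), plants in sorted(groups.items()):
            plants = np.array(plants, dtype=int)
            idx = self.omat[plants][:, list(pat)]
            self.groups.append({
                "pattern": np.array(pat, dtype=int), "abs_group": g,
                "plants": plants, "obs": idx,
            })

        # explicit random terms -> working sparse design Zt (n x r_total)
        self.random = list(random)
        rows, cols, vals = [], [], []
        col_param: list[int] = []
        self.param_names: list[str] = []

        def param_id(name: str) -> int:
            if name not in self.param_names:
                self.param_names.append(name)
            return self.param_names.index(name)

        self.term_slices: dict[str, slice] = {}
        self.term_L: dict[str, np.ndarray | None] = {}
        c0 = 0
        for term in self.random:
            z = term.z[order]
            q = len(term.levels)
            pid = param_id(term.variance)
            if term.G is None:
                r = q
                obs = np.where(z >= 0)[0]
                rows.extend(obs.tolist())
                cols.extend((c0 + z[obs]).tolist())
                vals.extend([1.0] * len(obs))
                self.term_L[term.name] = None
            else:
                L = _factor_psd(term.G, term.name)
                r = L.shape[1]
                obs = np.where(z >= 0)[0]
                rows.extend(np.repeat(obs, r).tolist())
                cols.extend(np.tile(np.arange(c0, c0 + r), len(obs)).tolist())
                vals.extend(L[z[obs]].ravel().tolist())
                self.term_L[term.name] = L
            self.term_slices[term.name] = slice(c0, c0 + r)
            col_param.extend([pid] * r)
            c0 += r
            term._z_sorted = z  # type: ignore[attr-defined]
        self.r_total = c0
        self.Zt = sp.csr_matrix(
            (np.array(vals), (np.array(rows, dtype=int), np.array(cols, dtype=int))),
            shape=(self.n, c0),
        ) if c0 else sp.csr_matrix((self.n, 0))
        self.col_param = np.array(col_param, dtype=int)
        for name in self.abs_group_params:
            param_id(name)
        self.n_var_params = len(self.param_names)
        self.scale = float(np.var(self.y)) or 1.0
        self._obs_of_cycle = [np.where(self.cycle0 == c)[0] for c in range(n_cycles)]

    # -- parameter packing -------------------------------------------------

    @property
    def n_r_params(self) -> int:
        C = self.n_cycles
        return C * (C + 1) // 2

    @property
    def n_free_params(self) -> int:
        return self.n_var_params + self.n_r_params

    def _tril_indices(self):
        return np.tril_indices(self.n_cycles)

    def pack(self, variances: dict[str, float], R: np.ndarray) -> np.ndarray:
        L = np.linalg.cholesky(R)
        return np.concatenate([
            np.array([variances[p] for p in self.param_names]),
            L[self._tril_indices()],
        ])

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = theta[: self.n_var_params]
        L = np.zeros((self.n_cycles, self.n_cycles))
        L[self._tril_indices()] = theta[self.n_var_params:]
        return v, L, L @ L.T

    def _bounds(self) -> list[tuple[float | None, float | None]]:
        lb_v = VAR_FLOOR * self.scale
        bounds: list[tuple[float | None, float | None]] = [
            (lb_v, None)
        ] * self.n_var_params
        iL, jL = self._tril_indices()
        lb_d = 1e-6 * np.sqrt(self.scale)
        for a, b in zip(iL, jL):
            bounds.append((lb_d, None) if a == b else (None, None))
        return bounds

    # -- core linear algebra ----------------------------------------------

    def _prepare(self, v: np.ndarray, R: np.ndarray):
        """Per-group residual-block inverses and the assembled csr R^{-1}."""
        ctx: dict = {"v": v, "R": R, "Sinv": [], "logdetR": 0.0}
        rows, cols, vals = [], [], []
        for g in self.groups:
            pat = g["pattern"]
            k = len(pat)
            Sg = R[np.ix_(pat, pat)].copy()
            gi = g["abs_group"]
            if gi >= 0:
                s = v[self.param_names.index(self.abs_group_params[gi])]
                Sg = Sg + s
            sign, ld = np.linalg.slogdet(Sg)
            if sign <= 0:
                raise np.linalg.LinAlgError("residual block not PD")
            Sinv = np.linalg.inv(Sg)
            ctx["Sinv"].append(Sinv)
            ctx["logdetR"] += ld * len(g["plants"])
            idx = g["obs"]  # (npl, k)
            npl = idx.shape[0]
            rr = np.repeat(idx, k, axis=1).ravel()
            cc = np.tile(idx, (1, k)).ravel()
            vv = np.tile(Sinv.ravel(), npl)
            rows.append(rr)
            cols.append(cc)
            vals.append(vv)
        Rinv = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        )
        ctx["Rinv"] = Rinv
        return ctx

    def _core(self, v: np.ndarray, R: np.ndarray):
        """Factorised quantities shared by the criterion, gradient and solve."""
        ctx = self._prepare(v, R)
        Rinv = ctx["Rinv"]
        X, y, Zt = self.X, self.y, self.Zt
        RX = Rinv @ X
        Ry = Rinv @ y
        ctx.update(RX=RX, Ry=Ry)
        XtRX = X.T @ RX
        XtRy = X.T @ Ry
        ytRy = y @ Ry

        if self.r_total:
            colv = v[self.col_param]
            H = Rinv @ Zt                      # sparse n x r
            S = (Zt.T @ H).toarray()
            SX = Zt.T @ RX
            Sy = Zt.T @ Ry
            M = S + np.diag(1.0 / colv)
            cM = sla.cho_factor(M, lower=True)
            MiSX = sla.cho_solve(cM, SX)
            MiSy = sla.cho_solve(cM, Sy)
            A = XtRX - SX.T @ MiSX
            a = XtRy - SX.T @ MiSy
            yVy = ytRy - Sy @ MiSy
            logdetM = 2.0 * np.sum(np.log(np.diag(cM[0])))
            logdetG = float(np.sum(np.log(colv)))
            ctx.update(H=H, S=S, SX=SX, Sy=Sy, cM=cM, MiSX=MiSX, MiSy=MiSy,
                       colv=colv)
        else:
            A, a, yVy = XtRX, XtRy, ytRy
            logdetM = logdetG = 0.0

        cA = sla.cho_factor((A + A.T) / 2.0, lower=True)
        beta = sla.cho_solve(cA, a)
        yPy = yVy - a @ beta
        logdetA = 2.0 * np.sum(np.log(np.diag(cA[0])))
        neg2 = (ctx["logdetR"] + logdetG + logdetM + logdetA + yPy
                + (self.n - self.p) * np.log(2.0 * np.pi))
        ctx.update(A=A, cA=cA, beta=beta, yPy=yPy, neg2=neg2)
        return ctx

    def _apply_Vinv(self, ctx, W: np.ndarray) -> np.ndarray:
        """V^{-1} W for a dense matrix/vector W."""
        Rinv = ctx["Rinv"]
        RW = Rinv @ W
        if not self.r_total:
            return RW
        ZtRW = self.Zt.T @ RW
        return RW - Rinv @ (self.Zt @ sla.cho_solve(ctx["cM"], ZtRW))

    def neg2_reml(self, variances: dict[str, float], R: np.ndarray) -> float:
        v = np.array([variances[p] for p in self.param_names])
        return self._core(v, R)["neg2"]

    def neg2_reml_dense(self, variances: dict[str, float], R: np.ndarray) -> float:
        """Direct dense evaluation of the REML criterion (test oracle)."""
        V = np.zeros((self.n, self.n))
        if self.r_total:
            colv = np.array([variances[p] for p in self.param_names])[self.col_param]
            Zd = self.Zt.toarray()
            V += (Zd * colv) @ Zd.T
        for g in self.groups:
            pat = g["pattern"]
            blk = R[np.ix_(pat, pat)].copy()
            if g["abs_group"] >= 0:
                blk = blk + variances[self.abs_group_params[g["abs_group"]]]
            for row in g["obs"]:
                V[np.ix_(row, row)] += blk
        sign, logdetV = np.linalg.slogdet(V)
        Vi = np.linalg.inv(V)
        A = self.X.T @ Vi @ self.X
        beta = np.linalg.solve(A, self.X.T @ Vi @ self.y)
        r = self.y - self.X @ beta
        return float(logdetV + np.linalg.slogdet(A)[1] + r @ Vi @ r
                     + (self.n - self.p) * np.log(2 * np.pi))

    # -- analytic gradient -------------------------------------------------

    def _neg2_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        v, Lc, R = self.unpack(theta)
        ctx = self._core(v, R)
        cA, beta = ctx["cA"], ctx["beta"]
        res = self.y - self.X @ beta
        Py = self._apply_Vinv(ctx, res)
        ViX = self._apply_Vinv(ctx, self.X)

        grad_v = np.zeros(self.n_var_params)

        # explicit terms: dV/dv = sum of z_j z_j^T over columns with that param
        if self.r_total:
            S, SX = ctx["S"], ctx["SX"]
            MiS = sla.cho_solve(ctx["cM"], S)
            dZVZ = np.diag(S) - np.einsum("ij,ji->i", S, MiS)
            ZViX = SX - S @ ctx["MiSX"]                # = Zt^T V^{-1} X
            AiZX = sla.cho_solve(cA, ZViX.T)           # p x r
            dCorr = np.einsum("rp,pr->r", ZViX, AiZX)
            u = self.Zt.T @ Py
            contrib = (dZVZ - dCorr) - u**2
            np.add.at(grad_v, self.col_param, contrib)

        # per-plant helpers
        Pymat = np.zeros((self.n_plants, self.n_cycles))
        Pymat[self.plant_idx, self.cycle0] = Py
        if self.r_total:
            Hm = (ctx["H"] @ sla.cho_solve(ctx["cM"], np.eye(self.r_total)))
            Hd = ctx["H"].toarray()
        else:
            Hm = Hd = None

        # absorbed variance groups: dV/ds = J over plants in the group
        for gi, pname in enumerate(self.abs_group_params):
            pid = self.param_names.index(pname)
            tr = 0.0
            quad = 0.0
            bs_list = []
            for g, Sinv in zip(self.groups, ctx["Sinv"]):
                if g["abs_group"] != gi:
                    continue
                idx = g["obs"]
                tr += float(Sinv.sum()) * len(g["plants"])
                if Hm is not None:
                    hm = Hm[idx].sum(axis=1)   # (npl, r)
                    hd = Hd[idx].sum(axis=1)
                    tr -= float(np.einsum("pr,pr->", hm, hd))
                prow = Pymat[g["plants"]][:, g["pattern"]].sum(axis=1)
                quad += float(np.sum(prow**2))
                bs_list.append(ViX[idx].sum(axis=1))
            if bs_list:
                bsum = np.concatenate(bs_list, axis=0)
                T = bsum.T @ bsum
                tr -= float(np.trace(sla.cho_solve(cA, T)))
            grad_v[pid] += tr - quad

        # R entries (independent-entry convention), then chain to Cholesky
    # dV/dR_cd = E_cd over plants observing both cycles c and d
        gR = np.zeros((self.n_cycles, self.n_cycles))
        ViXc = [np.zeros((self.n_plants, self.p)) for _ in range(self.n_cycles)]
        hasc = np.zeros((self.n_plants, self.n_cycles), dtype=bool)
        for c in range(self.n_cycles):
            obs = self._obs_of_cycle[c]
            ViXc[c][self.plant_idx[obs]] = ViX[obs]
            hasc[self.plant_idx[obs], c] = True
        Hmc = [None] * self.n_cycles
        Hdc = [None] * self.n_cycles
        if Hm is not None:
            for c in range(self.n_cycles):
                obs = self._obs_of_cycle[c]
                a = np.zeros((self.n_plants, self.r_total))
                b = np.zeros((self.n_plants, self.r_total))
                a[self.plant_idx[obs]] = Hm[obs]
                b[self.plant_idx[obs]] = Hd[obs]
                Hmc[c], Hdc[c] = a, b
        sinv_cd = np.zeros((self.n_cycles, self.n_cycles))
        for g, Sinv in zip(self.groups, ctx["Sinv"]):
            pat = g["pattern"]
            npl = len(g["plants"])
            sinv_cd[np.ix_(pat, pat)] += Sinv * npl
        for c in range(self.n_cycles):
            for d in range(self.n_cycles):
                both = hasc[:, c] & hasc[:, d]
                tr = sinv_cd[c, d]
                if Hm is not None:
                    tr -= float(np.einsum("pr,pr->", Hmc[c][both], Hdc[d][both]))
                T = ViXc[c][both].T @ ViXc[d][both]
                tr -= float(np.trace(sla.cho_solve(cA, T)))
                quad = float(np.sum(Pymat[both, c] * Pymat[both, d]))
                gR[c, d] = tr - quad
        gL = (gR + gR.T) @ Lc
        grad = np.concatenate([grad_v, gL[self._tril_indices()]])
        return float(ctx["neg2"]), grad

    # -- EM ----------------------------------------------------------------

    def em_step(self, variances: dict[str, float], R: np.ndarray,
                update_R: bool = True) -> tuple[dict[str, float], np.ndarray]:
        """One monotone EM-REML update of all variance parameters (and R).

        R is only updated when every plant is observed in all cycles (the
        complete-data EM for an unstructured residual); otherwise it is kept.
        """
        v = np.array([variances[p] for p in self.param_names])
        ctx = self._core(v, R)
        beta = ctx["beta"]
        res = self.y - self.X @ beta
        Py = self._apply_Vinv(ctx, res)
        ViX = self._apply_Vinv(ctx, self.X)
        cA = ctx["cA"]

        new = dict(variances)
        counts = {p: 0.0 for p in self.param_names}
        sums = {p: 0.0 for p in self.param_names}

        if self.r_total:
            S = ctx["S"]
            MiS = sla.cho_solve(ctx["cM"], S)
            dZVZ = np.diag(S) - np.einsum("ij,ji->i", S, MiS)
            ZViX = ctx["SX"] - S @ ctx["MiSX"]
            AiZX = sla.cho_solve(cA, ZViX.T)
            dZPZ = dZVZ - np.einsum("rp,pr->r", ZViX, AiZX)
            u = self.Zt.T @ Py
            colv = ctx["colv"]
            uhat = colv * u
            e2 = uhat**2 + colv - colv**2 * dZPZ
            for j in range(self.r_total):
                pname = self.param_names[self.col_param[j]]
                sums[pname] += e2[j]
                counts[pname] += 1.0

        Pymat = np.zeros((self.n_plants, self.n_cycles))
        Pymat[self.plant_idx, self.cycle0] = Py
        if self.r_total:
            Hm = ctx["H"] @ sla.cho_solve(ctx["cM"], np.eye(self.r_total))
            Hd = ctx["H"].toarray()
        for gi, pname in enumerate(self.abs_group_params):
            s = variances[pname]
            for g, Sinv in zip(self.groups, ctx["Sinv"]):
                if g["abs_group"] != gi:
                    continue
                idx = g["obs"]
                hhat = s * Pymat[g["plants"]][:, g["pattern"]].sum(axis=1)
                onePone = np.full(len(g["plants"]), float(Sinv.sum()))
                if self.r_total:
                    hm = Hm[idx].sum(axis=1)
                    hd = Hd[idx].sum(axis=1)
                    onePone -= np.einsum("pr,pr->p", hm, hd)
                bp = ViX[idx].sum(axis=1)
                onePone -= np.einsum("pj,jp->p", bp, sla.cho_solve(cA, bp.T))
                e2 = hhat**2 + s - s**2 * onePone
                sums[pname] += float(e2.sum())
                counts[pname] += len(g["plants"])
        for pname in self.param_names:
            if counts[pname]:
                new[pname] = max(sums[pname] / counts[pname],
                                 VAR_FLOOR * self.scale)

        Rnew = R
        complete = all(len(g["pattern"]) == self.n_cycles for g in self.groups)
        if update_R and complete:
            # E[e e^T | y] = R Py Py^T R + R - R P R  per plant, averaged
            acc = np.zeros((self.n_cycles, self.n_cycles))
            for g, Sinv in zip(self.groups, ctx["Sinv"]):
                idx = g["obs"]
                pv = Pymat[g["plants"]]          # complete patterns
                acc += R @ (pv.T @ pv) @ R
                Pblk = np.tile(Sinv, (len(g["plants"]), 1, 1))
                if self.r_total:
                    Pblk = Pblk - np.einsum("pkr,plr->pkl", Hm[idx], Hd[idx])
                bp = ViX[idx]                     # (npl, k, p)
                Ai_bp = sla.cho_solve(cA, bp.reshape(-1, self.p).T)
                Ai_bp = Ai_bp.T.reshape(bp.shape)
                Pblk = Pblk - np.einsum("pkj,plj->pkl", bp, Ai_bp)
                acc += len(g["plants"]) * R - R @ Pblk.sum(axis=0) @ R
            Rnew = acc / self.n_plants
            Rnew = (Rnew + Rnew.T) / 2.0
        return new, Rnew

    # -- fitting -----------------------------------------------------------

    def _default_start(self) -> tuple[dict[str, float], np.ndarray]:
        vy = self.scale
        variances = {p: 0.5 * vy / max(1, self.n_var_params)
                     for p in self.param_names}
        R = 0.5 * vy * np.eye(self.n_cycles)
        return variances, R

    def fit(
        self,
        start: tuple[dict[str, float], np.ndarray] | None = None,
        method: str = "auto",
        max_iter: int = MAX_ITER,
        em_warmup: int = 2,
    ) -> ModelFit:
        """Maximise the REML log-likelihood and return the solved model."""
        variances, R = start if start is not None else self._default_start()
        trajectory: list[float] = []

        if method in ("auto", "em") and em_warmup and method == "auto":
            for _ in range(em_warmup):
                variances, R = self.em_step(variances, R)

        if method == "em":
            prev = np.inf
            it = 0
            for it in range(max_iter):
                variances, R = self.em_step(variances, R)
                f = self.neg2_reml(variances, R)
                trajectory.append(f)
                if abs(prev - f) < CONV_LL_TOL * (1.0 + abs(f)):
                    break
                prev = f
            theta = self.pack(variances, R)
            return self._finish(theta, "em", it + 1, np.nan, True)

        theta0 = self.pack(variances, R)
        res = optimize.minimize(
            self._neg2_and_grad, theta0, jac=True, method="L-BFGS-B",
            bounds=self._bounds(),
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7,
                     "maxcor": 25},
        )
        trajectory.append(float(res.fun))
        ok = bool(res.success) or res.status == 0
        gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
        if not np.isfinite(res.fun):
            raise ConvergenceError(
                f"REML did not converge: {res.message}", trajectory
            )
        if not ok and method == "auto":
            # EM fallback from the best point reached
            v, _, Rcur = self.unpack(res.x)
            variances = dict(zip(self.param_names, v))
            prev = float(res.fun)
            for it in range(max_iter):
                variances, Rcur = self.em_step(variances, Rcur)
                f = self.neg2_reml(variances, Rcur)
                trajectory.append(f)
                if abs(prev - f) < CONV_LL_TOL * (1.0 + abs(f)):
                    break
                prev = f
            theta = self.pack(variances, Rcur)
            return self._finish(theta, "quasi-newton+em", it + 1, np.nan, True)
        if not ok:
            raise ConvergenceError(
                f"REML did not converge after {res.nit} iterations: "
                f"{res.message}", trajectory,
            )
        return self._finish(res.x, "quasi-newton", int(res.nit), gnorm, ok)

    def _finish(self, theta, method, n_iter, gnorm, converged) -> ModelFit:
        import pandas as pd

        v, _, R = self.unpack(theta)
        variances = dict(zip(self.param_names, v))
        ctx = self._core(v, R)
        beta = ctx["beta"]
        Ainv = sla.cho_solve(ctx["cA"], np.eye(self.p))
        res = self.y - self.X @ beta
        Py = self._apply_Vinv(ctx, res)

        blups: dict[str, pd.Series] = {}
        if self.r_total:
            u = self.Zt.T @ Py
            uhat = ctx["colv"] * u
            for term in self.random:
                s = self.term_slices[term.name]
                L = self.term_L[term.name]
                g = uhat[s] if L is None else L @ uhat[s]
                blups[term.name] = pd.Series(g, index=list(term.levels))
        abs_blups = None
        if self.absorbed is not None:
            Pymat = np.zeros((self.n_plants, self.n_cycles))
            Pymat[self.plant_idx, self.cycle0] = Py
            vals = np.zeros(self.n_plants)
            for pl in range(self.n_plants):
                gi = self.abs_group_of_plant[pl]
                if gi >= 0:
                    s = variances[self.abs_group_params[gi]]
                    vals[pl] = s * Pymat[pl].sum()
            mask = self.abs_group_of_plant >= 0
            abs_blups = pd.Series(vals[mask],
                                  index=list(self.plant_labels[mask]))

        lb = VAR_FLOOR * self.scale
        boundary = {p: variances[p] <= 2.0 * lb for p in self.param_names}
        neg2 = float(ctx["neg2"])
        return ModelFit(
            loglik=-0.5 * neg2,
            neg2_reml=neg2,
            variances=variances,
            R=R,
            beta=beta,
            beta_se=np.sqrt(np.diag(Ainv)),
            x_names=self.x_names,
            blups=blups,
            absorbed_blups=abs_blups,
            n_obs=self.n,
            n_params=self.n_free_params,
            converged=converged,
            n_iter=n_iter,
            grad_norm=gnorm,
            boundary=boundary,
            method=method,
            model=self,
        )

    def solve(self, variances: dict[str, float], R: np.ndarray) -> ModelFit:
        """BLUEs/BLUPs at fixed variance parameters (no optimisation)."""
        theta = self.pack(
            {p: max(variances[p], VAR_FLOOR * self.scale)
             for p in self.param_names}, R,
        )
        return self._finish(theta, "fixed-params", 0, np.nan, True)


def fit_reml(model: MixedModel, **kwargs) -> ModelFit:
    """Convenience wrapper: ``model.fit(**kwargs)``."""
    return model.fit(**kwargs)


def lr_test(full: ModelFit, reduced: ModelFit,
            boundary: bool = False) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested REML fits on identical fixed effects.

    When the single tested parameter is a variance constrained to be
    non-negative, ``boundary=True`` applies the 50:50 mixture of chi-square
    distributions with 0 and ``df`` degrees of freedom.
    """
    if full.x_names != reduced.x_names:
        raise ValueError("REML LR tests require identical fixed effects")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("models are not nested (reduced has more parameters)")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:
        return stat, 0, 1.0
    if boundary:
        p = 0.5 * stats.chi2.sf(stat, df)
        if df > 1:
            p += 0.5 * stats.chi2.sf(stat, df - 1)
        elif stat == 0.0:
            p = 1.0
    else:
        p = float(stats.chi2.sf(stat, df))
    return stat, df, float(min(1.0, p))
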