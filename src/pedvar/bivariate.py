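"""Bivariate A/D/H/E variance-component maximum likelihood.

Two traits per individual are modelled jointly: each component ``c``
contributes a 2x2 cross-trait covariance matrix ``C_c``, and a family's
stacked observation vector (individual-major: both traits of individual 1,
then individual 2, ...) has covariance

    Sigma = sum_c  R_c (x) C_c

where ``R_c`` is the family's structure matrix for that component and
``(x)`` the Kronecker product.  Each ``C_c`` is parameterised by its
Cholesky factor, which keeps it positive semi-definite throughout the
optimisation.  Fixed effects (per-trait intercept, age, sex) are profiled
out by GLS.  From the fitted matrices we report the per-component
cross-trait correlations ``r_c``, the combined (A+D) genetic correlation,
and the share of the phenotypic cross-covariance each component explains.

Per-trait missingness is handled by dropping the missing scalar entries
from the stacked vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .pedigree import PedigreeGraph, relationship_matrices
from .scales import inverse_normal_transform
from .varcomp import COMPONENTS, ComponentSpec, ADHE, FitError

logger = logging.getLogger(__name__)

_RANK0_TOL = 1e-5


@dataclass
class BivBlock:
    """One family: structure matrices, (m, 2) trait matrix, (m, p) covariates."""

    R: dict[str, np.ndarray]
    Y: np.ndarray                 # (m, 2), NaN = missing
    X: np.ndarray                 # (m, p) per-individual covariates
    family_id: str = ""


@dataclass
class _BivGroup:
    S: dict[str, np.ndarray]      # component -> masked kron structure (q, q)
    Yobs: np.ndarray              # (n, q)
    Xobs: np.ndarray              # (n, q, 2p)
    family_ids: list[str]


class BivariateDataset:
    """Blocks grouped by identical (structure, missingness) pattern."""

    def __init__(self, blocks: list[BivBlock], components: tuple[str, ...]):
        if not blocks:
            raise ValueError("no observation blocks")
        self.components = tuple(c for c in COMPONENTS if c in components)
        p = blocks[0].X.shape[1]
        self.p = 2 * p
        buckets: dict[bytes, list] = {}
        for b in blocks:
            mask = ~np.isnan(b.Y.ravel())
            if not mask.any():
                continue
            key = (
                b"".join(np.round(b.R[c], 9).tobytes() for c in self.components)
                + mask.tobytes()
            )
            buckets.setdefault(key, []).append((b, mask))
        self.groups: list[_BivGroup] = []
        for items in buckets.values():
            b0, mask = items[0]
            m = b0.Y.shape[0]
            S = {c: b0.R[c] for c in self.components}
            Ys, Xs = [], []
            for b, _ in items:
                yfull = b.Y.ravel()
                Xbig = np.zeros((2 * m, self.p))
                for t in range(2):
                    Xbig[t::2, t * p : (t + 1) * p] = b.X
                Ys.append(yfull[mask])
                Xs.append(Xbig[mask])
            self.groups.append(
                _BivGroup(
                    S={"mask": mask, **S},
                    Yobs=np.stack(Ys),
                    Xobs=np.stack(Xs),
                    family_ids=[b.family_id for b, _ in items],
                )
            )
        self.n_obs = sum(g.Yobs.size for g in self.groups)
        self.n_blocks = len(blocks)
        ally = np.concatenate([g.Yobs.ravel() for g in self.groups])
        self.var_y = float(np.var(ally))

    # -- likelihood -----------------------------------------------------------

    def _sigma(self, g: _BivGroup, C: dict[str, np.ndarray]) -> np.ndarray:
        mask = g.S["mask"]
        S = sum(np.kron(g.S[c], C[c]) for c in self.components)
        return S[np.ix_(mask, mask)]

    def profile_negloglik(self, C: dict[str, np.ndarray]):
        decs = []
        A = np.zeros((self.p, self.p))
        bvec = np.zeros(self.p)
        for g in self.groups:
            S = self._sigma(g, C)
            q = S.shape[0]
            try:
                L = linalg.cholesky(S + 1e-12 * np.eye(q), lower=True)
            except linalg.LinAlgError as exc:
                raise FitError(
                    f"singular bivariate covariance in family "
                    f"{g.family_ids[0]!r}"
                ) from exc
            Vw = linalg.solve_triangular(L, g.Yobs.T, lower=True)
            n = g.Yobs.shape[0]
            Xmat = g.Xobs.transpose(1, 0, 2).reshape(q, n * self.p)
            Uw = linalg.solve_triangular(L, Xmat, lower=True).reshape(q, n, self.p)
            A += np.einsum("qnp,qnr->pr", Uw, Uw)
            bvec += np.einsum("qnp,qn->p", Uw, Vw)
            decs.append((g, L, Vw, Uw))
        beta = linalg.solve(A, bvec, assume_a="pos")
        negll = 0.5 * self.n_obs * np.log(2.0 * np.pi)
        for g, L, Vw, Uw in decs:
            n = g.Yobs.shape[0]
            E = Vw - np.einsum("qnp,p->qn", Uw, beta)
            negll += n * np.sum(np.log(np.diag(L))) + 0.5 * np.sum(E * E)
        return float(negll), beta, A


def _theta_to_C(
    theta: np.ndarray, components: tuple[str, ...]
) -> dict[str, np.ndarray]:
    C = {}
    for k, c in enumerate(components):
        l11, l21, l22 = theta[3 * k : 3 * k + 3]
        Lc = np.array([[l11, 0.0], [l21, l22]])
        C[c] = Lc @ Lc.T
    return C


def blocks_from_phenotypes(
    peds: dict[str, PedigreeGraph],
    phenos: pd.DataFrame,
    traits: tuple[str, str],
    transform: bool = False,
) -> list[BivBlock]:
    """Build bivariate blocks from pedigrees and a two-trait phenotype table."""
    ph = phenos.copy()
    ph["individual_id"] = ph["individual_id"].astype(str)
    for t in traits:
        if transform:
            ph[t] = inverse_normal_transform(ph[t].to_numpy(float))
    mean_age = float(np.nanmean(ph["age"].to_numpy(float)))
    ph = ph.set_index("individual_id")
    blocks = []
    for fam in sorted(peds):
        ped = peds[fam]
        ids = [i for i in ped.order if i in ph.index]
        if not ids:
            continue
        sub = ph.loc[ids]
        Y = sub[list(traits)].to_numpy(float)
        keep = ~np.all(np.isnan(Y), axis=1)
        if not keep.any():
            continue
        ids = [i for i, k in zip(ids, keep) if k]
        sub = sub.loc[ids]
        Y = Y[keep]
        ages = {
            i: float(a)
            for i, a in zip(ids, sub["age"].to_numpy(float))
            if not np.isnan(a)
        }
        mats = relationship_matrices(ped, ages, ids=ids)
        age_col = sub["age"].to_numpy(float)
        age_col = np.where(np.isnan(age_col), mean_age, age_col)
        sex_col = (sub["sex"].astype(str) == "female").to_numpy(float)
        X = np.column_stack([np.ones(len(ids)), age_col, sex_col])
        R = {
            "A": mats.additive,
            "D": mats.dominance,
            "H": mats.household,
            "E": np.eye(len(ids)),
        }
        blocks.append(BivBlock(R=R, Y=Y, X=X, family_id=fam))
    return blocks


@dataclass
class BivariateFit:
    spec: ComponentSpec
    C: dict[str, np.ndarray]                 # component -> 2x2 covariance
    beta: np.ndarray                          # (2p,) trait-1 then trait-2 effects
    loglik: float
    n_obs: int
    converged: bool
    theta: np.ndarray | None = None
    theta_cov: np.ndarray | None = None
    boundary: dict[str, bool] = field(default_factory=dict)

    @property
    def r(self) -> dict[str, float]:
        """Cross-trait correlation of each component."""
        out = {}
        for c, M in self.C.items():
            denom = np.sqrt(M[0, 0] * M[1, 1])
            out[c] = float(M[0, 1] / denom) if denom > _RANK0_TOL**2 else float("nan")
        return out

    @property
    def r_genetic_combined(self) -> float:
        CA = self.C.get("A", np.zeros((2, 2)))
        CD = self.C.get("D", np.zeros((2, 2)))
        num = CA[0, 1] + CD[0, 1]
        den = np.sqrt((CA[0, 0] + CD[0, 0]) * (CA[1, 1] + CD[1, 1]))
        return float(num / den) if den > 0 else float("nan")

    @property
    def cov_share(self) -> dict[str, float]:
        return covariance_decomposition(self)

    @property
    def phenotypic_covariance(self) -> float:
        return float(sum(M[0, 1] for M in self.C.values()))

    @property
    def phenotypic_correlation(self) -> float:
        total = sum(self.C.values())
        return float(total[0, 1] / np.sqrt(total[0, 0] * total[1, 1]))

    def r_se(self) -> dict[str, float]:
        """Delta-method standard errors of the per-component correlations."""
        if self.theta is None or self.theta_cov is None:
            return {c: float("nan") for c in self.C}
        comps = tuple(self.spec)
        out = {}
        for c in comps:
            grad = _numeric_grad(
                lambda th: _corr_of(_theta_to_C(th, comps)[c]), self.theta
            )
            var = float(grad @ self.theta_cov @ grad)
            out[c] = float(np.sqrt(max(var, 0.0)))
        return out

    def summary(self) -> dict:
        return {
            "model": "".join(self.spec),
            "C": {c: self.C[c].tolist() for c in self.spec},
            "r": self.r,
            "r_genetic_combined": self.r_genetic_combined,
            "cov_share": self.cov_share,
            "phenotypic_covariance": self.phenotypic_covariance,
            "phenotypic_correlation": self.phenotypic_correlation,
            "beta": list(map(float, self.beta)),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


def _corr_of(M: np.ndarray) -> float:
    denom = np.sqrt(M[0, 0] * M[1, 1])
    return float(M[0, 1] / denom) if denom > 0 else 0.0


def _numeric_grad(fn, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    g = np.zeros_like(theta)
    for i in range(theta.size):
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        g[i] = (fn(up) - fn(dn)) / (2 * h)
    return g


def covariance_decomposition(fit: BivariateFit) -> dict[str, float]:
    """Proportion of the phenotypic cross-covariance from each component."""
    total = sum(M[0, 1] for M in fit.C.values())
    if abs(total) < 1e-10:
        raise ValueError("total cross-covariance is ~0; decomposition undefined")
    return {c: float(M[0, 1] / total) for c, M in fit.C.items()}


def fit_bivariate(
    dataset: BivariateDataset,
    spec: ComponentSpec | None = None,
    n_starts: int = 2,
    compute_se: bool = True,
) -> BivariateFit:
    """ML fit of the bivariate model via Cholesky-parameterised components."""
    spec = spec or ComponentSpec(dataset.components)
    if tuple(spec) != dataset.components:
        raise ValueError("dataset components do not match requested spec")
    comps = dataset.components
    k = len(comps)
    sd = np.sqrt(dataset.var_y)

    def negll(theta):
        f, _, _ = dataset.profile_negloglik(_theta_to_C(theta, comps))
        return f

    bounds = []
    for c in comps:
        # E's diagonal factors stay strictly positive so the stacked
        # covariance is never numerically singular during optimisation
        lo = 1e-3 * sd if c == "E" else 0.0
        bounds += [(lo, 10 * sd), (-10 * sd, 10 * sd), (lo, 10 * sd)]

    starts = []
    s0 = np.tile([sd / np.sqrt(k), 0.1 * sd, sd / np.sqrt(k)], k)
    starts.append(s0)
    s1 = np.tile([0.2 * sd, 0.0, 0.2 * sd], k)
    s1[-3:] = [0.8 * sd, 0.2 * sd, 0.7 * sd]   # E-heavy start
    starts.append(s1)
    s2 = np.tile([0.3 * sd, 0.15 * sd, 0.25 * sd], k)
    starts.append(s2)

    best = None
    for start in starts[: max(n_starts, 1)]:
        res = optimize.minimize(
            negll, start, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-11},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    theta = best.x
    C = _theta_to_C(theta, comps)
    _, beta, _ = dataset.profile_negloglik(C)
    boundary = {
        c: bool(np.trace(C[c]) < _RANK0_TOL * dataset.var_y) for c in comps
    }
    theta_cov = None
    if compute_se:
        try:
            H = _numeric_hessian(negll, theta)
            theta_cov = linalg.pinvh(H)
        except (linalg.LinAlgError, FitError):
            logger.warning("bivariate Hessian failed; SEs unavailable")
    if not best.success:
        logger.warning("bivariate optimizer: %s", best.message)
    return BivariateFit(
        spec=spec,
        C=C,
        beta=beta,
        loglik=-float(best.fun),
        n_obs=dataset.n_obs,
        converged=bool(best.success),
        theta=theta,
        theta_cov=theta_cov,
        boundary=boundary,
    )


def _numeric_hessian(fn, theta: np.ndarray) -> np.ndarray:
    """Central-difference Hessian with absolute steps sized for an O(1e4)
    log-likelihood (cancellation noise stays well below the curvature)."""
    k = theta.size
    h = np.maximum(1e-3, 1e-3 * np.abs(theta))
    H = np.zeros((k, k))
    f0 = fn(theta)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                up, dn = theta.copy(), theta.copy()
                up[i] += h[i]
                dn[i] -= h[i]
                H[i, i] = (fn(up) - 2 * f0 + fn(dn)) / h[i] ** 2
            else:
                pp, pm, mp, mm = (theta.copy() for _ in range(4))
                pp[i] += h[i]; pp[j] += h[j]
                pm[i] += h[i]; pm[j] -= h[j]
                mp[i] -= h[i]; mp[j] += h[j]
                mm[i] -= h[i]; mm[j] -= h[j]
                H[i, j] = H[j, i] = (fn(pp) - fn(pm) - fn(mp) + fn(mm)) / (
                    4 * h[i] * h[j]
                )
    return H
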