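"""Univariate A/D/H/E variance-component maximum likelihood on pedigrees.

The phenotype vector of a family is modelled as multivariate normal with
mean ``X beta`` (intercept, linear age, sex contrast) and covariance

    Sigma = sigma2_A * 2Phi + sigma2_D * Delta7 + sigma2_H * Hsh + sigma2_E * I

where 2Phi, Delta7 and Hsh are the additive, dominance and household
structure matrices from :mod:`pedvar.pedigree`.  Families are independent,
so the log-likelihood is a sum of small multivariate-normal blocks.  The
fixed effects are profiled out by generalised least squares at every
variance evaluation, and the variance components are maximised by bounded
quasi-Newton with an analytic profile gradient and multiple dispersed
starts.  Standard errors come from the observed information (central
finite differences of the analytic gradient); estimates on the zero
boundary get a flagged (NaN) standard error.

Blocks that are mutually unlinked (no nonzero off-diagonal in any structure
matrix) are split apart before fitting; the likelihood is identical either
way and the small dense blocks keep every solve cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .pedigree import PedigreeGraph, RelationshipMatrices, relationship_matrices
from .scales import inverse_normal_transform

logger = logging.getLogger(__name__)

COMPONENTS = ("A", "D", "H", "E")

#: Families larger than this are split at zero-covariance cut-points (they
#: always are anyway; the cap only bounds the dense fallback).
FAMILY_SIZE_CAP = 200

_BOUNDARY_TOL = 1e-6


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class ComponentSpec:
    """Which variance components are free.  E is always present; D requires A."""

    components: tuple[str, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        unknown = set(comps) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components: {sorted(unknown)}")
        if "E" not in comps:
            raise ValueError("E (unique environment) must always be included")
        if "D" in comps and "A" not in comps:
            raise ValueError("D requires A (biometrical convention)")
        object.__setattr__(
            self, "components", tuple(c for c in COMPONENTS if c in comps)
        )

    @classmethod
    def parse(cls, text: str) -> "ComponentSpec":
        return cls(tuple(text.upper()))

    def __iter__(self):
        return iter(self.components)

    def __len__(self) -> int:
        return len(self.components)

    def __contains__(self, c: str) -> bool:
        return c in self.components


ADHE = ComponentSpec(("A", "D", "H", "E"))


def family_covariance(
    spec: ComponentSpec, sigma2: dict[str, float], mats: RelationshipMatrices
) -> np.ndarray:
    """Model covariance of one family's phenotype vector."""
    n = len(mats.ids)
    structure = {
        "A": mats.additive,
        "D": mats.dominance,
        "H": mats.household,
        "E": np.eye(n),
    }
    sigma = np.zeros((n, n))
    for c in spec:
        sigma = sigma + sigma2.get(c, 0.0) * structure[c]
    try:
        linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError:
        logger.warning("family covariance numerically non-PSD; adding 1e-10 jitter")
        sigma = sigma + 1e-10 * np.eye(n)
    return sigma


# -- dataset ---------------------------------------------------------------------


@dataclass
class Block:
    """One independent observation block: structure matrices, trait, design."""

    R: dict[str, np.ndarray]     # component -> (m, m); "E" is the identity
    y: np.ndarray                # (m,)
    X: np.ndarray                # (m, p)
    family_id: str = ""


@dataclass
class _Group:
    R: dict[str, np.ndarray]
    Y: np.ndarray                # (n, m) stacked trait vectors
    X: np.ndarray                # (n, m, p) stacked designs
    family_ids: list[str]


class Dataset:
    """Observation blocks grouped by identical structure for vectorised
    likelihood evaluation."""

    def __init__(self, blocks: list[Block], components: tuple[str, ...]):
        if not blocks:
            raise ValueError("no observation blocks")
        self.components = tuple(components)
        self.p = blocks[0].X.shape[1]
        buckets: dict[bytes, list[Block]] = {}
        for b in blocks:
            key = b"".join(
                np.round(b.R[c], 9).tobytes() for c in self.components
            ) + bytes([b.R[self.components[0]].shape[0]])
            buckets.setdefault(key, []).append(b)
        self.groups: list[_Group] = []
        for bs in buckets.values():
            self.groups.append(
                _Group(
                    R=bs[0].R,
                    Y=np.stack([b.y for b in bs]),
                    X=np.stack([b.X for b in bs]),
                    family_ids=[b.family_id for b in bs],
                )
            )
        self.n_obs = sum(g.Y.size for g in self.groups)
        self.n_blocks = len(blocks)
        self.var_y = float(np.var(np.concatenate([g.Y.ravel() for g in self.groups])))

    # -- profile likelihood ---------------------------------------------------

    def _decompose(self, sigma2: np.ndarray):
        """Per-group Cholesky factors plus whitened Y and X."""
        out = []
        for g in self.groups:
            m = g.Y.shape[1]
            S = sum(s * g.R[c] for s, c in zip(sigma2, self.components))
            try:
                L = linalg.cholesky(S, lower=True)
            except linalg.LinAlgError as exc:
                fam = g.family_ids[0]
                raise FitError(
                    f"singular covariance in family {fam!r} at sigma2={sigma2}"
                ) from exc
            Vw = linalg.solve_triangular(L, g.Y.T, lower=True)          # (m, n)
            n, _, p = g.X.shape
            Xmat = g.X.transpose(1, 0, 2).reshape(m, n * p)
            Uw = linalg.solve_triangular(L, Xmat, lower=True).reshape(m, n, p)
            out.append((g, L, Vw, Uw))
        return out

    def gls_beta(self, sigma2: np.ndarray):
        dec = self._decompose(sigma2)
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        for _, L, Vw, Uw in dec:
            A += np.einsum("mnp,mnq->pq", Uw, Uw)
            b += np.einsum("mnp,mn->p", Uw, Vw)
        beta = linalg.solve(A, b, assume_a="pos")
        return beta, A, dec

    def profile_negloglik(self, sigma2: np.ndarray, grad: bool = False):
        """Negative log-likelihood with the fixed effects profiled out, and
        (optionally) its analytic gradient in the variance components."""
        beta, _, dec = self.gls_beta(sigma2)
        negll = 0.5 * self.n_obs * np.log(2.0 * np.pi)
        g_out = np.zeros(len(self.components))
        for g, L, Vw, Uw in dec:
            n, m = g.Y.shape
            E = Vw - np.einsum("mnp,p->mn", Uw, beta)   # whitened residuals
            negll += n * np.sum(np.log(np.diag(L))) + 0.5 * np.sum(E * E)
            if grad:
                Sinv = linalg.cho_solve((L, True), np.eye(m))
                U = linalg.solve_triangular(L.T, E, lower=False)  # Sigma^-1 r
                for k, c in enumerate(self.components):
                    Rc = g.R[c]
                    tr = n * np.sum(Sinv * Rc)
                    quad = np.einsum("in,ij,jn->", U, Rc, U)
                    g_out[k] += 0.5 * (tr - quad)
        if grad:
            return float(negll), g_out
        return float(negll)

    def restrict(self, spec: "ComponentSpec") -> "Dataset":
        """View of this dataset with a subset of the variance components."""
        comps = tuple(spec)
        if not set(comps) <= set(self.components):
            raise ValueError(f"components {comps} not all present in dataset")
        new = object.__new__(Dataset)
        new.components = comps
        new.p = self.p
        new.groups = [
            _Group(
                R={c: g.R[c] for c in comps},
                Y=g.Y,
                X=g.X,
                family_ids=g.family_ids,
            )
            for g in self.groups
        ]
        new.n_obs = self.n_obs
        new.n_blocks = self.n_blocks
        new.var_y = self.var_y
        return new

    def loglik(self, sigma2: dict[str, float], beta: np.ndarray | None = None) -> float:
        """Log-likelihood at given variance components (beta profiled when
        not supplied)."""
        vec = np.array([sigma2.get(c, 0.0) for c in self.components])
        if beta is None:
            return -self.profile_negloglik(vec)
        beta = np.asarray(beta, float)
        dec = self._decompose(vec)
        ll = -0.5 * self.n_obs * np.log(2.0 * np.pi)
        for g, L, Vw, Uw in dec:
            n = g.Y.shape[0]
            E = Vw - np.einsum("mnp,p->mn", Uw, beta)
            ll -= n * np.sum(np.log(np.diag(L))) + 0.5 * np.sum(E * E)
        return float(ll)


def _split_components(R: dict[str, np.ndarray]) -> list[np.ndarray]:
    """Indices of connected components of the combined nonzero pattern."""
    total = sum(np.abs(M) for M in R.values())
    m = total.shape[0]
    adj = total > 1e-12
    seen = np.zeros(m, bool)
    comps = []
    for s in range(m):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            nxt = np.where(adj[v] & ~seen)[0]
            seen[nxt] = True
            stack.extend(nxt.tolist())
        comps.append(np.array(sorted(comp)))
    return comps


def blocks_from_matrices(
    mats: RelationshipMatrices,
    y: np.ndarray,
    X: np.ndarray,
    family_id: str = "",
    components: tuple[str, ...] = COMPONENTS,
) -> list[Block]:
    """Turn one family's matrices + data into independent blocks, dropping
    missing trait entries (scalar-level deletion) and splitting unlinked
    subsets."""
    obs = np.where(~np.isnan(y))[0]
    if obs.size == 0:
        return []
    full = {
        "A": mats.additive,
        "D": mats.dominance,
        "H": mats.household,
        "E": np.eye(len(mats.ids)),
    }
    R = {c: full[c][np.ix_(obs, obs)] for c in components}
    linking = {c: R[c] for c in components if c != "E"}
    if linking:
        comps_ix = _split_components(linking)
    else:
        comps_ix = [np.array([i]) for i in range(obs.size)]
    blocks = []
    for comp in comps_ix:
        ix = np.ix_(comp, comp)
        blocks.append(
            Block(
                R={c: np.ascontiguousarray(R[c][ix]) for c in components},
                y=y[obs][comp],
                X=X[obs][comp],
                family_id=family_id,
            )
        )
    return blocks


def build_dataset(
    peds: dict[str, PedigreeGraph],
    phenos: pd.DataFrame,
    trait: str,
    transform: bool = False,
    spec: ComponentSpec = ADHE,
) -> Dataset:
    """Assemble a fitting dataset from pedigrees and a phenotype table.

    ``phenos`` needs columns individual_id, <trait>, age, sex.  Missing
    traits are dropped inside families; missing ages are imputed with the
    sample mean (for both the age covariate and the household rule the
    individual then counts as adult).
    """
    ph = phenos.copy()
    ph["individual_id"] = ph["individual_id"].astype(str)
    if transform:
        ph[trait] = inverse_normal_transform(ph[trait].to_numpy(float))
    mean_age = float(np.nanmean(ph["age"].to_numpy(float)))
    ph = ph.set_index("individual_id")
    blocks: list[Block] = []
    comps = tuple(spec)
    for fam in sorted(peds):
        ped = peds[fam]
        ids = [i for i in ped.order if i in ph.index]
        if not ids:
            continue
        sub = ph.loc[ids]
        ages = {
            i: float(a)
            for i, a in zip(ids, sub["age"].to_numpy(float))
            if not np.isnan(a)
        }
        mats = relationship_matrices(ped, ages, ids=ids)
        y = sub[trait].to_numpy(float)
        age_col = sub["age"].to_numpy(float)
        age_col = np.where(np.isnan(age_col), mean_age, age_col)
        sex_col = (sub["sex"].astype(str) == "female").to_numpy(float)
        X = np.column_stack([np.ones(len(ids)), age_col, sex_col])
        blocks.extend(blocks_from_matrices(mats, y, X, fam, comps))
    return Dataset(blocks, comps)


# -- fitting ---------------------------------------------------------------------


@dataclass
class UnivariateFit:
    spec: ComponentSpec
    sigma2: dict[str, float]
    se: dict[str, float]
    beta: np.ndarray
    beta_se: np.ndarray
    loglik: float
    n_obs: int
    converged: bool
    vcov: np.ndarray | None = None          # covariance of component estimates
    boundary: dict[str, bool] = field(default_factory=dict)
    message: str = ""

    @property
    def total_variance(self) -> float:
        return float(sum(self.sigma2.values()))

    @property
    def broad_h2(self) -> float:
        return broad_sense_h2(self)[0]

    def summary(self) -> dict:
        h2, h2_se = broad_sense_h2(self)
        return {
            "model": "".join(self.spec),
            "sigma2": {c: self.sigma2[c] for c in self.spec},
            "se": {c: self.se[c] for c in self.spec},
            "beta": list(map(float, self.beta)),
            "beta_se": list(map(float, self.beta_se)),
            "loglik": self.loglik,
            "total_variance": self.total_variance,
            "broad_h2": h2,
            "broad_h2_se": h2_se,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


def _starts(var_y: float, k: int) -> list[np.ndarray]:
    """Dispersed starting points on the variance scale."""
    eq = np.full(k, var_y / k)
    e_heavy = np.full(k, 0.05 * var_y)
    e_heavy[-1] = 0.8 * var_y
    a_heavy = np.full(k, 0.1 * var_y)
    a_heavy[0] = 0.6 * var_y
    return [eq, e_heavy, a_heavy]


def fit_univariate(
    dataset: Dataset,
    spec: ComponentSpec | None = None,
    n_starts: int = 3,
    compute_se: bool = True,
) -> UnivariateFit:
    """Maximum-likelihood A/D/H/E fit with non-negativity bounds.

    Runs ``n_starts`` dispersed starts of bounded L-BFGS-B (analytic
    gradient) and keeps the best likelihood.  Components whose estimate sits
    on the zero bound are flagged and their standard error reported as NaN.
    """
    spec = spec or ComponentSpec(dataset.components)
    if tuple(spec) != dataset.components:
        dataset = dataset.restrict(spec)
    k = len(dataset.components)
    var_y = dataset.var_y
    bounds = [(0.0, 20.0 * var_y)] * k
    bounds[-1] = (1e-8 * var_y, 20.0 * var_y)  # E strictly positive

    def obj(theta):
        f, g = dataset.profile_negloglik(theta, grad=True)
        return f, g

    best = None
    for start in _starts(var_y, k)[: max(n_starts, 1)]:
        res = optimize.minimize(
            obj, start, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    theta = np.maximum(best.x, 0.0)
    converged = bool(best.success)
    if not converged:
        logger.warning("optimizer did not report convergence: %s", best.message)

    boundary = {
        c: theta[i] <= _BOUNDARY_TOL * max(var_y, 1e-12)
        for i, c in enumerate(dataset.components)
    }
    se = {c: np.nan for c in dataset.components}
    vcov = None
    if compute_se:
        interior = [i for i, c in enumerate(dataset.components) if not boundary[c]]
        if interior:
            H = _hessian_from_grad(dataset, theta, interior)
            try:
                cov_int = linalg.inv(H)
                vcov = np.zeros((k, k))
                for a, ia in enumerate(interior):
                    for b, ib in enumerate(interior):
                        vcov[ia, ib] = cov_int[a, b]
                diag = np.diag(vcov).copy()
                bad = diag < 0
                diag[bad] = np.nan
                for i, c in enumerate(dataset.components):
                    if not boundary[c]:
                        se[c] = float(np.sqrt(diag[i]))
            except linalg.LinAlgError:
                logger.warning("observed information singular; SEs unavailable")

    beta, A, _ = dataset.gls_beta(theta)
    beta_cov = linalg.inv(A)
    loglik = -dataset.profile_negloglik(theta)
    return UnivariateFit(
        spec=spec,
        sigma2={c: float(theta[i]) for i, c in enumerate(dataset.components)},
        se=se,
        beta=beta,
        beta_se=np.sqrt(np.diag(beta_cov)),
        loglik=float(loglik),
        n_obs=dataset.n_obs,
        converged=converged,
        vcov=vcov,
        boundary=boundary,
        message=str(best.message),
    )


def _hessian_from_grad(
    dataset: Dataset, theta: np.ndarray, interior: list[int]
) -> np.ndarray:
    """Observed information on the interior axes: central differences of the
    analytic profile gradient (relative step 1e-4)."""
    k = len(interior)
    H = np.zeros((k, k))
    for a, ia in enumerate(interior):
        h = 1e-4 * max(abs(theta[ia]), 1e-3)
        up, dn = theta.copy(), theta.copy()
        up[ia] += h
        dn[ia] = max(dn[ia] - h, 0.0)
        step = up[ia] - dn[ia]
        _, gu = dataset.profile_negloglik(up, grad=True)
        _, gd = dataset.profile_negloglik(dn, grad=True)
        H[a] = (gu[interior] - gd[interior]) / step
    return 0.5 * (H + H.T)


def broad_sense_h2(fit: UnivariateFit) -> tuple[float, float]:
    """(A + D) / total variance, with a delta-method standard error."""
    comps = list(fit.spec)
    theta = np.array([fit.sigma2[c] for c in comps])
    total = theta.sum()
    if total <= 0:
        raise ValueError("zero total variance; heritability undefined")
    gen = sum(fit.sigma2.get(c, 0.0) for c in ("A", "D"))
    h2 = gen / total
    if fit.vcov is None:
        return float(h2), float("nan")
    grad = np.array(
        [((total - gen) if c in ("A", "D") else -gen) / total**2 for c in comps]
    )
    var = float(grad @ fit.vcov @ grad)
    return float(h2), float(np.sqrt(max(var, 0.0)))


@dataclass
class LRTResult:
    chi2: float
    delta_df: int
    p_value: float
    p_value_mixture: float | None = None


def likelihood_ratio_test(
    full_loglik: float,
    reduced_loglik: float,
    delta_df: int,
    mixture: bool = False,
) -> LRTResult:
    """-2 (LL_reduced - LL_full) against a central chi-square.

    ``mixture=True`` additionally reports the 50:50 chi2(0):chi2(1) mixture
    p-value appropriate when a single variance component is tested on its
    zero boundary.
    """
    chi2 = -2.0 * (reduced_loglik - full_loglik)
    if chi2 < -1e-6:
        raise FitError(
            f"reduced model fits better than full (chi2={chi2:.3g}); "
            "optimization failure"
        )
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, delta_df)) if delta_df > 0 else float(chi2 == 0.0)
    p_mix = None
    if mixture and delta_df == 1:
        p_mix = float(0.5 * stats.chi2.sf(chi2, 1) + (0.5 if chi2 <= 0 else 0.0))
    return LRTResult(float(chi2), int(delta_df), p, p_mix)


def compare_fits(full: UnivariateFit, reduced: UnivariateFit, **kw) -> LRTResult:
    if not set(reduced.spec.components) < set(full.spec.components):
        raise ValueError("reduced spec must be a strict subset of the full spec")
    ddf = len(full.spec) - len(reduced.spec)
    return likelihood_ratio_test(full.loglik, reduced.loglik, ddf, **kw)
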