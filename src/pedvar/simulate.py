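"""Synthetic extended twin-family data with known A/D/H/E architecture.

The generator emulates the composition of a large twin-register sample:
families drawn from a mix of templates (twin pairs with or without their
parents, non-twin sibs, twins with spouses and offspring, half-sib
households), with role-specific ages (twins centred on 28.3 years, parents
on 55.8).  Phenotypes are drawn per family from the generative model

    y = X beta + sum_c  L_c z_c,   cov = sum_c sigma2_c * R_c

with R_c the family's additive / dominance / household / identity
structure matrix, so every downstream module (correlations, univariate and
bivariate fits) can be tested against known truth.  Two traits (na, si)
are simulated jointly with per-component cross-trait correlations.

Default true parameters are the full-model estimates of the study this
package reanalyses (NA: A=0.11, D=0.28, H=0.066, E=0.34; SI: A=0.099,
D=0.32, H=0.066, E=0.36; component correlations 0.57/0.69/0.94/0.26), so
recovery experiments probe exactly that regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg

from .pedigree import (
    IndividualRecord,
    PedigreeGraph,
    household_matrix,
    relationship_matrices,
)
from .varcomp import (
    Block,
    ComponentSpec,
    Dataset,
    ADHE,
    blocks_from_matrices,
    fit_univariate,
)
from .bivariate import BivBlock, BivariateDataset

SURVEY_YEAR = 2000

#: Template mix calibrated to the published sample composition (about 24%
#: MZ individuals, 29% DZ, 23% parents, 15% non-twin sibs, mean 2.7
#: phenotyped members per family).
NTR_TEMPLATE_WEIGHTS: dict[str, float] = {
    "mz_pair": 0.224,
    "dz_pair": 0.287,
    "mz_nuclear": 0.061,
    "dz_nuclear": 0.061,
    "mz_nuclear_sib": 0.031,
    "dz_nuclear_sib": 0.031,
    "mz_spouses": 0.026,
    "dz_spouses": 0.028,
    "sib_pair": 0.105,
    "sib_parents": 0.142,
    "half_sibs": 0.004,
}


@dataclass
class SimulationConfig:
    """Study conditions for the generator.  Defaults are the published
    regime; see the module docstring."""

    n_families: int = 1000
    template_weights: dict[str, float] = field(
        default_factory=lambda: dict(NTR_TEMPLATE_WEIGHTS)
    )
    # trait architecture: per-trait variances and cross-trait correlations
    sigma2: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "na": {"A": 0.11, "D": 0.28, "H": 0.066, "E": 0.34},
            "si": {"A": 0.099, "D": 0.32, "H": 0.066, "E": 0.36},
        }
    )
    component_correlations: dict[str, float] = field(
        default_factory=lambda: {"A": 0.57, "D": 0.69, "H": 0.94, "E": 0.26}
    )
    # fixed effects (shared by both traits)
    beta_intercept: float = 0.2
    beta_age: float = -0.006       # per year
    beta_sex: float = 0.18         # female minus male contrast
    # role ages (years): mean, sd, low, high
    age_twin: tuple = (28.3, 10.0, 16.0, 70.0)
    age_twin_partnered: tuple = (45.0, 8.0, 25.0, 70.0)
    age_parent: tuple = (55.8, 8.0, 35.0, 90.0)
    age_sib: tuple = (30.0, 10.0, 16.0, 70.0)
    age_halfsib: tuple = (25.0, 8.0, 16.0, 60.0)
    offspring_age_gap: tuple = (26.0, 3.0)
    # dichotomisation: trait quantile above which both traits mean "Type D"
    prevalence: float = 0.21
    # item generation (plumbing only; loadings/thresholds are synthetic)
    item_loading: float = 0.7
    item_thresholds: tuple = (0.35, 1.45)
    item_missing_rate: float = 0.03
    n_waves: int = 2


# -- templates -------------------------------------------------------------------


@dataclass(frozen=True)
class _Member:
    mid: str
    father: str | None = None
    mother: str | None = None
    sex: str = "coin"            # male / female / coin / same:<mid> / opp:<mid>
    role: str = "sib"
    mz: str | None = None        # MZ group label within the family
    phenotyped: bool = True
    spouse_of: str | None = None
    twin: bool = False           # member of the (possibly DZ) twin pair


def _twin_family(mz: bool, n_sibs: int, parents_phenotyped: bool) -> list[_Member]:
    grp = "g1" if mz else None
    members = [
        _Member("fa", sex="male", role="parent", phenotyped=parents_phenotyped),
        _Member("mo", sex="female", role="parent", phenotyped=parents_phenotyped),
        _Member("t1", "fa", "mo", "coin", "twin", grp, twin=True),
        _Member(
            "t2", "fa", "mo", "same:t1" if mz else "coin", "twin", grp, twin=True
        ),
    ]
    for k in range(n_sibs):
        members.append(_Member(f"s{k+1}", "fa", "mo", "coin", "sib"))
    return members


def _twin_spouse_family(mz: bool) -> list[_Member]:
    grp = "g1" if mz else None
    return [
        _Member("fa", sex="male", role="parent", phenotyped=False),
        _Member("mo", sex="female", role="parent", phenotyped=False),
        _Member("t1", "fa", "mo", "coin", "twin_partnered", grp, twin=True),
        _Member(
            "t2", "fa", "mo", "same:t1" if mz else "coin",
            "twin_partnered", grp, twin=True,
        ),
        _Member("p1", sex="opp:t1", role="spouse", spouse_of="t1"),
        _Member("p2", sex="opp:t2", role="spouse", spouse_of="t2"),
        _Member("c1", "t1", "p1", "coin", "offspring"),
        _Member("c2", "t2", "p2", "coin", "offspring"),
    ]


_TEMPLATES: dict[str, list[_Member]] = {
    "mz_pair": _twin_family(True, 0, parents_phenotyped=False),
    "dz_pair": _twin_family(False, 0, parents_phenotyped=False),
    "mz_nuclear": _twin_family(True, 0, parents_phenotyped=True),
    "dz_nuclear": _twin_family(False, 0, parents_phenotyped=True),
    "mz_nuclear_sib": _twin_family(True, 1, parents_phenotyped=True),
    "dz_nuclear_sib": _twin_family(False, 1, parents_phenotyped=True),
    "mz_spouses": _twin_spouse_family(True),
    "dz_spouses": _twin_spouse_family(False),
    "sib_pair": [
        _Member("fa", sex="male", role="parent", phenotyped=False),
        _Member("mo", sex="female", role="parent", phenotyped=False),
        _Member("s1", "fa", "mo", "coin", "sib"),
        _Member("s2", "fa", "mo", "coin", "sib"),
    ],
    "sib_parents": [
        _Member("fa", sex="male", role="parent"),
        _Member("mo", sex="female", role="parent"),
        _Member("s1", "fa", "mo", "coin", "sib"),
    ],
    "half_sibs": [
        _Member("fa1", sex="male", role="parent", phenotyped=False),
        _Member("fa2", sex="male", role="parent", phenotyped=False),
        _Member("mo", sex="female", role="parent"),
        _Member("h1", "fa1", "mo", "coin", "halfsib"),
        _Member("h2", "fa2", "mo", "coin", "halfsib"),
    ],
}

def _member_sex(m: _Member, chosen: dict[str, str], rng) -> str:
    if m.sex in ("male", "female"):
        return m.sex
    if m.sex == "coin":
        return "male" if rng.random() < 0.5 else "female"
    kind, ref = m.sex.split(":")
    other = chosen[ref]
    if kind == "same":
        return other
    return "female" if other == "male" else "male"


def _draw_age(spec: tuple, rng) -> float:
    mean, sd, lo, hi = spec
    return float(np.clip(rng.normal(mean, sd), lo, hi))


@dataclass
class SimFamily:
    """One simulated family: structure, ages, and who is phenotyped."""

    family_id: str
    template: str
    ped: PedigreeGraph
    ages: dict[str, float]
    phenotyped: list[str]
    sexes: dict[str, str]


_AGE_SPECS = {
    "twin": "age_twin",
    "twin_partnered": "age_twin_partnered",
    "parent": "age_parent",
    "sib": "age_sib",
    "halfsib": "age_halfsib",
}


def _sample_roles(
    members: list[_Member], config: SimulationConfig, rng
) -> tuple[dict[str, str], dict[str, float]]:
    """Draw sexes and ages for one family (keyed by template member id)."""
    sexes: dict[str, str] = {}
    for m in members:
        sexes[m.mid] = _member_sex(m, sexes, rng)
    ages: dict[str, float] = {}
    twin_age = None
    for m in members:
        if m.role in ("twin", "twin_partnered"):
            if twin_age is None:
                twin_age = _draw_age(getattr(config, _AGE_SPECS[m.role]), rng)
            ages[m.mid] = twin_age
        elif m.role == "spouse":
            ages[m.mid] = float(np.clip(twin_age + rng.normal(2.0, 3.0), 18, 90))
        elif m.role == "offspring":
            gap_mean, gap_sd = config.offspring_age_gap
            ages[m.mid] = float(
                np.clip(twin_age - rng.normal(gap_mean, gap_sd), 14.0, 60.0)
            )
        else:
            ages[m.mid] = _draw_age(getattr(config, _AGE_SPECS[m.role]), rng)
    return sexes, ages


def _sample_family(
    template: str, family_id: str, config: SimulationConfig, rng
) -> SimFamily:
    members = _TEMPLATES[template]
    sexes, ages = _sample_roles(members, config, rng)
    prefix = f"{family_id}_"
    recs = []
    for m in members:
        recs.append(
            IndividualRecord(
                individual_id=prefix + m.mid,
                family_id=family_id,
                father_id=prefix + m.father if m.father else None,
                mother_id=prefix + m.mother if m.mother else None,
                sex=sexes[m.mid],
                birth_year=SURVEY_YEAR - round(ages[m.mid]),
                mz_group=f"{family_id}_{m.mz}" if m.mz else None,
                spouse_of=prefix + m.spouse_of if m.spouse_of else None,
            )
        )
    return SimFamily(
        family_id=family_id,
        template=template,
        ped=PedigreeGraph(recs),
        ages={prefix + k: v for k, v in ages.items()},
        phenotyped=[prefix + m.mid for m in members if m.phenotyped],
        sexes={prefix + k: v for k, v in sexes.items()},
    )


def _draw_templates(config: SimulationConfig, rng) -> list[str]:
    names = sorted(config.template_weights)
    w = np.array([config.template_weights[n] for n in names], float)
    if not np.isclose(w.sum(), 1.0, atol=1e-6):
        raise ValueError("template weights must sum to 1")
    return [names[i] for i in rng.choice(len(names), size=config.n_families, p=w / w.sum())]


def simulate_pedigrees(
    config: SimulationConfig, seed: int | np.random.Generator = 0
) -> list[SimFamily]:
    """Draw ``n_families`` families from the template mix (reproducible)."""
    rng = np.random.default_rng(seed)
    return [
        _sample_family(t, f"F{k:06d}", config, rng)
        for k, t in enumerate(_draw_templates(config, rng))
    ]


def pedigree_table(families: list[SimFamily]) -> pd.DataFrame:
    rows = []
    for fam in families:
        for iid in fam.ped.order:
            r = fam.ped.members[iid]
            rows.append(
                {
                    "family_id": r.family_id,
                    "individual_id": r.individual_id,
                    "father_id": r.father_id or "0",
                    "mother_id": r.mother_id or "0",
                    "sex": r.sex,
                    "mz_group": r.mz_group or "0",
                    "birth_year": r.birth_year,
                    "spouse_of": r.spouse_of or "0",
                }
            )
    return pd.DataFrame(rows)


# -- phenotypes ------------------------------------------------------------------


def _component_matrices(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Per-component 2x2 cross-trait covariance matrices from the config."""
    traits = list(config.sigma2)
    C = {}
    for c in ("A", "D", "H", "E"):
        v = [config.sigma2[t][c] for t in traits]
        r = config.component_correlations[c]
        C[c] = np.array(
            [
                [v[0], r * np.sqrt(v[0] * v[1])],
                [r * np.sqrt(v[0] * v[1]), v[1]],
            ]
        )
        if np.linalg.eigvalsh(C[c]).min() < -1e-10:
            raise ValueError(f"component {c}: implied 2x2 matrix not PSD")
    return C


class _TemplateCache:
    """Genetic structure matrices are fixed per template; only the household
    matrix depends on the family's ages."""

    def __init__(self):
        self._cache: dict[str, tuple] = {}

    def genetic(self, template: str) -> tuple:
        if template not in self._cache:
            fam = _sample_family(
                template, "TPL", SimulationConfig(), np.random.default_rng(0)
            )
            mats = relationship_matrices(fam.ped, {})
            suffix = [iid.split("_", 1)[1] for iid in mats.ids]
            order = {s: k for k, s in enumerate(suffix)}
            pheno_suffix = [m.mid for m in _TEMPLATES[template] if m.phenotyped]
            pidx = np.array([order[s] for s in pheno_suffix])
            self._cache[template] = (fam, mats, suffix, pidx)
        return self._cache[template]

    def structures(
        self, template: str, ages: dict[str, float]
    ) -> tuple[list[str], dict[str, np.ndarray]]:
        """Structure matrices of the phenotyped members, given this family's
        ages (keyed by template member id)."""
        tfam, tmats, suffix, pidx = self.genetic(template)
        hh = household_matrix(
            tfam.ped, {f"TPL_{s}": ages[s] for s in suffix}, ids=tmats.ids
        )
        ix = np.ix_(pidx, pidx)
        obs = [suffix[k] for k in pidx]
        R = {
            "A": tmats.additive[ix],
            "D": tmats.dominance[ix],
            "H": hh[ix],
            "E": np.eye(len(pidx)),
        }
        return obs, R


def _design(
    ids: list[str], ages: dict[str, float], sexes: dict[str, str]
) -> np.ndarray:
    age = np.array([ages[i] for i in ids])
    sex = np.array([1.0 if sexes[i] == "female" else 0.0 for i in ids])
    return np.column_stack([np.ones(len(ids)), age, sex])


def simulate_phenotypes(
    families: list[SimFamily],
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw both traits for every phenotyped member of every family.

    Returns a table with columns individual_id, family_id, na, si, naxsi,
    type_d, age, sex.  ``naxsi`` is the trait product; ``type_d`` marks
    individuals above the (1 - prevalence) quantile on both traits.
    """
    rng = np.random.default_rng(seed)
    C = _component_matrices(config)
    cache = _TemplateCache()
    beta = np.array([config.beta_intercept, config.beta_age, config.beta_sex])
    rows_id, rows_fam, Ys, ages, sexes = [], [], [], [], []
    for fam in families:
        prefix = f"{fam.family_id}_"
        ages_by_mid = {k.removeprefix(prefix): v for k, v in fam.ages.items()}
        sexes_by_mid = {k.removeprefix(prefix): v for k, v in fam.sexes.items()}
        obs, R = cache.structures(fam.template, ages_by_mid)
        m = len(obs)
        Sigma = sum(np.kron(R[c], C[c]) for c in C)
        L = linalg.cholesky(Sigma + 1e-12 * np.eye(2 * m), lower=True)
        X = _design(obs, ages_by_mid, sexes_by_mid)
        mean = X @ beta
        y = (L @ rng.standard_normal(2 * m)).reshape(m, 2) + mean[:, None]
        rows_id.extend(prefix + s for s in obs)
        rows_fam.extend([fam.family_id] * m)
        Ys.append(y)
        ages.extend(X[:, 1])
        sexes.extend("female" if s else "male" for s in X[:, 2])
    Y = np.vstack(Ys)
    df = pd.DataFrame(
        {
            "individual_id": rows_id,
            "family_id": rows_fam,
            "na": Y[:, 0],
            "si": Y[:, 1],
            "age": ages,
            "sex": sexes,
        }
    )
    df["naxsi"] = df["na"] * df["si"]
    # calibrate the per-trait quantile so the *joint* rate (both traits above
    # threshold) matches the target prevalence
    lo, hi = 0.01, 0.99
    for _ in range(40):
        q = 0.5 * (lo + hi)
        yes = (df["na"] >= df["na"].quantile(q)) & (df["si"] >= df["si"].quantile(q))
        if yes.mean() > config.prevalence:
            lo = q
        else:
            hi = q
    q = 0.5 * (lo + hi)
    df["type_d"] = np.where(
        (df["na"] >= df["na"].quantile(q)) & (df["si"] >= df["si"].quantile(q)),
        "yes",
        "no",
    )
    return df


# -- fast simulate->fit path ------------------------------------------------------


def simulate_blocks(
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
    trait: str = "na",
) -> Dataset:
    """Simulate and assemble a univariate fitting dataset in one pass.

    Identical generative model to :func:`simulate_phenotypes`, skipping the
    materialisation of per-family pedigree objects (template structure
    matrices are reused across families).
    """
    rng = np.random.default_rng(seed)
    C = _component_matrices(config)
    t_ix = list(config.sigma2).index(trait)
    cache = _TemplateCache()
    beta = np.array([config.beta_intercept, config.beta_age, config.beta_sex])
    templates = _draw_templates(config, rng)
    blocks: list[Block] = []
    for k, template in enumerate(templates):
        sexes, ages = _sample_roles(_TEMPLATES[template], config, rng)
        obs, R = cache.structures(template, ages)
        m = len(obs)
        Sigma = sum(np.kron(R[c], C[c]) for c in C)
        L = linalg.cholesky(Sigma + 1e-12 * np.eye(2 * m), lower=True)
        X = _design(obs, ages, sexes)
        mean = X @ beta
        y = (L @ rng.standard_normal(2 * m)).reshape(m, 2) + mean[:, None]
        blocks.append(Block(R=R, y=y[:, t_ix], X=X, family_id=f"F{k:06d}"))
    return Dataset(blocks, ("A", "D", "H", "E"))


def simulate_bivariate_blocks(
    config: SimulationConfig, seed: int | np.random.Generator = 0
) -> BivariateDataset:
    """Same as :func:`simulate_blocks` but keeping both traits."""
    rng = np.random.default_rng(seed)
    C = _component_matrices(config)
    cache = _TemplateCache()
    beta = np.array([config.beta_intercept, config.beta_age, config.beta_sex])
    templates = _draw_templates(config, rng)
    blocks: list[BivBlock] = []
    for k, template in enumerate(templates):
        sexes, ages = _sample_roles(_TEMPLATES[template], config, rng)
        obs, R = cache.structures(template, ages)
        m = len(obs)
        Sigma = sum(np.kron(R[c], C[c]) for c in C)
        L = linalg.cholesky(Sigma + 1e-12 * np.eye(2 * m), lower=True)
        X = _design(obs, ages, sexes)
        mean = X @ beta
        Y = (L @ rng.standard_normal(2 * m)).reshape(m, 2) + mean[:, None]
        blocks.append(BivBlock(R=R, Y=Y, X=X, family_id=f"F{k:06d}"))
    return BivariateDataset(blocks, ("A", "D", "H", "E"))


# -- item generation --------------------------------------------------------------


def simulate_items(
    phenos: pd.DataFrame,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Ordinal 0/1/2 item responses from the latent traits (long format).

    Six indicators per subscale: each item's latent value is
    ``loading * z + sqrt(1 - loading^2) * noise`` thresholded into three
    categories; items go missing independently at ``item_missing_rate``.
    Loadings and thresholds are synthetic placeholders used to exercise the
    scoring and imputation plumbing, not psychometric claims.
    """
    from .scales import NA_ITEM_CODES, SI_ITEM_CODES

    rng = np.random.default_rng(seed)
    lam = config.item_loading
    t1, t2 = config.item_thresholds
    rows = []
    for trait, codes in (("na", NA_ITEM_CODES), ("si", SI_ITEM_CODES)):
        z = phenos[trait].to_numpy(float)
        z = (z - np.nanmean(z)) / np.nanstd(z)
        for wave in range(1, config.n_waves + 1):
            for code in codes:
                latent = lam * z + np.sqrt(1 - lam**2) * rng.standard_normal(z.size)
                val = np.digitize(latent, [t1, t2]).astype(float)
                miss = rng.random(z.size) < config.item_missing_rate
                val[miss] = np.nan
                rows.append(
                    pd.DataFrame(
                        {
                            "individual_id": phenos["individual_id"],
                            "wave": wave,
                            "item_code": code,
                            "value": val,
                            "age_at_survey": phenos["age"],
                            "sex": phenos["sex"],
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True).sort_values(
        ["individual_id", "wave", "item_code"], kind="stable", ignore_index=True
    )


# -- recovery experiments ----------------------------------------------------------


def recovery_experiment(
    config: SimulationConfig,
    model_spec: ComponentSpec = ADHE,
    n_replicates: int = 20,
    seed: int = 0,
    trait: str = "na",
) -> pd.DataFrame:
    """Repeated simulate -> fit cycles.

    Reports, per variance component: truth, mean estimate, bias, empirical
    SD of the estimates, mean model SE, 95% CI coverage of the truth, and
    counts of boundary estimates and failed fits.
    """
    truth = config.sigma2[trait]
    root = np.random.default_rng(seed)
    est, ses, fails = [], [], 0
    for _ in range(n_replicates):
        child = root.spawn(1)[0]
        try:
            ds = simulate_blocks(config, child, trait=trait)
            fit = fit_univariate(ds, model_spec)
        except Exception:   # fit failures are counted, not fatal
            fails += 1
            continue
        est.append([fit.sigma2.get(c, np.nan) for c in model_spec])
        ses.append([fit.se.get(c, np.nan) for c in model_spec])
    est = np.array(est)
    ses = np.array(ses)
    rows = []
    for k, c in enumerate(model_spec):
        tv = truth.get(c, 0.0)
        e, s = est[:, k], ses[:, k]
        ok = ~np.isnan(s)
        cover = np.abs(e[ok] - tv) <= 1.959963984540054 * s[ok]
        rows.append(
            {
                "component": c,
                "truth": tv,
                "mean_estimate": float(np.nanmean(e)),
                "bias": float(np.nanmean(e) - tv),
                "empirical_se": float(np.nanstd(e, ddof=1)) if len(e) > 1 else np.nan,
                "mean_model_se": float(np.nanmean(s)),
                "ci95_coverage": float(cover.mean()) if ok.any() else np.nan,
                "n_boundary": int((e <= 1e-6).sum()),
                "n_replicates": int(len(e)),
                "n_failed": fails,
            }
        )
    return pd.DataFrame(rows)
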