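"""Familial correlations: pair extraction, Pearson and tetrachoric estimates,
bootstrap confidence intervals.

Symmetric relationships (twins, sibs, spouses) are double-entered — each
unordered pair contributes both orderings to the correlation — which makes
the estimate invariant to which member is listed first.  Asymmetric
relationships keep a fixed role order (parent first; grandparent first).

For the dichotomous Type D trait the familial resemblance is summarised by
the tetrachoric correlation: the correlation of a latent bivariate normal
whose double dichotomisation at per-margin thresholds reproduces the
observed 2x2 table.  The estimator is two-step, thresholds fixed at the
marginal normal quantiles and the correlation maximising the multinomial
likelihood of the four cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import PedigreeGraph, classify_pair

#: Relationships whose members are exchangeable, hence double-entered.
SYMMETRIC_RELATIONSHIPS = {
    "MZ", "DZ", "sib", "half-sib", "first-cousin", "first-cousin-MZ-parents",
    "double-first-cousin", "spouse",
}


@dataclass
class PairSet:
    """Complete trait-value pairs for one relationship/sex stratum."""

    relationship: str
    sex_stratum: str
    pairs: np.ndarray            # (n, 2) unique unordered pairs, fixed role order
    mean_age_role1: float | None = None
    mean_age_role2: float | None = None
    double_entry: bool = False

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def entered(self) -> np.ndarray:
        """Rows used for correlation: both orderings when double-entered."""
        if self.double_entry and len(self.pairs):
            return np.vstack([self.pairs, self.pairs[:, ::-1]])
        return self.pairs


def _sex_match(stratum: str, sex_i: str, sex_j: str) -> bool:
    if stratum in ("all", None):
        return True
    if stratum == "male":
        return sex_i == "male" and sex_j == "male"
    if stratum == "female":
        return sex_i == "female" and sex_j == "female"
    if stratum == "opposite":
        return sex_i != sex_j
    raise ValueError(f"unknown sex stratum {stratum!r}")


def extract_pairs(
    peds: dict[str, PedigreeGraph],
    phenos: pd.DataFrame,
    relationship: str,
    sex_stratum: str = "all",
    measure: str = "na",
    spouse_group: str | None = None,
) -> PairSet:
    """Collect complete pairs of ``measure`` values for one relationship.

    ``relationship`` may be a specific label (``"MZ"``, ``"father-son"``, ...)
    or a family: ``"parent-offspring"`` matches the four sexed labels, and
    ``"twin"`` matches MZ and DZ.  Spouse pairs can be split into
    ``spouse_group="parents-of-twins"`` (both members have offspring in the
    pedigree) versus ``"twin-spouse"`` (a twin and their partner).
    Asymmetric relationships enter in fixed role order: parent (or
    grandparent, or aunt/uncle) first.
    """
    values = phenos.set_index("individual_id")[measure]
    ages = (
        phenos.set_index("individual_id")["age"]
        if "age" in phenos.columns
        else pd.Series(dtype=float)
    )
    wanted = _expand_relationship(relationship)
    rows, a1, a2 = [], [], []
    for fam in sorted(peds):
        ped = peds[fam]
        ids = [i for i in ped.order if i in values.index]
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                i, j = ids[x], ids[y]
                label = classify_pair(ped, i, j)
                if label not in wanted:
                    continue
                if label == "spouse" and spouse_group is not None:
                    if _spouse_group(ped, i, j) != spouse_group:
                        continue
                i, j = _role_order(ped, i, j, label)
                si, sj = ped.members[i].sex, ped.members[j].sex
                if not _sex_match(sex_stratum, si, sj):
                    continue
                vi, vj = values.get(i), values.get(j)
                if vi is None or vj is None or pd.isna(vi) or pd.isna(vj):
                    continue
                rows.append((float(vi), float(vj)))
                a1.append(ages.get(i, np.nan))
                a2.append(ages.get(j, np.nan))
    arr = np.asarray(rows, dtype=float).reshape(-1, 2)
    symmetric = all(lbl in SYMMETRIC_RELATIONSHIPS for lbl in wanted)
    return PairSet(
        relationship=relationship,
        sex_stratum=sex_stratum,
        pairs=arr,
        mean_age_role1=float(np.nanmean(a1)) if rows else None,
        mean_age_role2=float(np.nanmean(a2)) if rows else None,
        double_entry=symmetric,
    )


def _expand_relationship(relationship: str) -> set[str]:
    if relationship == "parent-offspring":
        return {"father-son", "father-daughter", "mother-son", "mother-daughter"}
    if relationship == "twin":
        return {"MZ", "DZ"}
    return {relationship}


def _role_order(ped: PedigreeGraph, i: str, j: str, label: str) -> tuple[str, str]:
    if label in SYMMETRIC_RELATIONSHIPS:
        return i, j
    if label in ("father-son", "father-daughter", "mother-son", "mother-daughter"):
        # parent first
        if ped.members[j].father_id == i or ped.members[j].mother_id == i:
            return i, j
        return j, i
    if label in ("grandparental", "avuncular"):
        # elder generation first
        if ped.depth(i) <= ped.depth(j):
            return i, j
        return j, i
    return i, j


def _spouse_group(ped: PedigreeGraph, i: str, j: str) -> str:
    is_twin = lambda iid: ped.members[iid].mz_group is not None or any(
        classify_pair(ped, iid, o) == "DZ" for o in ped.members if o != iid
    )
    if is_twin(i) or is_twin(j):
        return "twin-spouse"
    return "parents-of-twins"


def pearson_correlation(pairs: PairSet | np.ndarray) -> float:
    """Product-moment correlation over the (double-entered) pair rows."""
    rows = pairs.entered() if isinstance(pairs, PairSet) else np.asarray(pairs, float)
    if len(rows) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(rows[:, 0]) == 0 or np.ptp(rows[:, 1]) == 0:
        warnings.warn("zero variance in one pair role; correlation undefined")
        return np.nan
    return float(np.corrcoef(rows[:, 0], rows[:, 1])[0, 1])


@dataclass
class TetrachoricResult:
    rho: float
    threshold_row: float
    threshold_col: float
    boundary: bool = False


def _binorm_cdf(h: float, k: float, rho: float) -> float:
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([h, k]))


def tetrachoric_loglik(table: np.ndarray, rho: float, h: float, k: float) -> float:
    """Multinomial log-likelihood of the 2x2 table under a latent bivariate
    normal dichotomised at thresholds (h, k); cell [0,0] is (below, below)."""
    p00 = _binorm_cdf(h, k, rho)
    p0_ = stats.norm.cdf(h)
    p_0 = stats.norm.cdf(k)
    p01 = p0_ - p00
    p10 = p_0 - p00
    p11 = 1.0 - p0_ - p_0 + p00
    probs = np.array([[p00, p01], [p10, p11]])
    probs = np.clip(probs, 1e-300, None)
    return float(np.sum(np.asarray(table) * np.log(probs)))


def tetrachoric_correlation(table) -> TetrachoricResult:
    """Two-step tetrachoric estimate from a 2x2 count table.

    Thresholds are fixed at the marginal normal quantiles; the correlation
    maximises the multinomial rectangle-integral likelihood.  Tables with an
    empty margin are undefined; an empty off-diagonal (or diagonal) with the
    rest filled drives the estimate to the +/-1 boundary, reported with a
    flag.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be a non-negative 2x2 count matrix")
    n = table.sum()
    row0, col0 = table[0].sum(), table[:, 0].sum()
    if row0 in (0, n) or col0 in (0, n):
        raise ValueError("tetrachoric correlation undefined: empty margin")
    h = stats.norm.ppf(row0 / n)
    k = stats.norm.ppf(col0 / n)
    if table[0, 1] == 0 and table[1, 0] == 0:
        return TetrachoricResult(1.0, h, k, boundary=True)
    if table[0, 0] == 0 and table[1, 1] == 0:
        return TetrachoricResult(-1.0, h, k, boundary=True)
    res = optimize.minimize_scalar(
        lambda r: -tetrachoric_loglik(table, r, h, k),
        bounds=(-0.999, 0.999),
        method="bounded",
        options={"xatol": 1e-7},
    )
    rho = float(res.x)
    return TetrachoricResult(rho, h, k, boundary=abs(rho) > 0.995)


def bootstrap_ci(
    pairs: PairSet | np.ndarray,
    statistic=pearson_correlation,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval, resampling unordered pairs.

    Pairs (not individuals) are resampled with replacement; double-entry, if
    any, is re-applied inside each resample.  Degenerate resamples (zero
    variance) are skipped with a warning and do not contribute.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    if isinstance(pairs, PairSet):
        base, de = pairs.pairs, pairs.double_entry
    else:
        base, de = np.asarray(pairs, float), False
    n = len(base)
    rng = np.random.default_rng(seed)
    vals = []
    n_skipped = 0
    for _ in range(n_boot):
        sample = base[rng.integers(0, n, size=n)]
        ps = PairSet("boot", "all", sample, double_entry=de)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                v = statistic(ps)
            except (ValueError, ZeroDivisionError):
                v = np.nan
        if np.isnan(v):
            n_skipped += 1
            continue
        vals.append(v)
    if n_skipped:
        warnings.warn(f"{n_skipped} degenerate bootstrap resamples skipped")
    if not vals:
        raise ValueError("all bootstrap resamples degenerate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def correlation_table(
    peds: dict[str, PedigreeGraph],
    phenos: pd.DataFrame,
    measures: tuple[str, ...] = ("na", "si", "naxsi"),
    strata: tuple[tuple[str, str], ...] = (
        ("MZ", "all"), ("MZ", "male"), ("MZ", "female"),
        ("DZ", "all"), ("DZ", "male"), ("DZ", "female"), ("DZ", "opposite"),
        ("sib", "all"),
        ("father-son", "all"), ("father-daughter", "all"),
        ("mother-son", "all"), ("mother-daughter", "all"),
    ),
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble a familial-correlation summary table with bootstrap CIs."""
    rows = []
    for measure in measures:
        for rel, sex in strata:
            ps = extract_pairs(peds, phenos, rel, sex, measure)
            if ps.n_pairs < 3:
                continue
            r = pearson_correlation(ps)
            lo, hi = bootstrap_ci(ps, n_boot=n_boot, seed=seed)
            rows.append(
                {
                    "measure": measure,
                    "relationship": rel,
                    "sex": sex,
                    "n_pairs": ps.n_pairs,
                    "mean_age_1": ps.mean_age_role1,
                    "mean_age_2": ps.mean_age_role2,
                    "correlation": r,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return pd.DataFrame(rows)
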