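"""Pedigree graphs and relationship-structure matrices.

An extended twin pedigree is a set of individuals with parent links, an
optional monozygotic (MZ) group label marking genetically identical
multiples, and an optional declared spouse link.  From the graph we derive,
for every pair of members,

* the kinship coefficient ``phi`` (probability that one allele drawn at
  random from each individual is identical by descent), whose doubled value
  ``2*phi`` scales the additive genetic variance shared by the pair;
* the fraternity (dominance) coefficient ``Delta7`` (probability that the
  pair shares *both* alleles identical by descent), which scales the shared
  dominance variance; and
* a household-sharing indicator built from the rule that spouses, and
  parents with their offspring up to age 18, co-reside.

MZ multiples are handled by collapsing each MZ group onto a single genotype
node before running the classic recursive kinship algorithm, which makes
group members exact genetic copies in every derived coefficient.

Founders are assumed unrelated and non-inbred.  The two-term fraternity
formula used here assumes non-inbreeding; pedigrees that violate this are
flagged with a warning rather than modelled.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Age (years, inclusive) up to which offspring share their parents' household.
HOUSEHOLD_CHILD_AGE = 18

#: Tokens treated as "no value" in pedigree CSV columns.
NULL_TOKENS = {"", "0", "NA", "nan", "None", None}


class PedigreeError(ValueError):
    """Raised when a pedigree fails validation (cycles, duplicates, ...)."""


@dataclass(frozen=True)
class IndividualRecord:
    """One pedigree member.

    ``mz_group`` links genetically identical multiples; all members of one
    group must share both parents.  ``spouse_of`` is an optional declared
    partner link (partners are also inferred from shared offspring).
    """

    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "female"
    birth_year: int | None = None
    mz_group: str | None = None
    spouse_of: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise PedigreeError(
                f"individual {self.individual_id!r}: sex must be 'male' or "
                f"'female', got {self.sex!r}"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class PedigreeGraph:
    """A validated pedigree: individuals with parent links, founders first.

    Validation repairs single-parent records by inserting a placeholder
    founder (logged), rejects duplicate ids, parentage cycles, and MZ groups
    whose members do not share both parents.
    """

    def __init__(self, records: Iterable[IndividualRecord]):
        self.members: dict[str, IndividualRecord] = {}
        for rec in records:
            if rec.individual_id in self.members:
                raise PedigreeError(f"duplicate individual_id {rec.individual_id!r}")
            self.members[rec.individual_id] = rec
        self._repair_parents()
        self.order: list[str] = self._toposort()
        self._depth = self._depths()
        self._check_mz_groups()
        self._rep = self._genotype_reps()
        self._kin_cache: dict[tuple[str, str], float] = {}

    # -- construction helpers -------------------------------------------------

    def _repair_parents(self) -> None:
        """Insert placeholder founders for half-specified or missing parents."""
        placeholders: dict[str, IndividualRecord] = {}
        updated: dict[str, IndividualRecord] = {}
        counter = 0
        for iid, rec in self.members.items():
            father, mother = rec.father_id, rec.mother_id
            if (father is None) != (mother is None):
                counter += 1
                new_id = f"_ph{counter}_{iid}"
                missing_sex = "male" if father is None else "female"
                placeholders[new_id] = IndividualRecord(
                    individual_id=new_id, family_id=rec.family_id, sex=missing_sex
                )
                logger.warning(
                    "individual %s has a single known parent; inserted placeholder "
                    "founder %s", iid, new_id,
                )
                if father is None:
                    updated[iid] = replace(rec, father_id=new_id)
                else:
                    updated[iid] = replace(rec, mother_id=new_id)
        self.members.update(updated)
        self.members.update(placeholders)
        # referenced parents without their own row also become founders
        missing: dict[str, IndividualRecord] = {}
        for rec in self.members.values():
            for pid, sex in ((rec.father_id, "male"), (rec.mother_id, "female")):
                if pid is not None and pid not in self.members and pid not in missing:
                    missing[pid] = IndividualRecord(
                        individual_id=pid, family_id=rec.family_id, sex=sex
                    )
                    logger.warning(
                        "parent %s referenced but not listed; added as founder", pid
                    )
        self.members.update(missing)

    def _toposort(self) -> list[str]:
        """Kahn topological sort, founders first; raises on parentage cycles."""
        n_parents = {
            iid: sum(p is not None for p in (r.father_id, r.mother_id))
            for iid, r in self.members.items()
        }
        children: dict[str, list[str]] = {iid: [] for iid in self.members}
        for iid, rec in self.members.items():
            for pid in (rec.father_id, rec.mother_id):
                if pid is not None:
                    children[pid].append(iid)
        queue = sorted(iid for iid, n in n_parents.items() if n == 0)
        order: list[str] = []
        while queue:
            iid = queue.pop(0)
            order.append(iid)
            for child in children[iid]:
                n_parents[child] -= 1
                if n_parents[child] == 0:
                    queue.append(child)
        if len(order) != len(self.members):
            cycle = sorted(set(self.members) - set(order))
            raise PedigreeError(f"parentage cycle involving individuals: {cycle}")
        return order

    def _depths(self) -> dict[str, int]:
        depth: dict[str, int] = {}
        for iid in self.order:
            rec = self.members[iid]
            if rec.is_founder:
                depth[iid] = 0
            else:
                depth[iid] = 1 + max(depth[rec.father_id], depth[rec.mother_id])
        return depth

    def _check_mz_groups(self) -> None:
        groups: dict[str, list[IndividualRecord]] = {}
        for rec in self.members.values():
            if rec.mz_group is not None:
                groups.setdefault(rec.mz_group, []).append(rec)
        for label, recs in groups.items():
            parents = {(r.father_id, r.mother_id) for r in recs}
            if len(parents) > 1:
                raise PedigreeError(
                    f"mz_group {label!r} members do not share both parents: {parents}"
                )

    def _genotype_reps(self) -> dict[str, str]:
        """Map each individual to the canonical member of its MZ group."""
        rep: dict[str, str] = {}
        groups: dict[str, list[str]] = {}
        for iid, rec in self.members.items():
            if rec.mz_group is not None:
                groups.setdefault(rec.mz_group, []).append(iid)
        for label, ids in groups.items():
            canon = min(ids)
            for iid in ids:
                rep[iid] = canon
        for iid in self.members:
            rep.setdefault(iid, iid)
        return rep

    # -- basic queries ---------------------------------------------------------

    def __contains__(self, iid: str) -> bool:
        return iid in self.members

    def __len__(self) -> int:
        return len(self.members)

    @property
    def founders(self) -> list[str]:
        return [iid for iid in self.order if self.members[iid].is_founder]

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        rec = self.members[iid]
        return rec.father_id, rec.mother_id

    def depth(self, iid: str) -> int:
        return self._depth[iid]

    def same_mz_group(self, i: str, j: str) -> bool:
        gi = self.members[i].mz_group
        return gi is not None and gi == self.members[j].mz_group

    def spouse_pairs(self) -> set[frozenset[str]]:
        """Partner pairs: declared spouse links plus pairs with shared offspring."""
        pairs: set[frozenset[str]] = set()
        for iid, rec in self.members.items():
            if rec.spouse_of is not None and rec.spouse_of in self.members:
                pairs.add(frozenset((iid, rec.spouse_of)))
            if not rec.is_founder:
                pairs.add(frozenset((rec.father_id, rec.mother_id)))
        return {p for p in pairs if len(p) == 2}

    def full_sibs(self, i: str, j: str) -> bool:
        """Share both literal parent ids (MZ co-parents count as distinct)."""
        ri, rj = self.members[i], self.members[j]
        return (
            not ri.is_founder
            and ri.father_id == rj.father_id
            and ri.mother_id == rj.mother_id
        )

    def half_sibs(self, i: str, j: str) -> bool:
        ri, rj = self.members[i], self.members[j]
        shared = int(ri.father_id is not None and ri.father_id == rj.father_id) + int(
            ri.mother_id is not None and ri.mother_id == rj.mother_id
        )
        return shared == 1


# -- kinship / dominance ------------------------------------------------------


def kinship(ped: PedigreeGraph, i: str, j: str) -> float:
    """Kinship coefficient phi(i, j) by the classic recursion on the
    MZ-collapsed genotype graph.

    phi(i, i) = (1 + phi(father, mother)) / 2; for i a non-ancestor of j,
    phi(i, j) = (phi(father_i, j) + phi(mother_i, j)) / 2; distinct founders
    are unrelated.  Members of one MZ group are the same genotype node, so
    their mutual kinship equals the self-kinship (0.5 when non-inbred).
    """
    if i not in ped or j not in ped:
        raise KeyError(f"individual not in pedigree: {i if i not in ped else j}")
    return _kin(ped, ped._rep[i], ped._rep[j])


def _kin(ped: PedigreeGraph, a: str, b: str) -> float:
    if a > b:
        a, b = b, a
    key = (a, b)
    cached = ped._kin_cache.get(key)
    if cached is not None:
        return cached
    ra = ped.members[a]
    if a == b:
        if ra.is_founder:
            val = 0.5
        else:
            val = 0.5 * (1.0 + _kin(ped, ped._rep[ra.father_id], ped._rep[ra.mother_id]))
    else:
        # recurse on the deeper individual so the other is never its descendant
        if ped.depth(a) < ped.depth(b):
            a2, b2 = b, a
        else:
            a2, b2 = a, b
        ra2 = ped.members[a2]
        if ra2.is_founder:
            val = 0.0
        else:
            val = 0.5 * (
                _kin(ped, ped._rep[ra2.father_id], b2)
                + _kin(ped, ped._rep[ra2.mother_id], b2)
            )
    ped._kin_cache[key] = val
    return val


def inbreeding_coefficient(ped: PedigreeGraph, i: str) -> float:
    rec = ped.members[i]
    if rec.is_founder:
        return 0.0
    return kinship(ped, rec.father_id, rec.mother_id)


def dominance_coefficient(ped: PedigreeGraph, i: str, j: str) -> float:
    """Fraternity coefficient Delta7(i, j): probability the pair shares both
    alleles identical by descent.

    Uses the non-inbred two-term identity
    ``Delta7 = phi(m_i, m_j) phi(f_i, f_j) + phi(m_i, f_j) phi(f_i, m_j)``
    with parents taken on the MZ-collapsed graph; MZ co-members (and an
    individual with itself) have Delta7 = 1; a pair involving a founder's
    unknown parents has Delta7 = 0.  Warns when inbreeding is detected,
    since the two-term formula then no longer holds.
    """
    if i not in ped or j not in ped:
        raise KeyError(f"individual not in pedigree: {i if i not in ped else j}")
    if ped._rep[i] == ped._rep[j]:
        return 1.0
    for k in (i, j):
        if inbreeding_coefficient(ped, k) > 0:
            warnings.warn(
                f"individual {k} is inbred; the two-term fraternity formula "
                "assumes non-inbreeding", stacklevel=2,
            )
    ri, rj = ped.members[i], ped.members[j]
    if ri.is_founder or rj.is_founder:
        return 0.0
    fi, mi = ped._rep[ri.father_id], ped._rep[ri.mother_id]
    fj, mj = ped._rep[rj.father_id], ped._rep[rj.mother_id]
    return _kin(ped, mi, mj) * _kin(ped, fi, fj) + _kin(ped, mi, fj) * _kin(
        ped, fi, mj
    )


# -- households ----------------------------------------------------------------


def household_groups(
    ped: PedigreeGraph, ages: Mapping[str, float] | None = None
) -> list[set[str]]:
    """Partition members into household groups.

    Each spouse pair forms a group; offspring aged <= 18 join their parents'
    group; an individual who has a spouse group of their own stays there
    (spouse group takes precedence over the parental one).  Everyone else is
    a singleton.  Missing age means adult, which conservatively avoids
    spurious household sharing.
    """
    ages = ages or {}
    parent: dict[str, str] = {iid: iid for iid in ped.members}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    partnered: set[str] = set()
    for pair in ped.spouse_pairs():
        a, b = sorted(pair)
        union(a, b)
        partnered.update(pair)

    for iid, rec in ped.members.items():
        if rec.is_founder:
            continue
        if iid in partnered:
            continue  # own spouse group wins over the parental household
        age = ages.get(iid)
        if age is None:
            logger.debug("no age for %s; treated as adult for households", iid)
            continue
        if age <= HOUSEHOLD_CHILD_AGE:
            union(rec.father_id, iid)

    groups: dict[str, set[str]] = {}
    for iid in ped.members:
        groups.setdefault(find(iid), set()).add(iid)
    return list(groups.values())


def household_matrix(
    ped: PedigreeGraph,
    ages: Mapping[str, float] | None = None,
    ids: Sequence[str] | None = None,
) -> np.ndarray:
    """0/1 indicator of household co-membership (block diagonal, unit diagonal)."""
    ids = list(ids) if ids is not None else list(ped.order)
    idx = {iid: k for k, iid in enumerate(ids)}
    mat = np.zeros((len(ids), len(ids)))
    for group in household_groups(ped, ages):
        present = [idx[i] for i in group if i in idx]
        for a in present:
            for b in present:
                mat[a, b] = 1.0
    np.fill_diagonal(mat, 1.0)
    return mat


# -- relationship matrices ------------------------------------------------------


@dataclass
class RelationshipMatrices:
    """Per-pedigree additive (2*Phi), dominance (Delta7) and household matrices."""

    ids: list[str]
    additive: np.ndarray
    dominance: np.ndarray
    household: np.ndarray

    def submatrices(self, keep: Sequence[str]) -> "RelationshipMatrices":
        pos = [self.ids.index(i) for i in keep]
        ix = np.ix_(pos, pos)
        return RelationshipMatrices(
            ids=list(keep),
            additive=self.additive[ix],
            dominance=self.dominance[ix],
            household=self.household[ix],
        )


def relationship_matrices(
    ped: PedigreeGraph,
    ages: Mapping[str, float] | None = None,
    ids: Sequence[str] | None = None,
) -> RelationshipMatrices:
    """Compute the three structure matrices for ``ids`` (default: all members)."""
    ids = list(ids) if ids is not None else list(ped.order)
    n = len(ids)
    add = np.zeros((n, n))
    dom = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            add[a, b] = add[b, a] = 2.0 * kinship(ped, ids[a], ids[b])
            dom[a, b] = dom[b, a] = dominance_coefficient(ped, ids[a], ids[b])
    hh = household_matrix(ped, ages, ids)
    return RelationshipMatrices(ids=ids, additive=add, dominance=dom, household=hh)


# -- pair classification ---------------------------------------------------------


#: Priority order used by :func:`classify_pair`; first match wins.
CLASSIFICATION_PRIORITY = (
    "MZ", "parent-offspring", "DZ", "sib", "half-sib", "grandparental",
    "avuncular", "double-first-cousin", "first-cousin-MZ-parents",
    "first-cousin", "spouse", "other",
)

_PO_LABELS = {
    ("male", "male"): "father-son",
    ("male", "female"): "father-daughter",
    ("female", "male"): "mother-son",
    ("female", "female"): "mother-daughter",
}


def classify_pair(ped: PedigreeGraph, i: str, j: str) -> str:
    """Label the relationship of a pair, by a fixed priority order.

    Full sibs with the same birth year are labelled ``DZ`` (twins), other
    full sibs ``sib``.  Parent-offspring labels carry the sexes
    (``father-son`` etc.).  Structural relations use literal parent links;
    only the ``first-cousin-MZ-parents`` class consults MZ groups of the
    linking parents.
    """
    ri, rj = ped.members[i], ped.members[j]
    if ped.same_mz_group(i, j):
        return "MZ"
    if rj.father_id == i or rj.mother_id == i:
        return _PO_LABELS[(ri.sex, rj.sex)]
    if ri.father_id == j or ri.mother_id == j:
        return _PO_LABELS[(rj.sex, ri.sex)]
    if ped.full_sibs(i, j):
        if (
            ri.birth_year is not None
            and ri.birth_year == rj.birth_year
        ):
            return "DZ"
        return "sib"
    if ped.half_sibs(i, j):
        return "half-sib"
    gp_i = _grandparents(ped, i)
    gp_j = _grandparents(ped, j)
    if j in gp_i or i in gp_j:
        return "grandparental"
    for a, b in ((i, j), (j, i)):
        for p in _parent_list(ped, b):
            if ped.full_sibs(a, p) or ped.same_mz_group(a, p):
                return "avuncular"
    pi, pj = _parent_list(ped, i), _parent_list(ped, j)
    if pi and pj:
        sib_links = [
            (a, b)
            for a in pi
            for b in pj
            if a != b and (ped.full_sibs(a, b) or ped.same_mz_group(a, b))
        ]
        if len(sib_links) >= 2 and len({a for a, _ in sib_links}) == 2:
            return "double-first-cousin"
        if sib_links:
            if any(ped.same_mz_group(a, b) for a, b in sib_links):
                return "first-cousin-MZ-parents"
            return "first-cousin"
    if frozenset((i, j)) in ped.spouse_pairs():
        return "spouse"
    return "other"


def _parent_list(ped: PedigreeGraph, iid: str) -> list[str]:
    rec = ped.members[iid]
    return [p for p in (rec.father_id, rec.mother_id) if p is not None]


def _grandparents(ped: PedigreeGraph, iid: str) -> set[str]:
    out: set[str] = set()
    for p in _parent_list(ped, iid):
        out.update(_parent_list(ped, p))
    return out


# -- CSV I/O ----------------------------------------------------------------------

PEDIGREE_COLUMNS = [
    "family_id", "individual_id", "father_id", "mother_id", "sex",
    "mz_group", "birth_year", "spouse_of",
]


def _null(tok) -> str | None:
    if tok is None or (isinstance(tok, float) and np.isnan(tok)):
        return None
    tok = str(tok).strip()
    return None if tok in NULL_TOKENS else tok


def records_from_frame(df: pd.DataFrame) -> list[IndividualRecord]:
    required = {"family_id", "individual_id", "father_id", "mother_id", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree table missing columns: {sorted(missing)}")
    recs = []
    for row in df.itertuples(index=False):
        by = _null(getattr(row, "birth_year", None))
        recs.append(
            IndividualRecord(
                individual_id=str(row.individual_id),
                family_id=str(row.family_id),
                father_id=_null(row.father_id),
                mother_id=_null(row.mother_id),
                sex=str(row.sex).strip().lower(),
                birth_year=int(float(by)) if by is not None else None,
                mz_group=_null(getattr(row, "mz_group", None)),
                spouse_of=_null(getattr(row, "spouse_of", None)),
            )
        )
    return recs


def load_pedigree(source) -> dict[str, PedigreeGraph]:
    """Read a pedigree CSV (path, file handle or DataFrame) into per-family graphs.

    Columns: family_id, individual_id, father_id, mother_id, sex and
    optionally mz_group, birth_year, spouse_of; "0" or empty means no value.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    graphs: dict[str, PedigreeGraph] = {}
    for fam, sub in df.groupby("family_id", sort=True):
        graphs[str(fam)] = PedigreeGraph(records_from_frame(sub))
    return graphs


def write_pedigree(graphs: Mapping[str, PedigreeGraph], path) -> None:
    rows = []
    for fam in sorted(graphs):
        ped = graphs[fam]
        for iid in ped.order:
            r = ped.members[iid]
            rows.append(
                {
                    "family_id": r.family_id,
                    "individual_id": r.individual_id,
                    "father_id": r.father_id or "0",
                    "mother_id": r.mother_id or "0",
                    "sex": r.sex,
                    "mz_group": r.mz_group or "0",
                    "birth_year": r.birth_year if r.birth_year is not None else "0",
                    "spouse_of": r.spouse_of or "0",
                }
            )
    pd.DataFrame(rows, columns=PEDIGREE_COLUMNS).to_csv(path, index=False)


def write_relationship_dump(mats: RelationshipMatrices, path) -> None:
    """Wide TSV dump of the three matrices for one family."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for name, mat in (
            ("additive", mats.additive),
            ("dominance", mats.dominance),
            ("household", mats.household),
        ):
            w.writerow([name] + mats.ids)
            for iid, row in zip(mats.ids, mat):
                w.writerow([iid] + [f"{v:.6g}" for v in row])
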