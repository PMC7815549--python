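"""Gene-dropping Monte Carlo: an independent check of relationship coefficients.

Founder alleles are labelled uniquely and transmitted down the pedigree by
fair Mendelian coin flips; MZ group members receive identical copies.  Over
many replicate "drops" the empirical identity-by-descent sharing of a pair
estimates twice the kinship coefficient, and the probability that the pair
shares *both* alleles estimates the fraternity coefficient Delta7.  This is
a simulation alternative to the recursive algorithms in
:mod:`pedvar.pedigree` and is used to validate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import PedigreeGraph


@dataclass
class GeneDropResult:
    """Monte-Carlo estimates with standard errors for one pair."""

    additive: float       # estimate of 2*phi
    additive_se: float
    dominance: float      # estimate of Delta7
    dominance_se: float
    n_drops: int


class GeneDropper:
    """Drop founder alleles down a pedigree ``n_drops`` times in parallel."""

    def __init__(self, ped: PedigreeGraph, n_drops: int, rng: np.random.Generator):
        self.ped = ped
        self.n_drops = int(n_drops)
        ids = list(ped.order)
        self.index = {iid: k for k, iid in enumerate(ids)}
        n = len(ids)
        pat = np.empty((n, self.n_drops), dtype=np.int32)
        mat = np.empty((n, self.n_drops), dtype=np.int32)
        next_allele = 0
        done: dict[str, int] = {}
        for iid in ids:
            rec = ped.members[iid]
            k = self.index[iid]
            rep = ped._rep[iid]
            if rep in done:
                # MZ co-member: identical genotype copy
                src = done[rep]
                pat[k] = pat[src]
                mat[k] = mat[src]
                continue
            if rec.is_founder:
                pat[k] = next_allele
                mat[k] = next_allele + 1
                next_allele += 2
            else:
                for out, pid in ((pat, rec.father_id), (mat, rec.mother_id)):
                    p = self.index[pid]
                    pick = rng.integers(0, 2, size=self.n_drops)
                    out[k] = np.where(pick == 0, pat[p], mat[p])
            done[rep] = k
        self.pat, self.mat = pat, mat

    def pair(self, i: str, j: str) -> GeneDropResult:
        a1, a2 = self.pat[self.index[i]], self.mat[self.index[i]]
        b1, b2 = self.pat[self.index[j]], self.mat[self.index[j]]
        if i == j:
            share = np.ones(self.n_drops)
            both = np.ones(self.n_drops)
        else:
            # 2*phi = expected half-count of IBD allele matches across the
            # four cross-individual allele pairs
            match = (
                (a1 == b1).astype(np.float64)
                + (a1 == b2)
                + (a2 == b1)
                + (a2 == b2)
            )
            share = 0.5 * match
            both = (
                ((a1 == b1) & (a2 == b2)) | ((a1 == b2) & (a2 == b1))
            ).astype(np.float64)
        n = self.n_drops
        return GeneDropResult(
            additive=float(share.mean()),
            additive_se=float(share.std(ddof=1) / np.sqrt(n)),
            dominance=float(both.mean()),
            dominance_se=float(both.std(ddof=1) / np.sqrt(n)),
            n_drops=n,
        )


def gene_drop_pair(
    ped: PedigreeGraph, i: str, j: str, n_drops: int = 100_000, seed: int = 0
) -> GeneDropResult:
    dropper = GeneDropper(ped, n_drops, np.random.default_rng(seed))
    return dropper.pair(i, j)
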