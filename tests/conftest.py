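import numpy as np
import pytest

from pedvar.pedigree import IndividualRecord, PedigreeGraph


@pytest.fixture
def nuclear_mz():
    """Parents + MZ twin pair + a younger non-twin sib."""
    return PedigreeGraph(
        [
            IndividualRecord("f", "fam", sex="male", birth_year=1955),
            IndividualRecord("m", "fam", sex="female", birth_year=1958),
            IndividualRecord("t1", "fam", "f", "m", "female", 1980, mz_group="g"),
            IndividualRecord("t2", "fam", "f", "m", "female", 1980, mz_group="g"),
            IndividualRecord("s1", "fam", "f", "m", "male", 1984),
        ]
    )


@pytest.fixture
def three_generation():
    """Grandparents, two sibling parents with spouses, and cousins; also an
    avuncular pair, grandparental pairs and a half-sib via remarriage."""
    return PedigreeGraph(
        [
            IndividualRecord("gf", "fam", sex="male"),
            IndividualRecord("gm", "fam", sex="female"),
            IndividualRecord("u1", "fam", "gf", "gm", "male", 1950),
            IndividualRecord("u2", "fam", "gf", "gm", "female", 1953),
            IndividualRecord("w1", "fam", sex="female"),
            IndividualRecord("w2", "fam", sex="male"),
            IndividualRecord("w3", "fam", sex="male"),
            IndividualRecord("c1", "fam", "u1", "w1", "male", 1980),
            IndividualRecord("c2", "fam", "w2", "u2", "female", 1982),
            IndividualRecord("c3", "fam", "w3", "u2", "male", 1990),  # half-sib of c2
        ]
    )


@pytest.fixture
def double_first_cousins():
    """Two sib pairs intermarry crosswise; their children are double first
    cousins."""
    recs = [
        IndividualRecord(i, "fam", sex=s)
        for i, s in [("a", "male"), ("b", "female"), ("c", "male"), ("d", "female")]
    ]
    recs += [
        IndividualRecord("p1", "fam", "a", "b", "male", 1950),
        IndividualRecord("p2", "fam", "a", "b", "female", 1952),
        IndividualRecord("q1", "fam", "c", "d", "female", 1951),
        IndividualRecord("q2", "fam", "c", "d", "male", 1953),
        IndividualRecord("x", "fam", "p1", "q1", "male", 1980),
        IndividualRecord("y", "fam", "q2", "p2", "female", 1981),
    ]
    return PedigreeGraph(recs)


@pytest.fixture
def mz_parent_cousins():
    """MZ twin sisters married to unrelated men; their children are cousins
    with MZ twins as parents."""
    recs = [
        IndividualRecord(i, "fam", sex=s)
        for i, s in [("gf", "male"), ("gm", "female"), ("h1", "male"), ("h2", "male")]
    ]
    recs += [
        IndividualRecord("t1", "fam", "gf", "gm", "female", 1955, mz_group="z"),
        IndividualRecord("t2", "fam", "gf", "gm", "female", 1955, mz_group="z"),
        IndividualRecord("c1", "fam", "h1", "t1", "male", 1980),
        IndividualRecord("c2", "fam", "h2", "t2", "female", 1982),
    ]
    return PedigreeGraph(recs)
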