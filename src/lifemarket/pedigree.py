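"""Coefficients of relationship from pedigrees, and the cohort lambda.

The coefficient of relationship r between two individuals B and C is the
classical genealogical path count: r_BC = sum over all ancestor paths p of
2^(-L(p)), where a path runs from B up to a common ancestor A and back down
to C without visiting any individual twice, and L(p) is its total number of
parent-child links.  Parent and offspring share one path of length 1
(r = 1/2); grandparent and grandchild one path of length 2 (r = 1/4); full
siblings two paths of length 2, one through each parent (r = 1/2).  This is
the zero-inbreeding simplification appropriate for random-bred human
populations; an optional mode applies Wright's inbreeding-adjusted
definition via the recursive kinship matrix.

Monozygotic twins are genetically one individual: the pair has r = 1 and a
path through either twin is the same path.  Internally each individual maps
to a *genotype class* (twins share a class) and all path counting runs on
classes, so a twin's child is related to the co-twin exactly like an own
child (r = 1/2).

The cohort lambda of a user is the sum of r between the user and every
other enrolled platform user; the valuation model scales the user's terms
by (1 + lambda), so one enrolled identical twin doubles a user's data
value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .exceptions import PedigreeError

__all__ = [
    "Individual",
    "Pedigree",
    "RelatednessMatrix",
    "read_ped",
    "write_ped",
    "relationship_coefficient",
    "kinship_coefficient",
    "inbreeding_coefficient",
    "relatedness_matrix",
    "cohort_lambda",
]


@dataclass(frozen=True)
class Individual:
    """One pedigree member; parent ids of ``None`` mean unknown (founder)."""

    iid: str
    fid: str = "0"
    father: str | None = None
    mother: str | None = None
    sex: int = 0  # PED coding: 1 male, 2 female, 0 unknown
    phenotype: str = "-9"


class Pedigree:
    """Directed acyclic parent->child graph with optional MZ-twin pairs."""

    def __init__(
        self,
        individuals: Iterable[Individual] = (),
        mz_twin_pairs: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self.individuals:
                raise PedigreeError(f"duplicate individual id {ind.iid!r}")
            self.individuals[ind.iid] = ind
        self.mz_twin_pairs: set[frozenset[str]] = {
            frozenset(p) for p in mz_twin_pairs
        }
        self._validate()
        self._class_of = self._genotype_classes()
        self._class_parents = self._class_parent_map()

    # -- construction checks ------------------------------------------------

    def _validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for ind in self.individuals.values():
            for parent in (ind.father, ind.mother):
                if parent is None:
                    continue
                if parent not in self.individuals:
                    raise PedigreeError(
                        f"individual {ind.iid!r} references missing parent {parent!r}"
                    )
                g.add_edge(parent, ind.iid)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise PedigreeError(f"pedigree contains a cycle: {path}")
        for pair in self.mz_twin_pairs:
            a, b = sorted(pair)
            if len(pair) != 2:
                raise PedigreeError(f"MZ twin pair {sorted(pair)} must have two ids")
            for iid in (a, b):
                if iid not in self.individuals:
                    raise PedigreeError(f"MZ twin id {iid!r} not in pedigree")
            ia, ib = self.individuals[a], self.individuals[b]
            if (ia.father, ia.mother) != (ib.father, ib.mother) and None not in (
                ia.father, ia.mother, ib.father, ib.mother
            ):
                raise PedigreeError(f"MZ twins {a!r}, {b!r} have different parents")
        self._graph = g

    # -- genotype classes (MZ twins merged) ---------------------------------

    def _genotype_classes(self) -> dict[str, str]:
        """Map each individual to a class id; MZ twins share one class."""
        class_of = {iid: iid for iid in self.individuals}
        for pair in self.mz_twin_pairs:
            a, b = sorted(pair)
            class_of[b] = class_of[a]
        return class_of

    def _class_parent_map(self) -> dict[str, set[str]]:
        parents: dict[str, set[str]] = {c: set() for c in self._class_of.values()}
        for ind in self.individuals.values():
            cls = self._class_of[ind.iid]
            for p in (ind.father, ind.mother):
                if p is not None:
                    parents[cls].add(self._class_of[p])
        return parents

    # -- queries -------------------------------------------------------------

    def __contains__(self, iid: str) -> bool:
        return iid in self.individuals

    def __len__(self) -> int:
        return len(self.individuals)

    def ids(self) -> list[str]:
        return list(self.individuals)

    def genotype_class(self, iid: str) -> str:
        if iid not in self.individuals:
            raise PedigreeError(f"unknown individual id {iid!r}")
        return self._class_of[iid]

    def class_parents(self, cls: str) -> set[str]:
        return self._class_parents[cls]

    def parents_of(self, iid: str) -> tuple[str | None, str | None]:
        ind = self.individuals[iid]
        return ind.father, ind.mother

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.mz_twin_pairs == other.mz_twin_pairs
        )


@dataclass
class RelatednessMatrix:
    """Symmetric map (id, id) -> r with r(x, x) = 1 by convention."""

    ids: list[str]
    values: dict[frozenset[str], float] = field(default_factory=dict)

    def r(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.values.get(frozenset((a, b)), 0.0)


# ---------------------------------------------------------------------------
# PED I/O
# ---------------------------------------------------------------------------

def read_ped(path: str | Path, mz_sidecar: str | Path | None = None) -> Pedigree:
    """Read a pedigree from a whitespace-delimited 6-column PED/FAM file.

    Columns are FID IID PAT MAT SEX PHENO with "0" marking an unknown
    parent.  ``mz_sidecar`` optionally names a text file listing one
    monozygotic twin pair (two ids) per line; PED has no field for this.
    """
    path = Path(path)
    individuals: list[Individual] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(f"{path}: line {lineno}: expected 6 columns")
            fid, iid, pat, mat, sex, pheno = fields[:6]
            individuals.append(
                Individual(
                    iid=iid,
                    fid=fid,
                    father=None if pat == "0" else pat,
                    mother=None if mat == "0" else mat,
                    sex=int(sex) if sex in ("0", "1", "2") else 0,
                    phenotype=pheno,
                )
            )
    pairs: list[tuple[str, str]] = []
    if mz_sidecar is not None:
        with open(mz_sidecar, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                ids = line.split()
                if len(ids) != 2:
                    raise PedigreeError(f"{mz_sidecar}: each line must list two ids")
                pairs.append((ids[0], ids[1]))
    return Pedigree(individuals, pairs)


def write_ped(
    pedigree: Pedigree, path: str | Path, mz_sidecar: str | Path | None = None
) -> None:
    """Write PED rows (insertion order) and, optionally, the MZ sidecar."""
    with open(path, "w", encoding="utf-8") as fh:
        for ind in pedigree.individuals.values():
            fh.write(
                f"{ind.fid} {ind.iid} {ind.father or '0'} {ind.mother or '0'} "
                f"{ind.sex} {ind.phenotype}\n"
            )
    if mz_sidecar is not None:
        with open(mz_sidecar, "w", encoding="utf-8") as fh:
            for pair in sorted(sorted(p) for p in pedigree.mz_twin_pairs):
                fh.write(f"{pair[0]} {pair[1]}\n")


# ---------------------------------------------------------------------------
# coefficient of relationship
# ---------------------------------------------------------------------------

def _ancestor_paths(ped: Pedigree, cls: str) -> dict[str, list[tuple[str, ...]]]:
    """All simple upward paths from a genotype class to each of its ancestors.

    Returns ancestor class -> list of node tuples (cls, ..., ancestor);
    the trivial path (cls,) of length 0 is included for cls itself.
    """
    out: dict[str, list[tuple[str, ...]]] = {}

    def walk(path: tuple[str, ...]) -> None:
        node = path[-1]
        out.setdefault(node, []).append(path)
        for parent in sorted(ped.class_parents(node)):
            if parent not in path:  # pedigrees are acyclic, but stay defensive
                walk(path + (parent,))

    walk((cls,))
    return out


def relationship_coefficient(
    ped: Pedigree, a: str, b: str, inbreeding_adjusted: bool = False
) -> float:
    """Coefficient of relationship r between individuals ``a`` and ``b``.

    Default: zero-inbreeding path counting, r = sum over paths of 2^-L.
    With ``inbreeding_adjusted=True``, Wright's definition
    r = 2 phi_ab / sqrt((1 + f_a)(1 + f_b)) is used instead, where phi is
    the kinship coefficient and f the inbreeding coefficient; the two
    agree on pedigrees whose common ancestors are non-inbred.
    """
    for iid in (a, b):
        if iid not in ped:
            raise PedigreeError(f"unknown individual id {iid!r}")
    ca, cb = ped.genotype_class(a), ped.genotype_class(b)
    if ca == cb:
        return 1.0
    if inbreeding_adjusted:
        num = 2.0 * kinship_coefficient(ped, a, b)
        den = math.sqrt(
            (1.0 + inbreeding_coefficient(ped, a)) * (1.0 + inbreeding_coefficient(ped, b))
        )
        return num / den

    paths_a = _ancestor_paths(ped, ca)
    paths_b = _ancestor_paths(ped, cb)
    r = 0.0
    for ancestor in paths_a.keys() & paths_b.keys():
        for pa in paths_a[ancestor]:
            for pb in paths_b[ancestor]:
                # the two legs must share only the common ancestor
                if set(pa[:-1]) & set(pb):
                    continue
                r += 2.0 ** (-(len(pa) - 1 + len(pb) - 1))
    return r


def kinship_coefficient(ped: Pedigree, a: str, b: str) -> float:
    """Recursive kinship coefficient phi on genotype classes.

    phi(x, x) = 1/2 (1 + f_x) with f_x the kinship of x's parents;
    phi(x, y) averages phi over the parents of whichever argument is not
    an ancestor of the other (founder parents contribute 0).
    """
    memo: dict[frozenset[str] | str, float] = {}

    depth_cache: dict[str, int] = {}

    def depth(cls: str) -> int:
        if cls not in depth_cache:
            parents = ped.class_parents(cls)
            depth_cache[cls] = 0 if not parents else 1 + max(depth(p) for p in parents)
        return depth_cache[cls]

    def phi(x: str, y: str) -> float:
        if x == y:
            parents = sorted(ped.class_parents(x))
            f = phi(parents[0], parents[1]) if len(parents) == 2 else 0.0
            return 0.5 * (1.0 + f)
        key = frozenset((x, y))
        if key in memo:
            return memo[key]
        # recurse through the deeper individual so the recursion terminates
        if depth(x) < depth(y):
            x, y = y, x
        parents = sorted(ped.class_parents(x))
        val = sum(phi(p, y) for p in parents) / 2.0 if parents else 0.0
        memo[key] = val
        return val

    return phi(ped.genotype_class(a), ped.genotype_class(b))


def inbreeding_coefficient(ped: Pedigree, iid: str) -> float:
    """f of an individual: the kinship coefficient of its parents (0 for founders)."""
    father, mother = ped.parents_of(iid)
    if father is None or mother is None:
        return 0.0
    return kinship_coefficient(ped, father, mother)


def relatedness_matrix(ped: Pedigree, ids: Iterable[str] | None = None) -> RelatednessMatrix:
    """Pairwise r over ``ids`` (default: all pedigree members)."""
    id_list = list(ids) if ids is not None else ped.ids()
    mat = RelatednessMatrix(ids=id_list)
    for i, a in enumerate(id_list):
        for b in id_list[i + 1:]:
            r = relationship_coefficient(ped, a, b)
            if r > 0:
                mat.values[frozenset((a, b))] = r
    return mat


def cohort_lambda(ped: Pedigree, user: str, cohort: Iterable[str]) -> float:
    """Relationship regularization lambda: sum of r(user, member) over the cohort.

    The user is excluded automatically; members absent from the pedigree
    contribute 0 (strangers). No cap is applied, so large enrolled
    families raise data value without bound.
    """
    if user not in ped:
        raise PedigreeError(f"unknown individual id {user!r}")
    lam = 0.0
    for member in set(cohort):
        if member == user or member not in ped:
            continue
        lam += relationship_coefficient(ped, user, member)
    return lam
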