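"""Pedigree assembly and additive relatedness.

Builds multi-generation pedigrees for wild populations where parentage is a
mixture of observed maternities, genetic assignments, and heuristic rules
(alpha-male paternity under inbreeding avoidance, dummy-parent sibships among
founders and co-migrant males).  From a validated pedigree the module computes
the additive (numerator) relationship matrix A by the tabular method, with
per-individual inbreeding coefficients on the diagonal, and summary statistics
(maternities, paternities, sibship counts, generation depth).

Identifiers are opaque strings.  Unknown parents are represented as ``None``;
empty strings in CSV input are treated as unknown.  Dummy parents created by
the sibship rules carry a reserved ``DUM:`` prefix and an ``is_dummy`` flag so
they can be excluded from phenotype joins.
"""

from __future__ import annotations

import graphlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("socped")

DUMMY_PREFIX = "DUM:"

__all__ = [
    "PedigreeRecord",
    "Pedigree",
    "AlphaTenure",
    "RelationshipMatrix",
    "PedigreeStats",
    "PedigreeValidationError",
    "DuplicateIdError",
    "SelfParentageError",
    "PedigreeCycleError",
    "SibshipConflictError",
    "validate_pedigree",
    "assign_alpha_paternity",
    "assign_founder_sibships",
    "prune_pedigree",
    "additive_relationship_matrix",
    "pedigree_summary",
    "read_pedigree_csv",
    "read_tenure_csv",
]


class PedigreeValidationError(ValueError):
    """Base class for pedigree validation failures."""


class DuplicateIdError(PedigreeValidationError):
    """Two records share the same individual identifier."""


class SelfParentageError(PedigreeValidationError):
    """An individual is listed as its own dam or sire."""


class PedigreeCycleError(PedigreeValidationError):
    """An individual is its own ancestor."""


class SibshipConflictError(PedigreeValidationError):
    """A sibship assignment targets an individual with both parents known."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: identifier, dam, sire, dummy flag, optional sex."""

    id: str
    dam: str | None = None
    sire: str | None = None
    is_dummy: bool = False
    sex: str | None = None  # "F", "M" or None for unknown


@dataclass(frozen=True)
class AlphaTenure:
    """Continuous period during which one male is the alpha of a group.

    ``start`` and ``end`` are inclusive (year, month) tuples.
    """

    group: str
    alpha_male: str
    start: tuple[int, int]
    end: tuple[int, int]

    def covers(self, ym: tuple[int, int]) -> bool:
        return self.start <= tuple(ym) <= self.end


class Pedigree:
    """A validated pedigree in topological (parents-first) order.

    Construct via :func:`validate_pedigree`; the constructor assumes the
    record list is already consistent and ordered.
    """

    def __init__(self, records: Sequence[PedigreeRecord],
                 implicit_founders: frozenset[str] = frozenset()):
        self.records: tuple[PedigreeRecord, ...] = tuple(records)
        self._by_id = {r.id: r for r in self.records}
        #: parents referenced but never listed, added as unknown-parent founders
        self.implicit_founders = implicit_founders

    # -- basic accessors ---------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> PedigreeRecord:
        return self._by_id[iid]

    def dam_of(self, iid: str) -> str | None:
        return self._by_id[iid].dam

    def sire_of(self, iid: str) -> str | None:
        return self._by_id[iid].sire

    def parents_of(self, iid: str) -> tuple[str | None, str | None]:
        r = self._by_id[iid]
        return r.dam, r.sire

    def is_founder(self, iid: str) -> bool:
        r = self._by_id[iid]
        return r.dam is None and r.sire is None

    def ancestors(self, iid: str, max_depth: int | None = None) -> set[str]:
        """All known ancestors of ``iid`` (any line), optionally depth-limited."""
        out: set[str] = set()
        frontier = [(iid, 0)]
        while frontier:
            cur, d = frontier.pop()
            if max_depth is not None and d >= max_depth:
                continue
            for p in self.parents_of(cur):
                if p is not None and p not in out:
                    out.add(p)
                    frontier.append((p, d + 1))
        return out

    def generation_depth(self) -> dict[str, int]:
        """Founders have depth 0; otherwise 1 + max(parent depths)."""
        depth: dict[str, int] = {}
        for r in self.records:  # topological order: parents precede offspring
            ps = [p for p in (r.dam, r.sire) if p is not None]
            depth[r.id] = 0 if not ps else 1 + max(depth[p] for p in ps)
        return depth

    def with_records(self, records: Sequence[PedigreeRecord]) -> "Pedigree":
        return validate_pedigree(records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "dam": [r.dam for r in self.records],
                "sire": [r.sire for r in self.records],
                "is_dummy": [r.is_dummy for r in self.records],
                "sex": [r.sex for r in self.records],
            }
        )


@dataclass(frozen=True)
class RelationshipMatrix:
    """Additive relationship matrix A with inbreeding coefficients F.

    ``A`` is symmetric positive semi-definite with ``diag(A) = 1 + F``;
    entries are twice the kinship coefficient (unitless).
    """

    ids: tuple[str, ...]
    A: np.ndarray
    F: np.ndarray

    def index_of(self, iid: str) -> int:
        try:
            return self._index[iid]
        except AttributeError:
            object.__setattr__(self, "_index", {v: i for i, v in enumerate(self.ids)})
            return self._index[iid]

    def relatedness(self, a: str, b: str) -> float:
        return float(self.A[self.index_of(a), self.index_of(b)])


@dataclass(frozen=True)
class PedigreeStats:
    maternities: int
    paternities: int
    full_sibships: int
    maternal_half_sibships: int
    paternal_half_sibships: int
    max_depth: int
    mean_depth: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_pedigree(records: Iterable[PedigreeRecord]) -> Pedigree:
    """Validate records and return a parents-first ordered :class:`Pedigree`.

    Parents referenced but absent from the record list are added as founders
    (tracked in ``Pedigree.implicit_founders``, inbreeding 0 by construction).

    Raises
    ------
    DuplicateIdError, SelfParentageError, PedigreeCycleError
    """
    records = list(records)
    if not records:
        raise PedigreeValidationError("empty record list")

    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise DuplicateIdError(f"duplicate id {r.id!r}")
        seen.add(r.id)
        if r.id == r.dam or r.id == r.sire:
            raise SelfParentageError(f"{r.id!r} is its own parent")

    implicit: set[str] = set()
    for r in records:
        for p in (r.dam, r.sire):
            if p is not None and p not in seen:
                implicit.add(p)
    full = [PedigreeRecord(p) for p in sorted(implicit)] + records

    ts = graphlib.TopologicalSorter(
        {r.id: [p for p in (r.dam, r.sire) if p is not None] for r in full}
    )
    try:
        order = list(ts.static_order())
    except graphlib.CycleError as exc:
        raise PedigreeCycleError(f"ancestry cycle: {exc.args[1]}") from exc

    by_id = {r.id: r for r in full}
    return Pedigree([by_id[i] for i in order], frozenset(implicit))


# ---------------------------------------------------------------------------
# heuristic parentage rules
# ---------------------------------------------------------------------------

def _descends_from_within(ped: Pedigree, iid: str, ancestor: str, depth: int) -> bool:
    """True if ``ancestor`` is a parent/grandparent/... of ``iid`` within ``depth``."""
    return ancestor in ped.ancestors(iid, max_depth=depth)


def assign_alpha_paternity(
    ped: Pedigree,
    conceptions: Mapping[str, tuple[str, tuple[int, int]]],
    tenures: Sequence[AlphaTenure],
    maternal_links: Pedigree | None = None,
) -> tuple[Pedigree, int]:
    """Fill missing sires with the group's alpha male at conception.

    The alpha is assigned as sire unless the subject's dam is a daughter or
    granddaughter of that alpha (inbreeding avoidance).  Descent is judged on
    ``maternal_links`` (default: ``ped`` itself) through either parental line,
    within two generations.  Subjects whose conception month falls outside all
    recorded tenures for their group are skipped with a logged warning.

    Returns the updated pedigree and the number of assignments made.
    """
    links = maternal_links if maternal_links is not None else ped
    new_records: dict[str, PedigreeRecord] = {r.id: r for r in ped.records}
    n_assigned = 0
    for subject, (group, ym) in conceptions.items():
        rec = new_records[subject]
        if rec.sire is not None:
            continue  # rule applies to unknown-sire subjects only
        tenure = next(
            (t for t in tenures if t.group == group and t.covers(ym)), None
        )
        if tenure is None:
            logger.warning(
                "no alpha tenure for group %s at %s; %s left unchanged",
                group, ym, subject,
            )
            continue
        alpha = tenure.alpha_male
        if alpha == subject:
            continue
        dam = rec.dam
        if dam is not None and dam in links and _descends_from_within(links, dam, alpha, 2):
            continue  # dam is daughter or granddaughter of the alpha
        new_records[subject] = replace(rec, sire=alpha)
        n_assigned += 1
    return validate_pedigree(list(new_records.values())), n_assigned


def assign_founder_sibships(
    ped: Pedigree,
    pairs: Sequence[tuple[str, str, str]],
) -> Pedigree:
    """Link founder/immigrant pairs through shared dummy parents.

    Pair classes:

    ``full_sib``
        both members share a newly created dummy dam AND dummy sire
        (relatedness 0.5 after matrix build);
    ``comigrant_unassigned``
        paternal half siblings — shared dummy sire only (0.25);
    ``natal_founder_unassigned``
        maternal half siblings — shared dummy dam only (0.25).

    Any parent slot of a listed individual left open by its sibship class is
    filled with a unique dummy parent, so no spurious sharing arises between
    pairs.  Dummy parents are flagged ``is_dummy`` and never phenotyped.
    """
    new_records: dict[str, PedigreeRecord] = {r.id: r for r in ped.records}
    dummies: list[PedigreeRecord] = []
    counter = sum(1 for r in ped.records if r.is_dummy)

    def new_dummy(sex: str) -> str:
        nonlocal counter
        counter += 1
        did = f"{DUMMY_PREFIX}{sex}{counter:04d}"
        dummies.append(PedigreeRecord(did, is_dummy=True, sex=sex))
        return did

    for a, b, cls in pairs:
        for m in (a, b):
            rec = new_records[m]
            if rec.dam is not None and rec.sire is not None:
                raise SibshipConflictError(
                    f"{m!r} already has both parents; cannot assign {cls} sibship"
                )
        if cls == "full_sib":
            dam, sire = new_dummy("F"), new_dummy("M")
            for m in (a, b):
                new_records[m] = replace(new_records[m], dam=dam, sire=sire)
        elif cls == "comigrant_unassigned":
            sire = new_dummy("M")
            for m in (a, b):
                new_records[m] = replace(new_records[m], sire=sire)
        elif cls == "natal_founder_unassigned":
            dam = new_dummy("F")
            for m in (a, b):
                new_records[m] = replace(new_records[m], dam=dam)
        else:
            raise ValueError(f"unknown sibship class {cls!r}")

    # fill remaining open slots of listed individuals with unique dummies
    listed = {m for a, b, _ in pairs for m in (a, b)}
    for m in sorted(listed):
        rec = new_records[m]
        if rec.dam is None:
            rec = replace(rec, dam=new_dummy("F"))
        if rec.sire is None:
            rec = replace(rec, sire=new_dummy("M"))
        new_records[m] = rec

    return validate_pedigree(dummies + list(new_records.values()))


def prune_pedigree(ped: Pedigree, phenotyped: set[str]) -> Pedigree:
    """Drop individuals uninformative for relatedness among ``phenotyped``.

    Iteratively removes non-phenotyped individuals with no retained
    descendants; what remains is the phenotyped set plus every ancestor of a
    phenotyped individual.  Idempotent.
    """
    if not phenotyped:
        raise PedigreeValidationError("empty phenotyped set")
    missing = phenotyped - set(ped.ids)
    if missing:
        raise PedigreeValidationError(f"phenotyped ids not in pedigree: {sorted(missing)}")

    retained = set(phenotyped)
    for s in phenotyped:
        retained |= ped.ancestors(s)
    records = [
        replace(
            r,
            dam=r.dam if r.dam in retained else None,
            sire=r.sire if r.sire in retained else None,
        )
        for r in ped.records
        if r.id in retained
    ]
    return validate_pedigree(records)


# ---------------------------------------------------------------------------
# additive relationship matrix (tabular method)
# ---------------------------------------------------------------------------

def additive_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Compute A recursively in pedigree order (the tabular method).

    ``a_ii = 1 + 0.5 * a(dam, sire)`` (0 if either parent unknown) and
    ``a_ij = 0.5 * (a(j, dam_i) + a(j, sire_i))`` for j earlier than i.
    Founders (implicit or explicit) have inbreeding coefficient 0.
    """
    ids = ped.ids
    n = len(ids)
    pos = {v: i for i, v in enumerate(ids)}
    dam_idx = np.array(
        [pos[r.dam] if r.dam is not None else -1 for r in ped.records], dtype=np.int64
    )
    sire_idx = np.array(
        [pos[r.sire] if r.sire is not None else -1 for r in ped.records], dtype=np.int64
    )

    A = np.zeros((n, n))
    for i in range(n):
        d, s = dam_idx[i], sire_idx[i]
        # off-diagonals with all earlier individuals, vectorized over j < i
        row = np.zeros(i)
        if d >= 0:
            row += 0.5 * A[d, :i]
        if s >= 0:
            row += 0.5 * A[s, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[d, s] if (d >= 0 and s >= 0) else 0.0)
    F = np.diag(A) - 1.0
    return RelationshipMatrix(tuple(ids), A, F)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def pedigree_summary(ped: Pedigree, count_dummy_parents: bool = True) -> PedigreeStats:
    """Count maternities, paternities, and sibship pairs; report depth.

    A pair is a full sibship when both parents are known and shared, and a
    maternal (paternal) half sibship when exactly the dam (sire) is shared.
    Sharing via a dummy parent counts — relatedness, not provenance, drives
    the classification.  With ``count_dummy_parents=False`` dummy parents are
    ignored entirely (links through them count neither as parentages nor as
    shared parents).
    """

    def known(p: str | None) -> str | None:
        if p is None:
            return None
        if not count_dummy_parents and (p in ped and ped[p].is_dummy):
            return None
        return p

    dams = {r.id: known(r.dam) for r in ped.records}
    sires = {r.id: known(r.sire) for r in ped.records}
    offspring = [r.id for r in ped.records if not r.is_dummy]

    maternities = sum(1 for i in offspring if dams[i] is not None)
    paternities = sum(1 for i in offspring if sires[i] is not None)

    full = mat_half = pat_half = 0
    for ii in range(len(offspring)):
        for jj in range(ii + 1, len(offspring)):
            a, b = offspring[ii], offspring[jj]
            share_dam = dams[a] is not None and dams[a] == dams[b]
            share_sire = sires[a] is not None and sires[a] == sires[b]
            if share_dam and share_sire:
                full += 1
            elif share_dam:
                mat_half += 1
            elif share_sire:
                pat_half += 1

    depth = ped.generation_depth()
    depths = [depth[i] for i in offspring]
    return PedigreeStats(
        maternities=maternities,
        paternities=paternities,
        full_sibships=full,
        maternal_half_sibships=mat_half,
        paternal_half_sibships=pat_half,
        max_depth=max(depths),
        mean_depth=float(np.mean(depths)),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_pedigree_csv(path) -> Pedigree:
    """Read ``id,dam,sire[,sex]`` CSV (empty field = unknown parent)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    recs = [
        PedigreeRecord(
            id=row["id"],
            dam=row["dam"] or None,
            sire=row["sire"] or None,
            is_dummy=row["id"].startswith(DUMMY_PREFIX),
            sex=(row.get("sex") or None) if "sex" in df.columns else None,
        )
        for _, row in df.iterrows()
    ]
    return validate_pedigree(recs)


def _parse_ym(s: str) -> tuple[int, int]:
    y, m = s.split("-")
    return int(y), int(m)


def read_tenure_csv(path) -> list[AlphaTenure]:
    """Read ``group,alpha_male,start,end`` CSV with ``YYYY-MM`` dates."""
    df = pd.read_csv(path, dtype=str)
    return [
        AlphaTenure(row["group"], row["alpha_male"],
                    _parse_ym(row["start"]), _parse_ym(row["end"]))
        for _, row in df.iterrows()
    ]
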