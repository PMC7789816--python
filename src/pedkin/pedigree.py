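"""Pedigree containers, registry-file I/O, filters and demographic statistics.

The central object is :class:`Pedigree`: a validated, topologically ordered
collection of individual records with parent links, sex, breed code (EMS-style,
e.g. ``THA``/``SIA``/``OSH``/``BAL``) and birth year.  Registry exports are
routinely incomplete, so unknown parents are first-class citizens: a missing
parent is simply an absent link, and a parent id that is referenced but never
defined materialises as a founder with breed ``UNKNOWN``.

Analysis cohorts follow the two-consecutive-year convention for populations
with strongly overlapping generations: a *population* is the set of parents of
the kittens born in a two-year window.
"""

from __future__ import annotations

import csv
import heapq
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .runlog import RunLog, get_runlog

UNKNOWN = "UNKNOWN"

#: tokens treated as "no parent" / "no value" in registry files
_MISSING_TOKENS = {"", "0", "na", "n/a", "none", "unknown", "nan", "."}

_SEX_MAP = {
    "m": "male", "male": "male", "1": "male", "sire": "male",
    "f": "female", "female": "female", "2": "female", "dam": "female",
}


class PedigreeError(Exception):
    """Base class for pedigree validation / query errors."""


class PedigreeValidationError(PedigreeError):
    pass


class EmptyPopulationError(PedigreeError):
    pass


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: identity, parent links, sex, breed and birth year."""

    id: str
    sire: Optional[str] = None
    dam: Optional[str] = None
    sex: str = "unknown"
    breed: str = UNKNOWN
    birth_year: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeValidationError("record with empty id")
        if self.sire == self.id or self.dam == self.id:
            raise PedigreeValidationError(f"individual {self.id!r} is its own parent")


@dataclass(frozen=True)
class Population:
    """A cohort of breeding animals drawn from one pedigree."""

    member_ids: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.member_ids) == 0:
            raise EmptyPopulationError(f"population {self.label!r} is empty")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise PedigreeValidationError(f"population {self.label!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.member_ids)

    def __iter__(self):
        return iter(self.member_ids)


@dataclass(frozen=True)
class CompletenessProfile:
    """Per-generation fraction of known ancestor slots plus the ECG summary."""

    per_generation_fraction: tuple[float, ...]
    ecg: float


class Pedigree:
    """Topologically ordered pedigree (every parent precedes its offspring).

    Construct via :meth:`from_records` (validates, sorts, auto-creates
    referenced-but-undefined parents as ``UNKNOWN``-breed founders) or through
    :func:`load_pedigree`.
    """

    def __init__(self, records: Sequence[PedigreeRecord]) -> None:
        # records assumed validated + topologically sorted (use from_records)
        self._records: list[PedigreeRecord] = list(records)
        self._index: dict[str, int] = {r.id: i for i, r in enumerate(self._records)}
        n = len(self._records)
        self._sire_idx = np.full(n, -1, dtype=np.int64)
        self._dam_idx = np.full(n, -1, dtype=np.int64)
        for i, r in enumerate(self._records):
            if r.sire is not None:
                self._sire_idx[i] = self._index[r.sire]
            if r.dam is not None:
                self._dam_idx[i] = self._index[r.dam]

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[PedigreeRecord]) -> "Pedigree":
        records = list(records)
        by_id: dict[str, PedigreeRecord] = {}
        for r in records:
            if r.id in by_id:
                raise PedigreeValidationError(f"duplicate id {r.id!r}")
            by_id[r.id] = r

        used_as_sire: set[str] = set()
        used_as_dam: set[str] = set()
        for r in records:
            if r.sire is not None:
                used_as_sire.add(r.sire)
            if r.dam is not None:
                used_as_dam.add(r.dam)
        conflict = used_as_sire & used_as_dam
        if conflict:
            an_id = sorted(conflict)[0]
            raise PedigreeValidationError(
                f"sex conflict: {an_id!r} is used both as sire and as dam"
            )

        # materialise referenced-but-undefined parents as UNKNOWN founders,
        # sex inferred from the slot they occupy
        out: list[PedigreeRecord] = []
        for pid in sorted(used_as_sire - set(by_id)):
            out.append(PedigreeRecord(pid, sex="male"))
        for pid in sorted(used_as_dam - set(by_id)):
            out.append(PedigreeRecord(pid, sex="female"))
        for pid in out:
            by_id[pid.id] = pid
        all_records = out + records

        # enforce parent-role sex where the record left it unknown
        fixed: dict[str, PedigreeRecord] = {}
        for r in all_records:
            want = "male" if r.id in used_as_sire else ("female" if r.id in used_as_dam else None)
            if want is not None:
                if r.sex not in ("unknown", want):
                    raise PedigreeValidationError(
                        f"sex conflict: {r.id!r} recorded as {r.sex} but used as "
                        f"{'sire' if want == 'male' else 'dam'}"
                    )
                if r.sex == "unknown":
                    r = replace(r, sex=want)
            fixed[r.id] = r

        ordered = _topological_sort(list(fixed.values()))
        return cls(ordered)

    # -- basic queries -----------------------------------------------------

    @property
    def records(self) -> tuple[PedigreeRecord, ...]:
        return tuple(self._records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, pid: str) -> bool:
        return pid in self._index

    def __getitem__(self, pid: str) -> PedigreeRecord:
        try:
            return self._records[self._index[pid]]
        except KeyError:
            raise PedigreeError(f"unknown individual {pid!r}") from None

    def index_of(self, pid: str) -> int:
        try:
            return self._index[pid]
        except KeyError:
            raise PedigreeError(f"unknown individual {pid!r}") from None

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(sire_idx, dam_idx) arrays in topological order; -1 = unknown."""
        return self._sire_idx, self._dam_idx

    def is_founder(self, pid: str, strict: bool = False) -> bool:
        """Founder status.

        ``strict=True``: both parents unknown.  ``strict=False`` (default, the
        convention used by the native-ancestry threshold): at least one parent
        unknown — a single unknown parent already breaks native traceability.
        """
        r = self[pid]
        if strict:
            return r.sire is None and r.dam is None
        return r.sire is None or r.dam is None

    def founders(self, strict: bool = False) -> tuple[str, ...]:
        return tuple(r.id for r in self._records if self.is_founder(r.id, strict=strict))

    def ancestor_closure(self, member_ids: Iterable[str]) -> tuple[str, ...]:
        """All members plus all their known ancestors, in topological order."""
        keep = np.zeros(len(self._records), dtype=bool)
        stack = [self.index_of(m) for m in member_ids]
        while stack:
            i = stack.pop()
            if keep[i]:
                continue
            keep[i] = True
            for p in (self._sire_idx[i], self._dam_idx[i]):
                if p >= 0 and not keep[p]:
                    stack.append(int(p))
        return tuple(self._records[i].id for i in np.nonzero(keep)[0])

    def subset(self, ids: Iterable[str]) -> "Pedigree":
        """Pedigree restricted to ``ids``; links to excluded parents dropped."""
        keep = set(ids)
        recs = []
        for r in self._records:
            if r.id not in keep:
                continue
            sire = r.sire if r.sire in keep else None
            dam = r.dam if r.dam in keep else None
            recs.append(replace(r, sire=sire, dam=dam))
        return Pedigree(recs)

    def breed_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self._records:
            out[r.breed] = out.get(r.breed, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Indiv": [r.id for r in self._records],
                "Sire": [r.sire or "" for r in self._records],
                "Dam": [r.dam or "" for r in self._records],
                "Sex": [r.sex for r in self._records],
                "Breed": [r.breed for r in self._records],
                "Born": [r.birth_year if r.birth_year is not None else "" for r in self._records],
            }
        )


def _topological_sort(records: list[PedigreeRecord]) -> list[PedigreeRecord]:
    """Kahn's algorithm with a heap on input position (stable, deterministic).

    Raises on parent-link cycles, naming one individual on the cycle.
    """
    pos = {r.id: i for i, r in enumerate(records)}
    children: dict[str, list[str]] = {r.id: [] for r in records}
    indeg = {r.id: 0 for r in records}
    for r in records:
        for p in (r.sire, r.dam):
            if p is not None:
                children[p].append(r.id)
                indeg[r.id] += 1
    heap = [pos[i] for i, d in indeg.items() if d == 0]
    heapq.heapify(heap)
    out: list[PedigreeRecord] = []
    while heap:
        i = heapq.heappop(heap)
        r = records[i]
        out.append(r)
        for c in children[r.id]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, pos[c])
    if len(out) != len(records):
        on_cycle = min(i for i, d in indeg.items() if d > 0)
        raise PedigreeValidationError(
            f"cycle through parent links involving individual {on_cycle!r}"
        )
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "id": "Indiv", "sire": "Sire", "dam": "Dam",
    "sex": "Sex", "breed": "Breed", "birth_year": "Born",
}


def _norm_token(tok: object) -> Optional[str]:
    if tok is None or (isinstance(tok, float) and np.isnan(tok)):
        return None
    s = str(tok).strip()
    if s.lower() in _MISSING_TOKENS:
        return None
    return s


def load_pedigree(
    source: str | Path | io.TextIOBase,
    column_map: Optional[Mapping[str, str]] = None,
    log: Optional[RunLog] = None,
) -> Pedigree:
    """Read a delimited registry file into a validated :class:`Pedigree`.

    The file must have a header row; the delimiter (comma or semicolon) is
    auto-detected.  ``column_map`` maps the logical names
    ``id, sire, dam, sex, breed, birth_year`` to file column names; the
    default expects ``Indiv,Sire,Dam,Sex,Breed,Born``.  Blank/``NA``/``0``
    parent fields are treated as unknown.
    """
    log = log or get_runlog()
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    first_line = text.splitlines()[0] if text else ""
    sep = ";" if first_line.count(";") > first_line.count(",") else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)

    missing_cols = [c for k, c in cols.items() if c not in df.columns and k in ("id", "sire", "dam")]
    if missing_cols:
        raise PedigreeValidationError(f"missing required columns: {missing_cols}")

    records = []
    n_missing_year = 0
    for _, row in df.iterrows():
        pid = _norm_token(row[cols["id"]])
        if pid is None:
            raise PedigreeValidationError("row with empty individual id")
        sex = "unknown"
        if cols["sex"] in df.columns:
            tok = _norm_token(row[cols["sex"]])
            if tok is not None:
                sex = _SEX_MAP.get(tok.lower(), "unknown")
        breed = UNKNOWN
        if cols["breed"] in df.columns:
            tok = _norm_token(row[cols["breed"]])
            if tok is not None:
                breed = tok.upper()
        year: Optional[int] = None
        if cols["birth_year"] in df.columns:
            tok = _norm_token(row[cols["birth_year"]])
            if tok is not None:
                year = int(float(tok))
        if year is None:
            n_missing_year += 1
        records.append(
            PedigreeRecord(
                id=pid,
                sire=_norm_token(row[cols["sire"]]),
                dam=_norm_token(row[cols["dam"]]),
                sex=sex,
                breed=breed,
                birth_year=year,
            )
        )
    ped = Pedigree.from_records(records)
    if n_missing_year:
        log.warn("missing_birth_years", count=n_missing_year)
    log.log("pedigree_loaded", n=len(ped), breeds=ped.breed_counts())
    return ped


def write_pedigree(ped: Pedigree, dest: str | Path | io.TextIOBase, sep: str = ",") -> None:
    """Write the standard ``Indiv,Sire,Dam,Sex,Breed,Born`` dialect (round-trippable)."""
    df = ped.to_frame()
    if isinstance(dest, (str, Path)):
        df.to_csv(dest, sep=sep, index=False, quoting=csv.QUOTE_MINIMAL)
    else:
        df.to_csv(dest, sep=sep, index=False, quoting=csv.QUOTE_MINIMAL)


# ---------------------------------------------------------------------------
# Breed-editing filters
# ---------------------------------------------------------------------------

def apply_last_native(
    ped: Pedigree, breed: str, last_native_year: int, log: Optional[RunLog] = None
) -> Pedigree:
    """Reassign late founders of ``breed`` to breed ``UNKNOWN``.

    Animals that enter the pedigree after the breed's founding phase without
    full parent information are not credible native founders; every founder
    (at least one unknown parent) of the given breed born *after*
    ``last_native_year`` has its breed set to ``UNKNOWN``.  Non-founders are
    untouched.  Idempotent.
    """
    log = log or get_runlog()
    changed = []
    recs = []
    for r in ped.records:
        if (
            r.breed == breed
            and (r.sire is None or r.dam is None)
            and r.birth_year is not None
            and r.birth_year > last_native_year
        ):
            recs.append(replace(r, breed=UNKNOWN))
            changed.append(r.id)
        else:
            recs.append(r)
    log.log("last_native_applied", breed=breed, threshold=last_native_year, reassigned=len(changed))
    return Pedigree(recs)


def correct_offspring_breed(ped: Pedigree, log: Optional[RunLog] = None) -> Pedigree:
    """Fix offspring recorded under a breed different from both parents'.

    Registries occasionally register kittens under a sister breed determined
    by a single visible trait (e.g. pointed, blue-eyed kittens out of two
    Oriental Shorthairs registered as Siamese).  Where both parents are known
    and share one breed (other than ``UNKNOWN``) the offspring's breed is set
    to the parents' breed.  Applied in topological order, so corrections
    cascade to later generations.  Idempotent.
    """
    log = log or get_runlog()
    breed_of: dict[str, str] = {}
    recs = []
    n = 0
    for r in ped.records:
        b = r.breed
        if r.sire is not None and r.dam is not None:
            bs, bd = breed_of[r.sire], breed_of[r.dam]
            if bs == bd and bs != UNKNOWN and b != bs:
                b = bs
                n += 1
        breed_of[r.id] = b
        recs.append(replace(r, breed=b) if b != r.breed else r)
    log.log("offspring_breed_corrected", corrected=n)
    return Pedigree(recs)


# ---------------------------------------------------------------------------
# Depth / completeness statistics
# ---------------------------------------------------------------------------

def _ecg_all(ped: Pedigree) -> np.ndarray:
    """Equivalent complete generations for every individual (topo order DP)."""
    sire, dam = ped.parent_indices()
    ecg = np.zeros(len(ped))
    for i in range(len(ped)):
        v = 0.0
        if sire[i] >= 0:
            v += 0.5 * (1.0 + ecg[sire[i]])
        if dam[i] >= 0:
            v += 0.5 * (1.0 + ecg[dam[i]])
        ecg[i] = v
    return ecg


def equivalent_complete_generations(ped: Pedigree, pid: str) -> float:
    """ECG = sum over known ancestors at generation g of (1/2)^g (parents g=1)."""
    return float(_ecg_all(ped)[ped.index_of(pid)])


def _known_slots(ped: Pedigree, pos: int, max_gen: int) -> np.ndarray:
    """Known ancestor slots of one individual per generation 1..max_gen.

    Slots are path-counted: a repeated ancestor fills every slot it occupies.
    """
    sire, dam = ped.parent_indices()
    # counts[g][i]: number of known ancestor paths of length g ending at i
    counts = np.zeros(max_gen)
    frontier: dict[int, int] = {pos: 1}
    for g in range(1, max_gen + 1):
        nxt: dict[int, int] = {}
        for i, mult in frontier.items():
            for p in (sire[i], dam[i]):
                if p >= 0:
                    nxt[int(p)] = nxt.get(int(p), 0) + mult
        counts[g - 1] = sum(nxt.values())
        frontier = nxt
        if not frontier:
            break
    return counts


def pedigree_completeness(ped: Pedigree, pop: Population, max_gen: int) -> CompletenessProfile:
    """Fraction of known ancestor slots per generation, averaged over a cohort."""
    if max_gen < 1:
        raise ValueError("max_gen must be >= 1")
    slot_sum = np.zeros(max_gen)
    ecgs = _ecg_all(ped)
    members = list(pop)
    if not members:
        raise EmptyPopulationError("empty population")
    for m in members:
        slot_sum += _known_slots(ped, ped.index_of(m), max_gen)
    denom = len(members) * (2.0 ** np.arange(1, max_gen + 1))
    frac = slot_sum / denom
    mean_ecg = float(np.mean([ecgs[ped.index_of(m)] for m in members]))
    return CompletenessProfile(tuple(frac), mean_ecg)


def ancestor_loss_coefficient(ped: Pedigree, pid: str, n_gen: int) -> float:
    """AVK: distinct known ancestors within ``n_gen`` over the maximum 2^(n+1)-2.

    1.0 means a complete, repeat-free pedigree window; lower values flag
    ancestor loss through missing records or repeated ancestors.
    """
    if n_gen < 1:
        raise ValueError("n_gen must be >= 1")
    sire, dam = ped.parent_indices()
    distinct: set[int] = set()
    frontier = {ped.index_of(pid)}
    for _ in range(n_gen):
        nxt: set[int] = set()
        for i in frontier:
            for p in (sire[i], dam[i]):
                if p >= 0:
                    nxt.add(int(p))
        distinct |= nxt
        frontier = nxt
        if not frontier:
            break
    return len(distinct) / (2 ** (n_gen + 1) - 2)


# ---------------------------------------------------------------------------
# Cohorts and demographic statistics
# ---------------------------------------------------------------------------

def breeding_cohort(ped: Pedigree, breed: str, years: tuple[int, int]) -> Population:
    """Parents of the kittens of ``breed`` born in the two-year window.

    A parent's own breed may differ (outcross parents are included); each
    parent counts once regardless of the number of litters.
    """
    y0, y1 = years
    if y1 != y0 + 1:
        raise ValueError("years must be two consecutive years (y, y+1)")
    members: list[str] = []
    seen: set[str] = set()
    found_kitten = False
    for r in ped.records:
        if r.breed != breed or r.birth_year is None or r.birth_year not in (y0, y1):
            continue
        found_kitten = True
        for p in (r.sire, r.dam):
            if p is not None and p not in seen:
                seen.add(p)
                members.append(p)
    if not found_kitten or not members:
        raise EmptyPopulationError(f"no {breed} kittens with known parents born in {y0}-{y1}")
    order = {pid: ped.index_of(pid) for pid in members}
    members.sort(key=order.__getitem__)
    return Population(tuple(members), label=f"{breed} {y0}-{y1}")


def filter_min_ecg(
    ped: Pedigree, pop: Population, min_ecg: float = 3.0, log: Optional[RunLog] = None
) -> Population:
    """Drop members with fewer than ``min_ecg`` equivalent complete generations.

    Individuals with shallow pedigrees bias kinship downwards; the exclusion
    is strict (``ecg < min_ecg`` removed, equality retained).  Idempotent.
    """
    log = log or get_runlog()
    ecgs = _ecg_all(ped)
    kept, removed = [], []
    for m in pop:
        (kept if ecgs[ped.index_of(m)] >= min_ecg else removed).append(m)
    log.log("ecg_filter", min_ecg=min_ecg, removed=removed, n_kept=len(kept))
    if not kept:
        raise EmptyPopulationError(f"ECG filter at {min_ecg} removed every member of {pop.label!r}")
    return Population(tuple(kept), label=pop.label)


def unknown_parentage_fraction(ped: Pedigree) -> float:
    """Unknown parent slots over all 2N slots."""
    if len(ped) == 0:
        raise PedigreeError("empty pedigree")
    sire, dam = ped.parent_indices()
    return float(((sire < 0).sum() + (dam < 0).sum()) / (2 * len(ped)))


def demographic_counts(ped: Pedigree, breed: str, years: tuple[int, int]) -> pd.DataFrame:
    """Per calendar year: kittens of ``breed`` born, and unique parents of those kittens."""
    y0, y1 = years
    rows = []
    for y in range(y0, y1 + 1):
        kittens = 0
        parents: set[str] = set()
        for r in ped.records:
            if r.breed == breed and r.birth_year == y:
                kittens += 1
                for p in (r.sire, r.dam):
                    if p is not None:
                        parents.add(p)
        rows.append({"year": y, "kittens": kittens, "breeding_individuals": len(parents)})
    return pd.DataFrame(rows).set_index("year")
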