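"""Registry-like synthetic pedigree generator.

Emulates the structure that the analysis modules assume about real cat
registry data: multiple breeds with overlapping generations (breeding
animals stay candidates for several years), regional subpopulations with
little cross-relationship, an introgression/founding event in which one
breed is built partly from another, configurable line-breeding versus
outcrossing propensity, missing parentage (default 9% of recordable parent
slots) and litter structure (Poisson litter sizes, mean 4.2, truncated at 1).

Everything is driven by a :class:`SimConfig` and a single seed; the same
seed reproduces the same pedigree bit for bit.  Alongside the emitted
pedigree (with parent links deleted at the missing-parentage rate) a *truth
sidecar* records each individual's region, true parents and foreign-ancestry
flag, for supervised validation of clustering and native-ancestry code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeRecord


class SimulationError(Exception):
    pass


@dataclass(frozen=True)
class BreedConfig:
    """One simulated breed: founder pool, founding year, breeding window."""

    code: str
    n_founders: int
    founding_year: int
    region_split: Optional[tuple[float, ...]] = None  # founder share per region
    active_until: Optional[int] = None  # last breeding year (None = sim end)
    recruits_per_year: Optional[int] = None  # per region; None = per-kitten rate

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("each breed needs at least 2 founders")


@dataclass(frozen=True)
class Introgression:
    """Cross-breed matings building ``target_breed`` partly from ``source_breed``."""

    source_breed: str
    target_breed: str
    fraction: float
    year: int
    duration: int = 5


@dataclass(frozen=True)
class SimConfig:
    breeds: tuple[BreedConfig, ...]
    years: tuple[int, int]
    seed: int = 0
    n_regions: int = 1
    migration_rate: float = 0.0
    #: "random" | "outcross" | "line_breed", one value or one per region
    mating_mode: str | tuple[str, ...] = "random"
    #: line-breeding propensity, one value or one per region
    p_line: float | tuple[float, ...] = 0.8
    outcross_depth: int = 2
    introgression: Optional[Introgression] = None
    litter_size_mean: float = 4.2
    missing_parent_rate: float = 0.09
    sex_ratio: float = 0.5
    candidates_per_litter: float = 1.6
    max_breeding_years: int = 6

    def mode_of(self, region: int) -> str:
        m = self.mating_mode
        return m[region] if isinstance(m, tuple) else m

    def p_line_of(self, region: int) -> float:
        p = self.p_line
        return p[region] if isinstance(p, tuple) else p

    def __post_init__(self) -> None:
        p_lines = self.p_line if isinstance(self.p_line, tuple) else (self.p_line,)
        for p in (self.migration_rate, self.missing_parent_rate, self.sex_ratio, *p_lines):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for m in (self.mating_mode if isinstance(self.mating_mode, tuple) else (self.mating_mode,)):
            if m not in ("random", "outcross", "line_breed"):
                raise ValueError(f"unknown mating mode {m!r}")
        if self.introgression is not None and not 0.0 <= self.introgression.fraction <= 1.0:
            raise ValueError("introgression fraction must lie in [0, 1]")


@dataclass
class _Ind:
    id: str
    sire: Optional[str]
    dam: Optional[str]
    sex: str
    breed: str
    birth_year: int
    region: int
    mask_sire: bool = False
    mask_dam: bool = False
    foreign: bool = False  # carries ancestry from another breed


@dataclass(frozen=True)
class SimResult:
    pedigree: Pedigree  # as emitted (masked parent links)
    truth: pd.DataFrame  # id-indexed: region, breed, sex, born, true parents, foreign


class _IncrementalKinship:
    """Tabular kinship maintained online over the active breeding stock.

    A child's row is derived from its parents' rows at recruitment time, so
    retired animals can be dropped without losing information needed later.
    """

    def __init__(self, capacity: int = 256) -> None:
        self.f = np.zeros((capacity, capacity))
        self.slot: dict[str, int] = {}
        self.free: list[int] = list(range(capacity - 1, -1, -1))

    def _grow(self) -> None:
        old = self.f.shape[0]
        new = np.zeros((old * 2, old * 2))
        new[:old, :old] = self.f
        self.f = new
        self.free.extend(range(old * 2 - 1, old - 1, -1))

    def _take(self, pid: str) -> int:
        if not self.free:
            self._grow()
        s = self.free.pop()
        self.f[s, :] = 0.0
        self.f[:, s] = 0.0
        self.slot[pid] = s
        return s

    def add_founder(self, pid: str) -> None:
        s = self._take(pid)
        self.f[s, s] = 0.5

    def add_child(self, pid: str, sire: str, dam: str) -> None:
        s = self._take(pid)  # may grow the matrix, so take the slot first
        si, di = self.slot[sire], self.slot[dam]
        row = 0.5 * (self.f[si, :] + self.f[di, :])
        f_sd = self.f[si, di]
        self.f[s, :] = row
        self.f[:, s] = row
        self.f[s, s] = 0.5 * (1.0 + f_sd)

    def kinship(self, a: str, b: str) -> float:
        return float(self.f[self.slot[a], self.slot[b]])

    def drop(self, pid: str) -> None:
        s = self.slot.pop(pid)
        self.f[s, :] = 0.0
        self.f[:, s] = 0.0
        self.free.append(s)


def _trunc_poisson(rng: np.random.Generator, mean: float) -> int:
    """Poisson(mean) truncated to >= 1 (resampling the zero class)."""
    for _ in range(1000):
        v = rng.poisson(mean)
        if v >= 1:
            return int(v)
    return 1


def simulate(config: SimConfig) -> SimResult:
    """Generate an overlapping-generation pedigree year by year.

    Raises :class:`SimulationError` naming the year if an active breed with
    breeding candidates cannot form a single pair.
    """
    rng = np.random.default_rng(config.seed)
    inds: dict[str, _Ind] = {}
    order: list[str] = []
    kin = _IncrementalKinship()
    # candidate pool: (breed, region) -> list of ids currently able to breed
    candidates: dict[tuple[str, int], list[str]] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:06d}"

    def region_split(bc: BreedConfig) -> list[int]:
        if bc.region_split is not None:
            probs = np.asarray(bc.region_split, dtype=float)
            if len(probs) != config.n_regions or probs.sum() <= 0:
                raise ValueError("region_split must give one share per region")
            probs = probs / probs.sum()
        else:
            probs = np.full(config.n_regions, 1.0 / config.n_regions)
        counts = rng.multinomial(bc.n_founders, probs)
        out: list[int] = []
        for r, c in enumerate(counts):
            out.extend([r] * int(c))
        return out

    def add_individual(ind: _Ind) -> None:
        inds[ind.id] = ind
        order.append(ind.id)

    # founders
    for bc in config.breeds:
        regions = region_split(bc)
        for j, r in enumerate(regions):
            ind = _Ind(
                id=new_id(), sire=None, dam=None,
                sex="male" if j % 2 == 0 else "female",
                breed=bc.code, birth_year=bc.founding_year, region=r,
            )
            add_individual(ind)
            kin.add_founder(ind.id)
            candidates.setdefault((bc.code, r), []).append(ind.id)

    def shares_ancestor(a: str, b: str, depth: int) -> bool:
        def anc(x: str) -> set[str]:
            out = {x}
            frontier = {x}
            for _ in range(depth):
                nxt = set()
                for i in frontier:
                    for p in (inds[i].sire, inds[i].dam):
                        if p is not None:
                            nxt.add(p)
                out |= nxt
                frontier = nxt
            return out

        return bool(anc(a) & anc(b))

    y0, y1 = config.years
    for year in range(y0 + 1, y1 + 1):
        # age out retired breeders
        for key, pool in candidates.items():
            keep = [
                i for i in pool
                if year - inds[i].birth_year <= config.max_breeding_years
            ]
            for i in pool:
                if i not in keep:
                    kin.drop(i)
            candidates[key] = keep

        newborns_by_key: dict[tuple[str, int], list[str]] = {}
        for bc in config.breeds:
            if year <= bc.founding_year:
                continue
            if bc.active_until is not None and year > bc.active_until:
                continue
            breed_pairs = 0
            intro = config.introgression
            intro_active = (
                intro is not None
                and intro.target_breed == bc.code
                and intro.year <= year < intro.year + intro.duration
            )
            for r in range(config.n_regions):
                pool = candidates.get((bc.code, r), [])
                females = [i for i in pool if inds[i].sex == "female"]
                males = [i for i in pool if inds[i].sex == "male"]
                rng.shuffle(females)
                rng.shuffle(males)
                n_pairs = min(len(females), len(males))
                for idx in range(n_pairs):
                    dam = females[idx]
                    sire = males[idx]
                    # cross-breed founding event takes precedence
                    if intro_active and rng.random() < intro.fraction:
                        src = [
                            i
                            for rr in range(config.n_regions)
                            for i in candidates.get((intro.source_breed, rr), [])
                            if inds[i].sex == "male"
                        ]
                        if src:
                            sire = src[rng.integers(0, len(src))]
                    elif config.migration_rate > 0 and rng.random() < config.migration_rate:
                        other = [
                            i
                            for rr in range(config.n_regions)
                            if rr != r
                            for i in candidates.get((bc.code, rr), [])
                            if inds[i].sex == "male"
                        ]
                        if other:
                            sire = other[rng.integers(0, len(other))]
                    elif config.mode_of(r) == "outcross":
                        tries = 0
                        pool_m = males.copy()
                        while (
                            shares_ancestor(sire, dam, config.outcross_depth)
                            and tries < 20
                            and pool_m
                        ):
                            sire = pool_m[rng.integers(0, len(pool_m))]
                            tries += 1
                    elif config.mode_of(r) == "line_breed" and rng.random() < config.p_line_of(r):
                        related = [
                            m for m in males if kin.kinship(m, dam) >= 0.125 and m != dam
                        ]
                        if related:
                            sire = related[rng.integers(0, len(related))]
                    breed_pairs += 1
                    litter = _trunc_poisson(rng, config.litter_size_mean)
                    for _ in range(litter):
                        kid = _Ind(
                            id=new_id(),
                            sire=sire,
                            dam=dam,
                            sex="male" if rng.random() < config.sex_ratio else "female",
                            breed=bc.code,
                            birth_year=year,
                            region=r,
                            mask_sire=rng.random() < config.missing_parent_rate,
                            mask_dam=rng.random() < config.missing_parent_rate,
                            foreign=(
                                inds[sire].breed != bc.code
                                or inds[dam].breed != bc.code
                                or inds[sire].foreign
                                or inds[dam].foreign
                            ),
                        )
                        add_individual(kid)
                        newborns_by_key.setdefault((bc.code, r), []).append(kid.id)
            if breed_pairs == 0:
                raise SimulationError(
                    f"no breeding pairs for breed {bc.code} in year {year}"
                )

        # recruitment of breeding candidates
        for bc in config.breeds:
            for r in range(config.n_regions):
                born = newborns_by_key.get((bc.code, r), [])
                if not born:
                    continue
                if bc.recruits_per_year is not None:
                    k = min(bc.recruits_per_year, len(born))
                    chosen = list(rng.choice(born, size=k, replace=False))
                else:
                    p = min(1.0, config.candidates_per_litter / config.litter_size_mean)
                    chosen = [i for i in born if rng.random() < p]
                for cid in chosen:
                    kin.add_child(cid, inds[cid].sire, inds[cid].dam)
                    candidates.setdefault((bc.code, r), []).append(cid)

    # emit pedigree with masked parent links
    records = []
    truth_rows = []
    for pid in order:
        ind = inds[pid]
        records.append(
            PedigreeRecord(
                id=ind.id,
                sire=None if ind.mask_sire else ind.sire,
                dam=None if ind.mask_dam else ind.dam,
                sex=ind.sex,
                breed=ind.breed,
                birth_year=ind.birth_year,
            )
        )
        truth_rows.append(
            {
                "id": ind.id, "region": ind.region, "breed": ind.breed,
                "sex": ind.sex, "born": ind.birth_year,
                "true_sire": ind.sire, "true_dam": ind.dam,
                "foreign_ancestry": ind.foreign,
            }
        )
    ped = Pedigree.from_records(records)
    truth = pd.DataFrame(truth_rows).set_index("id")
    return SimResult(ped, truth)


def scenario_presets() -> dict[str, SimConfig]:
    """Named study-condition scenarios.

    * ``thai_like`` — four weakly connected regions, outcrossing, and a
      founding phase in which roughly half of the matings draw a sire from a
      separate ``SIA`` pool (the introgression event), so current animals
      carry sizeable foreign contributions;
    * ``siamese_like`` — a single region with a strong line-breeding
      propensity, producing high inbreeding and mean kinship;
    * ``flat`` — a random-mating single-region control with full parentage
      recording.
    """
    return {
        "thai_like": SimConfig(
            breeds=(
                BreedConfig("SIA", 30, 1985, region_split=(1, 0, 0, 0),
                            active_until=2002, recruits_per_year=14),
                BreedConfig("THA", 40, 1995, recruits_per_year=6),
            ),
            years=(1985, 2017),
            n_regions=4,
            migration_rate=0.02,
            # regional breeding cultures differ: one strict outcrossing
            # region, one random, two line-breeding with different intensity
            mating_mode=("outcross", "random", "line_breed", "line_breed"),
            p_line=(0.0, 0.0, 0.5, 0.9),
            introgression=Introgression("SIA", "THA", fraction=0.5, year=1996, duration=4),
            seed=0,
        ),
        "siamese_like": SimConfig(
            breeds=(BreedConfig("SIA", 20, 1980, recruits_per_year=16),),
            years=(1980, 1999),
            n_regions=1,
            mating_mode="line_breed",
            p_line=0.8,
            seed=0,
        ),
        "flat": SimConfig(
            breeds=(BreedConfig("THA", 60, 2000, recruits_per_year=40),),
            years=(2000, 2019),
            n_regions=1,
            mating_mode="random",
            missing_parent_rate=0.0,
            max_breeding_years=4,
            seed=0,
        ),
    }
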