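"""Shared fixtures: tiny hand-built pedigrees, a random-pedigree factory and
independent oracles (recursive kinship, naive UPGMA, active-set OCS)."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pedkin import Pedigree, PedigreeRecord


def make_random_pedigree(rng: np.random.Generator, n: int, p_founder: float = 0.3,
                         breeds=("THA", "SIA")) -> Pedigree:
    """Random valid pedigree: new individuals are founders or pick earlier parents."""
    recs = [
        PedigreeRecord("m0", sex="male", breed=breeds[0], birth_year=2000),
        PedigreeRecord("f0", sex="female", breed=breeds[-1], birth_year=2000),
    ]
    males, females = ["m0"], ["f0"]
    for i in range(2, n):
        sex = "male" if rng.random() < 0.5 else "female"
        pid = ("m" if sex == "male" else "f") + str(i)
        if rng.random() < p_founder:
            recs.append(
                PedigreeRecord(pid, sex=sex, breed=str(rng.choice(breeds)),
                               birth_year=2000 + i)
            )
        else:
            recs.append(
                PedigreeRecord(pid, str(rng.choice(males)), str(rng.choice(females)),
                               sex=sex, breed=breeds[0], birth_year=2000 + i)
            )
        (males if sex == "male" else females).append(pid)
    return Pedigree.from_records(recs)


def recursive_kinship(ped: Pedigree, a: str, b: str, memo=None) -> float:
    """Top-down recursive definition of kinship (independent of the tabular code)."""
    if memo is None:
        memo = {}

    def f(i: str, j: str) -> float:
        ii, jj = ped.index_of(i), ped.index_of(j)
        if ii > jj:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            r = ped[i]
            v = 0.5 * (1.0 + (f(r.sire, r.dam) if r.sire and r.dam else 0.0))
        else:
            r = ped[j]  # the later individual; its parents precede it
            v = 0.0
            if r.sire:
                v += 0.5 * f(i, r.sire)
            if r.dam:
                v += 0.5 * f(i, r.dam)
        memo[key] = v
        return v

    return f(a, b)


def upgma_heights_naive(X: np.ndarray) -> list[float]:
    """O(n^3) average-linkage merge heights from the raw pairwise distances."""
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = float(np.mean([D[i, j] for i in clusters[a] for j in clusters[b]]))
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return heights


def ocs_active_set_oracle(M: np.ndarray, male: np.ndarray) -> tuple[float, np.ndarray]:
    """Brute-force OCS: enumerate every active set of the c >= 0 constraints.

    For each subset of coordinates pinned to zero, solve the
    equality-constrained QP (sex sums = 0.5) through its KKT system and keep
    the best feasible solution.
    """
    n = M.shape[0]
    A = np.vstack([male.astype(float), (~male).astype(float)])
    b = np.array([0.5, 0.5])
    best = None
    for r in range(n):
        for zero in itertools.combinations(range(n), r):
            free = [i for i in range(n) if i not in zero]
            Af = A[:, free]
            Mf = M[np.ix_(free, free)]
            K = np.block([
                [2.0 * Mf, Af.T],
                [Af, np.zeros((2, 2))],
            ])
            rhs = np.concatenate([np.zeros(len(free)), b])
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                continue
            c = np.zeros(n)
            c[free] = sol[: len(free)]
            if np.any(c < -1e-9):
                continue
            if abs(c[male].sum() - 0.5) > 1e-8 or abs(c[~male].sum() - 0.5) > 1e-8:
                continue
            val = float(c @ M @ c)
            if best is None or val < best[0]:
                best = (val, c)
    assert best is not None
    return best


@pytest.fixture
def trio() -> Pedigree:
    """Two unrelated founders and one offspring."""
    return Pedigree.from_records([
        PedigreeRecord("s", sex="male", breed="THA", birth_year=2000),
        PedigreeRecord("d", sex="female", breed="THA", birth_year=2000),
        PedigreeRecord("c", "s", "d", sex="male", breed="THA", birth_year=2002),
    ])


@pytest.fixture
def fullsib_mating() -> Pedigree:
    """Founders -> full sibs -> their offspring (F = 0.25)."""
    return Pedigree.from_records([
        PedigreeRecord("gs", sex="male", breed="THA", birth_year=2000),
        PedigreeRecord("gd", sex="female", breed="THA", birth_year=2000),
        PedigreeRecord("b", "gs", "gd", sex="male", breed="THA", birth_year=2002),
        PedigreeRecord("z", "gs", "gd", sex="female", breed="THA", birth_year=2002),
        PedigreeRecord("x", "b", "z", sex="male", breed="THA", birth_year=2004),
    ])
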