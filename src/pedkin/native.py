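"""Breed composition and kinship at native alleles.

When a breed has been built partly from other breeds, plain gene diversity
overstates how much of the *original* gene pool survives.  The remedy is to
condition on ancestry: an allele is *native* if it descends from a founder of
the native breed (after the lastNative reassignment, so late, undocumented
founders do not count).  Two quantities are tracked per pair (i, j):

* ``fN_ij`` — probability that two randomly drawn alleles (one from i, one
  from j) are IBD *and* both native;
* ``Q_ij`` — probability that both drawn alleles are native.

Their population means give the conditional gene diversity
``condGD = 1 − mean(fN)/mean(Q)`` and the native genome equivalents
``NGE = 1/(2(1 − condGD))`` — the number of unrelated native founders with
the same conditional diversity.

Both matrices are computed by a native-extended tabular recursion (the
deterministic, primary path); a Mendelian gene-dropping simulator provides an
independent Monte-Carlo estimate used for validation.  Diagonals use
two-draws-with-replacement semantics so that population means stay consistent
with the all-ordered-pairs convention of the plain kinship statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinship import KinshipMatrix
from .pedigree import Pedigree, PedigreeError, Population, UNKNOWN


class NoNativeAncestryError(PedigreeError):
    pass


@dataclass(frozen=True)
class NativeKinship:
    """Paired matrices fN (IBD and both native) and Q (both native)."""

    ids: tuple[str, ...]
    fN: np.ndarray
    Q: np.ndarray
    native_contribution: np.ndarray  # n_i per member
    native_breed: str

    def restrict(self, ids: list[str] | tuple[str, ...]) -> "NativeKinship":
        pos = {m: i for i, m in enumerate(self.ids)}
        idx = np.array([pos[m] for m in ids], dtype=np.int64)
        return NativeKinship(
            tuple(ids),
            self.fN[np.ix_(idx, idx)],
            self.Q[np.ix_(idx, idx)],
            self.native_contribution[idx],
            self.native_breed,
        )


@dataclass(frozen=True)
class NativeDiversityStats:
    cond_gd: float
    nge: float


@dataclass(frozen=True)
class GeneDropResult:
    """Monte-Carlo estimates of f, fN and Q with binomial standard errors."""

    ids: tuple[str, ...]
    f: np.ndarray
    fN: np.ndarray
    Q: np.ndarray
    reps: int

    def se(self, which: str = "f") -> np.ndarray:
        p = getattr(self, which)
        return np.sqrt(np.clip(p * (1.0 - p), 0.0, None) / self.reps)


# ---------------------------------------------------------------------------
# Breed composition
# ---------------------------------------------------------------------------

def breed_composition(ped: Pedigree, pop: Population | None = None) -> pd.DataFrame:
    """Expected genomic contribution of each founder breed per individual.

    A founder (both parents unknown) contributes unit mass to its own breed;
    every other individual averages its parents' compositions, an unknown
    parent counting as unit mass on ``UNKNOWN``.  Rows sum to 1.  Apply the
    lastNative reassignment first if native traceability matters.
    """
    breeds = sorted({r.breed for r in ped.records} | {UNKNOWN})
    col = {b: j for j, b in enumerate(breeds)}
    sire, dam = ped.parent_indices()
    comp = np.zeros((len(ped), len(breeds)))
    for i, r in enumerate(ped.records):
        if sire[i] < 0 and dam[i] < 0:
            comp[i, col[r.breed]] = 1.0
        else:
            v = np.zeros(len(breeds))
            for p in (sire[i], dam[i]):
                if p >= 0:
                    v += 0.5 * comp[p]
                else:
                    v[col[UNKNOWN]] += 0.5
            comp[i] = v
    ids = list(ped.ids)
    df = pd.DataFrame(comp, index=ids, columns=breeds)
    if pop is not None:
        df = df.loc[list(pop)]
    return df


def breed_contribution_history(
    ped: Pedigree, breed: str, years: tuple[int, int], step: int = 2
) -> pd.DataFrame:
    """Population-average breed composition per two-year breeding cohort."""
    from .pedigree import EmptyPopulationError, breeding_cohort

    comp = breed_composition(ped)
    rows = []
    y0, y1 = years
    for y in range(y0, y1, step):
        try:
            pop = breeding_cohort(ped, breed, (y, y + 1))
        except EmptyPopulationError:
            continue
        mean = comp.loc[list(pop)].mean(axis=0)
        mean["year_start"] = y
        rows.append(mean)
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows).set_index("year_start")


# ---------------------------------------------------------------------------
# Native kinship (deterministic recursion)
# ---------------------------------------------------------------------------

def native_kinship(ped: Pedigree, pop: Population, native_breed: str) -> NativeKinship:
    """Native-extended tabular method over the cohort's full ancestry.

    Founder bases (δ = 1 if the founder's breed is the native breed):
    ``fN_kk = δ/2``, ``Q_kk = δ``, ``fN_kl = 0`` and ``Q_kl = δ_k δ_l`` for
    distinct founders.  Non-founders follow the same averaging recursion as
    plain kinship, with diagonals ``fN_ii = (n_i + fN_{s,d})/2`` and
    ``Q_ii = (n_i + Q_{s,d})/2`` where n_i is i's native contribution; an
    unknown parent contributes 0 everywhere (its alleles are non-native and
    IBD with nothing).
    """
    members = tuple(pop)
    closure = ped.ancestor_closure(members)
    sub = {pid: i for i, pid in enumerate(closure)}
    all_ids = ped.ids
    sire_full, dam_full = ped.parent_indices()
    n = len(closure)
    fN = np.zeros((n, n))
    Q = np.zeros((n, n))
    nat = np.zeros(n)  # native contribution n_i
    founder_native = []
    for i, pid in enumerate(closure):
        gi = ped.index_of(pid)
        s, d = sire_full[gi], dam_full[gi]
        si = sub[all_ids[s]] if s >= 0 else -1
        di = sub[all_ids[d]] if d >= 0 else -1
        if si < 0 and di < 0:
            delta = 1.0 if ped.records[gi].breed == native_breed else 0.0
            founder_native.append(delta)
            nat[i] = delta
            if i > 0:
                # a new founder is unrelated to everything earlier: fN stays 0
                # and the two allele draws are independent, so Q_ij = δ_i n_j
                # (for an earlier founder j, n_j is its δ).
                Q[i, :i] = delta * nat[:i]
                Q[:i, i] = Q[i, :i]
            fN[i, i] = 0.5 * delta
            Q[i, i] = delta
        else:
            nat[i] = sum(0.5 * nat[p] for p in (si, di) if p >= 0)
            if i > 0:
                rfN = np.zeros(i)
                rQ = np.zeros(i)
                for p in (si, di):
                    if p >= 0:
                        rfN += 0.5 * fN[p, :i]
                        rQ += 0.5 * Q[p, :i]
                fN[i, :i] = rfN
                fN[:i, i] = rfN
                Q[i, :i] = rQ
                Q[:i, i] = rQ
            cross_fN = fN[si, di] if si >= 0 and di >= 0 else 0.0
            cross_Q = Q[si, di] if si >= 0 and di >= 0 else 0.0
            fN[i, i] = 0.5 * (nat[i] + cross_fN)
            Q[i, i] = 0.5 * (nat[i] + cross_Q)
    if not any(founder_native):
        raise NoNativeAncestryError(
            f"no {native_breed} founder in the ancestry of {pop.label!r}"
        )
    idx = np.array([sub[m] for m in members], dtype=np.int64)
    return NativeKinship(
        members,
        fN[np.ix_(idx, idx)],
        Q[np.ix_(idx, idx)],
        nat[idx],
        native_breed,
    )


def native_diversity(NK: NativeKinship) -> NativeDiversityStats:
    """condGD and NGE from the population means of fN and Q (all ordered pairs)."""
    mean_q = float(NK.Q.mean())
    if mean_q <= 0:
        raise NoNativeAncestryError("mean native probability Q is zero; condGD undefined")
    mean_fn = float(NK.fN.mean())
    cond_gd = 1.0 - mean_fn / mean_q
    nge = mean_q / (2.0 * mean_fn) if mean_fn > 0 else np.inf
    return NativeDiversityStats(cond_gd=cond_gd, nge=nge)


# ---------------------------------------------------------------------------
# Gene dropping (Monte-Carlo oracle)
# ---------------------------------------------------------------------------

def gene_dropping(
    ped: Pedigree,
    pop: Population,
    native_breed: str,
    reps: int = 10_000,
    seed: int | None = None,
) -> GeneDropResult:
    """Mendelian gene dropping over the cohort ancestry.

    Each founder receives two unique labelled alleles tagged native when the
    founder's breed matches; an unknown parent contributes a unique
    non-native allele.  Alleles transmit Mendelianly per replicate.  f, fN
    and Q are estimated from one random allele draw per individual per
    replicate (two independent draws for diagonals, i.e. with replacement).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    members = tuple(pop)
    closure = ped.ancestor_closure(members)
    sub = {pid: i for i, pid in enumerate(closure)}
    all_ids = ped.ids
    sire_full, dam_full = ped.parent_indices()
    n = len(closure)

    lab = np.empty((reps, n, 2), dtype=np.int64)
    nat = np.empty((reps, n, 2), dtype=bool)
    next_label = 0
    for i, pid in enumerate(closure):
        gi = ped.index_of(pid)
        s, d = sire_full[gi], dam_full[gi]
        si = sub[all_ids[s]] if s >= 0 else -1
        di = sub[all_ids[d]] if d >= 0 else -1
        for slot, p in ((0, si), (1, di)):
            if p < 0:
                is_founder_slot_native = (
                    si < 0 and di < 0 and ped.records[gi].breed == native_breed
                )
                lab[:, i, slot] = next_label
                nat[:, i, slot] = is_founder_slot_native
                next_label += 1
            else:
                c = rng.integers(0, 2, size=reps)
                lab[:, i, slot] = np.take_along_axis(
                    lab[:, p, :], c[:, None], axis=1
                )[:, 0]
                nat[:, i, slot] = np.take_along_axis(
                    nat[:, p, :], c[:, None], axis=1
                )[:, 0]

    midx = np.array([sub[m] for m in members], dtype=np.int64)
    m = len(midx)
    c1 = rng.integers(0, 2, size=(reps, m))
    c2 = rng.integers(0, 2, size=(reps, m))
    a1 = np.take_along_axis(lab[:, midx, :], c1[:, :, None], axis=2)[:, :, 0]
    a2 = np.take_along_axis(lab[:, midx, :], c2[:, :, None], axis=2)[:, :, 0]
    n1 = np.take_along_axis(nat[:, midx, :], c1[:, :, None], axis=2)[:, :, 0]
    n2 = np.take_along_axis(nat[:, midx, :], c2[:, :, None], axis=2)[:, :, 0]

    # Off-diagonals average the two independent draw-pairs (a1 vs a1, a2 vs
    # a2) per replicate, so the quoted binomial SE is a conservative bound.
    f_sum = np.zeros((m, m))
    fn_sum = np.zeros((m, m))
    q_sum = np.zeros((m, m))
    chunk = max(1, int(4e6 // max(m * m, 1)))
    for lo in range(0, reps, chunk):
        hi = min(lo + chunk, reps)
        for a, nn in ((a1, n1), (a2, n2)):
            eq = a[lo:hi, :, None] == a[lo:hi, None, :]
            both_nat = nn[lo:hi, :, None] & nn[lo:hi, None, :]
            f_sum += 0.5 * eq.sum(axis=0)
            fn_sum += 0.5 * (eq & both_nat).sum(axis=0)
            q_sum += 0.5 * both_nat.sum(axis=0)
    # diagonals: two independent with-replacement draws
    eq_d = a1 == a2
    nat_d = n1 & n2
    np.fill_diagonal(f_sum, eq_d.sum(axis=0))
    np.fill_diagonal(fn_sum, (eq_d & nat_d).sum(axis=0))
    np.fill_diagonal(q_sum, nat_d.sum(axis=0))

    return GeneDropResult(members, f_sum / reps, fn_sum / reps, q_sum / reps, reps)


def native_from_kinship(K: KinshipMatrix) -> NativeKinship:
    """Degenerate all-native view of a plain kinship matrix (fN = f, Q = 1)."""
    n = len(K.ids)
    return NativeKinship(K.ids, K.f.copy(), np.ones((n, n)), np.ones(n), "ALL")
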