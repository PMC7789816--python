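"""Pairwise kinship by the tabular method and derived diversity statistics.

The kinship coefficient f_ij is the probability that one allele drawn at
random from individual i and one from j are identical by descent.  The
tabular method builds the full matrix in one topological pass over the
ancestry of the cohort — all known ancestors back to the founders, never a
fixed-depth window, because truncated pedigrees systematically underestimate
kinship.

Derived statistics:

* mean kinship of an individual, ``mk_i = (1/N) Σ_j f_ij`` (self included);
* population mean kinship ``mk̄ = (1/N²) Σ_ij f_ij`` — the probability that
  two alleles drawn at random from the population are IBD;
* gene diversity ``GD = 1 − mk̄``;
* founder genome equivalents ``FGE = 1/(2·mk̄)`` — the number of unrelated
  founders that would carry the same gene diversity;
* inbreeding ``F_i = 2·f_ii − 1`` and its population mean F̄.

Note that mk̄ averages over all N² ordered pairs *including* self-kinships;
some tools exclude the diagonal, which changes FGE for small cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .pedigree import Pedigree, Population
from .runlog import RunLog, get_runlog


@dataclass(frozen=True)
class KinshipMatrix:
    """Symmetric pairwise kinship over an ordered member list."""

    ids: tuple[str, ...]
    f: np.ndarray  # (n, n) float64

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.f.shape != (n, n):
            raise ValueError("kinship matrix shape does not match id list")

    def restrict(self, ids: list[str] | tuple[str, ...]) -> "KinshipMatrix":
        """Submatrix for a subset of members (kinship is pairwise-intrinsic)."""
        pos = {m: i for i, m in enumerate(self.ids)}
        idx = np.array([pos[m] for m in ids], dtype=np.int64)
        return KinshipMatrix(tuple(ids), self.f[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.f, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class DiversityStats:
    """Population-level diversity summary derived from a kinship matrix."""

    mk_bar: float
    gd: float
    fge: float
    f_bar: float
    mk_i: np.ndarray  # per-individual mean kinship, order = KinshipMatrix.ids


@dataclass(frozen=True)
class KinshipHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    zero_bin_removed: bool
    overflow: int  # values beyond the top edge


def _closure_kinship(ped: Pedigree, member_ids: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Full tabular kinship over the ancestry closure of the members.

    Returns (closure matrix, index of each member within the closure).
    Founders: f_kk = 0.5, distinct founders unrelated.  Unknown parents
    contribute 0 (they are treated as unique, unrelated founders).
    """
    closure = ped.ancestor_closure(member_ids)
    sub = {pid: i for i, pid in enumerate(closure)}
    n = len(closure)
    all_ids = ped.ids
    sire_full, dam_full = ped.parent_indices()
    F = np.zeros((n, n))
    for i, pid in enumerate(closure):
        gi = ped.index_of(pid)
        s = sire_full[gi]
        d = dam_full[gi]
        si = sub[all_ids[s]] if s >= 0 else -1
        di = sub[all_ids[d]] if d >= 0 else -1
        if i > 0:
            row = np.zeros(i)
            if si >= 0:
                row += 0.5 * F[si, :i]
            if di >= 0:
                row += 0.5 * F[di, :i]
            F[i, :i] = row
            F[:i, i] = row
        F[i, i] = 0.5 * (1.0 + (F[si, di] if si >= 0 and di >= 0 else 0.0))
    member_idx = np.array([sub[m] for m in member_ids], dtype=np.int64)
    return F, member_idx


def kinship_matrix(ped: Pedigree, pop: Population) -> KinshipMatrix:
    """Tabular-method kinship restricted to the cohort, using full ancestry."""
    members = tuple(pop)
    F, idx = _closure_kinship(ped, members)
    return KinshipMatrix(members, F[np.ix_(idx, idx)])


def inbreeding(K: KinshipMatrix) -> tuple[np.ndarray, float]:
    """Per-individual F_i = 2 f_ii − 1 and the population mean F̄."""
    f_i = 2.0 * np.diag(K.f) - 1.0
    return f_i, float(f_i.mean())


def diversity_stats(K: KinshipMatrix) -> DiversityStats:
    mk_i = K.f.mean(axis=1)
    mk_bar = float(K.f.mean())
    f_i, f_bar = inbreeding(K)
    return DiversityStats(
        mk_bar=mk_bar,
        gd=1.0 - mk_bar,
        fge=1.0 / (2.0 * mk_bar) if mk_bar > 0 else np.inf,
        f_bar=f_bar,
        mk_i=mk_i,
    )


def fge_from_mean_kinship(mk_bar: float) -> float:
    """Founder genome equivalents from a population mean kinship."""
    if not 0.0 < mk_bar <= 1.0:
        raise ValueError("mean kinship must lie in (0, 1]")
    return 1.0 / (2.0 * mk_bar)


def pairwise_histogram(
    K: KinshipMatrix,
    use: str = "off_diagonal_kinship",
    remove_zero_bin: bool = False,
    bin_width: float = 0.001,
    top: float = 0.55,
) -> KinshipHistogram:
    """Histogram of off-diagonal kinships (unordered pairs) or of inbreeding.

    Bins are left-closed right-open on [0, ``top``]; the final bin is closed
    at ``top``.  Values above ``top`` go to an overflow count with a warning.
    Removing the zero bin (useful for display when most pairs are unrelated)
    is flagged in the result.
    """
    if use == "off_diagonal_kinship":
        iu = np.triu_indices(len(K.ids), k=1)
        values = K.f[iu]
    elif use == "inbreeding":
        values = 2.0 * np.diag(K.f) - 1.0
    else:
        raise ValueError(f"unknown histogram source {use!r}")
    edges = np.round(np.arange(0.0, top + bin_width / 2, bin_width), 10)
    overflow = int((values > top).sum())
    if overflow:
        warnings.warn(f"{overflow} values above {top} counted in overflow bin")
    counts, _ = np.histogram(values[values <= top], bins=edges)
    if remove_zero_bin:
        counts = counts.copy()
        counts[0] = 0
    return KinshipHistogram(edges, counts, remove_zero_bin, overflow)


def historic_trajectory(
    ped: Pedigree,
    breed: str,
    years: tuple[int, int],
    step: int = 2,
    min_ecg: float = 0.0,
    log: Optional[RunLog] = None,
) -> pd.DataFrame:
    """Diversity statistics per two-year breeding cohort across a year range.

    A two-year window approximates one generation interval in populations with
    overlapping generations.  Windows with no cohort are skipped and logged.
    Columns: n, mk_bar, gd, fge, f_bar, indexed by window start year.
    """
    from .pedigree import EmptyPopulationError, breeding_cohort, filter_min_ecg

    log = log or get_runlog()
    y0, y1 = years
    rows = []
    for y in range(y0, y1 + 1 - 1, step):
        try:
            pop = breeding_cohort(ped, breed, (y, y + 1))
            if min_ecg > 0:
                pop = filter_min_ecg(ped, pop, min_ecg, log=log)
        except EmptyPopulationError:
            log.log("window_skipped", breed=breed, window=(y, y + 1))
            continue
        st = diversity_stats(kinship_matrix(ped, pop))
        rows.append(
            {
                "year_start": y, "year_end": y + 1, "n": len(pop),
                "mk_bar": st.mk_bar, "gd": st.gd, "fge": st.fge, "f_bar": st.f_bar,
            }
        )
    return pd.DataFrame(rows)
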