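"""Subpopulation discovery from (mean kinship, inbreeding) features.

Regional subpopulations of a breed show up as groups of animals with similar
individual mean kinship mk_i and inbreeding F_i.  Both features are
probabilities in [0, 1], so no input scaling is applied.  Two clustering
routes are provided:

* **UPGMA** (average-linkage agglomeration on Euclidean distances) with the
  classical cluster-count criteria — cubic clustering criterion (CCC),
  pseudo-F (Calinski–Harabasz) and pseudo-t² (Duda–Hart merge statistic) —
  and a largest-discontinuity rule to pick k;
* **model-based clustering**: Gaussian mixtures whose component covariances
  are constrained through the eigenvalue decomposition Σ_g = λ_g D_g A_g D_gᵀ
  (volume λ, shape A with det 1, orientation D), each of the three factors
  either Equal across clusters, Variable, or spherical/Identity — the eight
  families EII, VII, EEE, VEE, VVE, EEV, VEV, VVV.  Model and k are selected
  by maximising BIC = 2·logL − m·ln(n).

Per-cluster diversity tables recompute every statistic (ECG, N_e, mk̄, F̄,
FGE, N_oc, NGE, N_ocatN) on the cluster members alone; clusters below a
minimum size are flagged "nd" and excluded, and a total row over the whole
population is appended.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .kinship import KinshipMatrix, diversity_stats, inbreeding
from .native import NativeKinship, native_diversity
from .ocs import InfeasibleError, effective_size, min_pkin, min_pkin_at_native
from .pedigree import Pedigree, Population

GMM_MODELS = ("EII", "VII", "EEE", "VEE", "VVE", "EEV", "VEV", "VVV")


@dataclass(frozen=True)
class FeatureMatrix:
    """Rows of (mk_i, F_i) per population member, unscaled."""

    ids: tuple[str, ...]
    X: np.ndarray  # (n, 2)


@dataclass(frozen=True)
class HClustResult:
    linkage: np.ndarray
    assignments: dict[int, np.ndarray]  # k -> labels (1..k)
    criteria: pd.DataFrame  # index k, columns ccc, pseudo_f, pseudo_t2
    selected_k: int
    candidates: dict[str, int]  # per-criterion candidate k


@dataclass(frozen=True)
class GMMResult:
    model_name: str
    k: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray  # (k, d, d)
    loglik: float
    bic: float
    responsibilities: np.ndarray
    labels: np.ndarray  # hard assignments 1..k
    n_params: int
    converged: bool
    regularised: bool = False


def features(K: KinshipMatrix) -> FeatureMatrix:
    """(mean kinship, inbreeding) rows for every member of the cohort."""
    mk_i = K.f.mean(axis=1)
    f_i, _ = inbreeding(K)
    return FeatureMatrix(K.ids, np.column_stack([mk_i, f_i]))


# ---------------------------------------------------------------------------
# UPGMA + cluster-count criteria
# ---------------------------------------------------------------------------

def _within_ss(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        w += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return w


def pseudo_f(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski–Harabasz: (B/(k−1)) / (W/(n−k))."""
    n = X.shape[0]
    k = len(np.unique(labels))
    if k < 2 or k >= n:
        return np.nan
    t = float(((X - X.mean(axis=0)) ** 2).sum())
    w = _within_ss(X, labels)
    b = t - w
    return (b / (k - 1)) / (w / (n - k)) if w > 0 else np.inf


def pseudo_t2(X: np.ndarray, labels_fine: np.ndarray, labels_coarse: np.ndarray) -> float:
    """Duda–Hart statistic for the pair of clusters merged between k+1 and k.

    t² = B_merge / ((W_1 + W_2)/(n_1 + n_2 − 2)) where B_merge is the
    between-group part of the merged cluster's sum of squares.
    """
    merged = None
    for lab in np.unique(labels_coarse):
        fine_labs = np.unique(labels_fine[labels_coarse == lab])
        if len(fine_labs) > 1:
            merged = (lab, fine_labs)
            break
    if merged is None:
        return np.nan
    lab, fine_labs = merged
    sub = X[labels_coarse == lab]
    w_merged = float(((sub - sub.mean(axis=0)) ** 2).sum())
    w_parts = 0.0
    n_tot = sub.shape[0]
    for fl in fine_labs:
        part = X[labels_fine == fl]
        w_parts += float(((part - part.mean(axis=0)) ** 2).sum())
    b = w_merged - w_parts
    if n_tot <= 2:
        return 0.0 if b <= 1e-30 else np.inf
    denom = w_parts / (n_tot - 2)
    if denom <= 0:
        return 0.0 if b <= 1e-30 else np.inf
    return b / denom


def ccc(X: np.ndarray, labels: np.ndarray) -> float:
    """Cubic clustering criterion (SAS formulation).

    Compares the observed R² of the partition with its expectation under a
    uniform distribution on a hyperbox aligned with the data's principal
    axes; large positive values favour the partition.
    """
    n, p = X.shape
    q = len(np.unique(labels))
    if q < 2 or q >= n:
        return np.nan
    Xc = X - X.mean(axis=0)
    t = float((Xc**2).sum())
    if t <= 0:
        return np.nan
    w = _within_ss(X, labels)
    r2 = 1.0 - w / t
    # eigenvalues of the covariance, largest first
    s2 = np.linalg.eigvalsh((Xc.T @ Xc) / (n - 1))[::-1]
    s = np.sqrt(np.clip(s2, 0.0, None))
    # choose p* and the scale c of the hyperbox edge iteratively
    pstar = p
    for cand in range(p, 0, -1):
        v = float(np.prod(s[:cand]))
        if v <= 0:
            continue
        c = (v / q) ** (1.0 / cand)
        if s[cand - 1] >= c:
            pstar = cand
            break
    else:
        return np.nan
    c = (float(np.prod(s[:pstar])) / q) ** (1.0 / pstar)
    u = s / c
    num = np.sum(1.0 / (n + u[:pstar])) + np.sum(u[pstar:] ** 2 / (n + u[pstar:]))
    den = np.sum(u**2)
    e_r2 = 1.0 - (num / den) * ((n - q) ** 2 / n) * (1.0 + 4.0 / n)
    if e_r2 >= 1.0 or r2 >= 1.0:
        return np.nan
    return np.log((1.0 - e_r2) / (1.0 - r2)) * np.sqrt(n * pstar / 2.0) / (
        (0.001 + e_r2) ** 1.2
    )


def cluster_criteria(X: np.ndarray, assignments: dict[int, np.ndarray]) -> pd.DataFrame:
    """CCC, pseudo-F and pseudo-t² per k (pseudo-t² needs the k+1 partition)."""
    ks = sorted(assignments)
    rows = []
    for k in ks:
        labels = assignments[k]
        row = {"k": k, "ccc": ccc(X, labels), "pseudo_f": pseudo_f(X, labels)}
        if k + 1 in assignments:
            row["pseudo_t2"] = pseudo_t2(X, assignments[k + 1], labels)
        else:
            row["pseudo_t2"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("k")


def _largest_discontinuity(criteria: pd.DataFrame) -> tuple[int, dict[str, int]]:
    """Pick k per criterion by the largest discontinuity, then take the mode.

    Traces are read from high k to low k: CCC and pseudo-F flag the k with
    the largest rise relative to k+1; pseudo-t² peaks at the merge that
    should not have happened, so the candidate is the bottom of the right
    flank — k+1 for the k with the largest rise from k+1 to k ... i.e. the
    partition just finer than the peak.  Ties go to the smaller k.
    """
    ks = np.array(sorted(criteria.index))
    candidates: dict[str, int] = {}
    for name in ("ccc", "pseudo_f"):
        vals = criteria[name].to_numpy()
        best_k, best_rise = None, -np.inf
        for i, k in enumerate(ks[:-1]):
            rise = vals[i] - vals[i + 1]
            if np.isfinite(rise) and rise > best_rise:
                best_k, best_rise = int(k), rise
        if best_k is not None:
            candidates[name] = best_k
    vals = criteria["pseudo_t2"].to_numpy()
    best_k, best_peak = None, -np.inf
    for i, k in enumerate(ks[:-1]):
        # peak of pseudo-t2 at partition k means the merge from k+1 to k was
        # bad; the recommended count sits one step finer
        if np.isfinite(vals[i]) and vals[i] > best_peak:
            best_k, best_peak = int(k) + 1, vals[i]
    if best_k is not None:
        candidates["pseudo_t2"] = best_k
    if not candidates:
        return 1, candidates
    votes = sorted(candidates.values())
    counts = {v: votes.count(v) for v in votes}
    top = max(counts.values())
    selected = min(v for v, c in counts.items() if c == top)
    return selected, candidates


def upgma(F: FeatureMatrix, k_max: int = 9) -> HClustResult:
    """Average-linkage (UPGMA) clustering of the feature rows.

    Euclidean distances; assignments for every k = 1..k_max; criteria table
    and the largest-discontinuity selection of k.
    """
    X = F.X
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 individuals to cluster")
    Z = linkage(X, method="average", metric="euclidean")
    k_max = min(k_max, n)
    assignments = {k: fcluster(Z, t=k, criterion="maxclust") for k in range(1, k_max + 1)}
    crit = cluster_criteria(X, assignments)
    selected, candidates = _largest_discontinuity(crit)
    return HClustResult(Z, assignments, crit, selected, candidates)


# ---------------------------------------------------------------------------
# Parameterised-covariance Gaussian mixtures
# ---------------------------------------------------------------------------

def _scatter_matrices(X, resp):
    """Per-component responsibility-weighted scatter W_g, sizes n_g, means."""
    n, d = X.shape
    k = resp.shape[1]
    n_g = resp.sum(axis=0)
    means = (resp.T @ X) / n_g[:, None]
    W = np.empty((k, d, d))
    for g in range(k):
        Xc = X - means[g]
        W[g] = (resp[:, g][:, None] * Xc).T @ Xc
    return n_g, means, W


def _mstep_cov(model: str, W: np.ndarray, n_g: np.ndarray, n: int) -> np.ndarray:
    """Constrained covariance M-step via the λDADᵀ decomposition.

    Closed forms where they exist (Celeux–Govaert); small flip-flop
    iterations for the shared-shape (VEV), shared-matrix (VEE) and
    shared-orientation (VVE) families.  VVE's orientation update is solved
    exactly for 2-D features by a 1-D search over the rotation angle.
    """
    k, d, _ = W.shape
    out = np.empty_like(W)
    if model == "EII":
        s2 = W.trace(axis1=1, axis2=2).sum() / (n * d)
        out[:] = s2 * np.eye(d)
    elif model == "VII":
        for g in range(k):
            out[g] = (np.trace(W[g]) / (n_g[g] * d)) * np.eye(d)
    elif model == "EEE":
        out[:] = W.sum(axis=0) / n
    elif model == "VVV":
        for g in range(k):
            out[g] = W[g] / n_g[g]
    elif model == "EEV":
        omegas, rots = [], []
        for g in range(k):
            vals, vecs = np.linalg.eigh(W[g])
            omegas.append(vals[::-1])
            rots.append(vecs[:, ::-1])
        lam_a = np.sum(omegas, axis=0) / n  # λ·A eigenvalues, shared
        for g in range(k):
            out[g] = rots[g] @ np.diag(lam_a) @ rots[g].T
    elif model == "VEV":
        omegas, rots = [], []
        for g in range(k):
            vals, vecs = np.linalg.eigh(W[g])
            omegas.append(np.clip(vals[::-1], 1e-300, None))
            rots.append(vecs[:, ::-1])
        omegas = np.array(omegas)
        a = omegas.sum(axis=0)
        a = a / np.prod(a) ** (1.0 / d)
        for _ in range(30):
            lam = (omegas / a).sum(axis=1) / (n_g * d)
            a_new = (omegas / lam[:, None]).sum(axis=0)
            a_new = a_new / np.prod(a_new) ** (1.0 / d)
            if np.max(np.abs(a_new - a)) < 1e-12:
                a = a_new
                break
            a = a_new
        lam = (omegas / a).sum(axis=1) / (n_g * d)
        for g in range(k):
            out[g] = lam[g] * rots[g] @ np.diag(a) @ rots[g].T
    elif model == "VEE":
        lam = np.array([np.trace(W[g]) / (n_g[g] * d) for g in range(k)])
        for _ in range(30):
            C = np.sum(W / lam[:, None, None], axis=0)
            C = C / np.linalg.det(C) ** (1.0 / d)
            Cinv = np.linalg.inv(C)
            lam_new = np.array(
                [np.trace(W[g] @ Cinv) / (n_g[g] * d) for g in range(k)]
            )
            if np.max(np.abs(lam_new - lam)) < 1e-14:
                lam = lam_new
                break
            lam = lam_new
        C = np.sum(W / lam[:, None, None], axis=0)
        C = C / np.linalg.det(C) ** (1.0 / d)
        for g in range(k):
            out[g] = lam[g] * C
    elif model == "VVE":
        if d != 2:
            raise NotImplementedError("VVE orientation update implemented for 2-D features")

        w00, w01, w11 = W[:, 0, 0], W[:, 0, 1], W[:, 1, 1]

        def neg_profile(theta):
            # diag of D'WD for D = rotation(theta); broadcasts over a grid of
            # angles (axis 0) and components (axis 1)
            theta = np.atleast_1d(np.asarray(theta, dtype=float))[:, None]
            c2 = np.cos(theta) ** 2
            s2 = 1.0 - c2
            cs = np.cos(theta) * np.sin(theta)
            b00 = c2 * w00 + 2 * cs * w01 + s2 * w11
            b11 = s2 * w00 - 2 * cs * w01 + c2 * w11
            prod = np.clip(b00 * b11, 1e-300, None)
            out_v = np.sum(n_g * np.log(prod), axis=1)
            return out_v if out_v.size > 1 else float(out_v[0])

        # period pi/2 (column swap); dense grid + local polish
        grid = np.linspace(0.0, np.pi / 2, 181)
        vals = neg_profile(grid)
        t0 = grid[int(np.argmin(vals))]
        res = minimize_scalar(
            neg_profile,
            bounds=(max(0.0, t0 - 0.02), min(np.pi / 2, t0 + 0.02)),
            method="bounded",
            options={"xatol": 1e-12},
        )
        theta = res.x if res.fun < vals.min() else t0
        ct, st = np.cos(theta), np.sin(theta)
        D = np.array([[ct, -st], [st, ct]])
        for g in range(k):
            diag = np.clip(np.diag(D.T @ W[g] @ D), 1e-300, None)
            det = np.prod(diag) ** (1.0 / d)
            A = np.diag(diag) / det
            lam = det / n_g[g]
            out[g] = lam * D @ A @ D.T
    else:
        raise ValueError(f"unknown covariance model {model!r}")
    return out


def gmm_n_params(model: str, k: int, d: int) -> int:
    """Free parameters: weights + means + covariance per family."""
    base = (k - 1) + k * d
    orient = d * (d - 1) // 2
    shape = d - 1
    cov = {
        "EII": 1,
        "VII": k,
        "EEE": 1 + shape + orient,
        "VEE": k + shape + orient,
        "VVE": k + k * shape + orient,
        "EEV": 1 + shape + k * orient,
        "VEV": k + shape + k * orient,
        "VVV": k * (1 + shape + orient),
    }[model]
    return base + cov


def _log_gauss(X, mean, cov):
    d = X.shape[1]
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    Xc = X - mean
    sol = np.linalg.solve(cov, Xc.T).T
    maha = np.einsum("ij,ij->i", Xc, sol)
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def gmm_fit(
    F: FeatureMatrix | np.ndarray,
    k: int,
    model_name: str,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    init_labels: Optional[np.ndarray] = None,
) -> GMMResult:
    """EM fit of a k-component Gaussian mixture with a constrained covariance.

    Initialised from a seeded k-means partition (or ``init_labels``);
    converged when the relative log-likelihood change drops below ``tol``.
    Covariances that collapse numerically are ridge-regularised and flagged.
    """
    X = F.X if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
    n, d = X.shape
    if k < 1 or n <= k:
        raise ValueError("need n > k >= 1")
    if model_name not in GMM_MODELS:
        raise ValueError(f"unknown model {model_name!r}")

    if init_labels is not None:
        labels = np.asarray(init_labels, dtype=int)
    elif k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
    resp = np.zeros((n, k))
    resp[np.arange(n), labels] = 1.0

    loglik = -np.inf
    regularised = False
    converged = False
    weights = np.full(k, 1.0 / k)
    means = np.zeros((k, d))
    covs = np.tile(np.eye(d), (k, 1, 1))
    for _ in range(max_iter):
        n_g, means, W = _scatter_matrices(X, resp)
        if np.any(n_g < d + 1e-6):
            raise np.linalg.LinAlgError("mixture component collapsed (too few points)")
        weights = n_g / n
        covs = _mstep_cov(model_name, W, n_g, n)
        # regularise components that collapsed (e.g. onto duplicated rows);
        # threshold is relative to the overall feature variance
        data_scale = max(float(np.trace(np.cov(X.T))) / d, 1e-300)
        for g in range(k):
            if np.min(np.linalg.eigvalsh(covs[g])) <= 1e-10 * data_scale:
                covs[g] = covs[g] + (1e-8 * data_scale) * np.eye(d)
                regularised = True
        log_p = np.column_stack(
            [np.log(np.clip(weights[g], 1e-300, None)) + _log_gauss(X, means[g], covs[g])
             for g in range(k)]
        )
        new_loglik = float(logsumexp(log_p, axis=1).sum())
        resp = np.exp(log_p - logsumexp(log_p, axis=1, keepdims=True))
        if np.isfinite(loglik) and abs(new_loglik - loglik) <= tol * (abs(loglik) + 1e-12):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    m = gmm_n_params(model_name, k, d)
    bic = 2.0 * loglik - m * np.log(n)
    return GMMResult(
        model_name=model_name,
        k=k,
        weights=weights,
        means=means,
        covariances=covs,
        loglik=loglik,
        bic=bic,
        responsibilities=resp,
        labels=resp.argmax(axis=1) + 1,
        n_params=m,
        converged=converged,
        regularised=regularised,
    )


def gmm_select(
    F: FeatureMatrix | np.ndarray,
    k_max: int = 9,
    models: Sequence[str] = GMM_MODELS,
    seed: int = 0,
    allow_regularised: bool = False,
) -> tuple[GMMResult, pd.DataFrame]:
    """Fit every (model, k) cell and return the BIC-maximising fit + surface.

    Fits whose covariances turned numerically singular (and were ridged) are
    excluded from selection by default — a component collapsing onto
    duplicated feature rows produces an unbounded likelihood, not evidence of
    structure; reference model-based clustering implementations report such
    cells as missing.
    """
    X = F.X if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)
    best: Optional[GMMResult] = None
    surface = pd.DataFrame(index=range(1, k_max + 1), columns=list(models), dtype=float)
    for k in range(1, k_max + 1):
        if k >= X.shape[0]:
            break
        if k == 1:
            init = np.zeros(X.shape[0], dtype=int)
        else:
            init = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
        for model in models:
            try:
                fit = gmm_fit(F, k, model, seed=seed, init_labels=init)
            except (np.linalg.LinAlgError, NotImplementedError, FloatingPointError, ValueError):
                continue
            if fit.regularised and not allow_regularised:
                continue
            surface.loc[k, model] = fit.bic
            if best is None or fit.bic > best.bic:
                best = fit
    if best is None:
        raise RuntimeError("all mixture fits failed")
    return best, surface


# ---------------------------------------------------------------------------
# PCA projection
# ---------------------------------------------------------------------------

def pca_projection(F: FeatureMatrix) -> dict[str, np.ndarray]:
    """Centred (unscaled) PCA of the feature rows.

    For 2-D features this is a rotation; the first axis follows whichever of
    the two features dominates the variance (typically the inbreeding
    coefficient).  Returns scores, loadings (columns = components) and the
    explained variance ratio.
    """
    X = F.X
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for a PCA")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * S
    var = S**2
    return {
        "scores": scores,
        "loadings": Vt.T,
        "explained_variance_ratio": var / var.sum() if var.sum() > 0 else var,
        "center": X.mean(axis=0),
    }


# ---------------------------------------------------------------------------
# Per-cluster diversity tables
# ---------------------------------------------------------------------------

def cluster_table(
    ped: Pedigree,
    pop: Population,
    assignments: np.ndarray,
    K: KinshipMatrix,
    NK: Optional[NativeKinship] = None,
    min_cluster_size: int = 4,
    L: float = 3.2,
    seed: int = 0,
    run_ocs: bool = True,
) -> pd.DataFrame:
    """Per-cluster diversity statistics in the standard table layout.

    Columns: N, ECG, Ne, mk_bar, F_bar, FGE, N_oc, NGE, N_ocatN.  Clusters
    below ``min_cluster_size`` keep their N but show "nd" (NaN) statistics.
    The total row recomputes everything on the full population, so cluster
    rows can be checked against module-level statistics.
    """
    from .pedigree import _ecg_all

    members = list(pop)
    if len(assignments) != len(members):
        raise ValueError("assignments must cover the population")
    sexes = {m: ped[m].sex for m in members}
    ecg_all = _ecg_all(ped)

    def one_row(ids: list[str], label) -> dict:
        sub_k = K.restrict(ids)
        st = diversity_stats(sub_k)
        n_m = sum(sexes[i] == "male" for i in ids)
        n_f = sum(sexes[i] == "female" for i in ids)
        row = {
            "cluster": label,
            "N": len(ids),
            "ECG": float(np.mean([ecg_all[ped.index_of(i)] for i in ids])),
            "Ne": effective_size(n_m, n_f) if n_m and n_f else np.nan,
            "mk_bar": st.mk_bar,
            "F_bar": st.f_bar,
            "FGE": st.fge,
            "N_oc": np.nan,
            "NGE": np.nan,
            "N_ocatN": np.nan,
        }
        if NK is not None:
            sub_nk = NK.restrict(ids)
            try:
                row["NGE"] = native_diversity(sub_nk).nge
            except Exception:
                pass
        if run_ocs and n_m and n_f:
            try:
                row["N_oc"] = min_pkin(sub_k, sexes, seed=seed).potential_fge
            except (InfeasibleError, ValueError):
                pass
            if NK is not None:
                try:
                    row["N_ocatN"] = min_pkin_at_native(
                        sub_k, sub_nk, sexes, seed=seed
                    ).potential_fge
                except (InfeasibleError, ValueError):
                    pass
        return row

    rows = []
    for lab in np.unique(assignments):
        ids = [m for m, a in zip(members, assignments) if a == lab]
        if len(ids) < min_cluster_size:
            rows.append(
                {"cluster": lab, "N": len(ids), "ECG": np.nan, "Ne": np.nan,
                 "mk_bar": np.nan, "F_bar": np.nan, "FGE": np.nan,
                 "N_oc": np.nan, "NGE": np.nan, "N_ocatN": np.nan, "nd": True}
            )
        else:
            rows.append({**one_row(ids, lab), "nd": False})
    rows.append({**one_row(members, "total"), "nd": False})
    return pd.DataFrame(rows).set_index("cluster")
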