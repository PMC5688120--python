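"""Markov state model estimation and spectral thermodynamics.

Discretizes tIC-space trajectories with K-means, counts lagged transitions,
trims to the largest strongly connected (ergodic) state set, and fits the
transition matrix by maximum likelihood under a detailed-balance constraint
using the classical self-consistent edge-weight iteration. The spectrum of
the reversible transition matrix yields equilibrium populations (stationary
left eigenvector), relaxation timescales t_i = −τ/ln μ_{i+1}, and the
GMRQ-style cross-validation score used for hyperparameter selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from . import tica as _tica
from .features import normalize_features

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/mol/K

__all__ = [
    "ClusterModel",
    "CountMatrix",
    "TransitionModel",
    "MacrostateMap",
    "kmeans_discretize",
    "count_transitions",
    "ergodic_trim",
    "mle_reversible",
    "spectral_decompose",
    "implied_timescale_scan",
    "assign_macrostates",
    "nearest_reference_rules",
    "macrostate_populations",
    "free_energies",
    "cross_validate",
    "KB_KCAL",
]


@dataclass
class ClusterModel:
    centers: np.ndarray
    n_clusters: int
    seed: int
    inertia: float

    def assign(self, x: np.ndarray) -> np.ndarray:
        """Nearest-center (Euclidean) assignment."""
        d = ((x[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d, axis=1)


@dataclass
class CountMatrix:
    matrix: np.ndarray
    lag: int  # frames
    mode: str = "sliding"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("count matrix must be square")
        if np.any(self.matrix < 0) or not np.all(np.isfinite(self.matrix)):
            raise ValueError("counts must be finite and non-negative")

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]


@dataclass
class TransitionModel:
    transition_matrix: np.ndarray
    lag_ns: float
    stationary: np.ndarray
    eigenvalues: np.ndarray        # descending, μ₁ = 1
    active_set: np.ndarray         # original state indices retained
    converged: bool = True
    n_iter: int = 0
    loglik: float = float("nan")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def timescales(self, n: int | None = None) -> np.ndarray:
        _, ts = spectral_decompose(self, n)
        return ts


def kmeans_discretize(tic_trajs, n_clusters: int, seed: int):
    """K-means (k-means++ seeding, fixed seed) over pooled tIC frames;
    returns the cluster model and one integer label array per trajectory."""
    tic_trajs = list(tic_trajs)
    if not tic_trajs:
        raise ValueError("no trajectories given")
    if n_clusters < 2:
        raise ValueError("n_clusters must be ≥ 2")
    x = np.concatenate([t.values for t in tic_trajs], axis=0)
    if x.shape[0] < n_clusters:
        raise ValueError("fewer frames than clusters")
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    labels = km.fit_predict(x)
    model = ClusterModel(km.cluster_centers_.copy(), n_clusters, seed, float(km.inertia_))
    out = []
    start = 0
    for t in tic_trajs:
        out.append(labels[start : start + t.values.shape[0]].astype(np.int64))
        start += t.values.shape[0]
    return model, out


def count_transitions(dtrajs, lag: int, n_states: int | None = None) -> CountMatrix:
    """Sliding-window transition counts: every in-trajectory (t, t+lag)
    pair increments C[s_t, s_{t+lag}]."""
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    if lag < 1:
        raise ValueError("lag must be ≥ 1")
    if n_states is None:
        n_states = int(max(d.max() for d in dtrajs if d.size)) + 1
    c = np.zeros((n_states, n_states))
    any_pairs = False
    for d in dtrajs:
        if d.size <= lag:
            continue
        any_pairs = True
        pairs = d[:-lag] * n_states + d[lag:]
        c += np.bincount(pairs, minlength=n_states * n_states).reshape(n_states, n_states)
    if not any_pairs:
        raise ValueError(f"no trajectory longer than lag {lag}")
    return CountMatrix(c, lag)


def ergodic_trim(counts: CountMatrix):
    """Restrict to the largest strongly connected component of the directed
    graph with an edge wherever C_ij > 0. Ties broken by total counts, then
    by lowest state index."""
    c = counts.matrix
    if not c.any():
        raise ValueError("all-zero count matrix")
    n_comp, labels = connected_components(
        scipy.sparse.csr_matrix(c > 0), directed=True, connection="strong"
    )
    best = None
    for k in range(n_comp):
        members = np.flatnonzero(labels == k)
        total = c[np.ix_(members, members)].sum()
        key = (members.size, total, -members[0])
        if best is None or key > best[0]:
            best = (key, members)
    active = best[1]
    return CountMatrix(c[np.ix_(active, active)], counts.lag), active


def mle_reversible(
    counts: CountMatrix,
    lag_ns: float = 1.0,
    tol: float = 1e-10,
    max_iter: int = 1_000_000,
    active_set: np.ndarray | None = None,
) -> TransitionModel:
    """Reversible maximum-likelihood transition matrix.

    Maximizes Π T_ij^{C_ij} under detailed balance via the self-consistent
    iteration on symmetric edge weights x_ij:

        x_ij ← (C_ij + C_ji) / (c_i/x_i + c_j/x_j),   x_i = Σ_j x_ij

    converged when the log-likelihood change per sweep falls below ``tol``.
    π_i = x_i / Σ x and T_ij = x_ij / x_i.
    """
    c = counts.matrix
    n = c.shape[0]
    rowsums = c.sum(axis=1)
    if np.any(rowsums == 0):
        raise ValueError("disconnected counts: run ergodic_trim first")
    csym = c + c.T
    x = csym.copy()
    mask = csym > 0
    loglik = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        xi = x.sum(axis=1)
        denom = rowsums[:, None] / xi[:, None] + rowsums[None, :] / xi[None, :]
        x = np.where(mask, csym / np.where(denom > 0, denom, 1.0), 0.0)
        xi = x.sum(axis=1)
        t = x / xi[:, None]
        with np.errstate(divide="ignore"):
            ll = float(np.sum(c[mask] * np.log(t[mask])))
        if abs(ll - loglik) < tol:
            loglik = ll
            converged = True
            break
        loglik = ll
    xi = x.sum(axis=1)
    pi = xi / xi.sum()
    t = x / xi[:, None]
    # exact row-stochasticity against accumulated round-off
    t /= t.sum(axis=1, keepdims=True)
    evals = _reversible_eigenvalues(t, pi)
    if active_set is None:
        active_set = np.arange(n)
    return TransitionModel(
        transition_matrix=t,
        lag_ns=float(lag_ns),
        stationary=pi,
        eigenvalues=evals,
        active_set=np.asarray(active_set, dtype=np.int64),
        converged=converged,
        n_iter=n_iter,
        loglik=loglik,
    )


def _reversible_eigenvalues(t: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Eigenvalues of a detailed-balance T via the symmetric conjugate
    D^{1/2} T D^{−1/2}; real by construction, sorted descending."""
    sqrt_pi = np.sqrt(pi)
    s = sqrt_pi[:, None] * t / sqrt_pi[None, :]
    evals = scipy.linalg.eigvalsh(0.5 * (s + s.T))
    return np.sort(evals)[::-1]


def spectral_decompose(model: TransitionModel, n_timescales: int | None = None):
    """Eigenvalues (descending) and implied timescales t_i = −τ/ln μ_{i+1}.

    Raises if the spectrum has an imaginary part beyond tolerance, which
    signals broken reversibility.
    """
    t = model.transition_matrix
    pi = model.stationary
    db_resid = np.max(np.abs(pi[:, None] * t - pi[None, :] * t.T))
    if db_resid < 1e-6:
        evals = _reversible_eigenvalues(t, pi)
    else:
        ev = np.linalg.eigvals(t)
        if np.max(np.abs(ev.imag)) > 1e-8:
            raise ValueError("complex eigenvalues beyond tolerance: transition matrix is not reversible")
        evals = np.sort(ev.real)[::-1]
    if n_timescales is None:
        n_timescales = len(evals) - 1
    n_timescales = min(n_timescales, len(evals) - 1)
    ts = np.array([
        _tica.timescale_of_component(mu, model.lag_ns) for mu in evals[1 : n_timescales + 1]
    ])
    return evals, ts


def implied_timescale_scan(dtrajs, lags, n_timescales: int, dt_ns: float = 1.0,
                           n_states: int | None = None):
    """Implied timescales vs lag (full counts→trim→reversible-MLE estimate
    per lag). Returns a table and the smallest scanned lag after which the
    slowest timescale varies by < 10% to the next scanned lag."""
    rows = []
    top = {}
    for lag in lags:
        counts = count_transitions(dtrajs, lag, n_states=n_states)
        trimmed, active = ergodic_trim(counts)
        if trimmed.n_states < 2:
            rows.append({"lag_frames": lag, "lag_ns": lag * dt_ns,
                         **{f"t{i+1}_ns": np.nan for i in range(n_timescales)}})
            continue
        model = mle_reversible(trimmed, lag_ns=lag * dt_ns, active_set=active)
        _, ts = spectral_decompose(model, n_timescales)
        row = {"lag_frames": lag, "lag_ns": lag * dt_ns}
        for i in range(n_timescales):
            row[f"t{i+1}_ns"] = ts[i] if i < len(ts) else np.nan
        rows.append(row)
        top[lag] = ts[0] if len(ts) else np.nan
    table = pd.DataFrame(rows)
    suggested = None
    slags = sorted(top)
    for a, b in zip(slags[:-1], slags[1:]):
        ta, tb = top[a], top[b]
        if np.isfinite(ta) and np.isfinite(tb) and abs(tb - ta) < 0.10 * abs(ta):
            suggested = a
            break
    return table, suggested


@dataclass
class MacrostateMap:
    """Total map from microstate (cluster index) to macrostate label."""

    labels: np.ndarray  # object array of labels, one per cluster center
    provenance: str = ""

    def members(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    @property
    def macrostates(self) -> list[str]:
        seen = []
        for l in self.labels:
            if l not in seen:
                seen.append(l)
        return seen


def nearest_reference_rules(reference_points: dict[str, np.ndarray]):
    """Partition rules assigning each cluster center to the macrostate with
    the nearest reference point (deterministic tie-break by listed order)."""
    labels = list(reference_points)
    pts = np.asarray([reference_points[l] for l in labels], dtype=float)

    def make(k):
        def pred(center):
            d = np.linalg.norm(pts - np.asarray(center)[None, :], axis=1)
            return int(np.argmin(d)) == k
        return pred

    return [(l, make(k)) for k, l in enumerate(labels)]


def assign_macrostates(cluster_model: ClusterModel, rules) -> MacrostateMap:
    """Apply labelled predicates to each cluster center; every center must
    satisfy exactly one predicate."""
    labels = np.empty(cluster_model.n_clusters, dtype=object)
    offenders = []
    for i, center in enumerate(cluster_model.centers):
        hits = [label for label, pred in rules if pred(center)]
        if len(hits) != 1:
            offenders.append((i, hits))
        else:
            labels[i] = hits[0]
    if offenders:
        raise ValueError(f"macrostate rules are not a partition; offending centers: {offenders}")
    return MacrostateMap(labels, provenance="predicate rules")


def macrostate_populations(model: TransitionModel, macro_map: MacrostateMap) -> dict[str, float]:
    """Sum the stationary distribution over each macrostate's microstates
    (restricted to the active set); populations sum to 1."""
    active_labels = macro_map.labels[model.active_set]
    return {
        label: float(model.stationary[active_labels == label].sum())
        for label in macro_map.macrostates
    }


def free_energies(populations, temperature: float = 300.0, reference=None):
    """G_i = −kT ln(p_i / p_ref) in kcal/mol.

    ``reference`` is a state label, an explicit reference population (float),
    or None (the highest-populated state). Zero populations map to +inf.
    """
    kt = KB_KCAL * temperature
    if isinstance(populations, dict):
        keys = list(populations)
        p = np.array([populations[k] for k in keys], dtype=float)
    else:
        keys = None
        p = np.asarray(populations, dtype=float)
    if isinstance(reference, str):
        p_ref = populations[reference]
    elif reference is None:
        p_ref = float(p.max())
    else:
        p_ref = float(reference)
    if p_ref <= 0:
        raise ValueError("reference population must be positive")
    with np.errstate(divide="ignore"):
        g = np.where(p > 0, -kt * np.log(np.maximum(p, 1e-300) / p_ref), np.inf)
    if keys is not None:
        return {k: float(v) for k, v in zip(keys, g)}
    return g


# --------------------------------------------------------------------------
# GMRQ-style cross-validation
# --------------------------------------------------------------------------

def _gmrq_score(train_model: TransitionModel, test_dtrajs, lag: int, m: int) -> float:
    """Generalized matrix Rayleigh quotient of the train model's top-m
    eigenfunctions evaluated on held-out trajectories.

    With V the top-m right eigenvectors (state-indicator coefficients) and
    C00/C0τ the test instantaneous/lagged indicator correlations,
    score = tr[(Vᵀ C00 V)⁻¹ (Vᵀ C0τ V)].
    """
    t = train_model.transition_matrix
    pi = train_model.stationary
    sqrt_pi = np.sqrt(pi)
    s = sqrt_pi[:, None] * t / sqrt_pi[None, :]
    evals, w = scipy.linalg.eigh(0.5 * (s + s.T))
    order = np.argsort(evals)[::-1][:m]
    v = w[:, order] / sqrt_pi[:, None]  # right eigenvectors of T

    # map original state indices -> position in active set
    n_orig = int(train_model.active_set.max()) + 1
    pos = -np.ones(n_orig, dtype=np.int64)
    pos[train_model.active_set] = np.arange(len(train_model.active_set))

    n = len(train_model.active_set)
    c00 = np.zeros((n, n))
    c0t = np.zeros((n, n))
    n_pairs = 0
    for d in test_dtrajs:
        d = np.asarray(d, dtype=np.int64)
        if d.size <= lag:
            continue
        a = np.where(d < n_orig, pos[np.minimum(d, n_orig - 1)], -1)
        s0, s1 = a[:-lag], a[lag:]
        ok = (s0 >= 0) & (s1 >= 0)
        s0, s1 = s0[ok], s1[ok]
        if s0.size == 0:
            continue
        np.add.at(c0t, (s0, s1), 1.0)
        np.add.at(c00, (s0, s0), 0.5)
        np.add.at(c00, (s1, s1), 0.5)
        n_pairs += s0.size
    if n_pairs == 0:
        raise ValueError("test fold has no usable frames")
    c00 /= n_pairs
    c0t = 0.5 * (c0t + c0t.T) / n_pairs
    a = v.T @ c0t @ v
    b = v.T @ c00 @ v
    b += 1e-12 * np.eye(m) * max(1.0, np.trace(b))
    return float(np.trace(scipy.linalg.solve(b, 0.5 * (a + a.T), assume_a="sym")))


def cross_validate(
    feature_trajs,
    grid: dict,
    n_folds: int = 5,
    seed: int = 0,
    markov_lag_ns: float = 80.0,
    n_timescales: int = 3,
    normalize: bool = True,
):
    """Grid search over (tica_lag_ns, n_components, kinetic_mapping,
    n_clusters) scored by the GMRQ (sum of the top n_timescales+1
    eigenvalues estimated variationally on held-out trajectories). Folds
    split whole trajectories. Returns (score table, best combination)."""
    feature_trajs = list(feature_trajs)
    if len(feature_trajs) < n_folds:
        raise ValueError("need at least n_folds trajectories")
    dt = feature_trajs[0].dt
    lag = int(round(markov_lag_ns / dt))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(feature_trajs))
    folds = np.array_split(order, n_folds)
    m = n_timescales + 1

    keys = ["tica_lag_ns", "n_components", "kinetic_mapping", "n_clusters"]
    combos = [dict(zip(keys, vals)) for vals in product(*(grid[k] for k in keys))]
    rows = []
    for combo in combos:
        scores = []
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(order, test_idx)
            train = [feature_trajs[i] for i in train_idx]
            test = [feature_trajs[i] for i in test_idx]
            if normalize:
                train, norm = normalize_features(train)
                test = [norm.transform(t) for t in test]
            tm = _tica.fit_tica(
                train, combo["tica_lag_ns"], combo["n_components"],
                kinetic_mapping=combo["kinetic_mapping"],
            )
            train_tics = _tica.transform(train, tm)
            test_tics = _tica.transform(test, tm)
            cm, train_dtrajs = kmeans_discretize(train_tics, combo["n_clusters"], seed)
            test_dtrajs = [cm.assign(t.values) for t in test_tics]
            counts = count_transitions(train_dtrajs, lag, n_states=combo["n_clusters"])
            trimmed, active = ergodic_trim(counts)
            model = mle_reversible(trimmed, lag_ns=markov_lag_ns, active_set=active)
            m_eff = min(m, model.n_states)
            scores.append(_gmrq_score(model, test_dtrajs, lag, m_eff))
        rows.append({**combo, "mean_score": float(np.mean(scores)),
                     "std_score": float(np.std(scores))})
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_score"].idxmax(), keys].to_dict()
    return table, best
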