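"""Kinetic Monte Carlo synthesis, mean first passage times, and bootstrap
uncertainty over trajectory resamples.

A fitted transition matrix can be propagated stochastically to stitch short
trajectories into arbitrarily long "mock" trajectories (kinetic Monte
Carlo), interrogated for mean first passage times by a linear solve, and
wrapped with percentile confidence intervals obtained by resampling whole
input trajectories and re-estimating the model. All times are ns internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msm import count_transitions, ergodic_trim, mle_reversible

__all__ = [
    "KMCTrajectory",
    "BootstrapSummary",
    "kmc_sample",
    "mfpt",
    "mfpt_matrix",
    "first_hit_times",
    "bootstrap_observables",
]


@dataclass
class KMCTrajectory:
    states: np.ndarray
    lag_ns: float
    seed: int
    structure_indices: np.ndarray | None = None

    @property
    def total_time_ns(self) -> float:
        return self.states.shape[0] * self.lag_ns

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]


@dataclass
class BootstrapSummary:
    name: str
    values: np.ndarray
    median: float
    lo95: float
    hi95: float
    n_rounds: int
    n_skipped: int
    seed: int


def _tlp(model):
    """Extract (transition matrix, lag ns, stationary) from a TransitionModel
    or any object exposing transition_matrix/dt-or-lag_ns/stationary."""
    t = np.asarray(model.transition_matrix, dtype=float)
    lag = getattr(model, "lag_ns", None)
    if lag is None:
        lag = model.dt
    pi = np.asarray(model.stationary, dtype=float)
    return t, float(lag), pi


def kmc_sample(model, n_frames: int, seed: int, start="stationary",
               structure_pool=None) -> KMCTrajectory:
    """Kinetic Monte Carlo: sequential categorical draws from the rows of T.

    ``start`` is a state index or "stationary". With ``structure_pool`` (a
    list of frame-index arrays per state) each step also records one
    uniformly drawn member frame of the current state, mirroring how
    representative structures are attached to a synthetic trajectory.
    """
    t, lag, pi = _tlp(model)
    n = t.shape[0]
    if n_frames < 1:
        raise ValueError("n_frames must be ≥ 1")
    rng = np.random.default_rng(seed)
    if start == "stationary":
        s = int(rng.choice(n, p=pi / pi.sum()))
    else:
        s = int(start)
        if not 0 <= s < n:
            raise ValueError(f"start state {s} outside active set of size {n}")
    cum = np.cumsum(t, axis=1)
    cum[:, -1] = 1.0
    states = np.empty(n_frames, dtype=np.int64)
    states[0] = s
    u = rng.random(n_frames - 1)
    for i in range(1, n_frames):
        s = int(np.searchsorted(cum[s], u[i - 1], side="right"))
        states[i] = s
    struct = None
    if structure_pool is not None:
        struct = np.array([rng.choice(structure_pool[si]) for si in states])
    return KMCTrajectory(states, lag, seed, struct)


def mfpt_matrix(t: np.ndarray, lag_ns: float, pi: np.ndarray, sources, sinks) -> float:
    """Mean first passage time (ns) from a π-weighted source set to a sink set.

    Solves m_i = τ + Σ_j T_ij m_j for i ∉ sinks with m = 0 on sinks, then
    averages m over the sources with weights π renormalized within the set.
    """
    n = t.shape[0]
    sources = np.atleast_1d(np.asarray(sources, dtype=np.int64))
    sinks = np.atleast_1d(np.asarray(sinks, dtype=np.int64))
    if sinks.size == 0:
        raise ValueError("empty sink set")
    sink_mask = np.zeros(n, dtype=bool)
    sink_mask[sinks] = True
    nonsink = np.flatnonzero(~sink_mask)
    m = np.zeros(n)
    if nonsink.size:
        q = t[np.ix_(nonsink, nonsink)]
        a = np.eye(nonsink.size) - q
        try:
            sol = np.linalg.solve(a, np.full(nonsink.size, lag_ns))
        except np.linalg.LinAlgError as e:
            raise ValueError("sink set unreachable from some source (singular system)") from e
        if np.any(sol < 0) or not np.all(np.isfinite(sol)):
            raise ValueError("sink set unreachable from some source")
        m[nonsink] = sol
    w = pi[sources]
    if w.sum() <= 0:
        # zero-measure source set (e.g. transient states of an absorbing
        # chain): fall back to uniform weighting within the set
        w = np.ones_like(w)
    return float(np.dot(w / w.sum(), m[sources]))


def mfpt(model, sources, sinks) -> float:
    """MFPT in ns between state sets of a transition model (see mfpt_matrix)."""
    t, lag, pi = _tlp(model)
    return mfpt_matrix(t, lag, pi, sources, sinks)


def first_hit_times(model, sources, sinks, n_walkers: int, seed: int,
                    max_steps: int | None = None):
    """Simulated first-hit time distribution of ``n_walkers`` independent
    kinetic Monte Carlo walkers started π-weighted on the sources.

    Walker *counts* per state are propagated with per-state multinomial
    draws — distributionally identical to independent walkers, but the cost
    per step is O(n_states²) regardless of walker count. Returns
    (mean_ns, sem_ns, n_absorbed).
    """
    t, lag, pi = _tlp(model)
    n = t.shape[0]
    sources = np.atleast_1d(np.asarray(sources, dtype=np.int64))
    sinks = np.atleast_1d(np.asarray(sinks, dtype=np.int64))
    rng = np.random.default_rng(seed)
    w = pi[sources]
    counts = np.zeros(n, dtype=np.int64)
    counts[sources] = rng.multinomial(n_walkers, w / w.sum())
    sink_mask = np.zeros(n, dtype=bool)
    sink_mask[sinks] = True
    # walkers that start on a sink have first-hit time 0
    hit_at = [int(counts[sink_mask].sum())]
    counts[sink_mask] = 0
    if max_steps is None:
        det = mfpt_matrix(t, 1.0, pi, sources, sinks)  # in steps
        max_steps = int(50 * det + 1000)
    step = 0
    while counts.sum() > 0 and step < max_steps:
        step += 1
        nxt = np.zeros(n, dtype=np.int64)
        for s in np.flatnonzero(counts):
            nxt += rng.multinomial(int(counts[s]), t[s])
        hit_at.append(int(nxt[sink_mask].sum()))
        nxt[sink_mask] = 0
        counts = nxt
    hits = np.asarray(hit_at, dtype=float)
    n_abs = int(hits.sum())
    if n_abs == 0:
        raise ValueError("no walker reached the sink within max_steps")
    steps = np.arange(hits.size, dtype=float)
    mean_steps = float(np.dot(hits, steps) / n_abs)
    var_steps = float(np.dot(hits, (steps - mean_steps) ** 2) / max(n_abs - 1, 1))
    return mean_steps * lag, np.sqrt(var_steps / n_abs) * lag, n_abs


def bootstrap_observables(
    dtrajs,
    lag: int,
    lag_ns: float,
    observables: dict,
    n_rounds: int = 200,
    seed: int = 0,
    n_states: int | None = None,
    tol: float = 1e-10,
) -> dict[str, BootstrapSummary]:
    """Percentile bootstrap over whole-trajectory resamples.

    Each round draws len(dtrajs) trajectories with replacement, re-estimates
    counts → ergodic trim → reversible MLE, and evaluates each observable
    (a callable taking the TransitionModel). Observables may return a float
    or a dict of floats (expanded into separate summaries). Rounds that fail
    estimation (e.g. a disconnected resample) are skipped and counted.
    Reported as median and 95% percentile interval, matching the
    median-with-sub/superscript convention.
    """
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    if len(dtrajs) < 2:
        raise ValueError("bootstrap needs at least 2 trajectories")
    if n_states is None:
        n_states = int(max(d.max() for d in dtrajs)) + 1
    rng = np.random.default_rng(seed)
    results: dict[str, list[float]] = {}
    n_skipped = 0
    for _ in range(n_rounds):
        idx = rng.integers(0, len(dtrajs), size=len(dtrajs))
        sample = [dtrajs[i] for i in idx]
        try:
            counts = count_transitions(sample, lag, n_states=n_states)
            trimmed, active = ergodic_trim(counts)
            model = mle_reversible(trimmed, lag_ns=lag_ns, active_set=active, tol=tol)
            round_vals = {}
            for name, func in observables.items():
                val = func(model)
                if isinstance(val, dict):
                    for k, v in val.items():
                        round_vals[f"{name}.{k}"] = float(v)
                else:
                    round_vals[name] = float(val)
        except (ValueError, np.linalg.LinAlgError):
            n_skipped += 1
            continue
        for k, v in round_vals.items():
            results.setdefault(k, []).append(v)
    summaries = {}
    for name, vals in results.items():
        arr = np.asarray(vals)
        summaries[name] = BootstrapSummary(
            name=name,
            values=arr,
            median=float(np.median(arr)),
            lo95=float(np.percentile(arr, 2.5)),
            hi95=float(np.percentile(arr, 97.5)),
            n_rounds=n_rounds,
            n_skipped=n_skipped,
            seed=seed,
        )
    return summaries
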