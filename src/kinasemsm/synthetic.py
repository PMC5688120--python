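"""Synthetic metastable dynamics with known thermodynamics and kinetics.

Every downstream stage of the pipeline (tICA, clustering, reversible MSM,
kinetic Monte Carlo, MFPT, bootstrap) is testable against ground truth
generated here: detailed-balance Markov chains over a four-macrostate kinase
landscape (active, intermediate, Src-like, DFG-out) with a hub topology —
the intermediate alone connects to the other three — Gaussian feature
emissions per microstate, AR(1) processes as an analytic tICA oracle, and
toy rigid structures for the geometry operations.

Transition probabilities use Metropolis-like barrier rates

    T_ij = c · exp(−(B_ij − G_i) / kT)    (i ≠ j, finite B_ij)

with symmetric barriers B, which guarantees detailed balance with the
Boltzmann stationary distribution π_i ∝ exp(−G_i/kT). Free energies are in
kcal/mol, times in ns, temperature in K (default 300 K, kT ≈ 0.596 kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.signal

from .features import CoordinateTrajectory, FeatureTrajectory, Topology
from .kinetics import mfpt_matrix
from .msm import KB_KCAL

MACROSTATES = ("active", "intermediate", "src_like", "dfg_out")
DFG_IN_MACROSTATES = ("active", "intermediate", "src_like")

__all__ = [
    "MACROSTATES",
    "DFG_IN_MACROSTATES",
    "GroundTruthChain",
    "EmissionSpec",
    "AR1Spec",
    "build_kinase_chain",
    "hub_barriers",
    "calibrate_btk_chains",
    "sample_discrete",
    "default_emission_spec",
    "emit_features",
    "sample_ar1",
    "make_toy_structure_pair",
]


@dataclass
class GroundTruthChain:
    """Detailed-balance transition matrix with known free energies, barriers
    and macrostate labels; the parameter-recovery oracle for the pipeline."""

    transition_matrix: np.ndarray
    dt: float                      # ns per step
    state_free_energies: np.ndarray  # kcal/mol
    barriers: np.ndarray             # kcal/mol; inf = disconnected
    macro_labels: np.ndarray         # per-microstate label
    temperature: float = 300.0

    def __post_init__(self) -> None:
        t = np.asarray(self.transition_matrix, dtype=float)
        if np.max(np.abs(t.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("rows must sum to 1 within 1e-12")
        pi = self.stationary
        db = np.max(np.abs(pi[:, None] * t - pi[None, :] * t.T))
        if db > 1e-10:
            raise ValueError(f"detailed balance violated: residual {db:.2e}")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def kt(self) -> float:
        return KB_KCAL * self.temperature

    @property
    def stationary(self) -> np.ndarray:
        w = np.exp(-(self.state_free_energies - self.state_free_energies.min()) / self.kt)
        return w / w.sum()

    def macro_members(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.macro_labels == label)

    def macro_populations(self) -> dict[str, float]:
        pi = self.stationary
        return {m: float(pi[self.macro_members(m)].sum())
                for m in dict.fromkeys(self.macro_labels)}

    def mfpt_macro(self, source_labels, sink_label: str) -> float:
        """MFPT (ns) from the π-weighted union of source macrostates to a
        sink macrostate, by linear solve."""
        if isinstance(source_labels, str):
            source_labels = [source_labels]
        sources = np.concatenate([self.macro_members(l) for l in source_labels])
        sinks = self.macro_members(sink_label)
        return mfpt_matrix(self.transition_matrix, self.dt, self.stationary, sources, sinks)

    # duck-type the TransitionModel surface used by kinetics
    @property
    def lag_ns(self) -> float:
        return self.dt

    def save(self, path) -> None:
        np.savez(
            path,
            transition_matrix=self.transition_matrix,
            dt=self.dt,
            state_free_energies=self.state_free_energies,
            barriers=self.barriers,
            macro_labels=np.asarray(self.macro_labels, dtype="U16"),
            temperature=self.temperature,
        )

    @classmethod
    def load(cls, path) -> "GroundTruthChain":
        z = np.load(path, allow_pickle=False)
        return cls(
            transition_matrix=z["transition_matrix"],
            dt=float(z["dt"]),
            state_free_energies=z["state_free_energies"],
            barriers=z["barriers"],
            macro_labels=z["macro_labels"].astype(object),
            temperature=float(z["temperature"]),
        )


def _connected(barriers: np.ndarray) -> bool:
    n = barriers.shape[0]
    adj = np.isfinite(barriers) & ~np.eye(n, dtype=bool)
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(adj[i]):
            if j not in seen:
                seen.add(int(j))
                stack.append(int(j))
    return len(seen) == n


def build_kinase_chain(
    free_energies,
    barriers,
    dt: float,
    temperature: float = 300.0,
    macro_labels=None,
    rate_scale: float | None = None,
    diag_margin: float = 0.1,
) -> GroundTruthChain:
    """Construct a detailed-balance chain from minima and symmetric barriers.

    Off-diagonal T_ij = c·exp(−(B_ij − G_i)/kT) for finite B_ij, zero
    otherwise; the diagonal absorbs the remainder. With ``rate_scale`` None,
    c is chosen so the largest off-diagonal row mass is 1 − diag_margin
    (metastability: every diagonal stays positive). The stationary
    distribution is Boltzmann in G by construction.
    """
    g = np.asarray(free_energies, dtype=float)
    b = np.asarray(barriers, dtype=float)
    n = g.shape[0]
    if dt <= 0:
        raise ValueError("dt must be positive")
    if b.shape != (n, n):
        raise ValueError("barrier matrix shape mismatch")
    if not np.array_equal(b, b.T):
        raise ValueError("barriers must be symmetric")
    kt = KB_KCAL * temperature
    finite = np.isfinite(b) & ~np.eye(n, dtype=bool)
    lo = np.maximum(g[:, None], g[None, :])
    if np.any(b[finite] < lo[finite] - 1e-12):
        raise ValueError("each finite barrier must be ≥ max of the two minima")
    if not _connected(b):
        raise ValueError("barrier graph is disconnected")

    rates = np.where(finite, np.exp(-(b - g[:, None]) / kt), 0.0)
    offsum = rates.sum(axis=1)
    if rate_scale is None:
        rate_scale = (1.0 - diag_margin) / offsum.max()
    t = rate_scale * rates
    diag = 1.0 - t.sum(axis=1)
    if np.any(diag < -1e-12):
        bad = int(np.argmin(diag))
        raise ValueError(
            f"row {bad}: off-diagonal mass {1 - diag[bad]:.3f} exceeds 1 at rate scale {rate_scale}"
        )
    np.fill_diagonal(t, np.maximum(diag, 0.0))
    t /= t.sum(axis=1, keepdims=True)
    if macro_labels is None:
        macro_labels = np.array(["state"] * n, dtype=object)
    return GroundTruthChain(t, dt, g, b, np.asarray(macro_labels, dtype=object), temperature)


def hub_barriers(
    g: np.ndarray,
    macro_labels: np.ndarray,
    intra_barrier: float = 0.8,
    hub_barrier: float = 1.5,
    flip_barrier: float = 3.0,
) -> np.ndarray:
    """Barrier matrix for the four-state hub topology at microstate level.

    All microstate pairs within a macrostate are connected with a low
    barrier ``intra_barrier`` above the higher minimum; intermediate↔active
    and intermediate↔src_like pairs get ``hub_barrier``; intermediate↔
    dfg_out pairs get ``flip_barrier`` (the DFG flip). Direct active↔
    src_like, active↔dfg_out and src_like↔dfg_out barriers are infinite.
    """
    n = g.shape[0]
    b = np.full((n, n), np.inf)
    hub_edges = {
        frozenset(("intermediate", "active")): hub_barrier,
        frozenset(("intermediate", "src_like")): hub_barrier,
        frozenset(("intermediate", "dfg_out")): flip_barrier,
    }
    for i in range(n):
        for j in range(i + 1, n):
            li, lj = macro_labels[i], macro_labels[j]
            if li == lj:
                height = intra_barrier
            else:
                height = hub_edges.get(frozenset((li, lj)))
                if height is None:
                    continue
            b[i, j] = b[j, i] = max(g[i], g[j]) + height
    return b


def _micro_free_energies(macro_pops: dict[str, float], n_micro: int, kt: float):
    """Microstate free energies realizing the macrostate populations with
    the macrostate weight split equally over its microstates."""
    labels = []
    g = []
    for m in MACROSTATES:
        p = macro_pops[m] / n_micro
        for _ in range(n_micro):
            labels.append(m)
            g.append(-kt * np.log(p))
    g = np.asarray(g)
    return g - g.min(), np.asarray(labels, dtype=object)


# Fixture targets: macrostate populations and forward DFG-flip MFPTs for the
# deprotonated (ASP) and protonated (ASH) ensembles.
ASP_POPULATIONS = {"active": 0.07, "intermediate": 0.40, "src_like": 0.52, "dfg_out": 0.01}
ASH_POPULATIONS = {"active": 0.06, "intermediate": 0.38, "src_like": 0.47, "dfg_out": 0.09}
ASP_MFPT_NS = 1.2e6   # 1.2 ms
ASH_MFPT_NS = 3.0e5   # 300 µs


def calibrate_btk_chains(
    dt: float = 80.0,
    temperature: float = 300.0,
    n_micro_per_macro: int = 3,
    asp_populations: dict | None = None,
    ash_populations: dict | None = None,
    asp_mfpt_ns: float = ASP_MFPT_NS,
    ash_mfpt_ns: float = ASH_MFPT_NS,
    intra_barrier: float = 0.8,
    hub_barrier: float = 1.5,
    rate_scale: float = 0.25,
    barrier_bracket: tuple[float, float] = (0.3, 9.0),
) -> tuple[GroundTruthChain, GroundTruthChain]:
    """Two packaged fixture chains matching the reported thermodynamic and
    kinetic signatures of DFG-Asp protonation.

    Microstate free energies are fixed exactly from the target macrostate
    populations (Boltzmann inversion, equal split within a macrostate); the
    intermediate↔dfg_out flip barrier is then calibrated by 1-D root finding
    so the π-weighted MFPT from the DFG-in macrostates to dfg_out hits the
    target. The rate prefactor is frozen so the root-find is monotone.
    """
    asp_populations = dict(asp_populations or ASP_POPULATIONS)
    ash_populations = dict(ash_populations or ASH_POPULATIONS)
    kt = KB_KCAL * temperature

    def one(pops: dict[str, float], target_ns: float) -> GroundTruthChain:
        total = sum(v for k, v in pops.items() if k != "intermediate")
        if total > 1.0:
            raise ValueError("population targets exceed 1")
        pops = {**pops, "intermediate": 1.0 - total}
        g, labels = _micro_free_energies(pops, n_micro_per_macro, kt)

        def chain_at(flip_barrier: float) -> GroundTruthChain:
            b = hub_barriers(g, labels, intra_barrier, hub_barrier, flip_barrier)
            return build_kinase_chain(g, b, dt, temperature, labels, rate_scale=rate_scale)

        def residual(flip_barrier: float) -> float:
            c = chain_at(flip_barrier)
            return c.mfpt_macro(list(DFG_IN_MACROSTATES), "dfg_out") - target_ns

        lo, hi = barrier_bracket
        f_lo, f_hi = residual(lo), residual(hi)
        if f_lo * f_hi > 0:
            raise ValueError(
                f"MFPT target {target_ns} ns not bracketed by flip barriers "
                f"[{lo}, {hi}] kcal/mol (residuals {f_lo:.3g}, {f_hi:.3g})"
            )
        b_star = scipy.optimize.brentq(residual, lo, hi, xtol=1e-12, rtol=1e-14)
        return chain_at(b_star)

    return one(asp_populations, asp_mfpt_ns), one(ash_populations, ash_mfpt_ns)


def sample_discrete(chain: GroundTruthChain, n_steps: int, n_trajs: int, seed: int,
                    start="stationary") -> list[np.ndarray]:
    """Forward-simulate label sequences by categorical draws from the rows
    of T; reproducible for identical seeds."""
    if n_steps < 2:
        raise ValueError("n_steps must be ≥ 2")
    t = chain.transition_matrix
    n = t.shape[0]
    rng = np.random.default_rng(seed)
    cum = np.cumsum(t, axis=1)
    cum[:, -1] = 1.0
    if start == "stationary":
        s = rng.choice(n, size=n_trajs, p=chain.stationary)
    else:
        s = np.full(n_trajs, int(start))
        if not 0 <= int(start) < n:
            raise ValueError(f"invalid start state {start}")
    out = np.empty((n_trajs, n_steps), dtype=np.int64)
    out[:, 0] = s
    for k in range(1, n_steps):
        u = rng.random(n_trajs)
        s = (u[:, None] >= cum[s]).sum(axis=1)
        out[:, k] = s
    return [out[i] for i in range(n_trajs)]


@dataclass
class EmissionSpec:
    """Per-microstate Gaussian feature emissions plus appended noise dims."""

    means: np.ndarray            # (n_states, d) signal-space means
    sigma: float = 1.0           # isotropic emission s.d. (used if covariances is None)
    covariances: np.ndarray | None = None  # (n_states, d, d), optional
    noise_dims: int = 0          # i.i.d. standard-normal distractor dims

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.means.ndim != 2:
            raise ValueError("means must be (n_states, d)")
        if self.covariances is not None:
            cov = np.asarray(self.covariances, dtype=float)
            if cov.shape != (self.means.shape[0], self.d, self.d):
                raise ValueError("covariances shape mismatch")
            for k in range(cov.shape[0]):
                if not np.allclose(cov[k], cov[k].T):
                    raise ValueError("covariances must be symmetric")
                if np.min(np.linalg.eigvalsh(cov[k])) <= 0:
                    raise ValueError("covariances must be positive definite")
            self.covariances = cov

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    @property
    def total_dims(self) -> int:
        return self.d + self.noise_dims


def default_emission_spec(
    chain: GroundTruthChain,
    d: int = 20,
    noise_dims: int = 30,
    macro_separation: float = 16.0,
    intra_offset: float = 1.2,
    sigma: float = 1.0,
    layout_seed: int = 1234,
) -> EmissionSpec:
    """Default emission layout for the four-macrostate fixtures.

    Macrostate means sit on the vertices of a regular tetrahedron with
    pairwise distance ``macro_separation``·σ; microstates within a
    macrostate are offset by ``intra_offset``·σ in seeded random directions,
    and ``noise_dims`` pure noise dimensions are appended as distractors.

    The default separation (16σ) emulates collective switch coordinates in
    MD feature vectors, where a conformational flip moves many correlated
    features by far more than their within-basin fluctuation. The variance a
    linear readout of a two-state exchange contributes scales as
    π(1−π)·separation², so this is also the scale at which the exchange of
    the ~1%-populated DFG-out basin remains one of the leading tICA modes
    (as the DFG flip is in the kinase ensembles this generator emulates)
    rather than drowning under intra-basin and distractor variance. The
    layout seed is part of the fixture definition, independent of sampling
    seeds.
    """
    rng = np.random.default_rng(layout_seed)
    macros = list(dict.fromkeys(chain.macro_labels))
    k = len(macros)
    # regular simplex: centered unit vectors, scaled to target pairwise distance
    verts = np.eye(k) - 1.0 / k
    pair = np.linalg.norm(verts[0] - verts[1])
    verts *= macro_separation * sigma / pair
    macro_means = np.zeros((k, d))
    macro_means[:, :k] = verts
    means = np.zeros((chain.n_states, d))
    for i, label in enumerate(chain.macro_labels):
        direction = rng.standard_normal(d)
        direction /= np.linalg.norm(direction)
        means[i] = macro_means[macros.index(label)] + intra_offset * sigma * direction
    return EmissionSpec(means=means, sigma=sigma, noise_dims=noise_dims)


def macro_mean_points(chain: GroundTruthChain, spec: EmissionSpec) -> dict[str, np.ndarray]:
    """Macrostate emission centroids in full feature space (signal dims
    padded with zeros over the noise dims); used to anchor macrostate rules."""
    out = {}
    for label in dict.fromkeys(chain.macro_labels):
        members = chain.macro_members(label)
        mean = np.zeros(spec.total_dims)
        mean[: spec.d] = spec.means[members].mean(axis=0)
        out[label] = mean
    return out


def emit_features(labels_list, spec: EmissionSpec, seed: int, dt: float = 80.0) -> list[FeatureTrajectory]:
    """Draw frame features from each state's Gaussian; appended noise dims
    are i.i.d. standard normal. Frame interval inherited from the chain."""
    rng = np.random.default_rng(seed)
    out = []
    names = [f"sig{i}" for i in range(spec.d)] + [f"noise{i}" for i in range(spec.noise_dims)]
    for labels in labels_list:
        labels = np.asarray(labels, dtype=np.int64)
        if labels.max(initial=0) >= spec.n_states or labels.min(initial=0) < 0:
            raise ValueError("label outside emission spec")
        n = labels.shape[0]
        x = np.empty((n, spec.total_dims))
        if spec.covariances is None:
            x[:, : spec.d] = spec.means[labels] + spec.sigma * rng.standard_normal((n, spec.d))
        else:
            x[:, : spec.d] = spec.means[labels]
            for s in np.unique(labels):
                idx = np.flatnonzero(labels == s)
                chol = np.linalg.cholesky(spec.covariances[s])
                x[np.ix_(idx, np.arange(spec.d))] += rng.standard_normal((idx.size, spec.d)) @ chol.T
        if spec.noise_dims:
            x[:, spec.d :] = rng.standard_normal((n, spec.noise_dims))
        out.append(FeatureTrajectory(x, dt, list(names)))
    return out


@dataclass
class AR1Spec:
    """Independent per-dimension AR(1) processes: the analytic tICA oracle.

    Autocorrelation at lag τ is exp(−τ/τ_r), so the top tICA eigenvalue on
    this data has a closed form.
    """

    relaxation_times: np.ndarray  # ns
    stationary_variances: np.ndarray
    dt: float                     # ns

    def __post_init__(self) -> None:
        self.relaxation_times = np.atleast_1d(np.asarray(self.relaxation_times, dtype=float))
        self.stationary_variances = np.atleast_1d(np.asarray(self.stationary_variances, dtype=float))
        if np.any(self.relaxation_times <= 0) or np.any(self.stationary_variances <= 0):
            raise ValueError("relaxation times and variances must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def sample_ar1(spec: AR1Spec, n_steps: int, seed: int) -> FeatureTrajectory:
    """Exact discrete-time AR(1): x_{t+1} = a x_t + √(v(1−a²)) ξ with
    a = exp(−dt/τ_r), started from the stationary distribution."""
    if n_steps < 2:
        raise ValueError("n_steps must be ≥ 2")
    rng = np.random.default_rng(seed)
    d = spec.relaxation_times.shape[0]
    a = np.exp(-spec.dt / spec.relaxation_times)
    v = spec.stationary_variances
    x = np.empty((n_steps, d))
    x[0] = np.sqrt(v) * rng.standard_normal(d)
    noise = rng.standard_normal((n_steps - 1, d)) * np.sqrt(v * (1.0 - a**2))
    for j in range(d):
        # x_t = a^t x_0 + Σ a^{t-1-k} ε_k : an IIR filter over the innovations
        driven = scipy.signal.lfilter([1.0], [1.0, -a[j]], noise[:, j])
        x[1:, j] = driven + x[0, j] * a[j] ** np.arange(1, n_steps)
    names = [f"ar1_{j}" for j in range(d)]
    return FeatureTrajectory(x, spec.dt, names)


# --------------------------------------------------------------------------
# Toy structures for the geometry module
# --------------------------------------------------------------------------

# every residue carries backbone plus distal side-chain atoms so that any
# named salt-bridge selection (CD/CZ/NZ) resolves regardless of numbering
_TOY_ATOMS = [
    ("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"),
    ("CD", "C"), ("CZ", "C"), ("NZ", "N"),
]


@dataclass
class ToyStructures:
    """Rigid-motion fixture: a reference frame, rigidly transformed copies,
    and a copy with one atom displaced by a known amount."""

    reference: CoordinateTrajectory
    transformed: CoordinateTrajectory
    displaced: CoordinateTrajectory
    displaced_atom: int
    displacement: float


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def make_toy_structure_pair(
    n_residues: int,
    displacement: float,
    seed: int,
    n_copies: int = 3,
    first_res_seq: int = 1,
    dt: float = 1.0,
) -> ToyStructures:
    """Synthetic mini-protein fixture for the geometry operations.

    Builds a helix-like backbone with CA/CD/CZ/NZ atom-name patterns and
    author-style residue numbers starting at ``first_res_seq``, plus
    rigidly transformed copies (RMSD after superposition must be 0) and a
    variant with one CA displaced by ``displacement`` Å (known no-fit RMSD).
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    records = []
    coords = []
    rise, turn, radius = 1.5, np.deg2rad(100.0), 2.3
    for r in range(n_residues):
        res_seq = first_res_seq + r
        res_name = ("ARG", "GLU", "LYS")[r % 3]
        theta = r * turn
        ca = np.array([radius * np.cos(theta), radius * np.sin(theta), rise * r])
        for name, element in _TOY_ATOMS:
            records.append({"name": name, "element": element,
                            "res_name": res_name, "res_seq": res_seq})
            coords.append(ca + 0.8 * rng.standard_normal(3))
    top = Topology(pd.DataFrame.from_records(records))
    ref = np.asarray(coords)

    frames = []
    for _ in range(n_copies):
        rot = _random_rotation(rng)
        trans = 10.0 * rng.standard_normal(3)
        frames.append(ref @ rot + trans)
    transformed = CoordinateTrajectory(np.stack(frames), dt, top)

    ca_indices = np.flatnonzero((top.atoms["name"] == "CA").to_numpy())
    moved_atom = int(ca_indices[n_residues // 2])
    disp = ref.copy()
    disp[moved_atom] += np.array([displacement, 0.0, 0.0])
    displaced = CoordinateTrajectory(disp[None], dt, top)

    reference = CoordinateTrajectory(ref[None], dt, top)
    return ToyStructures(reference, transformed, displaced, moved_atom, displacement)
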