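"""Configuration-driven orchestration of the full ensemble pipeline.

A single declarative config drives featurize → normalize → tICA → K-means →
reversible MSM → macrostate lumping → populations and free energies, with
explicit seeds everywhere so a rerun with the same config and inputs is
bit-identical. Two ensembles (e.g. deprotonated vs protonated DFG-Asp) are
compared on a *shared* discretization — tICA and clustering fit on pooled
data, counts and MSMs estimated per ensemble — so relative free energies of
the same states are directly comparable (ΔΔG per macrostate).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import msm as _msm
from . import tica as _tica
from .features import FeatureTrajectory, normalize_features
from .kinetics import bootstrap_observables
from .msm import (
    ClusterModel,
    MacrostateMap,
    TransitionModel,
    assign_macrostates,
    count_transitions,
    ergodic_trim,
    free_energies,
    kmeans_discretize,
    macrostate_populations,
    mle_reversible,
    nearest_reference_rules,
    spectral_decompose,
)

KB_KCAL = _msm.KB_KCAL

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "EnsembleComparison",
    "run_pipeline",
    "compare_ensembles",
    "fes_histogram",
    "frame_weights",
    "macro_reference_points",
]


@dataclass
class PipelineConfig:
    """Hyperparameters for one end-to-end run.

    Defaults mirror the selected model of the study this emulates
    (tICA lag 208 ns, 3 components, kinetic mapping, 80 ns Markov lag); the
    cluster count is set per dataset (190 for the full MD ensembles, 12 for
    the packaged synthetic fixtures).
    """

    tica_lag_ns: float = 208.0
    n_components: int = 3
    kinetic_mapping: bool = True
    shrinkage: float = 1e-8
    n_clusters: int = 190
    cluster_seed: int = 0
    markov_lag_ns: float = 80.0
    msm_tol: float = 1e-10
    normalize: bool = True
    temperature: float = 300.0
    n_bootstrap: int = 200
    bootstrap_seed: int = 0
    macrostate_references: dict = field(default_factory=dict)  # label -> tIC-space point

    def validate(self, dt: float) -> None:
        for name, lag in (("tICA", self.tica_lag_ns), ("Markov", self.markov_lag_ns)):
            k = round(lag / dt)
            if k < 1 or abs(k * dt - lag) > 1e-9 * max(1.0, lag):
                raise ValueError(f"{name} lag {lag} ns is not a positive multiple of dt = {dt} ns")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be ≥ 2")
        if self.n_components < 1:
            raise ValueError("n_components must be ≥ 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["macrostate_references"] = {
            k: np.asarray(v, dtype=float).tolist() for k, v in self.macrostate_references.items()
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class PipelineResult:
    config: PipelineConfig
    normalizer: object
    tica_model: _tica.TICAModel
    cluster_model: ClusterModel
    dtrajs: list
    projections: list
    msm_model: TransitionModel
    macro_map: MacrostateMap | None
    populations: dict | None
    free_energy: dict | None
    timescales_ns: np.ndarray
    log: list[str]

    def populations_table(self) -> pd.DataFrame:
        rows = [{"macrostate": k, "population": v, "free_energy_kcal_mol": self.free_energy[k]}
                for k, v in self.populations.items()]
        return pd.DataFrame(rows)


def macro_reference_points(macro_feature_points: dict, normalizer, tica_model) -> dict:
    """Project macrostate anchor points from feature space into tIC space
    through the fitted normalizer and tICA model."""
    out = {}
    for label, point in macro_feature_points.items():
        ft = FeatureTrajectory(np.asarray(point, dtype=float)[None, :], 1.0)
        if normalizer is not None:
            ft = normalizer.transform(ft)
        out[label] = _tica.transform(ft, tica_model).values[0]
    return out


def run_pipeline(config: PipelineConfig, trajs, macro_feature_points: dict | None = None,
                 output_dir=None) -> PipelineResult:
    """Execute normalize → tICA → cluster → MSM → macrostates → free energies.

    ``macro_feature_points`` (label → feature-space anchor) overrides
    config.macrostate_references (label → tIC-space point) for building the
    nearest-anchor macrostate rules; with neither, macrostate lumping is
    skipped. Rerunning with identical config, inputs and seeds is
    bit-identical.
    """
    trajs = list(trajs)
    if not trajs:
        raise ValueError("no input trajectories")
    dt = trajs[0].dt
    config.validate(dt)
    log: list[str] = []

    if config.normalize:
        work, normalizer = normalize_features(trajs)
        log.append(f"normalized {len(work)} trajectories, "
                   f"{int(normalizer.constant.sum())} constant features flagged")
    else:
        work, normalizer = trajs, None

    tica_model = _tica.fit_tica(
        work, config.tica_lag_ns, config.n_components,
        kinetic_mapping=config.kinetic_mapping, shrinkage=config.shrinkage,
    )
    log.append(f"tICA lag {config.tica_lag_ns} ns: top eigenvalues "
               f"{np.round(tica_model.eigenvalues[:config.n_components], 4).tolist()}")
    projections = _tica.transform(work, tica_model)

    cluster_model, dtrajs = kmeans_discretize(projections, config.n_clusters, config.cluster_seed)
    lag = int(round(config.markov_lag_ns / dt))
    counts = count_transitions(dtrajs, lag, n_states=config.n_clusters)
    trimmed, active = ergodic_trim(counts)
    if active.size < config.n_clusters:
        log.append(f"ergodic trim removed {config.n_clusters - active.size} states")
    model = mle_reversible(trimmed, lag_ns=config.markov_lag_ns, active_set=active,
                           tol=config.msm_tol)
    evals, ts = spectral_decompose(model, min(10, model.n_states - 1))
    log.append(f"MSM: {model.n_states} states, top implied timescales (ns) "
               f"{np.round(ts[:3], 1).tolist()}")

    macro_map = populations = g = None
    if macro_feature_points is not None:
        refs = macro_reference_points(macro_feature_points, normalizer, tica_model)
    elif config.macrostate_references:
        refs = {k: np.asarray(v, dtype=float) for k, v in config.macrostate_references.items()}
    else:
        refs = None
    if refs is not None:
        macro_map = assign_macrostates(cluster_model, nearest_reference_rules(refs))
        populations = macrostate_populations(model, macro_map)
        g = free_energies(populations, config.temperature)
        log.append(f"macrostate populations {np.round(list(populations.values()), 4).tolist()}")

    result = PipelineResult(
        config=config, normalizer=normalizer, tica_model=tica_model,
        cluster_model=cluster_model, dtrajs=dtrajs, projections=projections,
        msm_model=model, macro_map=macro_map, populations=populations,
        free_energy=g, timescales_ns=ts, log=log,
    )
    if output_dir is not None:
        _persist(result, Path(output_dir))
    return result


def bootstrap_pipeline(result: PipelineResult, extra_observables: dict | None = None):
    """Bootstrap the macrostate populations (and any extra observables) of a
    fitted run: whole discrete trajectories are resampled with replacement
    and the MSM stage re-estimated on the fixed discretization."""
    config = result.config
    lag = int(round(config.markov_lag_ns / result.projections[0].dt))
    macro_map = result.macro_map

    observables = {}
    if macro_map is not None:
        observables["population"] = lambda m: macrostate_populations(m, macro_map)
    if extra_observables:
        observables.update(extra_observables)
    return bootstrap_observables(
        result.dtrajs, lag, config.markov_lag_ns, observables,
        n_rounds=config.n_bootstrap, seed=config.bootstrap_seed,
        n_states=config.n_clusters, tol=config.msm_tol,
    )


@dataclass
class EnsembleComparison:
    """Two MSMs over one shared discretization, with per-macrostate
    populations, free energies (referenced to ensemble A's most populated
    state) and ΔΔG = G_b − G_a."""

    cluster_model: ClusterModel
    macro_map: MacrostateMap
    model_a: TransitionModel
    model_b: TransitionModel
    populations_a: dict
    populations_b: dict
    free_energy_a: dict
    free_energy_b: dict
    ddg: dict

    def table(self) -> pd.DataFrame:
        rows = []
        for k in self.populations_a:
            rows.append({
                "macrostate": k,
                "pop_a": self.populations_a[k],
                "pop_b": self.populations_b.get(k, np.nan),
                "g_a_kcal_mol": self.free_energy_a[k],
                "g_b_kcal_mol": self.free_energy_b.get(k, np.nan),
                "ddg_kcal_mol": self.ddg.get(k, np.nan),
            })
        return pd.DataFrame(rows)


def compare_ensembles(trajs_a, trajs_b, config: PipelineConfig,
                      macro_feature_points: dict | None = None) -> EnsembleComparison:
    """Fit tICA + clustering on the pooled ensembles, estimate one MSM per
    ensemble on the shared states, and report ΔΔG per macrostate with the
    reference convention: ensemble A's most populated macrostate is 0."""
    trajs_a, trajs_b = list(trajs_a), list(trajs_b)
    if not trajs_a or not trajs_b:
        raise ValueError("both ensembles must be non-empty")
    dt = trajs_a[0].dt
    config.validate(dt)

    pooled = trajs_a + trajs_b
    if config.normalize:
        pooled_n, normalizer = normalize_features(pooled)
    else:
        pooled_n, normalizer = pooled, None
    tica_model = _tica.fit_tica(
        pooled_n, config.tica_lag_ns, config.n_components,
        kinetic_mapping=config.kinetic_mapping, shrinkage=config.shrinkage,
    )
    projections = _tica.transform(pooled_n, tica_model)
    # fit the shared discretization on canonically ordered pooled frames so
    # the state definitions are invariant to the ensemble order
    stacked = np.concatenate([p.values for p in projections], axis=0)
    order = np.lexsort(stacked.T)
    sorted_traj = FeatureTrajectory(stacked[order], projections[0].dt)
    cluster_model, _ = kmeans_discretize([sorted_traj], config.n_clusters, config.cluster_seed)
    dtrajs = [cluster_model.assign(p.values) for p in projections]
    na = len(trajs_a)
    dtrajs_a, dtrajs_b = dtrajs[:na], dtrajs[na:]

    if macro_feature_points is not None:
        refs = macro_reference_points(macro_feature_points, normalizer, tica_model)
    elif config.macrostate_references:
        refs = {k: np.asarray(v, dtype=float) for k, v in config.macrostate_references.items()}
    else:
        raise ValueError("ensemble comparison requires macrostate references")
    macro_map = assign_macrostates(cluster_model, nearest_reference_rules(refs))

    lag = int(round(config.markov_lag_ns / dt))

    def fit_one(dt_list):
        counts = count_transitions(dt_list, lag, n_states=config.n_clusters)
        trimmed, active = ergodic_trim(counts)
        return mle_reversible(trimmed, lag_ns=config.markov_lag_ns, active_set=active,
                              tol=config.msm_tol)

    model_a = fit_one(dtrajs_a)
    model_b = fit_one(dtrajs_b)
    pops_a = macrostate_populations(model_a, macro_map)
    pops_b = macrostate_populations(model_b, macro_map)
    ref_label = max(pops_a, key=pops_a.get)
    g_a = free_energies(pops_a, config.temperature, reference=ref_label)
    g_b = free_energies(pops_b, config.temperature, reference=pops_a[ref_label])
    ddg = {}
    for k in pops_a:
        if pops_a.get(k, 0) > 0 and pops_b.get(k, 0) > 0:
            ddg[k] = g_b[k] - g_a[k]
        else:
            ddg[k] = float("nan")  # macrostate lost in one ensemble after trimming
    return EnsembleComparison(cluster_model, macro_map, model_a, model_b,
                              pops_a, pops_b, g_a, g_b, ddg)


def frame_weights(dtrajs, model: TransitionModel) -> list[np.ndarray]:
    """Per-frame MSM stationary weights: each frame carries π(state) divided
    by the state's total frame count (frames in trimmed states get 0)."""
    n_orig = int(model.active_set.max()) + 1
    pi_full = np.zeros(max(n_orig, int(max(d.max() for d in dtrajs)) + 1))
    pi_full[model.active_set] = model.stationary
    counts = np.zeros_like(pi_full)
    for d in dtrajs:
        counts += np.bincount(d, minlength=counts.size)
    w = np.where(counts > 0, pi_full / np.maximum(counts, 1), 0.0)
    return [w[d] for d in dtrajs]


def fes_histogram(projections, weights, bins=60, temperature: float = 300.0,
                  extent=None, ref_weight: float | None = None):
    """2-D free-energy surface over (tIC1, tIC2): G(bin) = −kT ln(w/w_ref).

    ``ref_weight`` defaults to the histogram's own maximum bin weight (the
    minimum is then 0 by construction); pass the reference ensemble's
    maximum bin weight to place two ensembles on one scale. Empty bins are
    NaN, not zero. Returns (G, x_edges, y_edges)."""
    if isinstance(projections, (list, tuple)):
        xy = np.concatenate([np.asarray(p.values if hasattr(p, "values") else p)[:, :2]
                             for p in projections], axis=0)
        w = np.concatenate([np.asarray(wi) for wi in weights])
    else:
        xy = np.asarray(projections)[:, :2]
        w = np.asarray(weights)
    rng_arg = None if extent is None else extent
    h, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1], bins=bins, range=rng_arg, weights=w)
    if h.max() <= 0:
        raise ValueError("all-empty weighted histogram")
    ref = float(h.max()) if ref_weight is None else float(ref_weight)
    kt = KB_KCAL * temperature
    with np.errstate(divide="ignore"):
        g = np.where(h > 0, -kt * np.log(h / ref), np.nan)
    return g, xe, ye


def _persist(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "n_trajectories": len(result.dtrajs),
        "n_frames": int(sum(len(d) for d in result.dtrajs)),
        "n_msm_states": int(result.msm_model.n_states),
        "log": result.log,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    np.savez(
        outdir / "models.npz",
        tica_eigenvalues=result.tica_model.eigenvalues,
        tica_eigenvectors=result.tica_model.eigenvectors,
        tica_means=result.tica_model.means,
        cluster_centers=result.cluster_model.centers,
        transition_matrix=result.msm_model.transition_matrix,
        stationary=result.msm_model.stationary,
        active_set=result.msm_model.active_set,
        timescales_ns=result.timescales_ns,
    )
    if result.populations is not None:
        result.populations_table().to_csv(outdir / "populations.csv", index=False)
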