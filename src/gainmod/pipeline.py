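"""End-to-end orchestration: simulate, filter, fit, test, cluster, decode.

:func:`run_pipeline` chains the stages on a synthetic cohort and reports a
manifest with survivor counts at every filter, mirroring how the analysis
cascade is reported for real recordings.  Every stochastic stage draws its
generator deterministically from the top-level seed, so identical configs
produce identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import decomposition as _dec
from . import modulators as _mod
from . import tuning as _tuning
from .binning import N_DIRECTIONS, N_SPEED_BINS
from .decode import run_experiment
from .simulate import generate_trials, sample_neuron, uniform_speed_sampler

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run (desk-scale defaults).

    ``mode_fractions`` sets the composition of the simulated cohort as
    fractions of (single-subunit, two-subunit shared, two-subunit
    independent, unmodulated) neurons.  Bootstrap and null counts default to
    desk scale (200); the full-scale settings used for real data (1000
    bootstraps, 10000 null curves) are reachable through the same fields.
    """

    seed: int = 0
    n_neurons: int = 40
    n_trials: int = 4800
    mode_fractions: tuple = (0.3, 0.3, 0.3, 0.1)
    noise_sd: float = 0.2
    speed_sampler: str = "uniform"  # "uniform" or "rest_lognormal"
    n_boot_modulation: int = 200
    n_boot_differential: int = 200
    n_null: int = 200
    lambdas: tuple = tuple(np.round(np.linspace(0.01, 0.1, 10), 10))
    n_inits: int = 5
    n_steps: int = 300
    alpha_differential: float = 0.01
    k_one_subunit: int = 9
    k_two_subunit: int = 12
    decoding: bool = False
    decoding_sizes: tuple = (2, 8, 32)
    decoding_pops: int = 20
    decoding_trials: int = 100
    out_dir: str | None = None


def _cohort(config: RunConfig, rng: np.random.Generator):
    specs = []
    f1, f_sh, f_ind, f_none = config.mode_fractions
    n = config.n_neurons
    counts = [round(n * f) for f in (f1, f_sh, f_ind)]
    counts.append(n - sum(counts))
    for mode, n_sub, c in (
        ("independent", 1, counts[0]),
        ("shared", 2, counts[1]),
        ("independent", 2, counts[2]),
        ("none", 1, counts[3]),
    ):
        specs += [(mode, n_sub)] * c
    return [
        sample_neuron(mode, n_sub, rng, noise_sd=config.noise_sd)
        for mode, n_sub in specs
    ], specs


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain; returns the manifest dict.

    Stages: simulate -> normalize -> tensors + QC -> specificity gate ->
    speed-modulation test -> sparse decomposition (lambda path, permutation
    null, selection) -> differential-modulation test (two-subunit neurons)
    -> modulator clustering -> optional decoding experiment.  If
    ``config.out_dir`` is set, artifacts (trials, curves, fits, cluster
    assignments, manifest) are written there.
    """
    t0 = time.time()
    ss = np.random.SeedSequence(config.seed)
    (
        rng_sim,
        rng_null,
        rng_modtest,
        rng_fit,
        rng_diff,
        rng_clust,
        rng_decode,
    ) = [np.random.default_rng(s) for s in ss.spawn(7)]

    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()}, "stages": {}}

    # --- simulate -----------------------------------------------------------
    neurons, specs = _cohort(config, rng_sim)
    sampler = uniform_speed_sampler() if config.speed_sampler == "uniform" else None
    trials = generate_trials(
        neurons, config.n_trials, rng_sim, speed_sampler=sampler
    )
    manifest["stages"]["simulated"] = len(neurons)

    # --- normalize, tensors, QC --------------------------------------------
    curves = {}
    qc_reasons = {}
    for nid, sub in trials.groupby("neuron_id"):
        sub = sub.copy()
        try:
            sub["response"] = _tuning.threshold_normalize(sub["response"].to_numpy())
        except _tuning.DegenerateNeuronError:
            qc_reasons[nid] = ["degenerate trace"]
            continue
        tensor = _tuning.build_tensor(sub)
        report = _tuning.qc_filters(tensor)
        if not report.passed:
            qc_reasons[nid] = report.reasons
            continue
        curves[nid] = (_tuning.average_frequency(tensor), sub)
    manifest["stages"]["qc_passed"] = len(curves)

    # --- permutation null cohort (shared by specificity gate and fits) -----
    cohort = np.stack([c.values for c, _ in curves.values()]) if curves else np.empty((0, 8, 8))
    if len(curves) == 0:
        manifest["stages"]["runtime_s"] = time.time() - t0
        return manifest
    picks = rng_null.integers(0, cohort.shape[0], size=config.n_null)
    permuted = rng_null.permuted(
        cohort[picks].reshape(config.n_null, -1), axis=1
    ).reshape(config.n_null, N_DIRECTIONS, N_SPEED_BINS)
    null_spec = np.array(
        [_tuning.specificity(c.mean(axis=1)) for c in permuted]
    )
    spec_threshold = float(np.quantile(null_spec, 0.95))

    lambdas = np.asarray(config.lambdas, dtype=float)
    null_snrs = np.empty((lambdas.size, config.n_null))
    for j, lam in enumerate(lambdas):
        _, _, snr = _dec.fit_curves(
            permuted, float(lam), config.n_inits, config.n_steps, rng_null
        )
        null_snrs[j] = snr

    # --- specificity gate ---------------------------------------------------
    tuned = {}
    for nid, (curve, sub) in curves.items():
        s = _tuning.sensory_tuning(curve).specificity
        if s > spec_threshold:
            tuned[nid] = (curve, sub)
    manifest["stages"]["sensory_tuned"] = len(tuned)
    manifest["specificity_threshold"] = spec_threshold

    # --- speed-modulation test ----------------------------------------------
    modulated = {}
    for nid, (curve, sub) in tuned.items():
        res = _tuning.test_modulation(
            sub, n_boot=config.n_boot_modulation, rng=rng_modtest
        )
        if res.significant:
            modulated[nid] = (curve, sub)
    manifest["stages"]["speed_modulated"] = len(modulated)

    # --- sparse decomposition -----------------------------------------------
    fits = {}
    for nid, (curve, sub) in modulated.items():
        model = _dec.SubunitDecomposition(curve)
        path = model.fit_path(
            lambdas, config.n_inits, config.n_steps, rng_fit
        )
        sel = _dec.select_fit(path, lambdas, null_snrs)
        if sel is not None:
            fits[nid] = sel
    manifest["stages"]["fit_significant"] = len(fits)
    manifest["n_significant_subunits"] = {
        str(nid): f.n_significant for nid, f in fits.items()
    }

    # --- differential test on two-subunit neurons ----------------------------
    differential = {}
    pairs = {}
    for nid, fit in fits.items():
        if fit.n_significant < 2:
            continue
        _, sub = modulated[nid]
        pair = _mod.ModulatorPair.from_fit(fit, neuron_id=nid)
        pairs[nid] = pair
        _, rho_data = _mod.corr_max_fit(pair.stronger, pair.weaker, rng=rng_diff)
        null = _mod.bootstrap_shared(
            sub, fit, n_boot=config.n_boot_differential, rng=rng_diff
        )
        res = _mod.test_differential(rho_data, null, alpha=config.alpha_differential)
        differential[nid] = res
    manifest["stages"]["two_subunit"] = len(pairs)
    manifest["stages"]["differentially_modulated"] = sum(
        r.significant for r in differential.values()
    )

    # --- clustering ----------------------------------------------------------
    clusters = {}
    feats_two = {
        nid: _cluster.feature_vector([p.stronger, p.weaker]) for nid, p in pairs.items()
    }
    feats_one = {
        nid: _cluster.feature_vector([f.scaled_modulators[f.significant_subunits[0]]])
        for nid, f in fits.items()
        if f.n_significant == 1
    }
    for name, feats, k in (
        ("two_subunit", feats_two, config.k_two_subunit),
        ("one_subunit", feats_one, config.k_one_subunit),
    ):
        if len(feats) >= 2:
            k_eff = min(k, len(feats))
            result = _cluster.kmeans_cluster(
                np.stack(list(feats.values())), k_eff, rng_clust
            )
            clusters[name] = {
                "neuron_ids": list(feats.keys()),
                "labels": result.labels.tolist(),
                "k": k_eff,
            }
    manifest["clusters"] = {
        name: {"k": c["k"], "n": len(c["labels"])} for name, c in clusters.items()
    }

    # --- optional decoding ----------------------------------------------------
    if config.decoding:
        curve_types = {}
        for neuron_type in ("DS", "OS_shared", "OS_independent"):
            ec = run_experiment(
                neuron_type,
                sizes=config.decoding_sizes,
                n_pops=config.decoding_pops,
                n_trials=config.decoding_trials,
                rng=rng_decode,
                noise_sd=config.noise_sd,
            )
            curve_types[neuron_type] = {
                "sizes": ec.population_sizes.tolist(),
                "direction_error_mean": ec.direction_error_mean.tolist(),
                "speed_error_mean": ec.speed_error_mean.tolist(),
            }
        manifest["decoding"] = curve_types

    manifest["qc_fail_reasons"] = {str(k): v for k, v in qc_reasons.items()}
    manifest["stages"]["runtime_s"] = round(time.time() - t0, 3)

    # --- artifacts ------------------------------------------------------------
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from . import io as _io

        _io.write_trials(trials, out / "trials.csv")
        _io.save_curves({nid: c for nid, (c, _) in curves.items()}, out / "curves.npz")
        _io.save_fits(fits, out / "fits.json")
        rows = []
        for name, c in clusters.items():
            for nid, lab in zip(c["neuron_ids"], c["labels"]):
                rows.append({"group": name, "neuron_id": nid, "cluster": lab})
        if rows:
            pd.DataFrame(rows).to_csv(out / "clusters.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
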