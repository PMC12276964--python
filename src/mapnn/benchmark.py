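"""Reproducible study routines: simulator calibration and parameter recovery.

These are the package's own reduced-scale counterparts of the full
benchmark: map widths, cycle counts and dataset counts are scaled so the
studies complete on a single CPU while preserving the benchmark priors
and procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import mrae
from .model import MapNN, ModelConfig, PairSubsetConfig
from .pipeline import dataset_from_source, random_map, simulate_source
from .simulate import SimParams, SimulationExtinct, run_simulation
from .training import MapDataset, TrainConfig, train

__all__ = ["calibration_study", "recovery_study", "CalibrationResult", "RecoveryResult"]


@dataclass
class CalibrationResult:
    """Input-vs-realized agreement, averaged over cells and replicates.

    ``sigma_pct_below_realized``: mean of 100*(realized - input)/realized
    for the dispersal channel (positive when the input sigma undershoots
    what the simulation actually produced).
    ``k_pct_above_realized``: mean of 100*(input - realized)/realized for
    the density channel (positive when K overshoots realized density).
    """

    sigma_pct_below_realized: float
    k_pct_above_realized: float
    per_rep_sigma: list = field(default_factory=list)
    per_rep_k: list = field(default_factory=list)
    n_reps: int = 0


def calibration_study(n_reps: int = 10, seed: int = 1, width: int = 25,
                      n_cycles: int = 750, burn_in: int = 250,
                      sigma_prior: tuple = (0.73, 3.08),
                      k_prior: tuple = (4.0, 12.0),
                      max_segments: int = 3) -> CalibrationResult:
    """Benchmark-style simulations comparing input maps with realized maps.

    Each replicate draws a random segmented map, runs the simulator, and
    averages the per-cell percent differences between the map parameters
    and the density/dispersal the simulation actually realized.
    """
    root = np.random.SeedSequence(seed)
    sigma_pcts, k_pcts = [], []
    streams = root.spawn(4 * n_reps)
    si = 0
    while len(sigma_pcts) < n_reps:
        rng = np.random.default_rng(streams[si])
        si += 1
        dmap = random_map(sigma_prior, k_prior, rng, width, max_segments)
        params = SimParams(n_cycles=n_cycles, burn_in=burn_in)
        try:
            res = run_simulation(dmap, params, rng, record_realized=True)
        except SimulationExtinct:
            continue  # fresh stream; benchmark priors make this very rare
        sig_in = dmap.dispersal.values
        K_in = dmap.density.values
        sig_re = res.realized.dispersal
        D_re = res.realized.density
        ok = np.isfinite(sig_re) & (sig_re > 0)
        sigma_pcts.append(float(np.mean((sig_re[ok] - sig_in[ok]) / sig_re[ok]) * 100))
        okd = D_re > 0
        k_pcts.append(float(np.mean((K_in[okd] - D_re[okd]) / D_re[okd]) * 100))
    return CalibrationResult(float(np.mean(sigma_pcts)), float(np.mean(k_pcts)),
                             sigma_pcts, k_pcts, n_reps)


@dataclass
class RecoveryResult:
    """Held-out accuracy of a reduced model vs the prior-mean baseline."""

    model_mrae_dispersal: float
    model_mrae_density: float
    baseline_mrae_dispersal: float
    baseline_mrae_density: float
    out_of_range_within_margin: float = float("nan")
    history: object = None
    test_estimates: list = field(default_factory=list)
    test_targets: list = field(default_factory=list)


def _reduced_model_config(n: int, m: int, w: int) -> ModelConfig:
    return ModelConfig(n=n, m=m, w=w, n_features=32, conv_channels=(16,),
                       pool=10, loc_hidden=64, combiner_hidden=32, f_hidden=64,
                       pair_encoding="relatedness", dtype="float32")


def recovery_study(seed: int = 1, width: int = 10, n: int = 20, m: int = 250,
                   n_train_sims: int = 50, draws_per_sim: int = 6,
                   n_test_sims: int = 8, n_cycles: int = 250, burn_in: int = 100,
                   sigma_prior: tuple = (0.25, 1.0), k_prior: tuple = (4.0, 40.0),
                   sigma_m: float = 0.3, max_segments: int = 2,
                   train_config: TrainConfig | None = None,
                   pair_config: PairSubsetConfig | None = None,
                   ensemble: int = 10) -> RecoveryResult:
    """Train a reduced model end-to-end and score it on held-out simulations.

    The reduced habitat (w=10) keeps the *relative* spatial scale of the
    full benchmark: dispersal priors and the mating/competition kernels
    are shrunk with the map so that sigma/w spans roughly the same range
    (a w=10 habitat with sigma up to 1 and sigma_m = 0.3 corresponds to
    the 50-cell habitat with sigma up to ~3 and sigma_m = 1).  Without
    this rescaling most reduced maps are close to panmictic and carry
    little spatial signal.

    Training datasets are resampled ``draws_per_sim`` times per simulation
    (the sample-set augmentation used at full scale).  The no-information
    baseline predicts the per-cell mean of the training targets everywhere;
    MRAE for both is computed against the held-out input maps.
    """
    from .inference import ensemble_predict

    root = np.random.SeedSequence(seed)
    sim_rng, data_rng, model_rng, pred_rng = (np.random.default_rng(s)
                                              for s in root.spawn(4))
    params = SimParams(n_cycles=n_cycles, burn_in=burn_in,
                       sigma_m=sigma_m, sigma_c=sigma_m)
    datasets: list[MapDataset] = []
    for _ in range(n_train_sims):
        dmap = random_map(sigma_prior, k_prior, sim_rng, width, max_segments)
        src = simulate_source(dmap, params, sim_rng)
        for _ in range(draws_per_sim):
            datasets.append(dataset_from_source(src, n, m, data_rng))
    test_sets: list[MapDataset] = []
    for _ in range(n_test_sims):
        dmap = random_map(sigma_prior, k_prior, sim_rng, width, max_segments)
        src = simulate_source(dmap, params, sim_rng)
        test_sets.append(dataset_from_source(src, n, m, data_rng))

    pair_config = pair_config or PairSubsetConfig(k_init=80, k_extract=40)
    train_config = train_config or TrainConfig(batch_size=10, learning_rate=3e-3,
                                               max_epochs=30, seed=seed)
    model = MapNN(_reduced_model_config(n, m, width), model_rng)
    result = train(model, datasets, train_config, pair_config)

    baseline = np.mean([d.target for d in datasets], axis=0)
    model_err = np.zeros(2)
    base_err = np.zeros(2)
    estimates, targets = [], []
    for d in test_sets:
        est = ensemble_predict(result.model, d.genotypes, d.locations, ensemble,
                               result.transform, pred_rng, pair_config).point
        model_err += np.asarray(mrae(d.target, est))
        base_err += np.asarray(mrae(d.target, baseline))
        estimates.append(est)
        targets.append(d.target)
    model_err /= len(test_sets)
    base_err /= len(test_sets)

    # out-of-range robustness: flat maps generated beyond the training
    # priors; predictions should stay within a modest margin of the prior
    oor_within = []
    from .maps import MapChannel, DemographicMap
    z = np.zeros((width, width), np.int64)
    oor_cases = [
        (min(sigma_prior[1] * 1.9, width / 3.0), np.sqrt(k_prior[0] * k_prior[1])),
        (np.sqrt(sigma_prior[0] * sigma_prior[1]), k_prior[1] * 2.0),
    ]
    for sig, K in oor_cases:
        dmap = DemographicMap(MapChannel(width, np.full((width, width), sig), z),
                              MapChannel(width, np.full((width, width), K), z))
        try:
            src = simulate_source(dmap, SimParams(n_cycles=n_cycles, burn_in=burn_in,
                                                  sigma_m=sigma_m, sigma_c=sigma_m),
                                  sim_rng)
        except SimulationExtinct:
            continue
        d = dataset_from_source(src, n, m, data_rng)
        est = ensemble_predict(result.model, d.genotypes, d.locations, ensemble,
                               result.transform, pred_rng, pair_config).point
        ok_sig = (est[:, :, 0] >= sigma_prior[0] / 1.5) & (est[:, :, 0] <= 1.5 * sigma_prior[1])
        ok_k = (est[:, :, 1] >= k_prior[0] / 1.5) & (est[:, :, 1] <= 1.5 * k_prior[1])
        oor_within += [ok_sig.mean(), ok_k.mean()]
    oor = float(np.mean(oor_within)) if oor_within else float("nan")

    return RecoveryResult(model_err[0], model_err[1], base_err[0], base_err[1],
                          oor, result.history, estimates, targets)
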