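"""The synthetic study generator: roster, printed masses, geometry,
determinism, pseudo-observations and parameter recovery."""

import json

import numpy as np
import pytest

import quadbalance as qb
from quadbalance.assessment import force_fit
from quadbalance.io import limb_to_dict
from quadbalance.synthetic import (
    ANIMAL_PRESETS,
    MUSCLE_ROSTER,
    PRINTED_MASSES_G,
    check_mme_feasible,
    cosine_tuning,
    generate_hindlimb_model,
    generate_pseudo_observations,
)


def test_roster_and_printed_masses(config):
    limb = generate_hindlimb_model(config)
    assert len(limb.muscles) == 31
    assert tuple(limb.muscle_names) == MUSCLE_ROSTER
    by_name = {m.name: m for m in limb.muscles}
    for name, mass in PRINTED_MASSES_G.items():
        assert by_name[name].mass == mass
    assert by_name["LG"].mass == 12.4
    assert by_name["ADF"].mass == 4.0  # common default for unlisted muscles


def test_same_seed_bit_identical_model(config):
    a = generate_hindlimb_model(config, seed=77)
    b = generate_hindlimb_model(config, seed=77)
    assert json.dumps(limb_to_dict(a)) == json.dumps(limb_to_dict(b))
    c = generate_hindlimb_model(config, seed=78)
    assert json.dumps(limb_to_dict(a)) != json.dumps(limb_to_dict(c))


def test_animal_presets_match_paradigm():
    assert ANIMAL_PRESETS["bi"]["stance_distances"] == (30.0, 27.0, 20.0, 13.0)
    assert ANIMAL_PRESETS["ru"]["com_height"] == 15.2
    assert len(ANIMAL_PRESETS["ni"]["stance_distances"]) == 3


def test_scenario_geometry(config, quadruped):
    stance = quadruped.stance
    assert stance.stance_width == 8.0
    ep = quadruped.endpoints * 100  # cm
    assert np.allclose(np.abs(ep[:, 0]), 4.0)
    assert np.allclose(np.abs(ep[:, 1]), stance.stance_distance / 2)
    assert np.allclose(quadruped.com_position[:2], 0.0)
    assert np.isclose(quadruped.com_position[2] * 100, 12.6)


def test_generated_scenario_admits_feasible_mme(quadruped):
    assert check_mme_feasible(quadruped, directions_deg=(0.0, 180.0))


def test_noiseless_observations_match_generator_exactly(config):
    obs = generate_pseudo_observations(config, noise=0.0, solve_forces=False)
    assert np.array_equal(obs.forces, obs.forces_true)
    assert np.array_equal(obs.emg, obs.emg_true)
    assert np.all(obs.forces[..., 2] >= 0)
    assert np.all(obs.emg >= 0)


def test_assessment_round_trip_on_noiseless_data(config, quadruped, mme_all_directions):
    """Predictions assessed against noiseless pseudo-observations built
    from the same solutions give R^2 = 1 in every force component."""
    pred = np.stack([r.limb_forces for r in mme_all_directions])
    rng_free = pred.copy()  # noiseless observations = predictions
    report = force_fit(pred, rng_free)
    for v in report.as_dict().values():
        assert np.isclose(v, 1.0)


def test_observation_noise_is_seeded(config):
    a = generate_pseudo_observations(config, seed=3, solve_forces=False)
    b = generate_pseudo_observations(config, seed=3, solve_forces=False)
    assert np.array_equal(a.forces, b.forces)
    assert np.array_equal(a.emg, b.emg)
    with pytest.raises(ValueError):
        generate_pseudo_observations(config, noise=-0.1, solve_forces=False)


def test_tuning_peak_recovery_under_noise(config):
    """Monte-Carlo recovery: at 10% noise the cosine peak directions are
    recovered within 15 degrees (90th percentile over 100 seeds)."""
    from quadbalance.assessment import fit_cosine_peak
    errors = []
    for seed in range(100):
        obs = generate_pseudo_observations(config, seed=seed, noise=0.10,
                                           stances=[config.preferred_stance()],
                                           solve_forces=False)
        true_peaks = obs.ground_truth["peak_dirs_deg"]
        for mi in range(len(obs.muscle_names)):
            est = fit_cosine_peak(obs.directions_deg, obs.emg[0, :, mi])
            err = abs((est - true_peaks[mi] + 180.0) % 360.0 - 180.0)
            errors.append(err)
    assert np.quantile(errors, 0.9) <= 15.0


def test_cosine_tuning_width():
    dirs = np.linspace(0, 360, 721)
    curve = cosine_tuning(dirs, peak_deg=90.0, halfwidth_deg=120.0, amplitude=2.0)
    assert np.isclose(curve.max(), 2.0)
    above_half = dirs[curve >= 1.0]
    assert np.isclose(above_half.max() - above_half.min(), 120.0, atol=1.5)
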