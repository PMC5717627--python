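import numpy as np
import pandas as pd
import pytest

import decision_landscapes as dl


@pytest.fixture(scope="session")
def alpha3_params():
    """Ground-truth asymmetric landscape used for simulate-then-fit checks."""
    return dl.LandscapeParams(
        alpha=3, tau=0.08, coeffs={(1, 1): 0.3, (2, 1): -0.1, (1, 2): 0.1}
    )


@pytest.fixture(scope="session")
def sim_dataset(alpha3_params):
    """20 noise-free trajectories from the ground-truth landscape, seeded
    symmetric starts (trials whose paths leave the arena are dropped)."""
    cfg = dl.SimulationConfig(dt=0.001, seed=7, start_offset_scale=0.02)
    return dl.generate_dataset(alpha3_params, 20, cfg, symmetric_starts=True)


@pytest.fixture(scope="session")
def preprocessed_dataset(sim_dataset):
    trajs, vels = [], []
    for t in sim_dataset:
        tt = dl.resample(dl.trim(t), 101)
        trajs.append(tt)
        vels.append(dl.estimate_velocity(tt))
    return trajs, vels


@pytest.fixture
def geometry():
    """Screen-pixel layout: start bottom-centre, targets in the top corners,
    device y growing downward."""
    return dl.ScreenGeometry(
        start=(640.0, 900.0),
        left_target=(140.0, 100.0),
        right_target=(1140.0, 100.0),
        y_up=False,
    )


def make_raw_csv(path, trials):
    """Write a long-format cursor log; ``trials`` is a list of dicts with
    participant, trial, times, xs, ys."""
    frames = []
    for tr in trials:
        frames.append(
            pd.DataFrame(
                {
                    "participant": tr["participant"],
                    "trial": tr["trial"],
                    "t": tr["times"],
                    "x": tr["xs"],
                    "y": tr["ys"],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


@pytest.fixture
def raw_log(tmp_path, geometry):
    """Two clean pixel-coordinate trials (one right, one left) plus the file path."""
    rng = np.random.default_rng(42)
    t = np.linspace(0.0, 1.0, 40)
    trials = []
    for trial, side in (("1", 1), ("2", -1)):
        frac = t  # monotone progress
        xs = 640.0 + side * 500.0 * frac + rng.normal(0, 2.0, t.size)
        ys = 900.0 - 800.0 * frac + rng.normal(0, 2.0, t.size)
        xs[0], ys[0] = 640.0, 900.0
        xs[-1] = 640.0 + side * 500.0
        ys[-1] = 100.0
        trials.append({"participant": "p1", "trial": trial, "times": t, "xs": xs, "ys": ys})
    path = make_raw_csv(tmp_path / "log.csv", trials)
    return path, trials


def straight_trajectory(duration=0.5, n=101, choice=1, pid="p", tid="t"):
    """Uniformly sampled straight path from (0,0) to (choice, 1)."""
    ts = np.linspace(0.0, duration, n)
    frac = ts / duration
    return dl.Trajectory(
        participant_id=pid, trial_id=tid, times=ts, xs=choice * frac, ys=frac, choice=choice
    )
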