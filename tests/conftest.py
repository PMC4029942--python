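import numpy as np
import pytest

from vitalkf import load_preset, pipeline, synthetic


@pytest.fixture(scope="session")
def subject1_session():
    """150 s subject-1-like session, fixed seed."""
    return synthetic.generate(synthetic.preset("subject1_like", seed=7, duration_s=150))


@pytest.fixture(scope="session")
def se1_adaptive_run(subject1_session):
    return pipeline.run(
        subject1_session.sensors,
        load_preset("SE1", adaptive=True),
        check_covariance_every=25,
    )


@pytest.fixture(scope="session")
def se1_nonadaptive_run(subject1_session):
    return pipeline.run(
        subject1_session.sensors, load_preset("SE1", adaptive=False)
    )


@pytest.fixture(scope="session")
def validation_session():
    """120 s equal-sensor session with noise in the identifiable regime."""
    return synthetic.generate(
        synthetic.preset("estimator_validation", seed=11, duration_s=120)
    )


@pytest.fixture(scope="session")
def validation_run(validation_session):
    """Adaptive run from generic defaults on the validation session."""
    return pipeline.run(
        validation_session.sensors, load_preset("DS"), record_params=True
    )


def windowed_heart_std_truth(session, config) -> np.ndarray:
    """Truth counterpart of the short-window heart-std estimator.

    Evaluates the same functional — std of a 0.5 s window divided by the
    heart divisor — on the noise-free signal components, averaged over all
    estimation instants after the warm-up.
    """
    clean = (
        session.truth.offset_track
        + session.truth.resp_component
        + session.truth.heart_component
    )
    w = config.short_window_len
    starts = range(config.warmup_samples, clean.shape[0] - w, config.cadence)
    vals = np.array(
        [clean[s : s + w].std(axis=0) / config.heart_std_divisor for s in starts]
    )
    return vals.mean(axis=0)
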