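import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import voxfrail as vf

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_vowel(seed=0, duration_s=1.0, **knobs):
    """Synthesize a vowel with defaults overridden by keyword knobs."""
    src = dict(f0=120.0, jitter_pct=0.5, shimmer_pct=2.0,
               open_quotient=0.6, noise_snr_db=30.0)
    tract = dict(drift_amplitude=10.0)
    for key, val in knobs.items():
        (src if key in src else tract)[key] = val
    spec = vf.VowelSpec(source=vf.GlottalSourceParams(**src),
                        tract=vf.VocalTractParams(**tract),
                        duration_s=duration_s, seed=seed)
    return vf.synthesize_vowel(spec)


def make_zero_perturbation_vowel(seed=0, duration_s=1.0, **knobs):
    """A vowel with no jitter, shimmer, formant drift or aspiration noise."""
    knobs.setdefault("jitter_pct", 0.0)
    knobs.setdefault("shimmer_pct", 0.0)
    knobs.setdefault("noise_snr_db", None)
    knobs.setdefault("drift_amplitude", 0.0)
    return make_vowel(seed=seed, duration_s=duration_s, **knobs)


@pytest.fixture(scope="session")
def zero_perturbation_vowel():
    return make_zero_perturbation_vowel()


@pytest.fixture(scope="session")
def default_vowel():
    return make_vowel(seed=3)


@pytest.fixture(autouse=True)
def _quiet_extractor_warnings():
    # skipped-frame notices from the formant tracker are expected on some
    # synthetic inputs and are asserted explicitly where they matter
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def make_replicate_vowel(seed, **knobs):
    """One replicate of a synthesis study: a new speaker per replicate.

    Each replicate draws its fundamental frequency from a speaker
    distribution (uniform 100-200 Hz, spanning typical male and female
    sustained-vowel f0). At a single fixed f0 the alignment of harmonics
    with the 800 Hz band edge adds ripple that can mask a monotone trend.
    """
    rng = np.random.default_rng(seed)
    knobs.setdefault("f0", rng.uniform(100.0, 200.0))
    return make_vowel(seed=seed, **knobs)


def mean_feature(feature_fn, knob, levels, n_reps, base_seed=17, **fixed):
    """Mean of a feature over replicate speakers at each knob level."""
    out = []
    for level in levels:
        vals = [feature_fn(make_replicate_vowel(1000 * r + base_seed,
                                                **{knob: level}, **fixed))
                for r in range(n_reps)]
        out.append(float(np.mean(vals)))
    return out
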