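"""Shared synthetic scenes (generated once per session; all fixtures are
seeded so the suite is deterministic)."""

import numpy as np
import pytest

from batforage import acoustics, synth


@pytest.fixture(scope="session")
def small_scene():
    """60 s scene, 3 gleaning + 3 hawking attacks, 94 kHz audio."""
    rng = np.random.default_rng(0)
    cfg = synth.SynthConfig(seed=0, duration=60.0, audio_fs=94000.0)
    cfg.schedule = synth.make_schedule(3, 3, 60.0, rng)
    rec, log = synth.generate_scene(cfg)
    return cfg, rec, log


@pytest.fixture(scope="session")
def small_scene_calls(small_scene):
    _, rec, _ = small_scene
    return acoustics.detect_calls(rec.audio, rec.audio_fs)


@pytest.fixture(scope="session")
def motion_scene():
    """240 s scene with a foraging bout in the middle third."""
    rng = np.random.default_rng(1)
    cfg = synth.SynthConfig(seed=1, duration=240.0, audio_fs=94000.0)
    cfg.schedule = synth.make_schedule(3, 3, 240.0, rng)
    rec, log = synth.generate_scene(cfg)
    return cfg, rec, log
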