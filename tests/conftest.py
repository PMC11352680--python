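import logging

import numpy as np
import pytest

import emgtaste as e

logging.getLogger("emgtaste").setLevel(logging.ERROR)


@pytest.fixture
def pre_config():
    return e.PreprocessConfig()


def make_window(samples, fs=1000.0, label="no", stage="raw", **prov):
    return e.WindowSample(
        samples=np.atleast_2d(np.asarray(samples, dtype=float)),
        fs=fs,
        label=label,
        provenance=prov,
        stage=stage,
    )


def silent_config(**kw):
    """SynthConfig with every noise source off; one taste unless overridden."""
    defaults = dict(
        n_participants=1,
        sessions=1,
        tastes=("no",),
        class_band_profiles={"no": np.zeros(13)},
        participant_heterogeneity=0.0,
        drift_coeff_scale=0.0,
        powerline_amp=0.0,
        powerline_harmonics=0,
        artifact_amp=0.0,
        outlier_prob=0.0,
        seed=0,
    )
    defaults.update(kw)
    return e.SynthConfig(**defaults)


def pipeline_dataset(cfg, eval_ready=True):
    """Generate -> preprocess -> features; optionally wrap as DatasetTable."""
    recs, _ = e.generate_dataset(cfg)
    pc = e.PreprocessConfig()
    windows = []
    for r in recs:
        windows.extend(e.preprocess_pipeline(r, pc))
    table = e.extract_feature_table(windows)
    if not eval_ready:
        return table
    return e.DatasetTable.from_dataframe(table)
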