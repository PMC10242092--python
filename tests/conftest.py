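import numpy as np
import pytest

import plethysym as ps


@pytest.fixture(scope="session")
def trio_archetypes():
    return ps.archetype_trio()


@pytest.fixture(scope="session")
def trio_noise_sd(trio_archetypes):
    """White-noise level corresponding to SNR 20 dB for the trio vocabulary."""
    return ps.noise_sd_for_snr(trio_archetypes, 20.0)


@pytest.fixture(scope="session")
def trio_cohort(trio_archetypes, trio_noise_sd):
    """Four noisy, warped recordings mixing the three trio archetypes."""
    mix = {"g": {"A0": 0.34, "C2": 0.33, "E4": 0.33}}
    return ps.generate_cohort(4, mix, trio_archetypes, cycles_per_recording=60,
                              noise_sd=trio_noise_sd, warp_pct=0.2, seed=2)


@pytest.fixture(scope="session")
def trio_fit(trio_cohort):
    """Models fitted on the trio cohort (K=3 per phase), with thresholds."""
    cfg = ps.PipelineConfig(k_insp=3, k_exp=3, seed=3)
    recs = [r for r, _ in trio_cohort]
    insp, exp = ps.subsample_training(recs, 60, cfg)
    mi, me, thi, the = ps.fit_models(insp, exp, cfg)
    return {"cfg": cfg, "recs": recs, "cohort": trio_cohort,
            "insp": insp, "exp": exp,
            "insp_model": mi, "exp_model": me,
            "insp_thr": thi, "exp_thr": the}
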