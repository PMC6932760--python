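import numpy as np
import pytest

from spindlequant import Movie, SimulationParams, generate_movie


@pytest.fixture
def small_params():
    """A fast 4-nucleus field for generic generator tests."""
    return SimulationParams(
        field_size_px=(256, 256),
        n_frames=6,
        n_nuclei=4,
        enrichment_slope1_per_s=0.0005,
        enrichment_slope2_per_s=0.001,
        phase_break_s=105.0,
        neb_time_s=105.0,
        peak_enrichment=0.2,
        cytoplasm_depletion_frac=0.1,
        noise_sd=5.0,
        n_cytoplasm_sites=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def fig1d_run():
    """One rendered fig1d-preset movie with its ground truth (shared)."""
    from spindlequant import builtin_preset
    from dataclasses import replace

    params = replace(builtin_preset("fig1d_rtnl1"), seed=3)
    return generate_movie(params)


def make_movie(data, pixel_size_um=0.1, frame_interval_s=35.0, channels=None):
    data = np.asarray(data)
    return Movie(
        data=data,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        channel_names=channels or [f"ch{i}" for i in range(data.shape[1])],
    )
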