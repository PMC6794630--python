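"""Shared fixtures: small geometries and noiseless imaging for fast runs.

The device physics is homogeneous along the channel axis in every scenario
studied here (initial conditions, sources, and events are uniform in y), so
tests use a channel length of 100 um; cross-channel transport is identical
to the full 7.5 mm device.
"""

import numpy as np
import pytest

from bbbchip.geometry import build_default_layout
from bbbchip.imaging import (
    AssayGroundTruth,
    ImagingModel,
    render_timelapse,
    simulate_dextran_assay,
)
from bbbchip.permeability import (
    PermeabilityAssayModel,
    default_control_volume,
    recommended_cv_depth_um,
)


@pytest.fixture(scope="session")
def short_layout():
    return build_default_layout(length_um=100.0)


@pytest.fixture(scope="session")
def noiseless_model():
    return ImagingModel().noiseless()


@pytest.fixture(scope="session")
def assay_roundtrip(short_layout, noiseless_model):
    """Run one synthetic assay end to end and return the estimate."""

    def _run(
        p_true_cm_s,
        solute="dextran_40kda",
        model=None,
        seed=1,
        fit_mode="two_point",
        window_s=600.0,
        n_frames=3,
        frame_interval_s=300.0,
        cv_depth_um=None,
        dx_um=25.0,
        layout=None,
    ):
        layout = layout if layout is not None else short_layout
        truth = AssayGroundTruth(
            p_true_cm_s=p_true_cm_s,
            solute=solute,
            layout=layout,
            n_frames=n_frames,
            frame_interval_s=frame_interval_s,
        )
        history = simulate_dextran_assay(truth, dx_um=dx_um, dt_s=10.0)
        stack = render_timelapse(
            history, model if model is not None else noiseless_model, seed
        )
        if cv_depth_um is None:
            d_gel = layout.materials["collagen_scaffold"].diffusivity[solute]
            cv_depth_um = recommended_cv_depth_um(d_gel, window_s)
        cv = default_control_volume(
            layout, stack.pixel_size_um, depth_um=cv_depth_um
        )
        return PermeabilityAssayModel.from_timelapse(stack, cv).fit(
            mode=fit_mode, window_s=window_s
        )

    return _run
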