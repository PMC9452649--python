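"""Shared test utilities."""

import numpy as np

from courtload import signal as sg
from courtload.calibrate import IntensityBands, band_minutes, classify_epochs


def recover_band_minutes(trace, mass, g_max):
    """Run the filter->force->band chain and return minutes per band.

    Thresholds come from the planted truth (band edges are fixed
    fractions of the acceleration at VO2max), so recovered minutes can be
    compared directly with planted bout schedules.
    """
    thresholds = np.array([0.1, 0.4, 0.9, 1.0]) * g_max * mass * sg.G_TO_MS2
    bands = IntensityBands(player_id=trace.player_id,
                           edges_pct=(10, 40, 90, 100),
                           thresholds_n=thresholds)
    filt = sg.bandpass_filter(trace)
    mag = sg.resultant_acceleration(filt)
    force = sg.compute_force_series(mag, mass, trace.sample_rate, 1.0,
                                    player_id=trace.player_id)
    return band_minutes(classify_epochs(force, bands), 1.0)
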