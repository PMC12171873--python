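"""Reference analysis parameters for the three published transporter
systems, as used to build their state models (lags in ns; frame interval
0.1 ns).  These are provided as configuration presets; reproducing the
published state assignments additionally requires the deposited
trajectories."""

REFERENCE_PARAMETERS = {
    "GLUT1-Apo": {
        "frame_interval": 0.1,
        "tica_lag": 1.0,
        "tica_components": 3,
        "n_microstates": 100,
        "msm_lag": 5.0,
        "igme_L": 9.5,
        "igme_tau_k": 0.4,
        "n_macro": 10,
    },
    "GLUT9-Apo": {
        "frame_interval": 0.1,
        "tica_lag": 0.2,
        "tica_components": 3,
        "n_microstates": 100,
        "msm_lag": 2.0,
        "igme_L": 9.6,
        "igme_tau_k": 0.4,
        "n_macro": 7,
    },
    "GLUT9-API": {
        "frame_interval": 0.1,
        "tica_lag": 2.0,
        "tica_components": 3,
        "n_microstates": 100,
        "msm_lag": 2.0,
        "igme_L": 9.5,
        "igme_tau_k": 0.1,
        "n_macro": 6,
    },
}

#: shared conventions of the pathway detector
PATHWAY_DEFAULTS = {
    "som_grid": (10, 10),
    "som_cycles": 5000,
    "distance_cap": 12.0,
    "contact_cutoff": 4.0,
    "occupancy_threshold": 0.5,
    "temperature": 310.0,
}
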