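"""Coherent reflection imaging through a dynamic scatterer, end to end.

A reflective mask sits a distance dz behind the scattering layer.  Its
field is propagated to the scatterer plane, multiplied frame by frame by a
fresh random-screen APSF (convolution at the camera), recorded as off-axis
holograms, demodulated back to complex fields, reconstructed with the
coherent (field) covariance retrieval, and finally Fresnel-propagated back
to the object plane.  The per-frame diffuser APSFs are then estimated from
the ratio of each measured field to the reconstruction.
"""

import numpy as np

from classim import ExperimentConfig, run_experiment

cfg = ExperimentConfig(
    mode="coherent",
    object_name="bars",
    grid=128,
    n_frames=180,
    screen={"corr_len_px": 4, "rms_rad": 2 * np.pi, "pupil_radius_frac": 0.25},
    n_iter=1000,
    dz_um=2000.0,
    wavelength_um=0.6328,
    pitch_um=5.5,
    holography=True,
    seed=3,
)

manifest = run_experiment(cfg)
m = manifest["metrics"]
print(f"frames: {cfg.n_frames}, grid: {cfg.grid}, dz = {cfg.dz_um} um, "
      f"holographic acquisition: {cfg.holography}")
print(f"r at scatterer plane (|recon| vs |effective object|): {m['r_recon']:.3f}")
print(f"r at object plane after back-propagation:             {m['r_object_plane']:.3f}")
print(f"r of raw mean field (no compensation):                {m['r_mean_frame']:.3f}")
print(f"mean APSF recovery correlation:                       {m['apsf_recovery_mean_r']:.3f}")
# back-propagating the compensated field focuses the mask; the uncompensated
# mean field stays speckle-blurred.  APSF correlations near 1 mean the
# per-frame diffuser phase is recovered from the data.
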