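"""Numeric defaults shared across the pipelines.

All values mirror the acquisition and analysis settings the pipelines were
designed around; command-line tools read them from here so every default
lives in one place.
"""

SPATIAL_BIN_FACTOR = 4          # 4x4 binning of raw widefield frames
HIGHPASS_HZ = 0.01              # second-order Butterworth high-pass corner
LOWPASS_HZ = 10.0               # second-order Butterworth low-pass corner
PRE_STIM_WINDOW_S = 0.5         # F0 baseline window before the stimulus
DURATION_FRACTION = 0.2         # response ends at 20% of peak
AREA_THRESHOLD_SD = 2.0         # active-area threshold: mean + 2 SD
PIXEL_SIZE_UM = 30.0            # binned widefield pixel pitch (~30 um)
EPSC_WINDOW_S = 0.150           # post-stimulus EPSC acceptance window
PHOTOSTIM_GRID = (15, 28)       # depth rows x columns of stimulation sites
DEPTH_PROFILE_BINS = 10         # cortical-depth log2FC profile bins
RADIAL_PROFILE_BINS = 100       # radial-axis bins for IUE-vs-contra L4
FOS_ROW_BINS = 30               # B2-C2-D2 row-profile bins
INTERACTION_ZONE_CM = 4.0       # square zone around each texture panel
SHIFT_TEST_DELTA = 0.1          # directional signed-rank shift
BOOTSTRAP_B_BINOMIAL = 4999     # bootstrap replicates, binomial GLMM
BOOTSTRAP_B_LINEAR = 999        # bootstrap replicates, linear mixed model
GLMM_QUAD_NODES = 25            # adaptive Gauss-Hermite nodes
ROLLING_BALL_RADIUS_DEPTH = 300  # background radius, cortical-depth ISH
ROLLING_BALL_RADIUS_FOS = 50     # background radius, fos sections
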