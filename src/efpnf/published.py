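"""Printed summary statistics of the randomized amyg-EFP-NF add-on trial.

These are the group-level numbers reported for the trial (55 women with
treatment-resistant childhood-sexual-abuse PTSD, 2.5/1 allocation to
EFP-neurofeedback add-on vs. continuing psychotherapy).  They serve two
purposes: as calibration inputs for the synthetic cohort generator, and
as inputs to the self-contained arithmetic reproductions (symptom-
reduction deltas, NNT from the absolute risk reduction).
"""

N_TEST = 40
N_CONTROL = 15

# Pre-treatment group means (SD) per instrument.
PRE_MEANS = {
    "test": {"CAPS5": 40.52, "PCL5": 42.97, "DES2": 28.93},
    "control": {"CAPS5": 43.06, "PCL5": 44.86, "DES2": 32.33},
}
PRE_SDS = {
    "test": {"CAPS5": 9.92, "PCL5": 16.83, "DES2": 19.06},
    "control": {"CAPS5": 10.0, "PCL5": 19.05, "DES2": 21.51},
}

# Post-treatment CAPS-5 means (SD) from the immediate-effect analysis.
POST_CAPS5 = {"test": 31.66, "control": 39.78}
POST_CAPS5_SD = {"test": 11.83, "control": 12.51}

# Reported CAPS-5 point reductions (pre minus post).
REDUCTION_CAPS5 = {"test": 8.86, "control": 3.28}

# Loss-of-diagnosis effect sizes.
ARR = 0.247          # absolute risk reduction
ARR_CI = (0.0186, 0.5131)
NNT = 4.04

# PCL-5 means at the 6-month follow-up (between-group post hoc).
PCL5_6M = {"test": 27.47, "control": 42.9}

# Instrument score ranges (totals).
SCORE_RANGES = {"CAPS5": (0.0, 80.0), "PCL5": (0.0, 80.0), "DES2": (0.0, 100.0)}

# A priori power analysis inputs reported for the trial.
POWER_ETA_SQ = 0.16
POWER_ALPHA = 0.05
POWER_TARGET = 0.8
POWER_REQUIRED_N = 45

# NF training signal summary (success-index units).
TRAINING_MEANS = {"Regulate": -0.58, "Watch": -0.40}
FIRST5_MEAN = -0.58
LAST5_MEAN = -0.82

TIMEPOINTS = ("pre", "post", "m1", "m3", "m6")
INSTRUMENTS = ("CAPS5", "PCL5", "DES2")
GROUPS = ("test", "control")
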