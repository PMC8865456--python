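"""Published reference regression table for a healthy-aging FDG-PET cohort.

Reported multiple-regression results (Y = b0 + b1*age [+ b2*age^2]) for
four metabolic network metrics within the whole brain and the functional
subnetworks of a published 100-parcel KLSE study of 67 healthy adults aged
20-82.  Coefficients are transcribed at their printed precision together
with the printed predictions at ages 20 and 80 and the printed lifespan
percent difference.  The table serves as input for arithmetic
verification: evaluating the model with the printed coefficients should
reproduce the printed predictions wherever coefficient rounding permits.
"""
from __future__ import annotations

import pandas as pd

# metric, scope, model, p, r, b0, b1, b2, printed Y(20), Y(80), %diff
_ROWS = [
    ("mean_strength", "whole_brain", "linear", 0.0001, 0.45, 0.34, -0.88e-3, None, 0.32, 0.27, -16.3),
    ("mean_strength", "frontoparietal", "quadratic", 0.0003, 0.48, 0.13, 6.80e-3, -0.08e-3, 0.23, 0.14, -41.2),
    ("mean_strength", "default_mode", "linear", 0.0179, 0.29, 0.31, -0.739e-3, None, 0.30, 0.25, -14.9),
    ("mean_strength", "control", "linear", 0.0048, 0.34, 0.44, -1.182e-3, None, 0.41, 0.34, -17.2),
    ("mean_strength", "dorsal_attention", "linear", 0.0061, 0.33, 0.50, -1.442e-3, None, 0.47, 0.38, -18.4),
    ("mean_strength", "ventral_attention", "linear", 1e-4, 0.48, 0.48, -2.06e-3, None, 0.44, 0.31, -28.3),
    ("char_path_length", "whole_brain", "linear", 1e-4, 0.49, 2.29, 5.26e-3, None, 2.39, 2.71, 13.2),
    ("char_path_length", "frontoparietal", "quadratic", 0.0001, 0.49, 4.56, -94.12e-3, 1.21e-3, 3.16, 4.78, 51.4),
    ("char_path_length", "default_mode", "linear", 0.0036, 0.35, 2.43, 7.19e-3, None, 2.57, 3.01, 16.8),
    ("char_path_length", "control", "linear", 0.0121, 0.30, 1.97, 4.78e-3, None, 2.07, 2.35, 13.9),
    ("char_path_length", "dorsal_attention", "linear", 0.0031, 0.36, 1.69, 6.28e-3, None, 1.81, 2.19, 20.8),
    ("char_path_length", "ventral_attention", "linear", 1e-4, 0.51, 1.72, 11.11e-3, None, 1.94, 2.61, 34.4),
    ("clustering", "whole_brain", "linear", 0.0001, 0.45, 0.36, -0.92e-3, None, 0.34, 0.28, -16.4),
    ("clustering", "frontoparietal", "quadratic", 0.0003, 0.47, 0.23, 9.40e-3, -0.11e-3, 0.37, 0.28, -24.8),
    ("clustering", "default_mode", "linear", 0.0314, 0.26, 0.34, -0.74e-3, None, 0.33, 0.29, -13.5),
    ("clustering", "control", "linear", 0.0048, 0.34, 0.49, -1.31e-3, None, 0.46, 0.39, -16.9),
    ("clustering", "dorsal_attention", "linear", 0.0117, 0.31, 0.58, -1.54e-3, None, 0.55, 0.45, -16.9),
    ("clustering", "ventral_attention", "linear", 1e-4, 0.47, 0.55, -2.29e-3, None, 0.51, 0.37, -27.0),
    ("local_efficiency", "whole_brain", "linear", 1e-4, 0.50, 0.24, -0.60e-3, None, 0.23, 0.20, -15.5),
    ("local_efficiency", "frontoparietal", "quadratic", 0.0011, 0.44, 0.05, 8.31e-3, -0.10e-3, 0.18, 0.08, -53.4),
    ("local_efficiency", "default_mode", "quadratic", 0.0134, 0.36, 0.15, 2.22e-3, -0.03e-3, 0.18, 0.15, -16.1),
    ("local_efficiency", "control", "linear", 0.0026, 0.36, 0.29, -0.93e-3, None, 0.27, 0.22, -20.4),
    ("local_efficiency", "dorsal_attention", "linear", 0.0096, 0.31, 0.34, -1.04e-3, None, 0.32, 0.26, -19.5),
    ("local_efficiency", "ventral_attention", "linear", 0.0001, 0.46, 0.29, -1.36e-3, None, 0.27, 0.19, -30.5),
]

COLUMNS = [
    "metric", "scope", "model", "p_value", "r",
    "beta0", "beta1", "beta2",
    "printed_pred20", "printed_pred80", "printed_pct_diff",
]


def reference_regression_table() -> pd.DataFrame:
    """The published significant regression rows as a DataFrame."""
    return pd.DataFrame(_ROWS, columns=COLUMNS)


#: (metric, scope) keys of the rows whose *printed* rounded coefficients
#: exactly reproduce all three printed values (Y20, Y80, %diff) under
#: half-away-from-zero rounding; the remaining rows differ only through
#: coefficient rounding and are therefore not arithmetically recomputable
#: at printed precision.
SELF_CONSISTENT_ROWS = (
    ("mean_strength", "dorsal_attention"),
    ("char_path_length", "default_mode"),
    ("char_path_length", "control"),
    ("clustering", "control"),
    ("local_efficiency", "dorsal_attention"),
)
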