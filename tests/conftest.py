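"""Shared fixtures: the bundled 14-item teaching-clinic survey and its
published per-item results, frozen for regression checks."""

from __future__ import annotations

import pytest

from kanokit.datasets import teaching_clinic_frequencies


@pytest.fixture(scope="session")
def clinic_freqs():
    """14-item frequency table of the teaching-clinic survey (N=101/item)."""
    return teaching_clinic_frequencies()


# item_id -> (traditional, CS 2dp, TS 2dp, optimized label)
CLINIC_ATTRIBUTES = {
    "1": ("A", 0.01, 0.83, "H (A + M)"),
    "2": ("M", 0.02, 0.90, "H (M + A)"),
    "3": ("A", 0.09, 0.84, "A"),
    "4": ("O", 0.01, 0.91, "H (O + A)"),
    "5": ("I", 0.05, 0.50, "I"),
    "6": ("O", 0.09, 0.99, "O"),
    "7": ("I", 0.07, 0.50, "I"),
    "8": ("A", 0.01, 0.71, "H (A + I)"),
    "9": ("A", 0.04, 0.70, "H (A + I)"),
    "10": ("A", 0.11, 0.88, "A"),
    "11": ("M", 0.19, 0.97, "M"),
    "12": ("O", 0.07, 0.72, "O"),
    "13": ("O", 0.15, 0.95, "O"),
    "14": ("O", 0.35, 0.98, "O"),
}

# item_id -> (SI 2dp, DSI 2dp)
CLINIC_INFLUENCES = {
    "1": (0.53, -0.52),
    "2": (0.56, -0.58),
    "3": (0.58, -0.50),
    "4": (0.64, -0.59),
    "5": (0.48, -0.12),
    "6": (0.61, -0.84),
    "7": (0.50, -0.14),
    "8": (0.50, -0.42),
    "9": (0.55, -0.37),
    "10": (0.76, -0.45),
    "11": (0.44, -0.88),
    "12": (0.49, -0.58),
    "13": (0.57, -0.90),
    "14": (0.67, -0.96),
}

CLINIC_CENTROID = (0.5650, 0.5607)  # (mean SI, mean |DSI|) at 4 dp

CLINIC_QUADRANTS = {
    "one-dimensional": {"4", "6", "13", "14"},
    "attractive": {"2", "11", "12"},
    "indifferent": {"1", "5", "7", "8", "9"},
    "must-be": {"3", "10"},
}
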