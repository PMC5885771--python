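"""Published external-benchmark confusion matrices used as metric fixtures.

Three external bitterant test sets have printed per-model confusion counts
(TP, TN, FP, FN) and the six derived metrics for several prediction tools.
The counts are inputs; the metric engine must reproduce every printed
metric from them at 3-decimal rounding, with ``None`` standing for the
"–" cells (undefined ratios on single-class data).

Datasets: "bitter_new" (23 bitterants, no non-bitterants), "unimi"
(23 bitterants / 33 non-bitterants), "phytochemical" (49 / 26).
"""

from __future__ import annotations

__all__ = ["BENCHMARK_ROWS"]

# (dataset, program, model, TP, TN, FP, FN,
#  accuracy, precision, specificity, sensitivity, f1, mcc)  — None = "–"
BENCHMARK_ROWS = [
    # -- 23 known bitterants, no non-bitterants ---------------------------
    ("bitter_new", "consensus", "CM01", 23, 0, 0, 0, 1.000, 1.000, None, 1.000, 1.000, None),
    ("bitter_new", "consensus", "CM02", 23, 0, 0, 0, 1.000, 1.000, None, 1.000, 1.000, None),
    ("bitter_new", "consensus", "CM03", 23, 0, 0, 0, 1.000, 1.000, None, 1.000, 1.000, None),
    ("bitter_new", "consensus", "CM04", 23, 0, 0, 0, 1.000, 1.000, None, 1.000, 1.000, None),
    ("bitter_new", "consensus", "CM05", 23, 0, 0, 0, 1.000, 1.000, None, 1.000, 1.000, None),
    ("bitter_new", "consensus", "CM06", 23, 0, 0, 0, 1.000, 1.000, None, 1.000, 1.000, None),
    ("bitter_new", "consensus", "CM07", 23, 0, 0, 0, 1.000, 1.000, None, 1.000, 1.000, None),
    ("bitter_new", "consensus", "CM08", 23, 0, 0, 0, 1.000, 1.000, None, 1.000, 1.000, None),
    ("bitter_new", "consensus", "CM09", 23, 0, 0, 0, 1.000, 1.000, None, 1.000, 1.000, None),
    ("bitter_new", "BitterX", "SVM", 17, 0, 0, 6, 0.739, 1.000, None, 0.739, 0.850, None),
    ("bitter_new", "BitterPredict", "Adaboost", 17, 0, 0, 6, 0.739, 1.000, None, 0.739, 0.850, None),
    # -- 23 bitterants / 33 non-bitterants --------------------------------
    ("unimi", "consensus", "CM01", 21, 18, 15, 2, 0.696, 0.583, 0.545, 0.913, 0.712, 0.471),
    ("unimi", "consensus", "CM02", 21, 18, 15, 2, 0.696, 0.583, 0.545, 0.913, 0.712, 0.471),
    ("unimi", "consensus", "CM03", 21, 19, 14, 2, 0.714, 0.600, 0.576, 0.913, 0.724, 0.497),
    ("unimi", "consensus", "CM04", 20, 18, 15, 3, 0.679, 0.571, 0.545, 0.870, 0.690, 0.422),
    ("unimi", "consensus", "CM05", 21, 19, 14, 2, 0.714, 0.600, 0.576, 0.913, 0.724, 0.497),
    ("unimi", "consensus", "CM06", 21, 18, 15, 2, 0.696, 0.583, 0.545, 0.913, 0.712, 0.471),
    ("unimi", "consensus", "CM07", 21, 19, 14, 2, 0.714, 0.600, 0.576, 0.913, 0.724, 0.497),
    ("unimi", "consensus", "CM08", 23, 18, 15, 0, 0.732, 0.605, 0.545, 1.000, 0.754, 0.575),
    ("unimi", "consensus", "CM09", 23, 18, 15, 0, 0.732, 0.605, 0.545, 1.000, 0.754, 0.575),
    ("unimi", "BitterX", "SVM", 15, 18, 14, 8, 0.600, 0.517, 0.562, 0.652, 0.577, 0.212),
    ("unimi", "BitterPredict", "Adaboost", 18, 28, 5, 5, 0.821, 0.783, 0.848, 0.783, 0.783, 0.631),
    # -- 49 bitterants / 26 non-bitterants --------------------------------
    ("phytochemical", "consensus", "CM01", 48, 20, 6, 1, 0.907, 0.889, 0.769, 0.980, 0.932, 0.794),
    ("phytochemical", "consensus", "CM02", 47, 20, 6, 2, 0.893, 0.887, 0.769, 0.959, 0.922, 0.761),
    ("phytochemical", "consensus", "CM03", 48, 20, 6, 1, 0.907, 0.889, 0.769, 0.980, 0.932, 0.794),
    ("phytochemical", "consensus", "CM04", 46, 21, 5, 3, 0.893, 0.902, 0.808, 0.939, 0.920, 0.762),
    ("phytochemical", "consensus", "CM05", 48, 20, 6, 1, 0.907, 0.889, 0.769, 0.980, 0.932, 0.794),
    ("phytochemical", "consensus", "CM06", 46, 20, 6, 3, 0.880, 0.885, 0.769, 0.939, 0.911, 0.731),
    ("phytochemical", "consensus", "CM07", 46, 18, 8, 3, 0.853, 0.852, 0.692, 0.939, 0.893, 0.669),
    ("phytochemical", "consensus", "CM08", 48, 19, 7, 1, 0.893, 0.873, 0.731, 0.980, 0.923, 0.764),
    ("phytochemical", "consensus", "CM09", 48, 21, 5, 1, 0.920, 0.906, 0.808, 0.980, 0.941, 0.823),
    ("phytochemical", "BitterX", "SVM", 46, 8, 18, 3, 0.720, 0.719, 0.308, 0.939, 0.814, 0.332),
    ("phytochemical", "BitterPredict", "Adaboost", 48, 18, 8, 1, 0.880, 0.857, 0.692, 0.980, 0.914, 0.735),
]
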