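"""Published baseline results for this dataset's validation experiments.

Confusion-matrix rows (accuracy, TP, FN, TN, FP) as released with the
original benchmark, chaos as the positive class.  Keys: (experiment context,
architecture, segment length).  Contexts: "exp1" — all segments; "exp2" —
first segments only; "exp3_all" / "exp3_first" — the quasi-periodic-augmented
test sets for the two trained-model families.

Used only as frozen expected values in tests; nothing is computed from them.
"""

# (accuracy, TP, FN, TN, FP)
REFERENCE_ROWS: dict[tuple[str, str, int], tuple[float, int, int, int, int]] = {
    ("exp1", "lstm", 50): (0.978, 107_389, 5_651, 139_992, 8),
    ("exp1", "lstm", 100): (0.989, 55_233, 1_287, 70_000, 0),
    ("exp1", "lstm", 200): (0.991, 27_708, 552, 35_000, 0),
    ("exp1", "cnn", 50): (0.979, 108_195, 4_845, 139_757, 243),
    ("exp1", "cnn", 100): (0.982, 54_781, 1_713, 69_457, 543),
    ("exp1", "cnn", 200): (0.985, 27_360, 900, 34_982, 18),
    ("exp2", "lstm", 50): (0.982, 5_485, 167, 6_942, 58),
    ("exp2", "lstm", 100): (0.977, 5_357, 295, 7_000, 0),
    ("exp2", "lstm", 200): (0.981, 5_419, 233, 7_000, 0),
    ("exp2", "cnn", 50): (0.980, 5_650, 2, 6_744, 256),
    ("exp2", "cnn", 100): (0.979, 5_499, 153, 6_885, 115),
    ("exp2", "cnn", 200): (0.980, 5_397, 255, 7_000, 0),
    ("exp3_all", "lstm", 50): (0.967, 107_389, 5_651, 195_423, 4_637),
    ("exp3_all", "lstm", 100): (0.985, 55_233, 1_287, 99_022, 1_008),
    ("exp3_all", "lstm", 200): (0.984, 27_708, 552, 49_352, 663),
    ("exp3_all", "cnn", 50): (0.924, 108_288, 4_752, 180_873, 19_187),
    ("exp3_all", "cnn", 100): (0.902, 54_781, 1_739, 86_382, 13_648),
    ("exp3_all", "cnn", 200): (0.957, 27_360, 900, 47_584, 2_431),
    ("exp3_first", "lstm", 50): (0.937, 5_485, 167, 9_183, 817),
    ("exp3_first", "lstm", 100): (0.981, 5_357, 295, 10_000, 0),
    ("exp3_first", "lstm", 200): (0.952, 5_419, 233, 9_488, 512),
    ("exp3_first", "cnn", 50): (0.951, 5_650, 2, 9_235, 765),
    ("exp3_first", "cnn", 100): (0.943, 5_499, 153, 9_262, 738),
    ("exp3_first", "cnn", 200): (0.970, 5_397, 255, 9_785, 215),
}
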