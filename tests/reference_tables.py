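"""Published reference rows used as worked-example fixtures.

``FEATURE_ROWS``: ten example rows of the back-feature table schema
(id, envelope volume, envelope area, projection area, shoulder width,
belly width, hip width) as printed in a field study; used purely as a
schema / round-trip fixture — the magnitudes are not unit-consistent and
are never interpreted.

``WEIGH_RESULTS``: twenty (actual, estimated) weight pairs in kg from a
field test set; used as the worked example for the error metrics.
"""

FEATURE_ROWS = [
    ("001", 1.092, 0.145, 3.278, 0.385, 0.492, 0.414),
    ("002", 1.049, 0.113, 4.83, 0.449, 0.357, 0.365),
    ("003", 0.893, 0.044, 2.884, 0.283, 0.304, 0.306),
    ("004", 0.927, 0.081, 3.867, 0.395, 0.325, 0.434),
    ("005", 0.989, 0.042, 3.978, 0.275, 0.317, 0.323),
    ("006", 0.946, 0.086, 3.465, 0.427, 0.373, 0.362),
    ("007", 0.887, 8.672, 0.082, 0.285, 0.035, 0.032),
    ("008", 0.983, 0.067, 3.391, 0.456, 0.412, 0.373),
    ("009", 0.883, 0.035, 2.774, 0.283, 0.353, 0.305),
    ("010", 0.901, 0.046, 3.325, 0.346, 0.364, 0.332),
]

WEIGH_RESULTS = [
    (238.0, 246.2),
    (239.5, 232.5),
    (243.0, 226.6),
    (244.5, 248.1),
    (246.5, 252.8),
    (247.5, 272.6),
    (249.0, 252.8),
    (250.0, 252.6),
    (250.5, 236.4),
    (251.0, 261.5),
    (251.5, 225.7),
    (252.5, 268.3),
    (254.0, 247.6),
    (256.5, 248.9),
    (259.5, 274.2),
    (262.5, 253.4),
    (263.0, 256.3),
    (264.0, 268.7),
    (264.5, 274.3),
    (265.5, 246.8),
]
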