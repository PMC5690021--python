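"""Published phantom-accuracy table used for arithmetic cross-checks.

Each row: (setup shift mm applied to all three couch axes,
lateral / vertical / longitudinal calculation errors mm, printed RMSE mm).
"""

PHANTOM_ROWS = [
    (0.5, 0.01, -0.03, -0.25, 0.14),
    (1.0, -0.04, 0.08, -0.26, 0.16),
    (2.0, -0.14, -0.19, -0.36, 0.25),
    (4.0, 0.08, 0.04, -0.40, 0.24),
    (10.0, 0.33, -0.15, -0.37, 0.30),
    (-0.5, 0.12, 0.08, -0.32, 0.20),
    (-1.0, -0.00, 0.13, -0.31, 0.19),
    (-2.0, -0.17, -0.21, -0.38, 0.27),
    (-4.0, 0.05, 0.00, -0.39, 0.23),
    (-10.0, -0.20, 0.20, -0.46, 0.31),
]

# published aggregate (mean +/- population SD over the ten positions)
TOTAL_RMSE_MEAN = 0.23
TOTAL_RMSE_SD = 0.05
TOTAL_LONG_MEAN = -0.35
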