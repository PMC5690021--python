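"""Recompute the published phantom-accuracy table's summary statistics.

The phantom validation of this method reported per-axis calculation errors
for ten couch positions plus per-position RMSEs and a Total row.  Given
the printed per-axis errors, the per-position RMSE and the aggregate
(with population SDs) follow by arithmetic; this reproduces them.
"""

from setuperr import PositioningError, aggregate_pattern, rmse_of_axes

# (setup mm on all axes, lateral, vertical, longitudinal error mm)
ROWS = [
    (0.5, 0.01, -0.03, -0.25),
    (1.0, -0.04, 0.08, -0.26),
    (2.0, -0.14, -0.19, -0.36),
    (4.0, 0.08, 0.04, -0.40),
    (10.0, 0.33, -0.15, -0.37),
    (-0.5, 0.12, 0.08, -0.32),
    (-1.0, -0.00, 0.13, -0.31),
    (-2.0, -0.17, -0.21, -0.38),
    (-4.0, 0.05, 0.00, -0.39),
    (-10.0, -0.20, 0.20, -0.46),
]

errors = []
print(f"{'setup':>6} {'lat':>6} {'vert':>6} {'long':>6} {'RMSE':>6}")
for setup, lat, vert, long_ in ROWS:
    e = PositioningError.from_axes(lat, vert, long_)
    errors.append(e)
    print(f"{setup:>6.1f} {lat:>6.2f} {vert:>6.2f} {long_:>6.2f} {e.rmse_mm:>6.2f}")

s = aggregate_pattern(errors)
print(f"\nTotal  {s.mean_lat_mm:>5.2f}+/-{s.sd_lat_mm:.2f} "
      f"{s.mean_vert_mm:>5.2f}+/-{s.sd_vert_mm:.2f} "
      f"{s.mean_long_mm:>5.2f}+/-{s.sd_long_mm:.2f} "
      f"{s.mean_rmse_mm:>5.2f}+/-{s.sd_rmse_mm:.2f}")
print("\nThe mean RMSE (0.23 mm) is about half the 0.446 mm pixel spacing: "
      "the method localizes below the pixel scale.")
print("Note the first row: RMSE of (0.01, -0.03, -0.25) is "
      f"{rmse_of_axes(0.01, -0.03, -0.25):.4f} mm, i.e. 0.15 at 2 d.p.; the "
      "published 0.14 reflects aggregation before rounding.")
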