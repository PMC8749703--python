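"""Group-level summary values from a published IMU study of 360° turning.

The study compared 14 stroke survivors (SS) with 14 healthy individuals
(HI) performing an on-spot 360° turn with four inertial sensors (sternum,
sacrum, both shanks).  Its raw recordings are not publicly deposited, so
this package uses the printed group summaries in two ways:

* the means/SDs parameterize the default :class:`turnkin.synthetic.GroupProfile`
  for each group, and
* the printed percentage columns serve as worked examples for the two
  percent-difference conventions in :mod:`turnkin.group_stats`.

``TEMPORAL_SUMMARY`` holds the whole-turn (temporally segmented) group
means; the three ``SPATIAL_*`` lists hold the per-partition means of the
spatially segmented analyses for the half-turn (k=2) and quarter-turn (k=4)
partitions together with the printed partition-comparison percentages
(symmetric percent change between consecutive partitions, rounded to
integer).
"""

# rows: parameter, placement, direction, (mean, sd) per group, printed p-value.
# Angular velocities are mean absolute angular velocity in °/s, ROM in °,
# durations in s, stance in %.
TEMPORAL_SUMMARY = [
    {"parameter": "n_cycles", "placement": "shank_leading", "direction": "",
     "SS": (5.86, 1.56), "HI": (3.5, 0.94), "p": 0.001},
    {"parameter": "turn_duration", "placement": "shank_leading", "direction": "",
     "SS": (7.67, 3.17), "HI": (3.72, 1.74), "p": 0.004},
    {"parameter": "stance_pct", "placement": "shank_leading", "direction": "",
     "SS": (53.28, 13.59), "HI": (38.96, 12.57), "p": 0.013},
    {"parameter": "angular_velocity", "placement": "sternum", "direction": "flexext",
     "SS": (0.89, 0.41), "HI": (1.43, 0.35), "p": 0.001},
    {"parameter": "angular_velocity", "placement": "sacrum", "direction": "flexext",
     "SS": (0.97, 0.44), "HI": (1.42, 0.34), "p": 0.004},
    {"parameter": "angular_velocity", "placement": "shank_leading", "direction": "flexext",
     "SS": (1.71, 0.37), "HI": (2.24, 0.37), "p": 0.004},
    {"parameter": "rom", "placement": "sternum", "direction": "lateral",
     "SS": (11.51, 5.03), "HI": (7.3, 3.48), "p": 0.021},
    {"parameter": "rom", "placement": "sacrum", "direction": "lateral",
     "SS": (8.88, 2.36), "HI": (7.31, 1.56), "p": 0.033},
    {"parameter": "rom", "placement": "sternum", "direction": "flexext",
     "SS": (8.69, 2.9), "HI": (5.24, 1.84), "p": 0.004},
    {"parameter": "rom", "placement": "sacrum", "direction": "flexext",
     "SS": (7.56, 2.73), "HI": (5.07, 1.28), "p": 0.014},
    {"parameter": "rom", "placement": "shank_leading", "direction": "flexext",
     "SS": (18.82, 7.64), "HI": (16.22, 5.73), "p": 0.324},
]

# Discussion-style whole-turn contrasts: (parameter row index in
# TEMPORAL_SUMMARY, larger group, printed integer percent difference relative
# to the other group's mean).
REFERENCE_PCT_DIFFS = [
    {"parameter": "n_cycles", "placement": "shank_leading", "direction": "",
     "larger": "SS", "printed_pct": 67},
    {"parameter": "turn_duration", "placement": "shank_leading", "direction": "",
     "larger": "SS", "printed_pct": 106},
    {"parameter": "angular_velocity", "placement": "sacrum", "direction": "flexext",
     "larger": "HI", "printed_pct": 46},
    {"parameter": "angular_velocity", "placement": "sternum", "direction": "flexext",
     "larger": "HI", "printed_pct": 61},
    {"parameter": "angular_velocity", "placement": "shank_leading", "direction": "flexext",
     "larger": "HI", "printed_pct": 31},
]

# Spatial (angular-partition) tables.  Each entry: one parameter × one group,
# with per-partition means for k=2 and k=4 and the printed integer
# partition-comparison percentages (k2: 2-vs-1; k4: 2-vs-1, 3-vs-2, 4-vs-3).
SPATIAL_ANGULAR_VELOCITY = [
    {"parameter": "angular_velocity", "placement": "sternum", "direction": "flexext",
     "group": "SS", "k2": (0.77, 0.67), "k2_cmp": (-14,),
     "k4": (0.71, 0.84, 0.84, 0.59), "k4_cmp": (17, 0, -35)},
    {"parameter": "angular_velocity", "placement": "sternum", "direction": "flexext",
     "group": "HI", "k2": (1.85, 1.08), "k2_cmp": (-53,),
     "k4": (1.76, 1.94, 1.82, 0.84), "k4_cmp": (10, -6, -74)},
    {"parameter": "angular_velocity", "placement": "sacrum", "direction": "flexext",
     "group": "SS", "k2": (0.82, 0.72), "k2_cmp": (-13,),
     "k4": (0.75, 0.91, 0.9, 0.63), "k4_cmp": (19, -1, -35)},
    {"parameter": "angular_velocity", "placement": "sacrum", "direction": "flexext",
     "group": "HI", "k2": (1.85, 1.08), "k2_cmp": (-53,),
     "k4": (1.77, 1.94, 1.84, 0.83), "k4_cmp": (9, -5, -76)},
    {"parameter": "angular_velocity", "placement": "shank_leading", "direction": "flexext",
     "group": "SS", "k2": (0.8, 0.7), "k2_cmp": (-13,),
     "k4": (0.7, 0.85, 0.83, 0.66), "k4_cmp": (19, -2, -23)},
    {"parameter": "angular_velocity", "placement": "shank_leading", "direction": "flexext",
     "group": "HI", "k2": (1.41, 1.03), "k2_cmp": (-31,),
     "k4": (0.38, 1.8, 1.42, 0.82), "k4_cmp": (130, -24, -54)},
    {"parameter": "angular_velocity", "placement": "shank_trailing", "direction": "flexext",
     "group": "SS", "k2": (0.86, 0.75), "k2_cmp": (-14,),
     "k4": (0.83, 1.08, 1.01, 0.64), "k4_cmp": (26, -7, -45)},
    {"parameter": "angular_velocity", "placement": "shank_trailing", "direction": "flexext",
     "group": "HI", "k2": (2.26, 1.13), "k2_cmp": (-67,),
     "k4": (3.4, 2.01, 2.68, 0.86), "k4_cmp": (-51, 29, -103)},
    {"parameter": "angular_velocity", "placement": "sternum", "direction": "rotation",
     "group": "SS", "k2": (0.23, 0.18), "k2_cmp": (-24,),
     "k4": (0.21, 0.26, 0.26, 0.15), "k4_cmp": (21, 0, -54)},
    {"parameter": "angular_velocity", "placement": "sternum", "direction": "rotation",
     "group": "HI", "k2": (0.4, 0.21), "k2_cmp": (-62,),
     "k4": (0.37, 0.42, 0.39, 0.15), "k4_cmp": (13, -7, -89)},
    {"parameter": "angular_velocity", "placement": "sacrum", "direction": "rotation",
     "group": "SS", "k2": (0.15, 0.14), "k2_cmp": (-7,),
     "k4": (0.14, 0.17, 0.17, 0.13), "k4_cmp": (19, 0, -27)},
    {"parameter": "angular_velocity", "placement": "sacrum", "direction": "rotation",
     "group": "HI", "k2": (0.39, 0.24), "k2_cmp": (-48,),
     "k4": (0.36, 0.4, 0.4, 0.19), "k4_cmp": (11, 0, -71)},
    {"parameter": "angular_velocity", "placement": "shank_leading", "direction": "rotation",
     "group": "SS", "k2": (0.06, 0.05), "k2_cmp": (-18,),
     "k4": (0.05, 0.06, 0.05, 0.06), "k4_cmp": (18, -18, 18)},
    {"parameter": "angular_velocity", "placement": "shank_leading", "direction": "rotation",
     "group": "HI", "k2": (0.23, 0.17), "k2_cmp": (-30,),
     "k4": (0.13, 0.3, 0.21, 0.16), "k4_cmp": (79, -35, -27)},
    {"parameter": "angular_velocity", "placement": "shank_trailing", "direction": "rotation",
     "group": "SS", "k2": (0.06, 0.04), "k2_cmp": (-40,),
     "k4": (0.08, 0.12, 0.05, 0.07), "k4_cmp": (40, -82, 33)},
    {"parameter": "angular_velocity", "placement": "shank_trailing", "direction": "rotation",
     "group": "HI", "k2": (0.34, 0.1), "k2_cmp": (-109,),
     "k4": (0.48, 0.28, 0.44, 0.11), "k4_cmp": (-53, 44, -120)},
    {"parameter": "angular_velocity", "placement": "sternum", "direction": "lateral",
     "group": "SS", "k2": (0.13, 0.09), "k2_cmp": (-36,),
     "k4": (0.13, 0.13, 0.13, 0.09), "k4_cmp": (0, 0, -36)},
    {"parameter": "angular_velocity", "placement": "sternum", "direction": "lateral",
     "group": "HI", "k2": (0.15, 0.07), "k2_cmp": (-73,),
     "k4": (0.14, 0.16, 0.13, 0.06), "k4_cmp": (13, -21, -74)},
    {"parameter": "angular_velocity", "placement": "sacrum", "direction": "lateral",
     "group": "SS", "k2": (0.05, 0.04), "k2_cmp": (-22,),
     "k4": (0.04, 0.07, 0.06, 0.04), "k4_cmp": (55, -15, -40)},
    {"parameter": "angular_velocity", "placement": "sacrum", "direction": "lateral",
     "group": "HI", "k2": (0.14, 0.09), "k2_cmp": (-43,),
     "k4": (0.17, 0.13, 0.14, 0.08), "k4_cmp": (-27, 7, -55)},
]

SPATIAL_ROM = [
    {"parameter": "rom", "placement": "sternum", "direction": "flexext",
     "group": "SS", "k2": (7.07, 7.77), "k2_cmp": (9,),
     "k4": (6.03, 5.97, 5.55, 6.77), "k4_cmp": (-1, -7, 20)},
    {"parameter": "rom", "placement": "sternum", "direction": "flexext",
     "group": "HI", "k2": (4.41, 4.42), "k2_cmp": (0,),
     "k4": (1.84, 3.6, 3.15, 3.65), "k4_cmp": (65, -13, 15)},
    {"parameter": "rom", "placement": "sacrum", "direction": "flexext",
     "group": "SS", "k2": (6.18, 6.88), "k2_cmp": (11,),
     "k4": (5.28, 5.14, 5.48, 6.13), "k4_cmp": (-3, 6, 11)},
    {"parameter": "rom", "placement": "sacrum", "direction": "flexext",
     "group": "HI", "k2": (3.41, 4.13), "k2_cmp": (19,),
     "k4": (1.85, 3.08, 2.92, 3.65), "k4_cmp": (50, -5, 22)},
    {"parameter": "rom", "placement": "shank_leading", "direction": "flexext",
     "group": "SS", "k2": (17.11, 17.84), "k2_cmp": (4,),
     "k4": (13.8, 14.73, 15.67, 15.78), "k4_cmp": (7, 6, 1)},
    {"parameter": "rom", "placement": "shank_leading", "direction": "flexext",
     "group": "HI", "k2": (10.64, 14.98), "k2_cmp": (34,),
     "k4": (3.25, 9.85, 9.62, 12.83), "k4_cmp": (101, -2, 29)},
    {"parameter": "rom", "placement": "shank_trailing", "direction": "flexext",
     "group": "SS", "k2": (19.11, 20.19), "k2_cmp": (5,),
     "k4": (18.04, 16.77, 17.68, 17.76), "k4_cmp": (-7, 5, 0)},
    {"parameter": "rom", "placement": "shank_trailing", "direction": "flexext",
     "group": "HI", "k2": (23.1, 23.36), "k2_cmp": (1,),
     "k4": (16.6, 20.23, 19.24, 19.33), "k4_cmp": (20, -5, 0)},
    {"parameter": "rom", "placement": "sacrum", "direction": "lateral",
     "group": "SS", "k2": (7.54, 7.65), "k2_cmp": (1,),
     "k4": (6.02, 6.04, 5.63, 7.15), "k4_cmp": (0, -7, 24)},
    {"parameter": "rom", "placement": "sacrum", "direction": "lateral",
     "group": "HI", "k2": (5.47, 6.71), "k2_cmp": (20,),
     "k4": (3.03, 4.46, 3.62, 5.81), "k4_cmp": (38, -21, 46)},
    {"parameter": "rom", "placement": "sternum", "direction": "lateral",
     "group": "SS", "k2": (9.46, 12.82), "k2_cmp": (30,),
     "k4": (7.65, 7.47, 6.72, 12.33), "k4_cmp": (-2, -11, 59)},
    {"parameter": "rom", "placement": "sternum", "direction": "lateral",
     "group": "HI", "k2": (4.65, 6.89), "k2_cmp": (39,),
     "k4": (2.37, 4.09, 3.58, 5.88), "k4_cmp": (53, -13, 49)},
]

SPATIAL_RELATIVE = [
    {"parameter": "angular_velocity", "placement": "leading_over_trailing",
     "direction": "flexext",
     "group": "SS", "k2": (0.95, 0.94), "k2_cmp": (-1,),
     "k4": (0.85, 1.03, 0.8, 1.05), "k4_cmp": (19, -25, 27)},
    {"parameter": "angular_velocity", "placement": "leading_over_trailing",
     "direction": "flexext",
     "group": "HI", "k2": (0.74, 0.96), "k2_cmp": (26,),
     "k4": (0.17, 1.22, 0.95, 0.95), "k4_cmp": (151, -25, 0)},
    {"parameter": "angular_velocity", "placement": "leading_over_trailing",
     "direction": "rotation",
     "group": "SS", "k2": (5.32, 18.52), "k2_cmp": (111,),
     "k4": (4.72, 2.21, 4.16, 1.58), "k4_cmp": (-72, 61, -90)},
    {"parameter": "angular_velocity", "placement": "leading_over_trailing",
     "direction": "rotation",
     "group": "HI", "k2": (1.05, 2.01), "k2_cmp": (63,),
     "k4": (0.32, 1.92, 10.71, 12.25), "k4_cmp": (143, 139, 13)},
    {"parameter": "rom", "placement": "leading_over_trailing", "direction": "flexext",
     "group": "SS", "k2": (1.11, 1.07), "k2_cmp": (-4,),
     "k4": (1.04, 1.15, 1.24, 1.18), "k4_cmp": (10, 8, -5)},
    {"parameter": "rom", "placement": "leading_over_trailing", "direction": "flexext",
     "group": "HI", "k2": (0.87, 0.93), "k2_cmp": (7,),
     "k4": (0.34, 1.08, 1.23, 0.87), "k4_cmp": (104, 13, -34)},
    {"parameter": "rom", "placement": "sternum_minus_sacrum", "direction": "rotation",
     "group": "SS", "k2": (21.94, 21.27), "k2_cmp": (-3,),
     "k4": (46.09, 25.24, 33.81, 28.25), "k4_cmp": (-58, 29, -18)},
    {"parameter": "rom", "placement": "sternum_minus_sacrum", "direction": "rotation",
     "group": "HI", "k2": (24.28, 9.9), "k2_cmp": (-84,),
     "k4": (39.3, 21.85, 6.45, 13.97), "k4_cmp": (-57, -109, 74)},
    {"parameter": "rom", "placement": "sternum_minus_sacrum", "direction": "lateral",
     "group": "SS", "k2": (14.64, 15.84), "k2_cmp": (8,),
     "k4": (14.68, 14.74, 15.83, 15.97), "k4_cmp": (0, 7, 1)},
    {"parameter": "rom", "placement": "sternum_minus_sacrum", "direction": "lateral",
     "group": "HI", "k2": (12.26, 11.98), "k2_cmp": (-2,),
     "k4": (12.4, 12.34, 12.81, 11.83), "k4_cmp": (0, 4, -8)},
    {"parameter": "rom", "placement": "sternum_minus_sacrum", "direction": "flexext",
     "group": "SS", "k2": (9.05, 8.77), "k2_cmp": (-3,),
     "k4": (9.04, 9.02, 8.69, 8.81), "k4_cmp": (0, -4, 1)},
    {"parameter": "rom", "placement": "sternum_minus_sacrum", "direction": "flexext",
     "group": "HI", "k2": (5.75, 5.2), "k2_cmp": (-10,),
     "k4": (5.88, 5.82, 5.05, 5.28), "k4_cmp": (-1, -14, 4)},
    {"parameter": "angular_velocity", "placement": "sternum_minus_sacrum",
     "direction": "rotation",
     "group": "SS", "k2": (0.19, 0.18), "k2_cmp": (-5,),
     "k4": (0.18, 0.21, 0.24, 0.16), "k4_cmp": (15, 13, -40)},
    {"parameter": "angular_velocity", "placement": "sternum_minus_sacrum",
     "direction": "rotation",
     "group": "HI", "k2": (0.44, 0.26), "k2_cmp": (-51,),
     "k4": (0.41, 0.45, 0.44, 0.2), "k4_cmp": (9, -2, -75)},
    {"parameter": "angular_velocity", "placement": "sternum_minus_sacrum",
     "direction": "lateral",
     "group": "SS", "k2": (0.14, 0.1), "k2_cmp": (-33,),
     "k4": (0.13, 0.17, 0.15, 0.09), "k4_cmp": (27, -13, -50)},
    {"parameter": "angular_velocity", "placement": "sternum_minus_sacrum",
     "direction": "lateral",
     "group": "HI", "k2": (0.17, 0.11), "k2_cmp": (-43,),
     "k4": (0.18, 0.17, 0.19, 0.09), "k4_cmp": (-6, 11, -71)},
    {"parameter": "angular_velocity", "placement": "sternum_minus_sacrum",
     "direction": "flexext",
     "group": "SS", "k2": (0.07, 0.06), "k2_cmp": (-15,),
     "k4": (0.05, 0.09, 0.08, 0.05), "k4_cmp": (57, -12, -46)},
    {"parameter": "angular_velocity", "placement": "sternum_minus_sacrum",
     "direction": "flexext",
     "group": "HI", "k2": (0.06, 0.03), "k2_cmp": (-67,),
     "k4": (0.06, 0.09, 0.05, 0.03), "k4_cmp": (40, -57, -50)},
]

ALL_SPATIAL_ROWS = (
    SPATIAL_ANGULAR_VELOCITY + SPATIAL_ROM + SPATIAL_RELATIVE
)


def temporal_mean(parameter: str, placement: str, direction: str,
                  group: str) -> float:
    """Look up one whole-turn group mean from :data:`TEMPORAL_SUMMARY`."""
    for row in TEMPORAL_SUMMARY:
        if (row["parameter"], row["placement"], row["direction"]) == \
                (parameter, placement, direction):
            return row[group][0]
    raise KeyError((parameter, placement, direction))
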