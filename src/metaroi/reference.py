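"""Published reference statistics for an ADNI-derived AD/MCI/NC cohort.

These are the group-level summary statistics (mean ± SD of regional volume
in mm^3, cortical surface area in mm^2 and mean cortical thickness in mm)
reported for a cohort of 789 T1-weighted MRI scans from the Alzheimer's
Disease Neuroimaging Initiative, spanning normal controls (NC), mild
cognitive impairment (MCI) and Alzheimer's disease (AD), with regional
morphometry computed by FreeSurfer. They parameterize the default
synthetic cohorts and anchor the detectability calculations.

``REFERENCE_DETECTABILITY`` holds the published per-feature diagnostic
accuracies (AUC) and percent changes for the three ordered group contrasts.
The ventricle AUC cells were evidently computed empirically on the
subject-level data rather than from the binormal formula (their long
right tails violate the Gaussian assumption), so they are retained here as
reported values, not as binormal-model predictions.
"""

from __future__ import annotations

from .sdt import GroupStats

GROUPS = ("NC", "MCI", "AD")

#: (region, measure) -> {group: GroupStats}; measures: volume mm^3,
#: surface mm^2, thickness mm. Bilateral totals / area-weighted means.
REFERENCE_GROUP_STATS: dict[tuple[str, str], dict[str, GroupStats]] = {
    ("entorhinal", "volume"): {
        "AD": GroupStats(3036.7, 813.7),
        "MCI": GroupStats(3617.2, 868.3),
        "NC": GroupStats(3912.4, 761.2),
    },
    ("entorhinal", "surface"): {
        "AD": GroupStats(788.5, 160.1),
        "MCI": GroupStats(820.4, 159.8),
        "NC": GroupStats(827.7, 157.8),
    },
    ("entorhinal", "thickness"): {
        "AD": GroupStats(2.743, 0.458),
        "MCI": GroupStats(3.110, 0.463),
        "NC": GroupStats(3.370, 0.278),
    },
    ("fusiform", "volume"): {
        "AD": GroupStats(15480.3, 2609.8),
        "MCI": GroupStats(16774.4, 2534.8),
        "NC": GroupStats(17653.6, 2245.0),
    },
    ("fusiform", "surface"): {
        "AD": GroupStats(5443.9, 795.5),
        "MCI": GroupStats(5690.3, 691.9),
        "NC": GroupStats(5759.1, 677.4),
    },
    ("fusiform", "thickness"): {
        "AD": GroupStats(2.462, 0.205),
        "MCI": GroupStats(2.563, 0.218),
        "NC": GroupStats(2.658, 0.134),
    },
    ("inferior-temporal", "volume"): {
        "AD": GroupStats(16736.9, 3092.3),
        "MCI": GroupStats(18950.8, 3277.3),
        "NC": GroupStats(19502.5, 2855.8),
    },
    ("inferior-temporal", "surface"): {
        "AD": GroupStats(5609.5, 940.0),
        "MCI": GroupStats(6025.3, 915.6),
        "NC": GroupStats(6115.3, 858.4),
    },
    ("inferior-temporal", "thickness"): {
        "AD": GroupStats(2.496, 0.188),
        "MCI": GroupStats(2.623, 0.193),
        "NC": GroupStats(2.685, 0.123),
    },
    ("middle-temporal", "volume"): {
        "AD": GroupStats(17415.8, 3065.2),
        "MCI": GroupStats(19058.1, 3087.8),
        "NC": GroupStats(20264.1, 2883.2),
    },
    ("middle-temporal", "surface"): {
        "AD": GroupStats(5744.3, 884.4),
        "MCI": GroupStats(6053.4, 791.3),
        "NC": GroupStats(6143.3, 820.2),
    },
    ("middle-temporal", "thickness"): {
        "AD": GroupStats(2.498, 0.200),
        "MCI": GroupStats(2.613, 0.201),
        "NC": GroupStats(2.717, 0.123),
    },
    ("temporal-pole", "volume"): {
        "AD": GroupStats(4305.1, 856.1),
        "MCI": GroupStats(4518.3, 730.5),
        "NC": GroupStats(4787.0, 650.7),
    },
    ("temporal-pole", "surface"): {
        "AD": GroupStats(880.5, 135.0),
        "MCI": GroupStats(902.1, 113.3),
        "NC": GroupStats(908.7, 108.0),
    },
    ("temporal-pole", "thickness"): {
        "AD": GroupStats(3.211, 0.385),
        "MCI": GroupStats(3.359, 0.360),
        "NC": GroupStats(3.552, 0.258),
    },
    ("precuneus", "volume"): {
        "AD": GroupStats(15656.2, 2500.8),
        "MCI": GroupStats(16362.9, 2493.1),
        "NC": GroupStats(17326.8, 2404.8),
    },
    ("precuneus", "surface"): {
        "AD": GroupStats(7025.9, 874.2),
        "MCI": GroupStats(7168.3, 827.4),
        "NC": GroupStats(7181.2, 954.4),
    },
    ("precuneus", "thickness"): {
        "AD": GroupStats(2.105, 0.174),
        "MCI": GroupStats(2.163, 0.185),
        "NC": GroupStats(2.265, 0.150),
    },
    ("para-hippocampal", "volume"): {
        "AD": GroupStats(3350.8, 625.6),
        "MCI": GroupStats(3555.4, 596.3),
        "NC": GroupStats(3834.9, 518.2),
    },
    ("para-hippocampal", "surface"): {
        "AD": GroupStats(1199.7, 148.4),
        "MCI": GroupStats(1218.4, 220.3),
        "NC": GroupStats(1229.9, 132.0),
    },
    ("para-hippocampal", "thickness"): {
        "AD": GroupStats(2.409, 0.304),
        "MCI": GroupStats(2.537, 0.323),
        "NC": GroupStats(2.690, 0.237),
    },
    ("hippocampus", "volume"): {
        "AD": GroupStats(5962.1, 1025.3),
        "MCI": GroupStats(6559.2, 1049.2),
        "NC": GroupStats(7238.4, 870.0),
    },
    ("amygdala", "volume"): {
        "AD": GroupStats(2340.9, 548.1),
        "MCI": GroupStats(2594.8, 542.8),
        "NC": GroupStats(2957.1, 476.6),
    },
    ("inferior-lateral-ventricle", "volume"): {
        "AD": GroupStats(3348.5, 2440.2),
        "MCI": GroupStats(2279.1, 1651.6),
        "NC": GroupStats(1500.5, 1066.1),
    },
    ("total-ventricle", "volume"): {
        "AD": GroupStats(57312.7, 27368.6),
        "MCI": GroupStats(49605.5, 24277.5),
        "NC": GroupStats(41296.2, 20535.1),
    },
}

#: Published diagnostic accuracy and percent change per feature and ordered
#: contrast. Keys: (region, measure, "REF_CMP"); values: (AUC, percent
#: change as the printed string, preserving its precision).
REFERENCE_DETECTABILITY: dict[tuple[str, str, str], tuple[float, str]] = {
    # cortical thickness
    ("entorhinal", "thickness", "NC_AD"): (0.879, "-20.5"),
    ("entorhinal", "thickness", "MCI_AD"): (0.676, "-12.5"),
    ("entorhinal", "thickness", "NC_MCI"): (0.730, "-8.02"),
    ("middle-temporal", "thickness", "NC_AD"): (0.832, "-8.40"),
    ("middle-temporal", "thickness", "MCI_AD"): (0.675, "-4.50"),
    ("middle-temporal", "thickness", "NC_MCI"): (0.653, "-3.90"),
    ("inferior-temporal", "thickness", "NC_AD"): (0.798, "-7.30"),
    ("inferior-temporal", "thickness", "MCI_AD"): (0.695, "-4.96"),
    ("inferior-temporal", "thickness", "NC_MCI"): (0.593, "-2.34"),
    ("fusiform", "thickness", "NC_AD"): (0.789, "-7.66"),
    ("fusiform", "thickness", "MCI_AD"): (0.652, "-4.02"),
    ("fusiform", "thickness", "NC_MCI"): (0.628, "-3.64"),
    ("temporal-pole", "thickness", "NC_AD"): (0.773, "-10.1"),
    ("temporal-pole", "thickness", "MCI_AD"): (0.618, "-4.51"),
    ("temporal-pole", "thickness", "NC_MCI"): (0.668, "-5.59"),
    ("para-hippocampal", "thickness", "NC_AD"): (0.764, "-11.0"),
    ("para-hippocampal", "thickness", "MCI_AD"): (0.623, "-5.18"),
    ("para-hippocampal", "thickness", "NC_MCI"): (0.638, "-5.85"),
    ("precuneus", "thickness", "NC_AD"): (0.754, "-7.32"),
    ("precuneus", "thickness", "MCI_AD"): (0.593, "-2.72"),
    ("precuneus", "thickness", "NC_MCI"): (0.656, "-4.61"),
    # cortical surface area
    ("entorhinal", "surface", "NC_AD"): (0.582, "-4.85"),
    ("entorhinal", "surface", "MCI_AD"): (0.566, "-3.97"),
    ("entorhinal", "surface", "NC_MCI"): (0.515, "-0.89"),
    ("middle-temporal", "surface", "NC_AD"): (0.593, "-6.71"),
    ("middle-temporal", "surface", "MCI_AD"): (0.614, "-5.24"),
    ("middle-temporal", "surface", "NC_MCI"): (0.523, "-1.47"),
    ("inferior-temporal", "surface", "NC_AD"): (0.665, "-8.63"),
    ("inferior-temporal", "surface", "MCI_AD"): (0.632, "-7.15"),
    ("inferior-temporal", "surface", "NC_MCI"): (0.531, "-1.48"),
    ("fusiform", "surface", "NC_AD"): (0.624, "-5.63"),
    ("fusiform", "surface", "MCI_AD"): (0.603, "-4.43"),
    ("fusiform", "surface", "NC_MCI"): (0.516, "-1.20"),
    ("temporal-pole", "surface", "NC_AD"): (0.569, "-3.15"),
    ("temporal-pole", "surface", "MCI_AD"): (0.561, "-2.42"),
    ("temporal-pole", "surface", "NC_MCI"): (0.502, "-0.73"),
    ("para-hippocampal", "surface", "NC_AD"): (0.571, "-2.49"),
    ("para-hippocampal", "surface", "MCI_AD"): (0.526, "-1.55"),
    ("para-hippocampal", "surface", "NC_MCI"): (0.547, "-0.94"),
    ("precuneus", "surface", "NC_AD"): (0.543, "-2.19"),
    ("precuneus", "surface", "MCI_AD"): (0.548, "-2.01"),
    ("precuneus", "surface", "NC_MCI"): (0.496, "-0.18"),
    # regional volume
    ("hippocampus", "volume", "NC_AD"): (0.828, "-19.3"),
    ("hippocampus", "volume", "MCI_AD"): (0.661, "-9.54"),
    ("hippocampus", "volume", "NC_MCI"): (0.790, "-9.85"),
    ("inferior-lateral-ventricle", "volume", "NC_AD"): (0.821, "76.2"),
    ("inferior-lateral-ventricle", "volume", "MCI_AD"): (0.669, "38.0"),
    ("inferior-lateral-ventricle", "volume", "NC_MCI"): (0.676, "41.2"),
    ("amygdala", "volume", "NC_AD"): (0.805, "-23.3"),
    ("amygdala", "volume", "MCI_AD"): (0.632, "-10.3"),
    ("amygdala", "volume", "NC_MCI"): (0.691, "-13.1"),
    ("entorhinal", "volume", "NC_AD"): (0.786, "-25.2"),
    ("entorhinal", "volume", "MCI_AD"): (0.693, "-17.5"),
    ("entorhinal", "volume", "NC_MCI"): (0.590, "-7.84"),
    ("middle-temporal", "volume", "NC_AD"): (0.752, "-15.1"),
    ("middle-temporal", "volume", "MCI_AD"): (0.652, "-9.00"),
    ("middle-temporal", "volume", "NC_MCI"): (0.604, "-6.13"),
    ("para-hippocampal", "volume", "NC_AD"): (0.736, "-13.5"),
    ("para-hippocampal", "volume", "MCI_AD"): (0.600, "-5.93"),
    ("para-hippocampal", "volume", "NC_MCI"): (0.641, "-7.56"),
    ("total-ventricle", "volume", "NC_AD"): (0.693, "32.5"),
    ("total-ventricle", "volume", "MCI_AD"): (0.584, "14.4"),
    ("total-ventricle", "volume", "NC_MCI"): (0.616, "18.3"),
    ("precuneus", "volume", "NC_AD"): (0.680, "-10.1"),
    ("precuneus", "volume", "MCI_AD"): (0.572, "-4.41"),
    ("precuneus", "volume", "NC_MCI"): (0.609, "-5.72"),
}

#: Features whose published NC_AD AUC is consistent with the binormal model
#: (the ventricle rows are not: heavy right skew makes their empirical AUC
#: exceed the Gaussian-formula value).
BINORMAL_CONSISTENT_NC_AD: tuple[tuple[str, str], ...] = (
    ("entorhinal", "thickness"),
    ("middle-temporal", "thickness"),
    ("inferior-temporal", "thickness"),
    ("fusiform", "thickness"),
    ("temporal-pole", "thickness"),
    ("para-hippocampal", "thickness"),
    ("precuneus", "thickness"),
    ("hippocampus", "volume"),
)
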