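"""Frozen roster of the radiomic feature set.

The full (unfiltered) set has 98 features in seven classes:

    shape2d     9   mesh-based 2D morphology of the ROI
    firstorder 16   14 intensity statistics + histogram Entropy/Uniformity
    glcm       22   gray-level co-occurrence, direction-averaged
    glrlm      16   gray-level run length, direction-averaged
    glszm      16   gray-level size zone (8-connected zones)
    gldm       14   gray-level dependence (alpha = 0)
    ngtdm       5   neighbourhood gray-tone difference

Filtered maps omit the shape class (89 features), since ROI morphology does
not depend on the applied intensity filter.  The canonical feature order is
class order as above with alphabetical order within each class; this order
fixes report rows and all downstream tie-breaking.

The 14-member intensity-statistic roster and the 22-member GLCM roster are
package choices frozen here (the GLCM catalogue drops SumAverage, a
duplicate of JointAverage for symmetric matrices, and MCC).
"""

from __future__ import annotations

SHAPE2D = (
    "Elongation",
    "MajorAxisLength",
    "MaximumDiameter",
    "MeshSurface",
    "MinorAxisLength",
    "Perimeter",
    "PerimeterSurfaceRatio",
    "PixelSurface",
    "Sphericity",
)

#: 14 intensity statistics computed on raw ROI intensities
FIRSTORDER_STATS = (
    "Energy",
    "Kurtosis",
    "Maximum",
    "Mean",
    "MeanAbsoluteDeviation",
    "Median",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Variance",
)
#: 2 intensity-histogram features computed on the discretized levels
FIRSTORDER_HISTOGRAM = ("Entropy", "Uniformity")
FIRSTORDER = tuple(sorted(FIRSTORDER_STATS + FIRSTORDER_HISTOGRAM))

GLCM = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
)

GLRLM = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

GLDM = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

NGTDM = (
    "Busyness",
    "Coarseness",
    "Complexity",
    "Contrast",
    "Strength",
)

#: class order used everywhere (report tables, heatmap panels, tie-breaks)
CLASS_ORDER = ("shape2d", "firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")

CLASS_ROSTERS: dict[str, tuple[str, ...]] = {
    "shape2d": SHAPE2D,
    "firstorder": FIRSTORDER,
    "glcm": GLCM,
    "glrlm": GLRLM,
    "glszm": GLSZM,
    "gldm": GLDM,
    "ngtdm": NGTDM,
}

CLASS_COUNTS = {name: len(roster) for name, roster in CLASS_ROSTERS.items()}

#: heatmap panel order used in cohort reports
PANEL_ORDER = ("shape2d", "firstorder", "glcm", "gldm", "glrlm", "glszm", "ngtdm")


def canonical_names(filter_id: str = "original") -> list[str]:
    """Canonical feature-name list for one preprocessing configuration.

    Names are ``<filter>_<class>_<Feature>``; filtered configurations omit
    the shape class.
    """
    names = []
    for cls in CLASS_ORDER:
        if cls == "shape2d" and filter_id != "original":
            continue
        names.extend(f"{filter_id}_{cls}_{feat}" for feat in CLASS_ROSTERS[cls])
    return names


def feature_class(name: str) -> str:
    """Extract the class token from a canonical feature name (the filter
    tag may itself contain underscores, e.g. ``wavelet_LL``)."""
    for token in name.split("_"):
        if token in CLASS_ROSTERS:
            return token
    raise ValueError(f"not a canonical feature name: {name!r}")


def split_name(name: str, filter_id: str) -> tuple[str, str]:
    """Canonical name -> (class, feature) given its known filter tag."""
    prefix = filter_id + "_"
    if not name.startswith(prefix):
        raise ValueError(f"{name!r} does not carry filter tag {filter_id!r}")
    cls, feat = name.removeprefix(prefix).split("_", 1)
    return cls, feat
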