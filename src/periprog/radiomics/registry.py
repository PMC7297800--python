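"""Registry of the 294 voxel-wise radiomics features.

13 first-order statistics and 29 second-order texture statistics (21 GLCM +
8 GLRLM) per modality, over the 7 co-registered MR modalities, give
7 * 42 = 294 features.  The printed second-order count (203 = 7 * 29)
exceeds the 26 named GLCM/GLRLM statistics per modality; the registry
closes the gap with three conventional extras — GLCM maximum probability,
GLCM sum average and GLRLM run-length non-uniformity normalized — tagged
``reconciliation=True`` so they can be identified or dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MODALITIES",
    "FIRST_ORDER_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "RECONCILIATION_NAMES",
    "FeatureSpec",
    "FeatureRegistry",
    "feature_registry",
]

#: the seven co-registered input modalities
MODALITIES = ("T1C", "FLAIR", "ADC", "FA", "DTI-p", "DTI-q", "rCBV")

FIRST_ORDER_NAMES = (
    "mean",
    "std",
    "median",
    "min",
    "max",
    "variance",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "uniformity",
    "rms",
    "mean_gray_level",
)

# 19 named Haralick-family statistics + 2 reconciliation extras, in the
# order the extraction kernel emits them.
GLCM_NAMES = (
    "autocorrelation",
    "contrast",
    "correlation_m",
    "correlation_p",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity_m",
    "homogeneity_p",
    "sum_of_squares",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "inverse_difference_normalized",
    "maximum_probability",
    "sum_average",
)

# 7 named run-length statistics + 1 reconciliation extra.
GLRLM_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_percentage",
    "run_length_nonuniformity",
    "low_gray_level_emphasis",
    "high_gray_level_emphasis",
    "run_length_nonuniformity_normalized",
)

RECONCILIATION_NAMES = frozenset(
    {"maximum_probability", "sum_average", "run_length_nonuniformity_normalized"}
)


@dataclass(frozen=True)
class FeatureSpec:
    """One feature column: (modality, family, statistic)."""

    modality: str
    family: str  # "first_order" | "glcm" | "glrlm"
    statistic: str
    reconciliation: bool = False

    @property
    def name(self) -> str:
        return f"{self.modality}.{self.family}.{self.statistic}"


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered list of the 294 feature columns."""

    features: tuple

    @property
    def names(self):
        return [f.name for f in self.features]

    def family_names(self, family: str):
        return [f.name for f in self.features if f.family == family]

    @property
    def n_first_order(self) -> int:
        return sum(f.family == "first_order" for f in self.features)

    @property
    def n_second_order(self) -> int:
        return sum(f.family in ("glcm", "glrlm") for f in self.features)

    def __len__(self) -> int:
        return len(self.features)

    def to_json_dict(self):
        return [
            {
                "name": f.name,
                "modality": f.modality,
                "family": f.family,
                "statistic": f.statistic,
                "reconciliation": f.reconciliation,
            }
            for f in self.features
        ]


def feature_registry(modalities=MODALITIES) -> FeatureRegistry:
    """Build the feature registry, modality-major, families in kernel order."""
    feats = []
    for m in modalities:
        for s in FIRST_ORDER_NAMES:
            feats.append(FeatureSpec(m, "first_order", s))
        for s in GLCM_NAMES:
            feats.append(FeatureSpec(m, "glcm", s, s in RECONCILIATION_NAMES))
        for s in GLRLM_NAMES:
            feats.append(FeatureSpec(m, "glrlm", s, s in RECONCILIATION_NAMES))
    reg = FeatureRegistry(tuple(feats))
    if len(modalities) == 7:
        assert len(reg) == 294 and reg.n_first_order == 91 and reg.n_second_order == 203
    return reg
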