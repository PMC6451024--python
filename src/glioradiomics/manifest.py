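"""Canonical 936-feature manifest.

Per image channel the engine emits 104 features on the original volume —
17 first-order, 22 GLCM descriptors at each of 3 voxel distances (66), and
21 GLRLM descriptors — and the same 104 on each of the 8 single-level
wavelet sub-bands, for 104 × 9 = 936. Names are structured
``<source>:<group>:<feature>`` with source in {original, LLL..HHH}.

Texture descriptors are averaged over the 13 unique 3-D directions; GLCM is
additionally reported per distance (1, 2, 3 voxels) while GLRLM is
direction-averaged once. The group arithmetic (17 + 87 = 104, x8 = 832,
total 936) is asserted at import time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

FIRST_ORDER_NAMES: tuple[str, ...] = (
    "range",
    "energy",
    "entropy",
    "kurtosis",
    "maximum",
    "mean",
    "median",
    "uniformity",
    "variance",
    "minimum",
    "skewness",
    "standard_deviation",
    "root_mean_square",
    "mean_absolute_deviation",
    "percentile_10",
    "percentile_90",
    "interquartile_range",
)

GLCM_NAMES: tuple[str, ...] = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "inverse_difference_moment",
    "imc1",
    "imc2",
    "inverse_variance",
    "joint_average",
    "max_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
)

GLRLM_NAMES: tuple[str, ...] = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized",
    "run_length_nonuniformity",
    "run_length_nonuniformity_normalized",
    "run_percentage",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
    "gray_level_variance",
    "run_length_variance",
    "run_entropy",
    "gray_level_mean",
    "run_length_mean",
    "gray_level_entropy",
    "run_length_entropy",
    "max_probability",
)

WAVELET_BAND_NAMES: tuple[str, ...] = ("LLL", "HLL", "LHL", "HHL", "LLH", "HLH", "LHH", "HHH")
SOURCES: tuple[str, ...] = ("original",) + WAVELET_BAND_NAMES
GLCM_DISTANCES: tuple[int, ...] = (1, 2, 3)


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered, named feature layout; the imaging <-> ML contract."""

    first_order: tuple[str, ...] = FIRST_ORDER_NAMES
    glcm: tuple[str, ...] = GLCM_NAMES
    glrlm: tuple[str, ...] = GLRLM_NAMES
    distances: tuple[int, ...] = GLCM_DISTANCES
    sources: tuple[str, ...] = SOURCES
    names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        names: list[str] = []
        for source in self.sources:
            for f in self.first_order:
                names.append(f"{source}:firstorder:{f}")
            for d in self.distances:
                for f in self.glcm:
                    names.append(f"{source}:glcm_d{d}:{f}")
            for f in self.glrlm:
                names.append(f"{source}:glrlm:{f}")
        object.__setattr__(self, "names", tuple(names))
        self.validate()

    def validate(self) -> None:
        n_texture = len(self.glcm) * len(self.distances) + len(self.glrlm)
        per_source = len(self.first_order) + n_texture
        if len(self.first_order) != 17:
            raise AssertionError("first-order group must have 17 features")
        if n_texture != 87:
            raise AssertionError(f"texture group must have 87 features, got {n_texture}")
        if per_source != 104:
            raise AssertionError("per-source feature count must be 104")
        n_wavelet = per_source * (len(self.sources) - 1)
        if n_wavelet != 832:
            raise AssertionError(f"wavelet fan-out must give 832 features, got {n_wavelet}")
        if len(self.names) != 936:
            raise AssertionError(f"manifest must name 936 features, got {len(self.names)}")
        if len(set(self.names)) != len(self.names):
            raise AssertionError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "n_features": len(self.names),
            "first_order": list(self.first_order),
            "glcm": list(self.glcm),
            "glrlm": list(self.glrlm),
            "distances": list(self.distances),
            "sources": list(self.sources),
            "names": list(self.names),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


DEFAULT_MANIFEST = FeatureManifest()
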