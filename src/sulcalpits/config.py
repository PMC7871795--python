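"""Pipeline configuration with the method's standard defaults.

The individual watershed thresholds (ThR=1.5, ThD=20 mm, ThA=50 mm^2) and
the group-level means used for normalization come from a healthy-adult
reference population; the group watershed uses (gThR=2, gThD=15, gThA=100).
Smoothing is FWHM 5 mm in 60 heat-equation iterations, DPF regularization
alpha=0.03, and classification is k=3 with 100 k-means replicates at a
two-tailed alpha of 0.05.  All values are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classification import ClassificationParams
from .parcellation import DEFAULT_GROUP_THRESHOLDS, SmoothingParams
from .watershed import DEFAULT_THRESHOLDS, Thresholds

__all__ = ["PipelineConfig", "REFERENCE_GROUP_MEANS"]

#: Healthy-adult reference group means for threshold normalization:
#: Fiedler length (mm) and surface area (mm^2) per hemisphere.
REFERENCE_GROUP_MEANS = {
    "left": {"fl": 231.8, "sa": 91616.0},
    "right": {"fl": 232.9, "sa": 91980.0},
}


@dataclass
class PipelineConfig:
    thresholds: Thresholds = field(default_factory=lambda: DEFAULT_THRESHOLDS)
    group_thresholds: Thresholds = field(
        default_factory=lambda: DEFAULT_GROUP_THRESHOLDS
    )
    smoothing: SmoothingParams = field(default_factory=SmoothingParams)
    dpf_alpha: float = 0.03
    classification: ClassificationParams = field(
        default_factory=ClassificationParams
    )
    alpha_level: float = 0.05
    #: Group means for threshold normalization; None = use the cohort's own
    #: per-hemisphere means (appropriate whenever the cohort IS the group).
    group_means: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.dpf_alpha > 0:
            raise ValueError("dpf_alpha must be positive")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must lie in (0, 1)")
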