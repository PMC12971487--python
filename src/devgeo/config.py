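"""Pipeline configuration with the analysis defaults.

Every threshold carries the analysis default (FWD censoring at 1.5 mm,
run rejection above 50% censored frames, dispersion cutoff 10, noise
ceiling floor 0.1, 1,000 bootstrap resamples) and every value can be
overridden; the full configuration is serialized next to pipeline outputs
for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass
class PipelineConfig:
    # motion / QC
    fwd_threshold_mm: float = 1.5
    max_censored_fraction: float = 0.5
    dispersion_max: float = 10.0
    highpass_hz: float = 0.01
    # inference
    n_boot: int = 1000
    ceiling_floor: float = 0.1
    n_ceiling_splits: int = 100
    fwd_bins: int = 10
    include_diagonal_feature_rsa: bool = True
    include_diagonal_dnn_rsa: bool = False
    # aggregation level per group: adults at subject level, infants at run
    # level (the arithmetic behind the printed pair counts)
    aggregation: dict = field(
        default_factory=lambda: {"2mo": "run", "9mo": "run", "adult": "subject"}
    )
    # synthetic cohort defaults
    seed: int = 0
    n_subjects: dict = field(
        default_factory=lambda: {"2mo": 12, "9mo": 12, "adult": 8}
    )
    runs_per_subject: int = 2
    n_voxels: int = 500
    sigma_group: float = 0.0
    sigma_individual: float = 0.5
    sigma_session: float = 0.5
    sigma_noise: float = 1.0
    mixture_weights: dict = field(
        default_factory=lambda: {"category": 1.0, "animacy_tripartite": 0.5}
    )
    run_dnn: bool = True
    run_mds: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))
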