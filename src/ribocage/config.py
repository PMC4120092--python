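"""Pipeline configuration: one flat mapping holding every stage parameter,
with YAML round-trip and the field-standard defaults embedded."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "DEFAULTS"]

DEFAULTS = dict(
    # tag reading / dedup
    mapq_min=10,
    pair_format="sam",
    # peak calling
    paraclu_max_len=100,  # bp
    paraclu_min_stability=2.0,
    paraclu_min_tags=1,
    # promoter classifier
    classifier_k=4,
    classifier_window=2000,  # bp around the TSS
    classifier_alpha=1.0,
    classifier_tau=0.0,
    classifier_tss_tolerance=100,
    # annotation
    downstream_window=10_000,  # bp past a gene 3' end for rescue
    exclude_biotypes=("pseudogene",),
    # enrichment statistics
    fdr_max=0.1,
    prior_count=0.125,
    dispersion_prior_weight=10.0,
    tmm_trim_m=0.30,
    tmm_trim_a=0.05,
    min_pooled_count=1,
    # compartment analyses
    richness_subsample=1000,  # m tags
    rank_window=200,  # genes per moving window
    dendrite_quantile=0.75,
    dendrite_quantile_nonzero_only=False,
    saturation_fractions=(0.25, 0.5, 1.0),
    run_saturation=True,
    # ncRNA screen
    max_span=100_000,  # bp
    tso_tail="GGG",
    tso_k=3,
    head_to_head_window=5000,
    seed=0,
)


@dataclass
class PipelineConfig:
    """All pipeline parameters plus workspace paths.

    Defaults follow the conventions of compartmentalized-translatome CAGE
    analysis: peak max length 100 bp, 2-kb classifier window, FDR <= 0.1,
    richness m = 1000, 200-gene rank window, dendritic upper quartile 0.75.
    """

    outdir: str = "ribocage_run"
    genome: str | None = None
    models_primary: str | None = None
    models_secondary: str | None = None
    repeats: str | None = None
    libraries: str | None = None
    srp_features: str | None = None
    aba_scores: str | None = None
    params: dict = field(default_factory=lambda: dict(DEFAULTS))
    sim: dict = field(default_factory=dict)  # overrides for SimConfig

    def __post_init__(self):
        merged = dict(DEFAULTS)
        merged.update(self.params)
        self.params = merged

    def __getitem__(self, key):
        return self.params[key]

    @property
    def seed(self) -> int:
        return int(self.params["seed"])

    # -- round trip ---------------------------------------------------------
    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["params"] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in self.params.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        params = data.pop("params", {})
        for k in ("exclude_biotypes", "saturation_fractions"):
            if k in params and isinstance(params[k], list):
                params[k] = tuple(params[k])
        return cls(params=params, **data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def path(self, *parts) -> Path:
        return Path(self.outdir).joinpath(*parts)
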