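"""Named parameterizations for the two standard experimental designs.

``n2a``: small cultured-cell design (3 vs 3 replicates) — full completeness
required in one group, imputation width 0.5 / downshift 1.6.

``brain``: larger in vivo design (11 bait vs 9 control) — 75% completeness
in one group, imputation width 0.4 / downshift 1.7.
"""

from __future__ import annotations

from dataclasses import replace

from .pipeline import PipelineParams

PIPELINE_PRESETS: dict[str, PipelineParams] = {
    "n2a": PipelineParams(min_valid_fraction=1.0, impute_width=0.5, impute_downshift=1.6),
    "brain": PipelineParams(min_valid_fraction=0.75, impute_width=0.4, impute_downshift=1.7),
}


def get_pipeline_preset(name: str, **overrides) -> PipelineParams:
    if name not in PIPELINE_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PIPELINE_PRESETS)}")
    return replace(PIPELINE_PRESETS[name], **overrides)
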