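"""Tunable knobs shared across the pipeline.

All thresholds live here rather than in the individual modules so a
deployment can retune them (e.g. the terminology sameAs threshold, which
is normally calibrated on an annotated linking set) without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class PipelineConfig:
    #: number of linking candidates kept per token
    top_k: int = 5
    #: tokens whose best similarity falls below this are "unknown"
    sim_floor: float = 0.4
    #: minimum averaged string similarity for an owl:sameAs terminology link
    same_as_threshold: float = 0.75
    #: cap on alternative segmentations returned by full mode
    full_mode_cap: int = 64
    #: cap on derivations enumerated from one parse forest
    forest_cap: int = 256
    #: cap on entity-assignment combinations per parse tree
    candidate_cap: int = 32
    #: strict mode rejects questions containing unknown tokens;
    #: lenient mode drops the tokens and answers the reduced question
    strict: bool = True
    #: width of age histogram bins (anchored at 0)
    age_bin_width: int = 10
    #: number of equal-width bins for other numeric distributions
    n_bins: int = 10
    #: cap on witness combinations explored per patient in a time join
    witness_cap: int = 10000


DEFAULT_CONFIG = PipelineConfig()
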