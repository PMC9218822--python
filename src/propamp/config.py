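"""Run-wide configuration: every numeric threshold of the pipeline.

All stage thresholds live in one serializable object so a result bundle
can embed the exact configuration that produced it. Unknown keys are
rejected on load.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict

from propamp.profiles import SearchConfig


class RunConfig(BaseModel):
    """Pipeline configuration with the published defaults.

    Search thresholds mirror :class:`propamp.profiles.SearchConfig`; the
    rest gate propeller assembly (strict >0.60 median blade identity,
    3-MADe linker grouping), de-novo repeat detection (empirical p <= 0.10),
    family/flank annotation (0.50 confidence, >=40 residues, >=30% profile
    coverage, <=5 iterations) and the intergenic fragment scan (>=20
    residues, <=15% stop content, permissive p <= 0.5 confidence gate).
    """

    model_config = ConfigDict(extra="forbid")

    # profile search
    max_iterations: int = 15
    inclusion_p: float = 0.005
    report_p: float = 0.05
    min_query_coverage: float = 0.80
    trim_max_gap_fraction: float = 0.70
    trim_min_overlap: float = 0.75
    trim_occupancy: float = 0.80
    length_filter_mades: float = 1.0
    n_shuffles: int = 200
    gap_open: float = 11.0
    gap_extend: float = 1.0
    pseudocount_weight: float = 1.0

    # propeller assembly
    identity_threshold: float = 0.60
    linker_mades: float = 3.0
    linker_two_sided: bool = True

    # repeat refinement
    repeat_p: float = 0.10
    min_repeat_period: int = 15
    max_decompose_depth: int = 5

    # family / flank annotation
    family_gate: float = 0.50
    flank_min_len: int = 40
    flank_min_cov: float = 0.30
    flank_max_iter: int = 5

    # DNA-level analyses
    min_diagnostic_positions: int = 1

    # intergenic fragment scan
    fragment_min_len: int = 20
    fragment_min_len_strict: bool = False  # True -> strictly more than
    fragment_max_stop: float = 0.15
    fragment_max_p: float = 0.5
    fragment_min_cov: float = 0.30

    # terminal-proximity census
    termini_thresholds: tuple[int, int] = (50, 30)

    rng_seed: int = 0

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            max_iterations=self.max_iterations,
            inclusion_p=self.inclusion_p,
            report_p=self.report_p,
            min_query_coverage=self.min_query_coverage,
            trim_max_gap_fraction=self.trim_max_gap_fraction,
            trim_min_overlap=self.trim_min_overlap,
            trim_occupancy=self.trim_occupancy,
            length_filter_mades=self.length_filter_mades,
            n_shuffles=self.n_shuffles,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            pseudocount_weight=self.pseudocount_weight,
            rng_seed=self.rng_seed,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.model_dump(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))
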