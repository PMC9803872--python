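"""Run configuration: the pipeline's fixed constants in one place."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass


@dataclass
class RunConfig:
    """Defaults for every threshold the pipeline applies.

    min_coverage: minimum spanning reads for an eligible epilocus.
    upper_quantile: per-sample coverage cap (nearest-rank quantile).
    jsd_cutoff: Jensen–Shannon distance above which two profiles differ.
    max_length: maximum epilocus span in bp.
    n_cpg: CpG sites per epilocus (only 4 is exercised).
    bin_size / min_epiloci_per_bin: neighborhood-concordance binning.
    boot_reps / calib_reps: bootstrap and calibration replicate counts.
    coverage_grid: calibration curve grid (inclusive bounds, step).
    """

    min_coverage: int = 50
    upper_quantile: float = 0.99
    jsd_cutoff: float = 0.26
    max_length: int = 100
    n_cpg: int = 4
    bin_size: int = 1000
    min_epiloci_per_bin: int = 3
    boot_reps: int = 1000
    calib_reps: int = 1000
    coverage_min: int = 20
    coverage_max: int = 200
    coverage_step: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.jsd_cutoff <= 1:
            raise ValueError("jsd_cutoff must be in (0, 1]")
        for name in (
            "min_coverage", "max_length", "n_cpg", "bin_size",
            "min_epiloci_per_bin", "boot_reps", "calib_reps",
            "coverage_min", "coverage_max", "coverage_step",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.upper_quantile <= 1:
            raise ValueError("upper_quantile must be in (0, 1]")

    @property
    def coverage_grid(self) -> tuple[int, ...]:
        return tuple(range(self.coverage_min, self.coverage_max + 1, self.coverage_step))

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def header(self) -> str:
        """One-line provenance comment for output files."""
        fields = dataclasses.asdict(self)
        return "config " + " ".join(f"{k}={v}" for k, v in sorted(fields.items()))
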