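"""Pipeline configuration.

Every analysis constant used anywhere in the pipeline lives here, so a run
is fully described by one :class:`PipelineConfig` plus a master seed.
Times are seconds throughout; milliseconds appear only in human-readable
report columns (suffixed ``_ms``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis chain.

    Defaults are the study's standard settings: 10 ms histogram bins, 500
    ISI-shuffle surrogates and 500 cross-correlogram bootstraps, the 6-9 Hz
    spike-and-wave band, a two-sided 5% critical value of 1.96, 1 s minimum
    episode duration and 1 s merge gap, a 2 s interictal guard band, a
    minimum of 10 ictal complex spikes for CS correlograms, and 100 s of
    well-isolated activity for inclusion of a unit.
    """

    # histogram / spectral settings
    bin_width: float = 0.010           # s, PSTH and correlogram bin
    psth_window: float = 0.5           # s, PSTH half-window around each trigger
    band: tuple[float, float] = (6.0, 9.0)   # Hz, GSWD frequency band
    z_crit: float = 1.96               # two-sided standard-normal 5% critical value
    n_shuffles: int = 500              # ISI-shuffle surrogates for PSTH nulls
    n_boot: int = 500                  # bootstrap surrogates for correlograms
    min_total_ictal: float = 2.0       # s, minimum summed episode length for a PSTH

    # episode detection
    mad_k: float = 4.0                 # threshold in robust SDs (scaled MAD)
    min_episode: float = 1.0           # s, minimum episode duration
    merge_gap: float = 1.0             # s, episodes closer than this are merged
    guard: float = 2.0                 # s, exclusion band around episodes
    ecog_channel: str = "M1"

    # synchrony
    max_lag: float = 0.25              # s, correlogram lag range
    zero_tol: float = 0.010            # s, "lag of ~0 ms" tolerance (one bin)
    min_ictal_cs: int = 10             # inclusion rule for CS correlograms

    # firing statistics
    burst_span: float = 0.100          # s, >=3 spikes within this span form a burst
    min_isolation: float = 100.0       # s, minimum well-isolated recording time
    cf_pause_min: float = 0.010        # s, Purkinje-cell identification pause

    # calcium
    ca_k: float = 3.5                  # event threshold in noise SDs
    ca_baseline_window: float = 10.0   # s, rolling-percentile baseline window
    ca_baseline_pct: float = 20.0      # percentile for the baseline
    ca_decay_tau: float = 0.15         # s, transient decay constant / refractory

    # run control
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.psth_window <= 0:
            raise ValueError("bin_width and psth_window must be positive")
        if self.n_shuffles < 1 or self.n_boot < 1:
            raise ValueError("n_shuffles and n_boot must be >= 1")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError(f"invalid frequency band {self.band}")
        if self.z_crit <= 0:
            raise ValueError("z_crit must be positive")
        if min(self.min_episode, self.merge_gap, self.guard, self.max_lag) < 0:
            raise ValueError("durations must be non-negative")
        if self.min_ictal_cs < 0:
            raise ValueError("min_ictal_cs must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
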