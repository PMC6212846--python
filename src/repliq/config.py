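"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .droplet import DEFAULT_DROPLET_VOLUME_NL, DEFAULT_DROPLETS_PER_WELL
from .simulate import DEFAULT_NB_SIZE, DEFAULT_SYNCHRONY_SD_MIN


@dataclass(frozen=True)
class RunConfig:
    """Defaults threaded through the pipeline and recorded in provenance."""

    seed: int = 0
    alpha: float = 0.05
    ci_level: float = 0.95
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    n_droplets_default: int = DEFAULT_DROPLETS_PER_WELL
    nb_size: float = DEFAULT_NB_SIZE
    synchrony_sd_min: float = DEFAULT_SYNCHRONY_SD_MIN

    def __post_init__(self) -> None:
        for name in ("alpha", "ci_level"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {value}")

    def to_dict(self) -> dict:
        return asdict(self)
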