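"""Run configuration for the end-to-end scoring pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .synthetic import PRESETS, TrackModelParams

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a full tracks-to-survival pipeline run.

    All lengths in nm, dose in Gy, mass stopping power in MeV cm^2/g.
    ``track_model`` is a preset name ("dense" / "sparse") or a mapping of
    :class:`~trackevent.synthetic.TrackModelParams` fields.
    """

    seed: int = 1
    track_model: str | dict = "dense"
    n_tracks: int = 50
    d_biv_nm: float = 2.0
    d_cv_nm: float = 12.0
    roi_radius_nm: float = 250.0
    roi_max_radius_nm: float | None = None
    n_sectors: int = 8
    head_trim_nm: float = 100.0
    tail_trim_nm: float = 50.0
    dose_gy: float = 2.0
    mass_stopping_power: float = 12.45
    p_d: float = 0.01
    r1: float = 0.0
    r2plus: float = 0.0
    truncation_tol: float = 1e-10
    outdir: str = "trackevent_run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.d_cv_nm <= self.d_biv_nm:
            raise ValueError("d_cv_nm must exceed d_biv_nm")
        for name in ("p_d", "r1", "r2plus"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dose_gy < 0:
            raise ValueError("dose must be non-negative")
        if self.mass_stopping_power <= 0:
            raise ValueError("mass stopping power must be positive")

    def track_params(self) -> TrackModelParams:
        if isinstance(self.track_model, str):
            try:
                return PRESETS[self.track_model]
            except KeyError:
                raise ValueError(
                    f"unknown track model preset {self.track_model!r}"
                ) from None
        return TrackModelParams(**self.track_model)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
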