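"""Analysis configuration.

All tunable parameters of the pipeline live in one declarative structure whose
defaults are the acquisition/analysis settings of the intraoperative study the
pipeline implements: ECoG downsampled to 2 kHz, high-gamma band 70-250 Hz,
notch bases at 50 Hz (mains) and 79 Hz (theatre equipment), 100,000 marker
rotations, 10,000 spherical spins, alpha = .05, 2.5-mm seed spheres and 5-mm
FWHM smoothing.  Configs round-trip through YAML and hash stably so that every
output file can record exactly which settings produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


def _default_extra_bands() -> dict[str, tuple[float, float]]:
    # Side bands used to probe specificity of the high-gamma result.
    return {
        "delta": (1.0, 4.0),
        "alpha": (8.0, 12.0),
        "beta": (13.0, 30.0),
        "gamma": (30.0, 70.0),
    }


@dataclass
class AnalysisConfig:
    """Pipeline-wide parameters with study defaults.

    Parameters
    ----------
    fs_target : float
        Sampling rate (Hz) the ECoG is decimated to before analysis.
    hg_band : tuple of float
        High-gamma band edges in Hz; the primary band of interest.
    extra_bands : dict
        Named additional bands (Hz pairs) for the band-specificity analysis.
    notch_bases : list of float
        Base frequencies (Hz) whose harmonics are notched out.
    n_rotations : int
        Number of random marker rotations in the loop permutation test.
    n_spins : int
        Number of random sphere rotations in the spatial spin test.
    alpha_level : float
        Two-tailed significance threshold used throughout.
    seed_radius_mm : float
        Radius of the spherical fMRI seed placed at each electrode.
    smooth_fwhm_mm : float
        Full-width-half-maximum of the Gaussian smoothing of connectivity maps.
    rng_seed : int
        Seed for every stochastic stage.
    """

    fs_target: float = 2000.0
    hg_band: tuple[float, float] = (70.0, 250.0)
    extra_bands: dict[str, tuple[float, float]] = field(default_factory=_default_extra_bands)
    notch_bases: list[float] = field(default_factory=lambda: [50.0, 79.0])
    n_rotations: int = 100_000
    n_spins: int = 10_000
    alpha_level: float = 0.05
    seed_radius_mm: float = 2.5
    smooth_fwhm_mm: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bands = {"hg": tuple(self.hg_band), **{k: tuple(v) for k, v in self.extra_bands.items()}}
        for name, (lo, hi) in bands.items():
            if not (0 <= lo < hi):
                raise ValueError(f"band {name!r}: need 0 <= low < high, got ({lo}, {hi})")
        for count_name in ("n_rotations", "n_spins"):
            if getattr(self, count_name) < 1:
                raise ValueError(f"{count_name} must be >= 1")
        if not 0.0 < self.alpha_level < 1.0:
            raise ValueError("alpha_level must lie strictly between 0 and 1")
        if self.fs_target <= 0:
            raise ValueError("fs_target must be positive")
        if self.seed_radius_mm <= 0 or self.smooth_fwhm_mm < 0:
            raise ValueError("seed_radius_mm must be > 0 and smooth_fwhm_mm >= 0")

    @property
    def all_bands(self) -> dict[str, tuple[float, float]]:
        """All analysis bands keyed by name, high gamma first."""
        return {"hg": tuple(self.hg_band), **{k: tuple(v) for k, v in self.extra_bands.items()}}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hg_band"] = list(self.hg_band)
        d["extra_bands"] = {k: list(v) for k, v in self.extra_bands.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "hg_band" in d:
            d["hg_band"] = tuple(d["hg_band"])
        if "extra_bands" in d:
            d["extra_bands"] = {k: tuple(v) for k, v in d["extra_bands"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def content_hash(self) -> str:
        """Short stable digest of the configuration, recorded in output headers."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
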