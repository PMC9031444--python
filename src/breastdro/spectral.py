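"""Chemical-shift spectral models for tissue classes.

Each tissue class carries a spectral model: a set of resonance peaks at
chemical-shift offsets (ppm relative to water) with relative amplitudes that
sum to one. Water is purely on-resonance (single peak at 0 ppm); fat uses a
multi-peak model of the triglyceride spectrum whose peak table ships as an
editable YAML config rather than hard-coded constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = ["SpectralModel", "water_spectrum", "default_fat_spectrum", "load_spectrum_yaml"]

_AMPLITUDE_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SpectralModel:
    """Resonance peaks as (offset_ppm, relative_amplitude) pairs.

    Amplitudes must be in (0, 1] and sum to 1 within 1e-9. A pure
    on-resonance species is the single peak (0.0, 1.0).
    """

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("spectral model needs at least one peak")
        peaks = tuple((float(p), float(a)) for p, a in self.peaks)
        for _, a in peaks:
            if not (0.0 < a <= 1.0):
                raise ValueError(f"peak amplitude {a} outside (0, 1]")
        total = sum(a for _, a in peaks)
        if abs(total - 1.0) > _AMPLITUDE_SUM_TOL:
            raise ValueError(f"peak amplitudes sum to {total}, expected 1")
        object.__setattr__(self, "peaks", peaks)

    @property
    def on_resonance(self) -> bool:
        return len(self.peaks) == 1 and self.peaks[0][0] == 0.0


def water_spectrum() -> SpectralModel:
    """Water: completely on-resonance."""
    return SpectralModel(peaks=((0.0, 1.0),))


def load_spectrum_yaml(path) -> SpectralModel:
    """Load a spectral model from a YAML file with a ``peaks`` list of
    ``{offset_ppm, amplitude}`` mappings. Amplitudes are renormalised to sum
    exactly to 1 so user-edited tables remain valid."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    raw = [(float(p["offset_ppm"]), float(p["amplitude"])) for p in doc["peaks"]]
    total = sum(a for _, a in raw)
    if total <= 0:
        raise ValueError("spectrum amplitudes must be positive")
    return SpectralModel(peaks=tuple((p, a / total) for p, a in raw))


def default_fat_spectrum() -> SpectralModel:
    """Nine-peak subcutaneous-fat spectral model (bundled config).

    Offsets are ppm relative to water (4.7 ppm); the dominant methylene
    peak sits at -3.4 ppm (about -217 Hz at 1.5 T), which sets the familiar
    2.2 / 4.2 ms opposed-/in-phase echo times.
    """
    ref = resources.files("breastdro") / "data" / "fat_spectrum_subcutaneous_9peak.yaml"
    with resources.as_file(ref) as path:
        return load_spectrum_yaml(path)
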